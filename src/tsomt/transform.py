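"""Two-stage transport map: brain → ball → cube, with resampling helpers.

The composed map f*_{ρ,δ} = f*_δ⁻¹ ∘ f*_ρ chains the brain→ball transport
map with the inverse of a precomputed cube→ball transport map (the cube
stage has constant density δ ≡ 1 and is case independent, so it is built
once per resolution and cached).  Because both stages preserve their local
measures, the composition carries ρ(τ)|τ| over to the image volume in the
cube, so dense (tumor-weighted) brain regions occupy proportionally more
cube voxels.

An optional rotation of the unit ball between the stages provides data
augmentation; mirror/rotation schemes of the cube and the probability vote
implement the test-time postprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import special_ortho_group

from .boundary import solve_boundary_omt
from .density import uniform_density
from .interior import HomotopySchedule, VolumetricMap, run_homotopy
from .mesh import BALL_VOLUME, TetMesh, locate_regular, normalize_mesh, \
    tetrahedralize

__all__ = [
    "ImageLocator",
    "CubeGrid",
    "build_cube_ball_map",
    "TSOMTMap",
    "compose",
    "cube_voxel_centers",
    "forward_resample",
    "inverse_labels",
    "apply_scheme",
    "invert_scheme",
    "vote",
    "random_ball_rotation",
]

CUBE_SIDE = BALL_VOLUME ** (1.0 / 3.0)   # side of the volume-4π/3 cube


class ImageLocator:
    """Point location in the (deformed) image of a tetrahedral mesh.

    A KD-tree over image-tet centroids proposes candidate tets; barycentric
    coordinates decide containment.  Queries outside every tet are snapped
    to the tet maximizing the minimum barycentric coordinate (expected only
    in a thin layer at the curved image boundary) and flagged.
    """

    def __init__(self, mesh: TetMesh, image: np.ndarray, bary_tol: float = 1e-9):
        self.mesh = mesh
        self.image = np.asarray(image, dtype=np.float64)
        self.bary_tol = bary_tol
        centroids = self.image[mesh.tets].mean(axis=1)
        self._tree = cKDTree(centroids)

    def locate(self, points: np.ndarray):
        """Return (tet ids, (n,4) barycentric coords, snapped flags)."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        n = len(pts)
        tet_ids = np.full(n, -1, dtype=np.int64)
        bary = np.zeros((n, 4))
        best_min = np.full(n, -np.inf)
        unresolved = np.arange(n)
        n_tets = self.mesh.n_tets
        for k in (8, 64, 512):
            k = min(k, n_tets)
            _, cand = self._tree.query(pts[unresolved], k=k)
            cand = np.atleast_2d(cand)
            b = self._bary_batch(pts[unresolved], cand)     # (m, k, 4)
            minb = b.min(axis=2)                            # (m, k)
            best = np.argmax(minb, axis=1)
            rows = np.arange(len(unresolved))
            better = minb[rows, best] > best_min[unresolved]
            upd = unresolved[better]
            tet_ids[upd] = cand[rows[better], best[better]]
            bary[upd] = b[rows[better], best[better]]
            best_min[upd] = minb[rows[better], best[better]]
            unresolved = unresolved[best_min[unresolved] < -self.bary_tol]
            if len(unresolved) == 0 or k == n_tets:
                break
        snapped = best_min < -self.bary_tol
        return tet_ids, bary, snapped

    def _bary_batch(self, pts: np.ndarray, cand: np.ndarray) -> np.ndarray:
        quads = self.image[self.mesh.tets[cand]]            # (m, k, 4, 3)
        mats = (quads[:, :, 1:] - quads[:, :, :1]).transpose(0, 1, 3, 2)
        rhs = pts[:, None, :] - quads[:, :, 0]
        det_ok = np.abs(np.linalg.det(mats)) > 1e-300
        sol = np.zeros_like(rhs)
        if det_ok.all():
            sol = np.linalg.solve(mats, rhs[..., None])[..., 0]
        else:
            safe = np.where(det_ok[..., None, None], mats,
                            np.eye(3)[None, None])
            sol = np.linalg.solve(safe, rhs[..., None])[..., 0]
            sol[~det_ok] = -np.inf
        return np.concatenate([1.0 - sol.sum(axis=2, keepdims=True), sol],
                              axis=2)

    def pull_back(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map image points back to source coordinates (inverse evaluation)."""
        tet_ids, bary, snapped = self.locate(points)
        src = np.einsum("nj,njk->nk", bary,
                        self.mesh.vertices[self.mesh.tets[tet_ids]])
        return src, snapped


_CUBE_CACHE: dict[tuple, VolumetricMap] = {}


def build_cube_ball_map(n: int = 24, schedule: HomotopySchedule | int = 8,
                        lam: float = 0.1, cache: bool = True,
                        inner_iterations: int = 2) -> VolumetricMap:
    """Transport map of an n³-cell Kuhn cube onto the unit ball (δ ≡ 1).

    The result is case independent, fully determined by (n, p, λ), and is
    cached in memory; the solvers use direct sparse factorizations, so a
    rebuild with the same inputs is bitwise identical.
    """
    if n < 8:
        raise ValueError("cube resolution n must be >= 8")
    p = schedule.p if isinstance(schedule, HomotopySchedule) else int(schedule)
    key = (n, p, lam, inner_iterations)
    if cache and key in _CUBE_CACHE:
        return _CUBE_CACHE[key]
    mask = np.ones((n, n, n), dtype=bool)
    mesh = normalize_mesh(tetrahedralize(mask))
    dens = uniform_density(mesh)
    bmap = solve_boundary_omt(mesh.boundary(), dens, lam=lam)
    vmap = run_homotopy(mesh, dens, bmap, HomotopySchedule(p),
                        inner_iterations=inner_iterations)
    vmap.diagnostics["boundary"] = bmap
    if cache:
        _CUBE_CACHE[key] = vmap
    return vmap


@dataclass
class TSOMTMap:
    """Composed two-stage map with forward/inverse point evaluation.

    ``forward`` sends brain-mesh coordinates to cube coordinates,
    ``inverse`` sends cube coordinates back to brain-mesh coordinates; both
    frames are the normalized ones (volume 4π/3, centred at the origin).
    ``stage1.mesh.to_voxel`` converts back to voxel coordinates.
    """

    stage1: VolumetricMap                # brain -> ball
    stage2: VolumetricMap                # cube -> ball
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    _loc1: ImageLocator | None = field(default=None, repr=False)
    _loc2: ImageLocator | None = field(default=None, repr=False)
    _src1: ImageLocator | None = field(default=None, repr=False)
    _pullback: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=np.float64)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-10) \
                or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthogonal with det +1")

    @property
    def loc1(self) -> ImageLocator:
        if self._loc1 is None:
            self._loc1 = ImageLocator(self.stage1.mesh, self.stage1.image)
        return self._loc1

    @property
    def loc2(self) -> ImageLocator:
        if self._loc2 is None:
            self._loc2 = ImageLocator(self.stage2.mesh, self.stage2.image)
        return self._loc2

    def forward(self, points: np.ndarray) -> np.ndarray:
        """Brain-mesh coordinates → cube coordinates."""
        mesh = self.stage1.mesh
        if mesh.regular:
            tet_ids, bary = locate_regular(mesh, points)
        else:
            if self._src1 is None:
                self._src1 = ImageLocator(mesh, mesh.vertices)
            tet_ids, bary, _ = self._src1.locate(points)
        ball = self.stage1.evaluate(tet_ids, bary)
        ball = ball @ self.rotation.T
        cube, _ = self.loc2.pull_back(ball)
        return cube

    def inverse(self, points: np.ndarray) -> np.ndarray:
        """Cube coordinates → brain-mesh coordinates."""
        tet_ids, bary = locate_regular(self.stage2.mesh, points)
        ball = self.stage2.evaluate(tet_ids, bary)
        ball = ball @ self.rotation
        brain, _ = self.loc1.pull_back(ball)
        return brain

    def pull_back_grid(self, n: int) -> np.ndarray:
        """Brain-voxel coordinates of all n³ cube voxel centres (cached)."""
        if n not in self._pullback:
            w = cube_voxel_centers(n)
            x_mesh = self.inverse(w)
            self._pullback[n] = self.stage1.mesh.to_voxel(x_mesh)
        return self._pullback[n]

    def composed_image(self) -> np.ndarray:
        """Cube-frame images of all brain-mesh vertices (per-tet volumes of
        the composed map are computed from these)."""
        ball = self.stage1.image @ self.rotation.T
        cube, _ = self.loc2.pull_back(ball)
        return cube


def compose(stage1: VolumetricMap, stage2: VolumetricMap,
            rotation: np.ndarray | None = None) -> TSOMTMap:
    """Compose the brain→ball and cube→ball stages into the brain→cube map."""
    R = np.eye(3) if rotation is None else rotation
    return TSOMTMap(stage1=stage1, stage2=stage2, rotation=R)


def cube_voxel_centers(n: int) -> np.ndarray:
    """Centres of the n³ voxels of the normalized cube, C-order flattened."""
    step = CUBE_SIDE / n
    ax = -CUBE_SIDE / 2.0 + (np.arange(n) + 0.5) * step
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)


@dataclass
class CubeGrid:
    """U-Net-ready n³ cube: 4 grayscale channels plus an integer label grid."""

    channels: np.ndarray                 # (n, n, n, 4) in [0, 1]
    labels: np.ndarray                   # (n, n, n) ints in {0,1,2,3}
    n: int
    provenance: dict = field(default_factory=dict)


def forward_resample(grayscale: np.ndarray, labels: np.ndarray,
                     tmap: TSOMTMap, n: int = 128) -> CubeGrid:
    """Sample the brain volume on the cube grid through the inverse map.

    Every cube voxel centre w is pulled back to brain coordinates; grayscale
    channels are trilinear samples there and the label is that of the
    containing brain voxel (nearest voxel, no interpolation).  One shared
    map serves all four modalities.
    """
    from scipy.ndimage import map_coordinates

    grayscale = np.asarray(grayscale, dtype=np.float64)
    if grayscale.ndim == 3:
        grayscale = grayscale[..., None]
    x_vox = tmap.pull_back_grid(n)
    coords = x_vox.T
    nch = grayscale.shape[-1]
    channels = np.empty((n ** 3, nch))
    for c in range(nch):
        channels[:, c] = map_coordinates(grayscale[..., c], coords,
                                         order=1, mode="nearest")
    idx = np.rint(x_vox).astype(np.int64)
    np.clip(idx, 0, np.asarray(labels.shape) - 1, out=idx)
    lab = np.asarray(labels)[idx[:, 0], idx[:, 1], idx[:, 2]]
    return CubeGrid(channels=channels.reshape(n, n, n, nch),
                    labels=lab.reshape(n, n, n).astype(np.int8), n=n,
                    provenance={"n": n})


def inverse_labels(cube_labels: np.ndarray, tmap: TSOMTMap,
                   brain_shape: tuple[int, int, int],
                   mask: np.ndarray | None = None) -> np.ndarray:
    """Convert cube labels back to the brain voxel grid (two-rule procedure).

    Rule (a): a brain voxel receiving pulled-back cube voxel centres takes
    their majority label (ties towards the larger, i.e. tumor-preserving,
    label).  Rule (b): every remaining brain-mask voxel takes the label of
    the cube centre whose pulled-back point is nearest to the voxel centre.
    Voxels outside the mask stay 0.
    """
    cube_labels = np.asarray(cube_labels)
    n = cube_labels.shape[0]
    if mask is None:
        mask = tmap.stage1.mesh.grid_mask
        if mask.shape != tuple(brain_shape):
            raise ValueError("mesh grid is coarsened; pass the full-resolution mask")
    x_vox = tmap.pull_back_grid(n)
    lab_flat = cube_labels.ravel()

    idx = np.rint(x_vox).astype(np.int64)
    np.clip(idx, 0, np.asarray(brain_shape) - 1, out=idx)
    flat = np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), brain_shape)

    nvox = int(np.prod(brain_shape))
    counts = np.zeros((nvox, 4), dtype=np.int32)
    np.add.at(counts, (flat, lab_flat.astype(np.int64)), 1)
    received = counts.sum(axis=1) > 0
    # majority with ties resolved towards the larger label: scan 3 -> 0
    out = np.zeros(nvox, dtype=np.int8)
    best = np.full(nvox, -1, dtype=np.int32)
    for lbl in (3, 2, 1, 0):
        better = counts[:, lbl] > best
        out[better] = lbl
        best = np.maximum(best, counts[:, lbl])
    out[~received] = 0

    mask_flat = np.asarray(mask, dtype=bool).ravel()
    rest = np.flatnonzero(mask_flat & ~received)
    if len(rest):
        centers = np.stack(np.unravel_index(rest, brain_shape), axis=1)
        tree = cKDTree(x_vox)
        _, j = tree.query(centers.astype(np.float64))
        out[rest] = lab_flat[j]
    out[~mask_flat] = 0
    return out.reshape(brain_shape)


def apply_scheme(cube: np.ndarray, k: int) -> np.ndarray:
    """Mirror/rotation schemes R₁–R₄ acting slice-wise on the first two axes.

    R₁: 90° counterclockwise quarter turn; R₂: left-right mirror (second
    axis); R₃: up-down mirror (first axis); R₄: R₂ followed by R₁.
    """
    if k == 1:
        return np.rot90(cube, 1, axes=(0, 1))
    if k == 2:
        return np.flip(cube, axis=1)
    if k == 3:
        return np.flip(cube, axis=0)
    if k == 4:
        return np.rot90(np.flip(cube, axis=1), 1, axes=(0, 1))
    raise ValueError("scheme index k must be in {1, 2, 3, 4}")


def invert_scheme(cube: np.ndarray, k: int) -> np.ndarray:
    """Exact inverse of :func:`apply_scheme`."""
    if k == 1:
        return np.rot90(cube, -1, axes=(0, 1))
    if k == 2:
        return np.flip(cube, axis=1)
    if k == 3:
        return np.flip(cube, axis=0)
    if k == 4:
        return np.flip(np.rot90(cube, -1, axes=(0, 1)), axis=1)
    raise ValueError("scheme index k must be in {1, 2, 3, 4}")


def vote(prob_maps, rule: str = "printed") -> np.ndarray:
    """Combine five probability cubes p₀..p₄ into a tumor/healthy decision.

    ``rule='printed'`` keeps the literal inequality Σ p_k > 1 − Σ p_k (i.e.
    Σ p_k > ½, a low effective threshold); ``rule='mean'`` uses the
    mean-majority variant Σ p_k > 5/2.  Probability maps must already be
    mapped back to the reference orientation via :func:`invert_scheme`.
    """
    probs = [np.asarray(p, dtype=np.float64) for p in prob_maps]
    if len({p.shape for p in probs}) != 1:
        raise ValueError("probability cubes must share one shape")
    total = np.sum(probs, axis=0)
    if rule == "printed":
        return total > 0.5
    if rule == "mean":
        return total > len(probs) / 2.0
    raise ValueError(f"unknown vote rule {rule!r}")


def random_ball_rotation(seed: int) -> np.ndarray:
    """Uniformly distributed rotation matrix (det +1), reproducible by seed."""
    rng = np.random.default_rng(seed)
    return special_ortho_group.rvs(3, random_state=rng)
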