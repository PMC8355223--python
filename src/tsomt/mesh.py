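"""Voxel masks and tetrahedral meshes of genus-zero solids.

A masked voxel volume is turned into a conforming tetrahedral mesh by
splitting every unit voxel cell into six positively oriented tetrahedra
along a globally fixed diagonal (the Kuhn/Freudenthal split), so shared
faces match across neighbouring cells.  The mesh is then centred at its
volume-weighted centroid and scaled to total volume 4π/3, the canonical
normalization for the ball-target transport solves.

Coordinate convention: voxel centres sit at integer coordinates, 0-based,
axis order (x, y, z); cell corners therefore sit at half-integers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "MeshTopologyError",
    "TetMesh",
    "SurfaceMesh",
    "voxel_mask",
    "ensure_genus_zero",
    "coarsen_mask",
    "tetrahedralize",
    "normalize_mesh",
    "boundary_surface",
    "smooth_mesh",
    "collapse_pinned_tets",
    "build_solid_mesh",
]

BALL_VOLUME = 4.0 * np.pi / 3.0

# The six Kuhn tetrahedra of a unit cell, one per permutation of the axes.
# Tet #m covers the points whose fractional coordinates satisfy
# f[perm[0]] >= f[perm[1]] >= f[perm[2]].
_PERMS = tuple(itertools.permutations((0, 1, 2)))


def _perm_corner_offsets() -> np.ndarray:
    """(6, 4, 3) integer corner offsets of the six Kuhn tets, positively oriented."""
    out = np.zeros((6, 4, 3), dtype=np.int64)
    for m, perm in enumerate(_PERMS):
        p0 = np.zeros(3, dtype=np.int64)
        p1 = p0.copy()
        p1[perm[0]] = 1
        p2 = p1.copy()
        p2[perm[1]] = 1
        p3 = np.ones(3, dtype=np.int64)
        quad = [p0, p1, p2, p3]
        # odd permutations give negative orientation; swap the last two corners
        sign = 1
        for a in range(3):
            for b in range(a + 1, 3):
                if perm[a] > perm[b]:
                    sign = -sign
        if sign < 0:
            quad[2], quad[3] = quad[3], quad[2]
        out[m] = np.stack(quad)
    return out


_KUHN_OFFSETS = _perm_corner_offsets()

# oriented (outward) faces of a positively oriented tet (0,1,2,3),
# listed opposite vertex 0,1,2,3 respectively
_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]], dtype=np.int64)

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


class MeshTopologyError(ValueError):
    """The voxel set does not bound a closed genus-zero surface."""


@dataclass
class SurfaceMesh:
    """Closed oriented boundary surface of a :class:`TetMesh`.

    ``vertex_map`` maps surface-vertex indices into volume-vertex indices;
    ``triangles`` are outward oriented and indexed in surface numbering.
    """

    vertices: np.ndarray          # (nB, 3)
    triangles: np.ndarray         # (F, 3) surface-local indices
    vertex_map: np.ndarray        # (nB,) into the parent mesh

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def edges(self) -> np.ndarray:
        e = np.concatenate([self.triangles[:, [0, 1]],
                            self.triangles[:, [1, 2]],
                            self.triangles[:, [2, 0]]])
        return np.unique(np.sort(e, axis=1), axis=0)

    def areas(self, points: np.ndarray | None = None) -> np.ndarray:
        p = self.vertices if points is None else points
        a, b, c = (p[self.triangles[:, i]] for i in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + len(self.triangles)


@dataclass
class TetMesh:
    """Tetrahedral mesh with positively oriented tets.

    For meshes built from a voxel mask, ``grid_mask`` and the derived lookup
    tables enable O(1) point location (voxel cell -> Kuhn tet), and
    ``center``/``scale`` record the normalizing affine transform
    ``x_mesh = (x_voxel - center) * scale``.
    """

    vertices: np.ndarray                     # (V, 3) float64
    tets: np.ndarray                         # (T, 4) int64
    grid_mask: np.ndarray | None = None      # (X, Y, Z) bool
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: float = 1.0
    grid_step: int = 1                       # mask-grid cell size in voxels
    smoothed: bool = False                   # vertices moved off the grid
    _boundary: SurfaceMesh | None = field(default=None, repr=False)
    _mask_flat: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    @property
    def regular(self) -> bool:
        """True when the mesh still is the unmodified Kuhn grid mesh."""
        return self._mask_flat is not None and not self.smoothed

    def tet_volumes(self, points: np.ndarray | None = None) -> np.ndarray:
        """Signed volumes of all tets (positive for the stored orientation)."""
        p = self.vertices if points is None else points
        v0, v1, v2, v3 = (p[self.tets[:, i]] for i in range(4))
        return np.einsum("ij,ij->i", np.cross(v1 - v0, v2 - v0), v3 - v0) / 6.0

    def volume(self) -> float:
        return float(self.tet_volumes().sum())

    def edges(self) -> np.ndarray:
        pairs = [[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]]
        e = np.concatenate([self.tets[:, p] for p in pairs])
        return np.unique(np.sort(e, axis=1), axis=0)

    def boundary(self) -> SurfaceMesh:
        if self._boundary is None:
            self._boundary = boundary_surface(self)
        return self._boundary

    def to_grid(self, points: np.ndarray) -> np.ndarray:
        """Map mesh coordinates back to mask-grid cell coordinates."""
        return np.asarray(points) / self.scale + self.center

    def to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map mesh coordinates back to original voxel coordinates.

        When the mask was block-coarsened by ``grid_step``, one grid cell
        spans ``grid_step`` voxels and the two frames differ by an affine.
        """
        g = self.to_grid(points)
        if self.grid_step == 1:
            return g
        return g * self.grid_step + (self.grid_step - 1) / 2.0

    def from_voxel(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=np.float64)
        if self.grid_step != 1:
            p = (p - (self.grid_step - 1) / 2.0) / self.grid_step
        return (p - self.center) * self.scale


def voxel_mask(grayscale: np.ndarray, min_intensity: float = 0.0) -> np.ndarray:
    """Foreground mask: any modality above threshold, cleaned to genus zero.

    ``grayscale`` is (X, Y, Z) or (X, Y, Z, modalities).  Keeps the largest
    6-connected component, morphologically closes small gaps and fills
    internal cavities so the boundary surface is a topological sphere.
    """
    g = np.asarray(grayscale)
    fg = (g > min_intensity) if g.ndim == 3 else (g > min_intensity).any(axis=-1)
    if not fg.any():
        raise ValueError("no foreground: mask empty after thresholding")
    labels, n = ndimage.label(fg, structure=_FACE_STRUCT)
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        fg = labels == np.argmax(counts)
    return ensure_genus_zero(fg)


def _mask_is_genus_zero(mask: np.ndarray) -> bool:
    try:
        mesh = tetrahedralize(mask, check=True)
    except MeshTopologyError:
        return False
    return mesh.boundary().euler_characteristic() == 2


def _repair_nonmanifold(mask: np.ndarray, max_sweeps: int = 20) -> np.ndarray:
    """Fill diagonal checkerboard configurations that pinch the boundary.

    Two voxels meeting only along an edge (a 2×2 plaquette with one filled
    diagonal) or only at a corner (a 2×2×2 block with one filled space
    diagonal) make the boundary surface non-manifold.  Filling one empty
    voxel of each such configuration resolves it; the operation only adds
    voxels, so the sweep terminates.
    """
    m = mask.copy()
    for _ in range(max_sweeps):
        changed = False
        for a, b in ((0, 1), (0, 2), (1, 2)):
            sl = [slice(None)] * 3

            def plaq(da, db):
                s = list(sl)
                s[a] = slice(1, None) if da else slice(None, -1)
                s[b] = slice(1, None) if db else slice(None, -1)
                return m[tuple(s)]

            p00, p01, p10, p11 = plaq(0, 0), plaq(0, 1), plaq(1, 0), plaq(1, 1)
            bad = p00 & p11 & ~p01 & ~p10
            if bad.any():
                p01 |= bad
                changed = True
            bad = p01 & p10 & ~p00 & ~p11
            if bad.any():
                p00 |= bad
                changed = True
        # corner-touching space diagonals of the 2x2x2 block
        def _s(d):
            return slice(1, None) if d else slice(None, -1)

        c = [m[_s(dx), _s(dy), _s(dz)]
             for dx in (0, 1) for dy in (0, 1) for dz in (0, 1)]
        others = lambda i, j: [k for k in range(8) if k not in (i, j)]  # noqa: E731
        for i, j in ((0, 7), (1, 6), (2, 5), (3, 4)):
            bad = c[i] & c[j]
            for k in others(i, j):
                bad = bad & ~c[k]
            if bad.any():
                c[others(i, j)[0]] |= bad
                changed = True
        if not changed:
            return m
    return m


def ensure_genus_zero(mask: np.ndarray) -> np.ndarray:
    """Repair a mask by closing/dilation + cavity filling until its boundary
    is a topological sphere (escalating morphological strength)."""
    repairs = [None,
               lambda m: ndimage.binary_closing(m, structure=_FACE_STRUCT),
               lambda m: ndimage.binary_closing(m, structure=_FACE_STRUCT,
                                                iterations=2),
               lambda m: ndimage.binary_dilation(m, structure=_FACE_STRUCT),
               lambda m: ndimage.binary_closing(
                   ndimage.binary_dilation(m, structure=_FACE_STRUCT),
                   structure=_FACE_STRUCT),
               lambda m: ndimage.binary_dilation(m, structure=_FACE_STRUCT,
                                                 iterations=2)]
    m = mask.astype(bool).copy()
    for repair in repairs:
        if repair is not None:
            m = np.pad(m, 2)
            m = repair(m)[2:-2, 2:-2, 2:-2]
        m = _repair_nonmanifold(m)
        m = ndimage.binary_fill_holes(m, structure=_FACE_STRUCT)
        labels, n = ndimage.label(m, structure=_FACE_STRUCT)
        if n > 1:
            counts = np.bincount(labels.ravel())
            counts[0] = 0
            m = labels == np.argmax(counts)
        if _mask_is_genus_zero(m):
            return m
    raise MeshTopologyError(
        "mask boundary is not genus zero after closing/dilation repair")


def coarsen_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    """Block-downsample a mask by ``factor`` with a majority rule (tie -> filled)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return mask.astype(bool).copy()
    m = np.asarray(mask, dtype=bool)
    pad = [(0, (-s) % factor) for s in m.shape]
    m = np.pad(m, pad)
    sx, sy, sz = (s // factor for s in m.shape)
    blocks = m.reshape(sx, factor, sy, factor, sz, factor)
    counts = blocks.sum(axis=(1, 3, 5))
    out = 2 * counts >= factor ** 3
    if not out.any():
        raise ValueError("downsampling emptied the mask")
    return ensure_genus_zero(out)


def auto_coarsen(mask: np.ndarray, max_vertices: int = 250_000) -> tuple[np.ndarray, int]:
    """Smallest factor whose mesh has at most ``max_vertices`` vertices."""
    factor = 1
    while True:
        m = coarsen_mask(mask, factor)
        # vertex count of the Kuhn mesh = number of distinct cell corners
        n_vert = _corner_count(m)
        if n_vert <= max_vertices:
            return m, factor
        factor += 1


def _corner_count(mask: np.ndarray) -> int:
    used = np.zeros(tuple(s + 1 for s in mask.shape), dtype=bool)
    idx = np.argwhere(mask)
    for off in itertools.product((0, 1), repeat=3):
        used[tuple((idx + off).T)] = True
    return int(used.sum())


def tetrahedralize(mask: np.ndarray, check: bool = True) -> TetMesh:
    """Kuhn 6-tet split of every masked voxel cell into a conforming mesh.

    Vertices sit at cell corners (half-integer coordinates); the total mesh
    volume equals the number of masked voxels exactly.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    shape = mask.shape
    cshape = tuple(s + 1 for s in shape)
    vox = np.argwhere(mask)                       # (N, 3) voxel indices

    corner_used = np.zeros(cshape, dtype=bool)
    for off in itertools.product((0, 1), repeat=3):
        corner_used[tuple((vox + off).T)] = True
    corner_id = np.cumsum(corner_used.ravel()).reshape(cshape) - 1
    corner_id[~corner_used] = -1

    cx, cy, cz = np.nonzero(corner_used)
    vertices = np.stack([cx, cy, cz], axis=1).astype(np.float64) - 0.5

    n = len(vox)
    tets = np.empty((6 * n, 4), dtype=np.int64)
    for m in range(6):
        for j in range(4):
            off = _KUHN_OFFSETS[m, j]
            tets[m::6, j] = corner_id[vox[:, 0] + off[0],
                                      vox[:, 1] + off[1],
                                      vox[:, 2] + off[2]]

    mesh = TetMesh(vertices=vertices, tets=tets, grid_mask=mask,
                   _mask_flat=np.flatnonzero(mask.ravel()))
    if check:
        surf = mesh.boundary()
        if surf.euler_characteristic() != 2:
            raise MeshTopologyError(
                f"boundary Euler characteristic "
                f"{surf.euler_characteristic()} != 2 (non genus-zero mask)")
    return mesh


def boundary_surface(mesh: TetMesh) -> SurfaceMesh:
    """Outward-oriented boundary triangles (faces of tet-multiplicity one)."""
    faces = mesh.tets[:, _TET_FACES.reshape(-1)].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    order = np.lexsort(key.T[::-1])
    skey = key[order]
    first = np.ones(len(skey), dtype=bool)
    first[1:] = (skey[1:] != skey[:-1]).any(axis=1)
    grp = np.cumsum(first) - 1
    counts = np.bincount(grp)
    boundary_rows = order[np.isin(grp, np.flatnonzero(counts == 1))]
    btris = faces[boundary_rows]
    if len(btris) == 0:
        raise MeshTopologyError("mesh has no boundary faces")

    # each boundary edge must be shared by exactly two boundary triangles
    e = np.concatenate([btris[:, [0, 1]], btris[:, [1, 2]], btris[:, [2, 0]]])
    e = np.sort(e, axis=1)
    _, ecounts = np.unique(e, axis=0, return_counts=True)
    if not np.all(ecounts == 2):
        raise MeshTopologyError("boundary surface is not closed/manifold")

    bverts = np.unique(btris)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[bverts] = np.arange(len(bverts))
    return SurfaceMesh(vertices=mesh.vertices[bverts],
                       triangles=remap[btris],
                       vertex_map=bverts)


def normalize_mesh(mesh: TetMesh) -> TetMesh:
    """Centre at the volume-weighted centroid and rescale to volume 4π/3.

    The affine parameters are stored on the result (``center``, ``scale``)
    so original voxel coordinates can be restored exactly.
    """
    vols = mesh.tet_volumes()
    total = vols.sum()
    if total <= 0:
        raise ValueError("mesh has non-positive volume")
    tet_centroids = mesh.vertices[mesh.tets].mean(axis=1)
    center = (tet_centroids * vols[:, None]).sum(axis=0) / total
    scale = (BALL_VOLUME / total) ** (1.0 / 3.0)
    verts = (mesh.vertices - center) * scale
    new_center = mesh.center + center / mesh.scale
    out = TetMesh(vertices=verts, tets=mesh.tets, grid_mask=mesh.grid_mask,
                  center=new_center, scale=mesh.scale * scale,
                  grid_step=mesh.grid_step, _mask_flat=mesh._mask_flat)
    return out


def smooth_mesh(mesh: TetMesh, rounds: int = 30, lam: float = 0.4,
                sweeps: int = 10, eps: float = 1e-5,
                max_damp: int = 25) -> TetMesh:
    """Round off the voxel-staircase boundary (grid-coarsening remesh analogue).

    Each round takes one Laplacian smoothing step of the boundary vertices
    along the surface graph, relaxes the interior by Jacobi averaging
    sweeps, and then locally damps the displacement of any vertex incident
    to a tetrahedron whose volume would drop below ``eps`` (grid units) —
    so smoothing proceeds everywhere except exactly where it would invert
    an element.  Without this step the staircase creases produce wedge
    tetrahedra whose spherical images have orientation fixed by the convex
    target, not by the source: concave ("valley") wedges fold no matter how
    well the transport converges.  Smoothing turns almost all of them
    convex; the few wedges stuck against the positivity floor are removed
    by :func:`collapse_slivers`.
    """
    import scipy.sparse as sp

    surf = mesh.boundary()
    nB = surf.n_vertices
    e = surf.edges()
    sadj = sp.coo_matrix((np.ones(2 * len(e)),
                          (np.concatenate([e[:, 0], e[:, 1]]),
                           np.concatenate([e[:, 1], e[:, 0]]))),
                         shape=(nB, nB)).tocsr()
    sdeg = np.asarray(sadj.sum(axis=1)).ravel()[:, None]

    n = mesh.n_vertices
    B = surf.vertex_map
    interior = np.ones(n, dtype=bool)
    interior[B] = False
    edges = mesh.edges()
    adj = sp.coo_matrix((np.ones(2 * len(edges)),
                         (np.concatenate([edges[:, 0], edges[:, 1]]),
                          np.concatenate([edges[:, 1], edges[:, 0]]))),
                        shape=(n, n)).tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()[:, None]

    tets = mesh.tets

    def volumes(p):
        v0, v1, v2, v3 = (p[tets[:, i]] for i in range(4))
        return np.einsum("ij,ij->i", np.cross(v1 - v0, v2 - v0), v3 - v0) / 6.0

    pos = mesh.vertices.copy()
    for _ in range(rounds):
        cand = pos.copy()
        cand[B] = pos[B] + lam * (sadj @ pos[B] / sdeg - pos[B])
        for _ in range(sweeps):
            avg = adj @ cand / deg
            cand[interior] = avg[interior]
        for _ in range(max_damp):
            bad = volumes(cand) <= eps
            if not bad.any():
                break
            badv = np.unique(tets[bad])
            cand[badv] = 0.5 * (cand[badv] + pos[badv])
        still = volumes(cand) <= 0
        if still.any():
            cand[np.unique(tets[still])] = pos[np.unique(tets[still])]
        pos = cand

    return TetMesh(vertices=pos, tets=tets, grid_mask=mesh.grid_mask,
                   center=mesh.center, scale=mesh.scale,
                   grid_step=mesh.grid_step, smoothed=True,
                   _mask_flat=mesh._mask_flat)


def collapse_pinned_tets(mesh: TetMesh, max_passes: int = 40) -> TetMesh:
    """Collapse every tetrahedron whose four vertices all lie on the boundary.

    The image of such a "pinned" tet is dictated entirely by the boundary
    map; on the convex spherical target its orientation follows the local
    in-sphere configuration, not the source, so pinned wedges across
    concave creases fold no matter how well the transport converges.  Each
    pass collapses one edge of every pinned tet (trying all directed edges
    and, as a fallback, moving the surviving endpoint to the edge midpoint)
    whenever all surviving remapped tets stay positively oriented, and
    repeats until no pinned tet remains.  Best applied to a smoothed mesh,
    followed by a light re-smoothing pass; the result is a valid conforming
    mesh without the grid lookup tables.
    """
    verts = mesh.vertices.copy()
    tets = mesh.tets.copy()
    n = len(verts)

    def volumes_at(t, u, upos):
        pts = verts[t]                     # (m, 4, 3)
        pts[t == u] = upos
        v0, v1, v2, v3 = pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3]
        return np.einsum("ij,ij->i", np.cross(v1 - v0, v2 - v0), v3 - v0) / 6.0

    for _ in range(max_passes):
        faces = tets[:, _TET_FACES.reshape(-1)].reshape(-1, 3)
        key = np.sort(faces, axis=1)
        uniq, counts = np.unique(key, axis=0, return_counts=True)
        bnd = np.zeros(n, dtype=bool)
        bnd[np.unique(uniq[counts == 1])] = True
        pinned = np.flatnonzero(bnd[tets].all(axis=1))
        if len(pinned) == 0:
            break
        order = np.argsort(tets.ravel(), kind="stable")
        flat_tet = order // 4
        starts = np.searchsorted(tets.ravel()[order], np.arange(n + 1))
        dirty = np.zeros(n, dtype=bool)
        progress = False
        for t_id in pinned:
            quad = tets[t_id]
            if quad[0] < 0 or dirty[quad].any():
                continue
            # shortest edges first: collapsing them perturbs the mesh least
            cand = sorted((np.linalg.norm(verts[quad[a]] - verts[quad[b]]), a, b)
                          for a in range(4) for b in range(4) if a != b)
            done = False
            for _, a, b in cand:
                v, u = int(quad[a]), int(quad[b])
                inc = np.unique(np.concatenate(
                    [flat_tet[starts[v]:starts[v + 1]],
                     flat_tet[starts[u]:starts[u + 1]]]))
                inc = inc[(tets[inc] >= 0).all(axis=1)]
                mod = tets[inc].copy()
                mod[mod == v] = u
                s = np.sort(mod, axis=1)
                degen = (s[:, :-1] == s[:, 1:]).any(axis=1)
                surv = mod[~degen]
                pos_ok = None
                for trial in (0.5 * (verts[u] + verts[v]), verts[u]):
                    if len(surv) == 0 or volumes_at(surv, u, trial).min() > 1e-9:
                        pos_ok = trial
                        break
                if pos_ok is None:
                    continue
                verts[u] = pos_ok
                tets[inc] = mod
                tets[inc[degen]] = -1
                dirty[np.unique(mod)] = True
                dirty[v] = True
                progress = done = True
                break
            if not done:
                dirty[quad] = True
        tets = tets[(tets >= 0).all(axis=1)]
        if not progress:
            break
    used = np.zeros(n, dtype=bool)
    used[np.unique(tets)] = True
    remap = np.cumsum(used) - 1
    out = TetMesh(vertices=verts[used], tets=remap[tets],
                  grid_mask=mesh.grid_mask, center=mesh.center,
                  scale=mesh.scale, grid_step=mesh.grid_step,
                  smoothed=mesh.smoothed, _mask_flat=None)
    out.boundary()                       # validates closed manifold boundary
    return out


def build_solid_mesh(mask: np.ndarray, smooth_rounds: int = 30,
                     post_rounds: int = 10) -> TetMesh:
    """Mask → normalized solver-ready mesh (the remeshing pipeline).

    Kuhn tetrahedralization, boundary smoothing, pinned-tet collapse, light
    re-smoothing, then centring/scaling to volume 4π/3.  This is the mesh
    preparation used by the case pipeline before the transport solves.
    """
    mesh = tetrahedralize(mask)
    if smooth_rounds > 0:
        mesh = smooth_mesh(mesh, rounds=smooth_rounds)
    mesh = collapse_pinned_tets(mesh)
    if post_rounds > 0:
        mesh = smooth_mesh(mesh, rounds=post_rounds)
    return normalize_mesh(mesh)


def locate_regular(mesh: TetMesh, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Point location in a voxel-grid Kuhn mesh (mesh coordinates).

    Returns (tet ids, (n,4) barycentric coordinates).  Points outside the
    mask are assigned to the tet of the nearest masked voxel cell.
    """
    if mesh.grid_mask is None:
        raise ValueError("mesh was not built from a voxel grid")
    mask = mesh.grid_mask
    pts_vox = mesh.to_grid(np.atleast_2d(points))
    cell = np.floor(pts_vox + 0.5).astype(np.int64)
    np.clip(cell, 0, np.asarray(mask.shape) - 1, out=cell)
    outside = ~mask[cell[:, 0], cell[:, 1], cell[:, 2]]
    if outside.any():
        # snap to nearest masked cell (expected only in a thin boundary layer)
        from scipy.spatial import cKDTree
        occ = np.argwhere(mask)
        tree = cKDTree(occ)
        _, j = tree.query(pts_vox[outside])
        cell[outside] = occ[j]
    frac = pts_vox - (cell - 0.5)
    np.clip(frac, 0.0, 1.0, out=frac)
    # Kuhn tet index = rank permutation of the fractional coordinates
    perm = np.argsort(-frac, axis=1, kind="stable")
    perm_code = perm[:, 0] * 2 + (perm[:, 1] > perm[:, 2])
    # map (first_axis, second>third) to index in _PERMS ordering
    code_to_m = np.empty(6, dtype=np.int64)
    for m, p in enumerate(_PERMS):
        code_to_m[p[0] * 2 + (p[1] > p[2])] = m
    tet_in_cell = code_to_m[perm_code]
    flat = np.ravel_multi_index((cell[:, 0], cell[:, 1], cell[:, 2]), mask.shape)
    vox_rank = np.searchsorted(mesh._mask_flat, flat)
    tet_ids = vox_rank * 6 + tet_in_cell
    bary = barycentric(mesh, tet_ids, np.atleast_2d(points))
    return tet_ids, bary


def barycentric(mesh: TetMesh, tet_ids: np.ndarray, points: np.ndarray,
                image: np.ndarray | None = None) -> np.ndarray:
    """Barycentric coordinates of ``points`` in the given tets."""
    p = mesh.vertices if image is None else image
    quads = p[mesh.tets[tet_ids]]                 # (n, 4, 3)
    mats = (quads[:, 1:] - quads[:, :1]).transpose(0, 2, 1)   # (n, 3, 3)
    rhs = points - quads[:, 0]
    sol = np.linalg.solve(mats, rhs[..., None])[..., 0]
    return np.concatenate([1.0 - sol.sum(axis=1, keepdims=True), sol], axis=1)
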