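"""Interior mass-transport map M → B³ by homotopy continuation.

Given the spherical boundary map g, the boundary is swept along the homotopy
g_t(v) = (1−t) v + t g(v) over a uniform schedule t_k = k/p, and at each knot
the interior vertices solve the linear system

    [L_V(f^(k−1))]_II f^(k)_I = −[L_V(f^(k−1))]_IB g_{t_k},

where L_V(f) is the mass-weighted Laplacian with modified cotangent weights

    w_ij(f) = 1/9 Σ_τ |f([v_i,v_k,v_ℓ])| |f([v_j,v_ℓ,v_k])| cos θ / (ρ(τ)|τ|),

θ being the dihedral angle between the two image faces opposite the edge
(i, j) inside the image tetrahedron.  Starting from the identity, f^(p) is
the desired density-weighted transport map into the unit ball.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .density import DensityField
from .mesh import TetMesh

__all__ = [
    "HomotopySchedule",
    "VolumetricMap",
    "mass_weight",
    "mass_laplacian",
    "solve_interior_step",
    "run_homotopy",
]

# (i, j | k, l) slot patterns: each unordered edge of a tet with its opposite edge
_EDGE_PATTERNS = ((0, 1, 2, 3), (0, 2, 1, 3), (0, 3, 1, 2),
                  (1, 2, 0, 3), (1, 3, 0, 2), (2, 3, 0, 1))


@dataclass
class HomotopySchedule:
    """Uniform partition 0 = t_0 < t_1 < ... < t_p = 1."""

    p: int = 8

    def __post_init__(self):
        if self.p < 1:
            raise ValueError("p must be a positive integer")

    @property
    def knots(self) -> np.ndarray:
        return np.arange(self.p + 1) / self.p


@dataclass
class VolumetricMap:
    """Piecewise-linear simplicial map given by per-vertex image points."""

    mesh: TetMesh
    image: np.ndarray                    # (V, 3)
    density: DensityField | None = None
    diagnostics: dict = field(default_factory=dict)

    def image_volumes(self) -> np.ndarray:
        """Signed image volumes |f(τ)| under the source orientation."""
        return self.mesh.tet_volumes(self.image)

    def folded_count(self) -> int:
        return int(np.count_nonzero(self.image_volumes() <= 0))

    def evaluate(self, tet_ids: np.ndarray, bary: np.ndarray) -> np.ndarray:
        """Evaluate the map at located points (barycentric pull-forward)."""
        return np.einsum("nj,njk->nk", bary, self.image[self.mesh.tets[tet_ids]])


def homotopy_boundary(surface_vertices: np.ndarray, g: np.ndarray,
                      t: float) -> np.ndarray:
    """Convex combination g_t(v) = (1−t) v + t g(v) on the boundary."""
    if not 0.0 <= t <= 1.0:
        raise ValueError("t must lie in [0, 1]")
    return (1.0 - t) * surface_vertices + t * g


def _edge_weight_terms(mesh: TetMesh, density: DensityField,
                       image: np.ndarray):
    """Yield (i, j, w) contributions of all six edge slots of every tet."""
    tets = mesh.tets
    vols = mesh.tet_volumes()
    mass = density.rho_tet * vols
    if np.any(mass <= 0):
        raise ValueError("non-positive source tet mass rho(tau)|tau|")
    p = image[tets]                      # (T, 4, 3)
    for (si, sj, sk, sl) in _EDGE_PATTERNS:
        fi, fj, fk, fl = p[:, si], p[:, sj], p[:, sk], p[:, sl]
        na = 0.5 * np.cross(fk - fi, fl - fi)    # vector area of f([i,k,l])
        nb = 0.5 * np.cross(fl - fj, fk - fj)    # vector area of f([j,l,k])
        # orient both outward (away from the opposite vertex)
        sa = -np.sign(np.einsum("ij,ij->i", na, fj - fi))
        sb = -np.sign(np.einsum("ij,ij->i", nb, fi - fj))
        sa[sa == 0] = 1.0
        sb[sb == 0] = 1.0
        # |A1||A2| cos(theta) = -(na_out . nb_out) for the interior dihedral
        num = -np.einsum("ij,ij->i", na, nb) * sa * sb
        yield tets[:, si], tets[:, sj], num / (9.0 * mass)


def mass_weight(mesh: TetMesh, density: DensityField, image: np.ndarray,
                i: int, j: int) -> float:
    """Modified cotangent weight w_ij(f) of a single edge (for inspection)."""
    total = 0.0
    for ii, jj, w in _edge_weight_terms(mesh, density, image):
        total += w[(ii == i) & (jj == j)].sum()
        total += w[(ii == j) & (jj == i)].sum()
    return float(total)


def mass_laplacian(mesh: TetMesh, density: DensityField,
                   image: np.ndarray) -> sp.csr_matrix:
    """Mass-weighted Laplacian L_V(f): symmetric with zero row sums."""
    n = mesh.n_vertices
    rows, cols, vals = [], [], []
    for i, j, w in _edge_weight_terms(mesh, density, image):
        rows += [i, j]
        cols += [j, i]
        vals += [-w, -w]
    L = sp.coo_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(n, n)).tocsr()
    L = L - sp.diags(np.asarray(L.sum(axis=1)).ravel())
    return L


def solve_interior_step(mesh: TetMesh, density: DensityField,
                        image_prev: np.ndarray,
                        boundary_values: np.ndarray) -> np.ndarray:
    """One linear solve for the interior vertices with the boundary pinned."""
    surf = mesh.boundary()
    B = surf.vertex_map
    I = np.setdiff1d(np.arange(mesh.n_vertices), B)
    if len(I) == 0:
        out = image_prev.copy()
        out[B] = boundary_values
        return out
    L = mass_laplacian(mesh, density, image_prev)
    L_II = L[np.ix_(I, I)].tocsc()
    rhs = -(L[np.ix_(I, B)] @ boundary_values)
    try:
        lu = spla.splu(L_II)
    except RuntimeError as exc:         # singular factorization
        raise ValueError(
            "singular interior system (disconnected interior vertices)") from exc
    x = np.column_stack([lu.solve(rhs[:, c]) for c in range(3)])
    rhs_norm = np.linalg.norm(rhs)
    if rhs_norm > 0:
        resid = np.linalg.norm(L_II @ x - rhs) / rhs_norm
        if not np.isfinite(resid) or resid > 1e-8:
            raise ValueError(f"interior solve residual too large: {resid:.2e}")
    out = image_prev.copy()
    out[I] = x
    out[B] = boundary_values
    return out


def run_homotopy(mesh: TetMesh, density: DensityField, g: np.ndarray,
                 schedule: HomotopySchedule | int = 8,
                 inner_iterations: int = 1) -> VolumetricMap:
    """Drive the boundary from the identity to g and track the interior.

    ``g`` is the spherical boundary image ((nB, 3), surface-local order) or a
    :class:`~tsomt.boundary.BoundaryMap`.  One linear solve is performed per
    homotopy knot by default; ``inner_iterations > 1`` re-assembles L_V at the
    fresh iterate within each knot.
    """
    if hasattr(g, "g"):
        g = g.g
    if isinstance(schedule, int):
        schedule = HomotopySchedule(schedule)
    surf = mesh.boundary()
    vB = surf.vertices
    f = mesh.vertices.copy()             # f^(0) = id
    for t in schedule.knots[1:]:
        bvals = homotopy_boundary(vB, g, t)
        for _ in range(max(1, inner_iterations)):
            f = solve_interior_step(mesh, density, f, bvals)
    vmap = VolumetricMap(mesh=mesh, image=f, density=density)
    vols = vmap.image_volumes()
    src_mass = density.rho_tet * mesh.tet_volumes()
    with np.errstate(divide="ignore"):
        stretch = np.where(vols > 0, src_mass / np.where(vols > 0, vols, 1.0), np.inf)
    vmap.diagnostics = {
        "p": schedule.p,
        "folded": int(np.count_nonzero(vols <= 0)),
        "mass_stretch_mean": float(np.mean(stretch[np.isfinite(stretch)])),
    }
    return vmap
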