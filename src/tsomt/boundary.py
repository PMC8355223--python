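"""Area-measure-preserving spherical parameterization of the mesh boundary.

The boundary surface ∂M of the normalized brain mesh is mapped onto the unit
sphere S² by minimizing the regularized area-stretch energy

    E_A(g) = Σ_ℓ ‖L_A(g) g^ℓ‖²  +  λ Σ_i ‖g_i − v_i/‖v_i‖‖² a_ρ(v_i),

where L_A(g) is the area-weighted cotangent Laplacian whose weights are
divided by the area-stretch factor σ_{g⁻¹}(α) = ρ(α)|α| / |g(α)|; at a
minimum the image areas match the (density-weighted) source areas face by
face.  The optimization alternates linear solves in the stereographic plane:
vertices on the southern hemisphere are relaxed while the northern ones are
held fixed, the plane is inverted (z ↦ 1/z̄, i.e. the sphere is flipped), and
the roles swap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .density import DensityField
from .mesh import SurfaceMesh

__all__ = [
    "BoundaryMap",
    "stereographic",
    "inverse_stereographic",
    "triangle_areas",
    "area_stretch_factor",
    "area_laplacian",
    "area_energy",
    "initial_spherical_map",
    "solve_boundary_omt",
]


@dataclass
class BoundaryMap:
    """Spherical image of the boundary vertices plus solve diagnostics."""

    g: np.ndarray                       # (nB, 3) unit vectors
    energies: list = field(default_factory=list)
    max_sigma_dev: float = np.nan       # max |sigma - 1| (normalized measure)
    folded: int = 0
    converged: bool = False
    iterations: int = 0


def stereographic(g: np.ndarray) -> np.ndarray:
    """South-pole chart: g on S² (minus the north pole) to the complex plane.

    The north pole maps to complex infinity (numpy ``inf``), represented
    explicitly.
    """
    g = np.atleast_2d(g)
    denom = 1.0 - g[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        h = (g[:, 0] + 1j * g[:, 1]) / denom
    h[denom == 0] = np.inf
    return h


def inverse_stereographic(h: np.ndarray) -> np.ndarray:
    """Exact analytic inverse of :func:`stereographic`."""
    h = np.atleast_1d(h)
    out = np.zeros((len(h), 3))
    inf = ~np.isfinite(h)
    hf = np.where(inf, 0.0, h)
    r2 = hf.real ** 2 + hf.imag ** 2
    d = 1.0 + r2
    out[:, 0] = 2.0 * hf.real / d
    out[:, 1] = 2.0 * hf.imag / d
    out[:, 2] = (r2 - 1.0) / d
    out[inf] = (0.0, 0.0, 1.0)
    return out


def triangle_areas(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    a, b, c = (points[tris[:, i]] for i in range(3))
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def _source_area_measure(surface: SurfaceMesh, density: DensityField) -> np.ndarray:
    """ρ(α)|α| per boundary face."""
    return density.rho_face * surface.areas()


def area_stretch_factor(surface: SurfaceMesh, g: np.ndarray,
                        density: DensityField, normalized: bool = True) -> np.ndarray:
    """Per-face area-stretch factor σ_{g⁻¹}(α) = ρ(α)|α| / |g(α)|.

    With ``normalized=True`` both measures are rescaled to unit total first,
    so σ = 1 means exact relative area preservation regardless of whether the
    total source area measure equals the sphere area 4π.  Degenerate image
    triangles give +inf.
    """
    src = _source_area_measure(surface, density)
    img = triangle_areas(g, surface.triangles)
    if normalized:
        src = src / src.sum()
        tot = img.sum()
        img = img / tot if tot > 0 else img
    with np.errstate(divide="ignore"):
        return np.where(img > 0, src / np.where(img > 0, img, 1.0), np.inf)


def _corner_cotangents(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """(F, 3) cotangents of the angle at each triangle corner."""
    p = points[tris]                      # (F, 3, 3)
    cots = np.empty((len(tris), 3))
    for m in range(3):
        a = p[:, (m + 1) % 3] - p[:, m]
        b = p[:, (m + 2) % 3] - p[:, m]
        cross = np.linalg.norm(np.cross(a, b), axis=1)
        cots[:, m] = np.einsum("ij,ij->i", a, b) / np.maximum(cross, 1e-300)
    return cots


def area_laplacian(surface: SurfaceMesh, g: np.ndarray,
                   density: DensityField) -> sp.csr_matrix:
    """Area-weighted Laplacian L_A(g): symmetric, zero row sums.

    Off-diagonal (i, j) on boundary edges is −½ Σ_α cot(θ at the vertex
    opposite (i, j) in the image triangle g(α)) / σ_{g⁻¹}(α), summed over
    the two faces α containing the edge.  Since cot θ_k = (e_a·e_b)/(2|g(α)|)
    for the image edges e_a, e_b meeting at the opposite corner, the ratio
    collapses to (e_a·e_b)/(2ρ(α)|α|): the image area cancels, so the weight
    stays finite even for degenerate image triangles (the stretch-energy
    form of the cotangent weight).
    """
    tris = surface.triangles
    src_measure = _source_area_measure(surface, density)
    if np.any(src_measure <= 0):
        raise ValueError("collapsed source triangle (sigma = 0)")
    p = g[tris]                           # (F, 3, 3) image corners
    w = np.empty((len(tris), 3))
    for m in range(3):                    # corner m is opposite edge (m+1, m+2)
        a = p[:, (m + 1) % 3] - p[:, m]
        b = p[:, (m + 2) % 3] - p[:, m]
        w[:, m] = -0.5 * np.einsum("ij,ij->i", a, b) / (2.0 * src_measure)

    n = surface.n_vertices
    rows, cols, vals = [], [], []
    for m in range(3):                    # corner m is opposite edge (m+1, m+2)
        i, j = tris[:, (m + 1) % 3], tris[:, (m + 2) % 3]
        rows += [i, j]
        cols += [j, i]
        vals += [w[:, m], w[:, m]]
    L = sp.coo_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(n, n)).tocsr()
    L = L - sp.diags(np.asarray(L.sum(axis=1)).ravel())
    return L


def _alignment_targets(surface: SurfaceMesh) -> np.ndarray:
    v = surface.vertices
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def area_energy(surface: SurfaceMesh, g: np.ndarray, density: DensityField,
                lam: float, targets: np.ndarray | None = None) -> float:
    """The regularized area-stretch energy E_A(g)."""
    L = area_laplacian(surface, g, density)
    smooth = sum(float(np.linalg.norm(L @ g[:, ell]) ** 2) for ell in range(3))
    if lam == 0:
        return smooth
    diff = g - (_alignment_targets(surface) if targets is None else targets)
    align = float(np.sum(np.einsum("ij,ij->i", diff, diff) * density.local_area))
    return smooth + lam * align


def spherical_folds(surface: SurfaceMesh, g: np.ndarray) -> int:
    """Number of image triangles with inward (flipped) orientation."""
    a, b, c = (g[surface.triangles[:, i]] for i in range(3))
    det = np.einsum("ij,ij->i", np.cross(a, b), c)
    return int(np.count_nonzero(det <= 0))


def _center_sphere_map(surface: SurfaceMesh, g: np.ndarray,
                       max_iter: int = 200, tol: float = 1e-4) -> np.ndarray:
    """Damped centering so the area-weighted image centroid is near the origin."""
    g = g.copy()
    for _ in range(max_iter):
        areas = triangle_areas(g, surface.triangles)
        cent = g[surface.triangles].mean(axis=1)
        c = (cent * areas[:, None]).sum(axis=0) / max(areas.sum(), 1e-300)
        if np.linalg.norm(c) < tol:
            break
        g = g - 0.7 * c
        g /= np.linalg.norm(g, axis=1, keepdims=True)
    return g


def initial_spherical_map(surface: SurfaceMesh, density: DensityField) -> np.ndarray:
    """Initial sphere map: punctured harmonic flattening + inverse projection.

    The triangle farthest from the surface centroid is removed and its three
    vertices pinned to a large planar triangle; the remaining vertices solve
    the cotangent-harmonic system in the plane (a convex-combination map, so
    the flattening is an embedding for the voxel-boundary triangle shapes).
    The plane is rescaled so the median radius maps to the equator, pulled
    back to the sphere, and the image centroid is moved to the origin.
    """
    tris = surface.triangles
    centroid = surface.vertices.mean(axis=0)
    face_cent = surface.vertices[tris].mean(axis=1)
    far = int(np.argmax(np.linalg.norm(face_cent - centroid, axis=1)))

    cots = _corner_cotangents(surface.vertices, tris)
    n = surface.n_vertices
    rows, cols, vals = [], [], []
    for m in range(3):
        i, j = tris[:, (m + 1) % 3], tris[:, (m + 2) % 3]
        w = 0.5 * np.clip(cots[:, m], 0.0, None)   # clamp: keep convex weights
        rows += [i, j]
        cols += [j, i]
        vals += [-w, -w]
    L = sp.coo_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(n, n)).tocsr()
    L = L - sp.diags(np.asarray(L.sum(axis=1)).ravel())

    fixed = tris[far]
    R = 2.0
    targets = R * np.exp(2j * np.pi * (np.arange(3) / 3.0))
    h = np.zeros(n, dtype=complex)
    h[fixed] = targets
    free = np.setdiff1d(np.arange(n), fixed)
    A = L[np.ix_(free, free)].tocsc()
    rhs = -L[np.ix_(free, fixed)] @ targets
    lu = spla.splu(A)
    h[free] = lu.solve(rhs.real) + 1j * lu.solve(rhs.imag)

    r = np.abs(h)
    h = h / np.median(r[np.isfinite(r) & (r > 0)])
    g = inverse_stereographic(h)
    g /= np.linalg.norm(g, axis=1, keepdims=True)
    return _center_sphere_map(surface, g)


def _hemisphere_pass(surface: SurfaceMesh, g: np.ndarray, density: DensityField,
                     lam: float, targets: np.ndarray) -> np.ndarray:
    """Relax the southern-hemisphere vertices in the stereographic plane."""
    south = g[:, 2] <= 0
    if not south.any() or south.all():
        return g
    L = area_laplacian(surface, g, density)
    a = density.local_area.copy()
    # the alignment term is posed on the sphere; in the southern chart only
    # targets away from the north pole have a faithful planar image
    a[targets[:, 2] > 0.5] = 0.0
    A = L + lam * sp.diags(a)
    h = stereographic(g)
    u = stereographic(targets)
    u[~np.isfinite(u)] = 0.0
    rhs_full = lam * a * u
    S = np.flatnonzero(south)
    N = np.flatnonzero(~south)
    A_SS = A[np.ix_(S, S)].tocsc()
    rhs = rhs_full[S] - A[np.ix_(S, N)] @ h[N]
    lu = spla.splu(A_SS)
    h_S = lu.solve(rhs.real) + 1j * lu.solve(rhs.imag)
    h = h.copy()
    h[S] = h_S
    g_new = inverse_stereographic(h)
    g_new /= np.linalg.norm(g_new, axis=1, keepdims=True)
    return g_new


def _canonical_rotation(surface: SurfaceMesh, density: DensityField) -> np.ndarray:
    """Principal-axes frame of the boundary (area-weighted), deterministically
    signed via third moments.

    The alternating-hemisphere solves single out the z axis (the
    stereographic pole), so the raw algorithm is not rotation-equivariant.
    Solving in the surface's own principal frame and rotating the result
    back removes the dependence on how the input happens to be oriented.
    """
    w = density.local_area
    X = surface.vertices
    mu = (X * w[:, None]).sum(axis=0) / w.sum()
    Y = X - mu
    C = Y.T @ (Y * w[:, None])
    _, vecs = np.linalg.eigh(C)           # ascending eigenvalues
    R = vecs[:, ::-1]                     # major axis first
    for k in range(3):
        if float(((Y @ R[:, k]) ** 3 * w).sum()) < 0:
            R[:, k] = -R[:, k]
    if np.linalg.det(R) < 0:
        R[:, 2] = -R[:, 2]
    return R


def solve_boundary_omt(surface: SurfaceMesh, density: DensityField,
                       lam: float = 0.1, tol: float = 1e-6,
                       max_iter: int = 100, init: str = "radial",
                       canonicalize: bool = True) -> BoundaryMap:
    """Alternating-hemisphere minimization of the area-stretch energy.

    Each outer iteration relaxes the southern hemisphere (northern fixed),
    flips the sphere (the plane inversion z ↦ 1/z̄) and relaxes the other
    half.  Iterations that increase the energy are rejected; the best iterate
    is returned with convergence and fold diagnostics.

    ``init='radial'`` starts from the normalized radial projection v/‖v‖ —
    fold-free on star-shaped boundaries, the exact minimizer of the
    alignment term, and an empirically stable seed for the alternating
    solves.  ``init='harmonic'`` starts from the punctured harmonic
    flattening (:func:`initial_spherical_map`); its strong area concentration
    near the puncture can seed folds that the iteration does not recover
    from, so it is not the default.
    """
    Rc = _canonical_rotation(surface, density) if canonicalize else np.eye(3)
    targets = _alignment_targets(surface) @ Rc
    flip = np.array([1.0, 1.0, -1.0])

    if init == "radial":
        g = targets.copy()
    elif init == "harmonic":
        g = initial_spherical_map(surface, density) @ Rc
    else:
        raise ValueError(f"unknown init {init!r}")
    best_g = g
    best_E = area_energy(surface, g, density, lam, targets)
    energies = [best_E]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g = _hemisphere_pass(surface, g, density, lam, targets)
        g = _hemisphere_pass(surface, g * flip, density, lam, targets * flip) * flip
        E = area_energy(surface, g, density, lam, targets)
        prev = energies[-1]
        energies.append(E)
        if E < best_E:                     # accepted iterate
            rel = (best_E - E) / max(best_E, 1e-300)
            best_E, best_g = E, g
            if rel < tol:
                converged = True
                break
        elif abs(E - prev) / max(prev, 1e-300) < tol:
            converged = True               # stagnated at the plateau
            break

    best_g = best_g @ Rc.T                # back to the input frame
    sigma = area_stretch_factor(surface, best_g, density, normalized=True)
    return BoundaryMap(
        g=best_g,
        energies=energies,
        max_sigma_dev=float(np.max(np.abs(sigma[np.isfinite(sigma)] - 1.0))),
        folded=spherical_folds(surface, best_g),
        converged=converged,
        iterations=it,
    )
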