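"""Per-vertex densities driving the mass-transport solves.

Grayscale values φ ∈ [0, 1] become vertex densities ρ(v) = exp(φ(v)) ∈ [1, e].
Simplex densities are vertex averages, ρ(τ) = ¼ Σ ρ(v_i) on tetrahedra and
ρ(α) = ⅓ Σ ρ(v_i) on boundary triangles, and the local mass / local area
measures are

    m_ρ(v) = ¼ ρ(v) Σ_{τ ⊃ v} |τ|,      a_ρ(v) = ⅓ ρ(v) Σ_{α ⊃ v} |α|,

so that Σ_v m_ρ(v) = Σ_τ ρ(τ)|τ| and Σ_v a_ρ(v) = Σ_α ρ(α)|α| exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "DensityField",
    "normalize_grayscale",
    "equalize_histogram",
    "sample_at_vertices",
    "density_from_grayscale",
    "uniform_density",
    "augmentation_density",
]


@dataclass
class DensityField:
    """Vertex density and the derived simplex densities and local measures."""

    rho_vertex: np.ndarray     # (V,)
    rho_tet: np.ndarray        # (T,)
    rho_face: np.ndarray       # (F,) on boundary triangles
    local_mass: np.ndarray     # (V,) m_rho(v)
    local_area: np.ndarray     # (nB,) a_rho(v) on boundary vertices

    @property
    def total_mass(self) -> float:
        return float(self.local_mass.sum())

    @property
    def total_area(self) -> float:
        return float(self.local_area.sum())


def normalize_grayscale(raw: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Standardize then affinely map masked intensities onto [0, 1].

    Subtracts the mean and divides by the standard deviation over masked
    voxels, then shifts/rescales the observed range to [0, 1].  Voxels
    outside the mask are set to 0; a constant input maps to 0.5.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if mask is None:
        mask = np.ones(raw.shape, dtype=bool)
    vals = raw[mask]
    if vals.size == 0:
        raise ValueError("empty mask")
    sd = vals.std()
    if sd == 0:
        out = np.zeros_like(raw)
        out[mask] = 0.5
        return out
    z = (vals - vals.mean()) / sd
    z = (z - z.min()) / (z.max() - z.min())
    out = np.zeros_like(raw)
    out[mask] = z
    return out


def equalize_histogram(phi: np.ndarray, mask: np.ndarray | None = None,
                       bins: int = 256) -> np.ndarray:
    """Classical CDF remapping of masked values in [0, 1].

    The transfer function is the (non-decreasing) empirical CDF evaluated at
    the bin of each value, so the output is order preserving and fills [0, 1]
    more uniformly.
    """
    phi = np.asarray(phi, dtype=np.float64)
    if phi.min() < 0 or phi.max() > 1:
        raise ValueError("phi must lie in [0, 1]")
    if mask is None:
        mask = np.ones(phi.shape, dtype=bool)
    vals = phi[mask]
    hist, edges = np.histogram(vals, bins=bins, range=(0.0, 1.0))
    cdf = np.cumsum(hist).astype(np.float64)
    if cdf[-1] == 0:
        return phi.copy()
    cdf /= cdf[-1]
    idx = np.minimum((vals * bins).astype(np.int64), bins - 1)
    out = np.zeros_like(phi)
    out[mask] = cdf[idx]
    return out


def sample_at_vertices(volume: np.ndarray, mesh) -> np.ndarray:
    """Trilinear sample of a voxel-centre grid at the mesh vertices.

    Vertices sit at cell corners (half-integer voxel coordinates); the grid
    holds one value per voxel centre (integer coordinates).
    """
    coords = mesh.to_voxel(mesh.vertices).T
    return ndimage.map_coordinates(np.asarray(volume, dtype=np.float64),
                                   coords, order=1, mode="nearest")


def density_from_grayscale(phi_vertex: np.ndarray, mesh,
                           surface=None) -> DensityField:
    """Build the full density field ρ = exp(φ) on a mesh from vertex grayscale."""
    phi_vertex = np.asarray(phi_vertex, dtype=np.float64)
    if phi_vertex.min() < -1e-12 or phi_vertex.max() > 1 + 1e-12:
        raise ValueError("vertex grayscale must lie in [0, 1]")
    rho_v = np.exp(np.clip(phi_vertex, 0.0, 1.0))
    return _field_from_rho(rho_v, mesh, surface)


def _field_from_rho(rho_v: np.ndarray, mesh, surface=None) -> DensityField:
    surf = mesh.boundary() if surface is None else surface
    vols = mesh.tet_volumes()
    rho_tet = rho_v[mesh.tets].mean(axis=1)
    rho_face = rho_v[surf.vertex_map[surf.triangles]].mean(axis=1)

    star_vol = np.zeros(mesh.n_vertices)
    np.add.at(star_vol, mesh.tets.ravel(), np.repeat(vols, 4))
    local_mass = 0.25 * rho_v * star_vol

    areas = surf.areas()
    star_area = np.zeros(surf.n_vertices)
    np.add.at(star_area, surf.triangles.ravel(), np.repeat(areas, 3))
    local_area = (rho_v[surf.vertex_map] / 3.0) * star_area

    return DensityField(rho_vertex=rho_v, rho_tet=rho_tet, rho_face=rho_face,
                        local_mass=local_mass, local_area=local_area)


def uniform_density(mesh, surface=None) -> DensityField:
    """Constant density ρ ≡ 1 (the ball/cube target measure δ)."""
    return _field_from_rho(np.ones(mesh.n_vertices), mesh, surface)


def augmentation_density(phi_vertices: np.ndarray, mesh,
                         surface=None) -> DensityField:
    """Augmentation density ρ₂ = exp(¼ Σ_i φ_i) from the four modalities.

    ``phi_vertices`` is (4, V) or (V, 4): normalized per-vertex grayscale of
    FLAIR, T1, T1CE and T2.
    """
    phis = np.asarray(phi_vertices, dtype=np.float64)
    if phis.ndim != 2 or 4 not in phis.shape:
        raise ValueError("expected four grayscale channels")
    if phis.shape[0] != 4:
        phis = phis.T
    if phis.shape[1] != mesh.n_vertices:
        raise ValueError("grayscale channels do not match the mesh")
    return density_from_grayscale(phis.mean(axis=0), mesh, surface)
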