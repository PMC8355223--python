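"""Transport-quality and segmentation metrics.

Map-quality metrics (transport cost, total mass-measure distortion, local
stretch ratio, bijectivity rate) operate on a source mesh with density and
the per-vertex image points of a simplicial map.  Segmentation metrics
(Dice, sensitivity, specificity, HD/HD95, conversion loss) operate on voxel
label sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .density import DensityField
from .interior import VolumetricMap
from .mesh import TetMesh

__all__ = [
    "OMTReport",
    "ConfusionCounts",
    "transport_cost",
    "total_distortion",
    "stretch_ratio",
    "bijectivity",
    "omt_report",
    "conversion_loss",
    "segmentation_scores",
    "hausdorff",
    "hd95",
    "CLASS_LABELS",
    "class_mask",
]

#: BraTS/MSD tumor-class label groupings
CLASS_LABELS = {"WT": (1, 2, 3), "TC": (2, 3), "ET": (3,)}


def class_mask(labels: np.ndarray, cls: str) -> np.ndarray:
    """Boolean mask of a tumor class (WT/TC/ET) in a {0,1,2,3} label volume."""
    return np.isin(labels, CLASS_LABELS[cls])


@dataclass
class OMTReport:
    transport_cost: float
    total_distortion: float
    stretch_mean: float
    stretch_sd: float
    folded_count: int
    bijectivity_rate: float             # percent
    conversion_loss: dict | None = None


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @classmethod
    def from_masks(cls, pred: np.ndarray, truth: np.ndarray) -> "ConfusionCounts":
        pred = np.asarray(pred, dtype=bool)
        truth = np.asarray(truth, dtype=bool)
        return cls(TP=int(np.count_nonzero(pred & truth)),
                   FP=int(np.count_nonzero(pred & ~truth)),
                   FN=int(np.count_nonzero(~pred & truth)),
                   TN=int(np.count_nonzero(~pred & ~truth)))


def _resolve(fmap, image, density) -> tuple[TetMesh, np.ndarray, DensityField]:
    if isinstance(fmap, VolumetricMap):
        return fmap.mesh, fmap.image, (density or fmap.density)
    return fmap, image, density


def transport_cost(fmap, density: DensityField | None = None,
                   image: np.ndarray | None = None) -> float:
    """T_c(f) = Σ_v ‖v − f(v)‖² m_ρ(v)."""
    mesh, img, dens = _resolve(fmap, image, density)
    d = mesh.vertices - img
    return float(np.sum(np.einsum("ij,ij->i", d, d) * dens.local_mass))


def _vertex_star_sums(mesh: TetMesh, per_tet: np.ndarray) -> np.ndarray:
    out = np.zeros(mesh.n_vertices)
    np.add.at(out, mesh.tets.ravel(), np.repeat(per_tet, 4))
    return out


def _normalized_measures(mesh, img, dens):
    src = mesh.tet_volumes() * dens.rho_tet
    imgv = mesh.tet_volumes(img)
    tot_img = imgv.sum()
    if tot_img <= 0:
        raise ValueError("degenerate image: |f(M)| <= 0")
    m_hat = _vertex_star_sums(mesh, src) / src.sum()
    v_hat = _vertex_star_sums(mesh, imgv) / tot_img
    return m_hat, v_hat


def total_distortion(fmap, density: DensityField | None = None,
                     image: np.ndarray | None = None) -> float:
    """D_M(f) = ¼ Σ_v |normalized vertex mass − normalized image volume|."""
    mesh, img, dens = _resolve(fmap, image, density)
    m_hat, v_hat = _normalized_measures(mesh, img, dens)
    return float(0.25 * np.abs(m_hat - v_hat).sum())


def stretch_ratio(fmap, density: DensityField | None = None,
                  image: np.ndarray | None = None):
    """R_M(f, v): per-vertex ratio of normalized source mass to image volume.

    Returns (ratios, mean, sd); a vertex star with zero image volume yields
    +inf and is excluded from the summary statistics.
    """
    mesh, img, dens = _resolve(fmap, image, density)
    m_hat, v_hat = _normalized_measures(mesh, img, dens)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(v_hat > 0, m_hat / np.where(v_hat > 0, v_hat, 1.0), np.inf)
    finite = np.isfinite(r)
    return r, float(r[finite].mean()), float(r[finite].std())


def bijectivity(fmap, image: np.ndarray | None = None) -> tuple[int, float]:
    """(folded tet count, bijectivity rate in percent)."""
    if isinstance(fmap, VolumetricMap):
        mesh, img = fmap.mesh, fmap.image
    else:
        mesh, img = fmap, image
    vols = mesh.tet_volumes(img)
    folded = int(np.count_nonzero(vols <= 0))
    return folded, 100.0 * (1.0 - folded / len(vols))


def omt_report(fmap, density: DensityField | None = None,
               image: np.ndarray | None = None,
               conversion_losses: dict | None = None) -> OMTReport:
    mesh, img, dens = _resolve(fmap, image, density)
    _, mean, sd = stretch_ratio(mesh, dens, img)
    folded, rate = bijectivity(mesh, img)
    return OMTReport(
        transport_cost=transport_cost(mesh, dens, img),
        total_distortion=total_distortion(mesh, dens, img),
        stretch_mean=mean, stretch_sd=sd,
        folded_count=folded, bijectivity_rate=rate,
        conversion_loss=conversion_losses,
    )


def conversion_loss(a: np.ndarray, b: np.ndarray) -> float:
    """1 − Dice of two voxel sets; two empty sets agree perfectly (0)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 0.0
    inter = int(np.count_nonzero(a & b))
    return 1.0 - 2.0 * inter / (na + nb)


def segmentation_scores(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(Dice, sensitivity, specificity); undefined denominators give NaN."""
    tp, fp, fn, tn = counts.TP, counts.FP, counts.FN, counts.TN
    dice = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else np.nan
    sens = tp / (tp + fn) if (tp + fn) > 0 else np.nan
    spec = tn / (tn + fp) if (tn + fp) > 0 else np.nan
    return dice, sens, spec


_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    """Voxels of the set with at least one face neighbour outside it."""
    mask = np.asarray(mask, dtype=bool)
    interior = ndimage.binary_erosion(mask, structure=_STRUCT6, border_value=0)
    return np.argwhere(mask & ~interior)


def _directed_percentile(src: np.ndarray, dst: np.ndarray, q: float) -> float:
    tree = cKDTree(dst)
    d, _ = tree.query(src)
    return float(np.percentile(d, q))


def hausdorff(a: np.ndarray, b: np.ndarray, percentile: float = 100.0,
              mode: str = "max") -> float:
    """(Percentile) Hausdorff distance between the boundaries of two masks.

    ``mode='max'`` takes the maximum of the two directed percentile
    distances (mirroring the max–min structure of the plain HD);
    ``mode='pooled'`` takes the percentile of the pooled directed distances.
    Distances are in voxel units (isotropic 1 mm grids).  Empty boundaries
    give +inf.
    """
    pa, pb = _boundary_points(a), _boundary_points(b)
    if len(pa) == 0 or len(pb) == 0:
        return np.inf
    if mode == "max":
        return max(_directed_percentile(pa, pb, percentile),
                   _directed_percentile(pb, pa, percentile))
    if mode == "pooled":
        ta, tb = cKDTree(pb), cKDTree(pa)
        d = np.concatenate([ta.query(pa)[0], tb.query(pb)[0]])
        return float(np.percentile(d, percentile))
    raise ValueError(f"unknown mode {mode!r}")


def hd95(a: np.ndarray, b: np.ndarray, mode: str = "max") -> float:
    """95th-percentile Hausdorff distance between two masks' boundaries."""
    return hausdorff(a, b, percentile=95.0, mode=mode)
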