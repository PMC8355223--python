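"""Seedable brain-like 4-modality phantoms with nested tumor labels.

The phantom emulates the structure of multimodal brain-tumor MRI cases: a
genus-zero "brain" (a smoothly perturbed superellipsoid filling roughly 14%
of the cuboid grid, matching the 12–20% brain fill of real scans), four
smooth grayscale modalities with modality-specific tumor contrast (FLAIR
brightest on the whole tumor, T1CE on the enhancing tumor, T2 on the tumor
core), and nested integer labels ET ⊆ TC ⊆ WT occupying a few percent of
the brain.  Background voxels are exactly zero in every modality, so
foreground masking by thresholding at zero recovers the brain.

It does not emulate MRI physics (bias fields, noise correlations,
multi-focal lesions); what it exercises is the geometry/measure pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["PhantomSpec", "make_phantom", "make_prob_fixture", "MODALITIES"]

MODALITIES = ("FLAIR", "T1", "T1CE", "T2")


@dataclass
class PhantomSpec:
    """Parameters of the synthetic brain volume (defaults are the study
    conditions used throughout the tests)."""

    size: int = 64
    semi_axes: tuple = (0.375, 0.32, 0.28)   # fractions of the grid size
    superellipse_exponent: float = 2.3
    perturbation: float = 0.07               # radial perturbation amplitude
    wt_fraction: float = 0.07                # target WT volume / brain volume
    tc_ratio: float = 0.72                   # TC radius / WT radius
    et_ratio: float = 0.57                   # ET radius / WT radius
    tumor_offset: tuple = (0.18, -0.10, 0.08)  # tumor centre, units of semi-axes
    base_intensity: float = 1000.0
    field_sd: float = 250.0                  # smooth random-field amplitude
    smooth_sigma: float = 5.0                # voxels; band limit of the field
    tumor_contrast: dict = field(default_factory=lambda: {
        # raw-intensity offsets added on (WT, TC, ET) per modality
        "FLAIR": (900.0, 150.0, 100.0),
        "T1": (-250.0, -100.0, 50.0),
        "T1CE": (100.0, 150.0, 900.0),
        "T2": (250.0, 700.0, 150.0),
    })
    seed: int = 0


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Band-limited random field with zero mean and unit SD."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    return (f - f.mean()) / max(f.std(), 1e-12)


def make_phantom(spec: PhantomSpec | None = None):
    """Generate (grayscale (X,Y,Z,4), labels (X,Y,Z)) deterministically.

    Raw grayscale is nonnegative with background exactly 0; labels follow
    the BraTS convention {0,1,2,3} with nesting ET ⊆ TC ⊆ WT ⊆ brain.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    s = spec.size
    shape = (s, s, s)
    ax = np.arange(s) - (s - 1) / 2.0
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")

    semi = np.array(spec.semi_axes) * s
    q = spec.superellipse_exponent
    u = (np.abs(X / semi[0]) ** q + np.abs(Y / semi[1]) ** q
         + np.abs(Z / semi[2]) ** q) ** (1.0 / q)
    eta = _smooth_field(rng, shape, spec.smooth_sigma)
    brain = u <= 1.0 + spec.perturbation * eta
    brain = ndimage.binary_fill_holes(brain)
    labels_cc, n_cc = ndimage.label(brain)
    if n_cc > 1:
        counts = np.bincount(labels_cc.ravel())
        counts[0] = 0
        brain = labels_cc == np.argmax(counts)

    brain_vox = int(brain.sum())
    r_wt = (3.0 * spec.wt_fraction * brain_vox / (4.0 * np.pi)) ** (1.0 / 3.0)
    center = np.array(spec.tumor_offset) * semi
    if np.any(np.abs(center) + r_wt > semi):
        raise ValueError("tumor does not fit inside the brain")
    d2 = ((X - center[0]) / 1.08) ** 2 + ((Y - center[1]) / 0.95) ** 2 \
        + ((Z - center[2]) / 0.97) ** 2
    d = np.sqrt(d2)
    labels = np.zeros(shape, dtype=np.int8)
    labels[brain & (d <= r_wt)] = 1
    labels[brain & (d <= spec.tc_ratio * r_wt)] = 2
    labels[brain & (d <= spec.et_ratio * r_wt)] = 3

    grayscale = np.zeros(shape + (4,))
    for c, name in enumerate(MODALITIES):
        base = spec.base_intensity + spec.field_sd * _smooth_field(
            rng, shape, spec.smooth_sigma)
        wt_off, tc_off, et_off = spec.tumor_contrast[name]
        base = base + wt_off * (labels >= 1) + tc_off * (labels >= 2) \
            + et_off * (labels == 3)
        vol = np.where(brain, np.clip(base, 50.0, None), 0.0)
        grayscale[..., c] = vol
    return grayscale, labels


def make_prob_fixture(labels: np.ndarray, noise: float = 0.05,
                      seed: int = 0, eps: float = 0.05) -> np.ndarray:
    """Synthetic stand-in for a segmentation network's probability output.

    Probability 1−eps on tumor voxels, eps elsewhere, plus clipped Gaussian
    noise of the given SD; with zero noise, thresholding at ½ recovers the
    tumor mask exactly.
    """
    rng = np.random.default_rng(seed)
    tumor = np.asarray(labels) > 0
    p = np.where(tumor, 1.0 - eps, eps).astype(np.float64)
    if noise > 0:
        p = p + noise * rng.standard_normal(p.shape)
    return np.clip(p, 0.0, 1.0)
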