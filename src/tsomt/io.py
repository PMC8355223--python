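"""NIfTI case I/O and the serialized transport-map container."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["CaseBundle", "read_case", "write_case", "save_map", "load_map"]

#: fixed modality order of the 4th axis
MODALITY_ORDER = ("FLAIR", "T1", "T1CE", "T2")


@dataclass
class CaseBundle:
    """One case: 4-modality grayscale, integer labels, and NIfTI metadata."""

    grayscale: np.ndarray               # (X, Y, Z, 4)
    labels: np.ndarray | None           # (X, Y, Z) int8
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    case_id: str = ""


def _coerce_labels(arr: np.ndarray) -> np.ndarray:
    rounded = np.rint(arr)
    if not np.allclose(arr, rounded, atol=1e-6):
        raise ValueError("label volume holds non-integer values")
    return rounded.astype(np.int8)


def read_case(image_path, label_path=None, case_id: str = "") -> CaseBundle:
    """Read a 4D NIfTI image (modalities on the 4th axis) plus labels.

    Also accepts a 3D image (one modality).  The image and label grids must
    share shape and affine.
    """
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 3:
        data = data[..., None]
    if data.ndim != 4:
        raise ValueError(f"{image_path}: expected 3D or 4D image")
    labels = None
    if label_path is not None:
        lab = nib.load(str(label_path))
        if lab.shape[:3] != img.shape[:3] or not np.allclose(lab.affine, img.affine):
            raise ValueError(
                f"shape/affine mismatch between {image_path} and {label_path}")
        labels = _coerce_labels(np.asarray(lab.dataobj, dtype=np.float64))
    return CaseBundle(grayscale=data, labels=labels, affine=img.affine,
                      case_id=case_id or Path(str(image_path)).stem)


def write_case(bundle: CaseBundle, image_path, label_path=None) -> None:
    nib.save(nib.Nifti1Image(bundle.grayscale, bundle.affine), str(image_path))
    if label_path is not None and bundle.labels is not None:
        nib.save(nib.Nifti1Image(bundle.labels.astype(np.int16), bundle.affine),
                 str(label_path))


def save_map(tmap, path, mask: np.ndarray | None = None) -> None:
    """Serialize a two-stage map (meshes, density, images, rotation).

    ``mask`` is the full-resolution brain mask (needed by the inverse label
    conversion when the mesh grid was coarsened); it defaults to the mesh's
    own grid mask.
    """
    mesh1 = tmap.stage1.mesh
    if mask is None:
        mask = mesh1.grid_mask
    header = {
        "format": "tsomt-map",
        "version": 1,
        "brain_shape": list(mask.shape),
        "cube_cells": int(tmap.stage2.mesh.grid_mask.shape[0]),
    }
    np.savez_compressed(
        str(path),
        header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
        rotation=tmap.rotation,
        mask=np.asarray(mask, dtype=bool),
        s1_vertices=mesh1.vertices,
        s1_tets=mesh1.tets,
        s1_grid_mask=mesh1.grid_mask,
        s1_center=mesh1.center,
        s1_scale=np.array([mesh1.scale]),
        s1_grid_step=np.array([mesh1.grid_step]),
        s1_smoothed=np.array([mesh1.smoothed]),
        s1_image=tmap.stage1.image,
        s1_rho=tmap.stage1.density.rho_vertex,
        s2_n=np.array([tmap.stage2.mesh.grid_mask.shape[0]]),
        s2_image=tmap.stage2.image,
    )


def load_map(path):
    """Rebuild a :class:`~tsomt.transform.TSOMTMap` from :func:`save_map`.

    Returns ``(tmap, mask)`` with the full-resolution brain mask.
    """
    from .density import _field_from_rho, uniform_density
    from .interior import VolumetricMap
    from .mesh import TetMesh, normalize_mesh, tetrahedralize
    from .transform import TSOMTMap

    with np.load(str(path)) as z:
        mesh1 = TetMesh(vertices=z["s1_vertices"], tets=z["s1_tets"],
                        grid_mask=z["s1_grid_mask"], center=z["s1_center"],
                        scale=float(z["s1_scale"][0]),
                        grid_step=int(z["s1_grid_step"][0]),
                        smoothed=bool(z["s1_smoothed"][0]))
        if mesh1.regular:
            # rebuild the cell -> tet lookup for closed-form point location
            mesh1._mask_flat = np.flatnonzero(mesh1.grid_mask.ravel())
        dens1 = _field_from_rho(z["s1_rho"], mesh1)
        stage1 = VolumetricMap(mesh=mesh1, image=z["s1_image"], density=dens1)
        n2 = int(z["s2_n"][0])
        mesh2 = normalize_mesh(tetrahedralize(np.ones((n2, n2, n2), dtype=bool)))
        stage2 = VolumetricMap(mesh=mesh2, image=z["s2_image"],
                               density=uniform_density(mesh2))
        return TSOMTMap(stage1=stage1, stage2=stage2,
                        rotation=z["rotation"]), z["mask"]
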