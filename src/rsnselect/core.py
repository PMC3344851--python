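"""Core data container for a single subject's 4D BOLD run and its NIfTI I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

MIN_VOLUMES = 60


@dataclass
class BoldRun:
    """One subject's 4D BOLD time series on a regular voxel grid.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        BOLD signal in arbitrary units.
    tr_seconds : float
        Repetition time between volumes.
    mask : ndarray of bool, shape (x, y, z)
        Brain mask; analysis operations only touch in-mask voxels.
    voxel_mm : tuple of 3 floats
        Voxel edge lengths in millimetres.
    """

    data: np.ndarray
    tr_seconds: float
    mask: np.ndarray
    voxel_mm: tuple = (3.0, 3.0, 3.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, t)")
        if self.data.shape[-1] < MIN_VOLUMES:
            raise ValueError(
                f"need at least {MIN_VOLUMES} volumes, got {self.data.shape[-1]}"
            )
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match spatial grid")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        self.voxel_mm = tuple(float(v) for v in self.voxel_mm)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_mm) + [1.0])
        return aff

    def in_mask(self) -> np.ndarray:
        """Return the (t, n_in_mask_voxels) time-by-voxel matrix."""
        return self.data[self.mask].T

    def with_data(self, data: np.ndarray) -> "BoldRun":
        return BoldRun(data=data, tr_seconds=self.tr_seconds, mask=self.mask,
                       voxel_mm=self.voxel_mm)


def save_run(run: BoldRun, path, sidecar: dict | None = None) -> None:
    """Write a run as NIfTI-1 plus an optional JSON sidecar (same stem)."""
    path = Path(path)
    img = nib.Nifti1Image(run.data.astype(np.float32), run.affine)
    img.header.set_zooms(tuple(run.voxel_mm) + (run.tr_seconds,))
    nib.save(img, str(path))
    meta = {"tr_seconds": run.tr_seconds, "voxel_mm": list(run.voxel_mm)}
    if sidecar:
        meta.update(sidecar)
    path.with_suffix("").with_suffix(".json").write_text(
        json.dumps(meta, indent=2, sort_keys=True)
    )


def load_run(path, mask: np.ndarray | None = None) -> BoldRun:
    """Load a 4D NIfTI as a BoldRun; TR and voxel size come from the header,
    overridden by a JSON sidecar if present."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()
    voxel_mm = tuple(float(z) for z in zooms[:3])
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    sidecar = path.with_suffix("").with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        tr = float(meta.get("tr_seconds", tr))
        voxel_mm = tuple(meta.get("voxel_mm", voxel_mm))
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    return BoldRun(data=data, tr_seconds=tr, mask=mask, voxel_mm=voxel_mm)
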