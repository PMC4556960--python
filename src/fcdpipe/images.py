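"""In-memory containers for 4D BOLD volumes and motion traces.

All images in this package live on a common isotropic analysis grid; the
affine is diagonal (voxel size on the diagonal, origin at voxel (0,0,0)).
Registration/normalization is out of scope: images are assumed aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd


class FcdPipeError(ValueError):
    """User-facing error (bad inputs or configuration)."""


@dataclass
class BoldImage:
    """A 4D voxel time-series volume.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        BOLD-like signal.
    voxel_size_mm : tuple of 3 floats
        Isotropic or anisotropic voxel edge lengths in mm.
    tr_s : float
        Repetition time (sampling interval) in seconds.
    brain_mask : ndarray of bool, shape (x, y, z)
        Analysis mask; voxels outside are never modified by any
        preprocessing step and never contribute to nuisance means.
    provenance : list of str
        Ordered record of applied processing steps.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    tr_s: float
    brain_mask: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise FcdPipeError(f"BOLD data must be 4D, got shape {self.data.shape}")
        if np.isscalar(self.voxel_size_mm):
            self.voxel_size_mm = (float(self.voxel_size_mm),) * 3
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise FcdPipeError("voxel sizes must be positive")
        if self.tr_s <= 0:
            raise FcdPipeError("tr_s must be positive")
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.brain_mask.shape != self.data.shape[:3]:
            raise FcdPipeError(
                f"mask shape {self.brain_mask.shape} does not match "
                f"spatial shape {self.data.shape[:3]}"
            )

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size_mm
        return aff

    def with_data(self, data: np.ndarray, step: str) -> "BoldImage":
        """Return a copy holding `data` with `step` appended to provenance."""
        return replace(
            self, data=np.asarray(data, dtype=np.float64),
            provenance=self.provenance + [step],
        )

    # --- NIfTI round trip -------------------------------------------------

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms(self.voxel_size_mm + (self.tr_s,))
        return img

    def save(self, path, mask_path=None) -> None:
        nib.save(self.to_nifti(), str(path))
        if mask_path is not None:
            nib.save(
                nib.Nifti1Image(self.brain_mask.astype(np.uint8), self.affine),
                str(mask_path),
            )

    @classmethod
    def from_nifti(cls, path, mask_path=None, tr_s: float | None = None) -> "BoldImage":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        zooms = img.header.get_zooms()
        voxel = tuple(float(z) for z in zooms[:3])
        if tr_s is None:
            tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
        if mask_path is not None:
            mask = np.asanyarray(nib.load(str(mask_path)).dataobj) > 0
        else:
            mask = np.ones(data.shape[:3], dtype=bool)
        return cls(data=data, voxel_size_mm=voxel, tr_s=tr_s, brain_mask=mask)


@dataclass
class MotionTrace:
    """Six rigid-body motion parameters per volume.

    translations_mm has shape (t, 3); rotations_deg has shape (t, 3).
    """

    translations_mm: np.ndarray
    rotations_deg: np.ndarray

    def __post_init__(self) -> None:
        self.translations_mm = np.atleast_2d(np.asarray(self.translations_mm, float))
        self.rotations_deg = np.atleast_2d(np.asarray(self.rotations_deg, float))
        if self.translations_mm.shape[1] != 3 or self.rotations_deg.shape[1] != 3:
            raise FcdPipeError("motion trace needs 3 translation and 3 rotation columns")
        if len(self.translations_mm) != len(self.rotations_deg):
            raise FcdPipeError("translation and rotation series differ in length")
        if len(self.translations_mm) == 0:
            raise FcdPipeError("motion trace is empty")

    def __len__(self) -> int:
        return len(self.translations_mm)

    def drop_initial(self, n: int) -> "MotionTrace":
        if n >= len(self):
            raise FcdPipeError(f"cannot drop {n} of {len(self)} motion rows")
        return MotionTrace(self.translations_mm[n:], self.rotations_deg[n:])

    def as_array(self) -> np.ndarray:
        """(t, 6) array: 3 translations (mm) then 3 rotations (deg)."""
        return np.hstack([self.translations_mm, self.rotations_deg])

    def to_tsv(self, path) -> None:
        cols = ["trans_x_mm", "trans_y_mm", "trans_z_mm",
                "rot_x_deg", "rot_y_deg", "rot_z_deg"]
        df = pd.DataFrame(self.as_array(), columns=cols)
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path) -> "MotionTrace":
        arr = pd.read_csv(path, sep="\t").to_numpy(dtype=float)
        if arr.shape[1] != 6:
            raise FcdPipeError(f"motion TSV must have 6 columns, got {arr.shape[1]}")
        return cls(arr[:, :3], arr[:, 3:])


def save_map(map3d: np.ndarray, voxel_size_mm, path) -> None:
    """Write a 3D map as NIfTI-1 with a diagonal affine."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = (
        voxel_size_mm if not np.isscalar(voxel_size_mm) else (voxel_size_mm,) * 3
    )
    nib.save(nib.Nifti1Image(np.asarray(map3d, dtype=np.float32), aff), str(path))
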