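"""NIfTI volume/mask I/O and segmentation masking.

Arrays are kept in the stored NIfTI array order (axis 0 first); for the
BraTS-shaped data this puts the 155-length axis first. Mask label codes
default to the BraTS dialect (1 = necrotic core, 2 = edema, 4 = enhancing
tumor) and are remappable via ``subregion_codes``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

DEFAULT_SUBREGION_CODES = {"necrotic_core": 1, "edema": 2, "enhancing_tumor": 4}


@dataclass
class MRVolume:
    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    modality: str = ""
    patient_id: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"MRVolume must be 3D, got shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("MRVolume contains non-finite voxels")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self):
        return self.voxels.shape

    def with_voxels(self, voxels: np.ndarray,
                    spacing: tuple | None = None) -> "MRVolume":
        return MRVolume(voxels, spacing or self.spacing_mm, self.modality,
                        self.patient_id)


@dataclass
class SegmentationMask:
    labels: np.ndarray
    subregion_codes: dict = field(
        default_factory=lambda: dict(DEFAULT_SUBREGION_CODES))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(
                f"SegmentationMask must be 3D, got shape {self.labels.shape}")
        allowed = set(self.subregion_codes.values()) | {0}
        present = set(np.unique(self.labels).tolist())
        if not present <= allowed:
            raise ValueError(
                f"mask labels {sorted(present - allowed)} outside declared "
                f"code set {sorted(allowed)}")

    @property
    def shape(self):
        return self.labels.shape

    def foreground(self, subregions: list[str] | None = None) -> np.ndarray:
        """Boolean union of the selected subregions (all three by default)."""
        names = subregions or list(self.subregion_codes)
        codes = [self.subregion_codes[n] for n in names]
        return np.isin(self.labels, codes)


def read_volume(path: str | Path, modality: str = "",
                patient_id: str = "") -> MRVolume:
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:  # nibabel raises several error types
        raise IOError(f"cannot read NIfTI volume at {path}: {exc}") from exc
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return MRVolume(data, spacing, modality, patient_id)


def read_mask(path: str | Path,
              subregion_codes: dict | None = None) -> SegmentationMask:
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:
        raise IOError(f"cannot read NIfTI mask at {path}: {exc}") from exc
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask, got shape {data.shape}")
    return SegmentationMask(np.rint(data).astype(np.int16),
                            subregion_codes or dict(DEFAULT_SUBREGION_CODES))


def write_volume(vol: MRVolume, path: str | Path) -> Path:
    path = Path(path)
    affine = np.diag(list(vol.spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(vol.voxels.astype(np.float64), affine), str(path))
    return path


def apply_mask(volume: MRVolume, mask: SegmentationMask,
               subregions: list[str] | None = None) -> MRVolume:
    """Zero every voxel outside the selected tumor subregions.

    By default the union of all three subregions is kept. Idempotent.
    """
    if volume.shape != mask.shape:
        raise ValueError(
            f"volume shape {volume.shape} != mask shape {mask.shape}")
    keep = mask.foreground(subregions)
    return volume.with_voxels(np.where(keep, volume.voxels, 0.0))
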