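"""Volumetric preprocessing: mask → crop → downscale → pad → normalize.

The default geometry reproduces the study pipeline on BraTS-shaped input:
155×240×240 → crop 140×172×164 (a fixed window sized to the largest tumor,
centered on each patient's tumor centroid) → block-mean downscale by 2 to
70×86×82 at 2 mm spacing → zero-pad the last axis to square 86×86 slices →
per-volume min-max scaling to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import MRVolume, SegmentationMask, apply_mask


@dataclass
class PreprocessConfig:
    crop_shape: tuple[int, int, int] = (140, 172, 164)
    downscale_factor: int = 2
    target_slice_edge: int = 86
    mask_subregions: list[str] | None = None   # None = union of all three

    def validate(self) -> None:
        if self.downscale_factor < 1:
            raise ValueError("downscale_factor must be >= 1")
        need = -(-self.crop_shape[2] // self.downscale_factor)  # ceil div
        if self.target_slice_edge < need:
            raise ValueError(
                f"target_slice_edge {self.target_slice_edge} smaller than "
                f"downscaled last axis {need}")


def crop_to_tumor(volume: MRVolume, mask: SegmentationMask,
                  crop_shape: tuple[int, int, int]) -> MRVolume:
    """Fixed-size crop centered on the tumor centroid, clipped in-bounds.

    The same window applies to every modality of a patient because it is a
    function of the (shared) mask only.
    """
    if volume.shape != mask.shape:
        raise ValueError(
            f"volume shape {volume.shape} != mask shape {mask.shape}")
    for c, s in zip(crop_shape, volume.shape):
        if c > s:
            raise ValueError(
                f"crop_shape {crop_shape} exceeds volume shape {volume.shape}")
    fg = mask.labels > 0
    if not fg.any():
        raise ValueError("empty segmentation mask: no tumor to center on")
    centroid = np.array(np.nonzero(fg)).mean(axis=1)
    starts = []
    for c, ctr, s in zip(crop_shape, centroid, volume.shape):
        start = int(round(ctr - c / 2))
        start = min(max(start, 0), s - c)   # shift minimally to fit
        starts.append(start)
    sl = tuple(slice(st, st + c) for st, c in zip(starts, crop_shape))
    return volume.with_voxels(volume.voxels[sl])


def crop_window(mask: SegmentationMask,
                crop_shape: tuple[int, int, int]) -> tuple[slice, ...]:
    """The crop slices for a mask (for applying one window to many volumes)."""
    fg = mask.labels > 0
    if not fg.any():
        raise ValueError("empty segmentation mask: no tumor to center on")
    centroid = np.array(np.nonzero(fg)).mean(axis=1)
    starts = []
    for c, ctr, s in zip(crop_shape, centroid, mask.shape):
        start = int(round(ctr - c / 2))
        start = min(max(start, 0), s - c)
        starts.append(start)
    return tuple(slice(st, st + c) for st, c in zip(starts, crop_shape))


def downscale(volume: MRVolume, factor: int) -> MRVolume:
    """Non-overlapping block-mean downscale; spacing multiplies by factor.

    Each output voxel is the mean of a factor³ cell; trailing remainders on
    odd-length axes are dropped (floor semantics).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return volume
    v = volume.voxels
    new = tuple(s // factor for s in v.shape)
    if min(new) < 1:
        raise ValueError(
            f"factor {factor} larger than volume shape {v.shape}")
    trimmed = v[:new[0] * factor, :new[1] * factor, :new[2] * factor]
    blocks = trimmed.reshape(new[0], factor, new[1], factor, new[2], factor)
    out = blocks.mean(axis=(1, 3, 5))
    spacing = tuple(s * factor for s in volume.spacing_mm)
    return volume.with_voxels(out, spacing)


def pad_square_slices(volume: MRVolume, target_edge: int) -> MRVolume:
    """Symmetrically zero-pad the last axis to ``target_edge`` (extra voxel
    on the high side when the deficit is odd)."""
    d, h, w = volume.shape
    if w > target_edge:
        raise ValueError(
            f"last axis {w} exceeds target edge {target_edge}")
    if h != target_edge:
        raise ValueError(
            f"second axis {h} must equal target edge {target_edge}")
    deficit = target_edge - w
    lo = deficit // 2
    hi = deficit - lo
    out = np.pad(volume.voxels, ((0, 0), (0, 0), (lo, hi)))
    return volume.with_voxels(out)


def minmax_normalize(volume: MRVolume) -> MRVolume:
    """Affine rescale of the whole array to [0, 1] (per patient-modality
    volume). The value distribution's shape and relative distances are
    preserved."""
    v = volume.voxels
    vmin, vmax = v.min(), v.max()
    if vmax == vmin:
        raise ValueError(
            f"degenerate range: constant volume (value {vmin}) cannot be "
            "min-max normalized")
    return volume.with_voxels((v - vmin) / (vmax - vmin))


def preprocess_volume(volume: MRVolume, mask: SegmentationMask,
                      config: PreprocessConfig | None = None) -> MRVolume:
    """The full chain: mask → crop → downscale → pad → min-max normalize."""
    cfg = config or PreprocessConfig()
    cfg.validate()
    out = apply_mask(volume, mask, cfg.mask_subregions)
    out = crop_to_tumor(out, mask, cfg.crop_shape)
    out = downscale(out, cfg.downscale_factor)
    out = pad_square_slices(out, cfg.target_slice_edge)
    return minmax_normalize(out)
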