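"""Automatic volume-of-interest definition from the post-operative image.

The image is partitioned into four disjoint, exhaustive VOIs:

* FC — the two cortical fragments plus their flood-filled marrow cavities,
* FP — the fragment periphery (voxels a boundary ray crosses before
  striking cortical bone),
* DP — the defect periphery (rays striking the interpolated periosteal
  surface across the gap),
* DC — the defect centre (everything else).

Normalisation constants: ``TV_defect = |DC| * voxel^3`` and
``TV_fragment = |FC| * voxel^3`` (mm^3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imageproc import DensityImage

__all__ = [
    "VOISet",
    "DEBRIS_THRESHOLD",
    "find_fragments",
    "fill_marrow",
    "interpolate_periosteum",
    "raycast_partition",
    "define_vois",
]

# Binarisation threshold that disconnects surgical debris from the fragments.
DEBRIS_THRESHOLD = 645.0

# Label codes used when serialising a VOISet as a single volume.
VOI_CODES = {"DC": 0, "DP": 1, "FC": 2, "FP": 3}


@dataclass
class VOISet:
    """Disjoint DC/DP/FC/FP masks plus total-volume constants (mm^3)."""

    dc: np.ndarray
    dp: np.ndarray
    fc: np.ndarray
    fp: np.ndarray
    voxel_size: float  # um

    def __post_init__(self) -> None:
        masks = [self.dc, self.dp, self.fc, self.fp]
        shapes = {m.shape for m in masks}
        if len(shapes) != 1:
            raise ValueError("VOI masks must share one shape")
        total = sum(m.astype(np.int64) for m in masks)
        if not np.all(total == 1):
            raise ValueError("VOI masks must be pairwise disjoint and cover the image")

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.voxel_size / 1000.0) ** 3

    @property
    def tv_defect(self) -> float:
        return float(self.dc.sum()) * self.voxel_volume_mm3

    @property
    def tv_fragment(self) -> float:
        return float(self.fc.sum()) * self.voxel_volume_mm3

    def mask(self, name: str) -> np.ndarray:
        return getattr(self, name.lower())

    def tv_for(self, name: str) -> float:
        """TV normaliser for a VOI: defect TV for DC/DP, fragment TV for FC/FP."""
        return self.tv_defect if name.upper() in ("DC", "DP") else self.tv_fragment

    def labels(self) -> np.ndarray:
        out = np.zeros(self.dc.shape, dtype=np.uint8)
        for name, code in VOI_CODES.items():
            out[self.mask(name)] = code
        return out


def find_fragments(
    postop: DensityImage,
    threshold: float = DEBRIS_THRESHOLD,
    connectivity: int = 26,
) -> np.ndarray:
    """Locate the two cortical fragments in the post-operative frame.

    Binarises at ``threshold``, labels connected components (26-connected by
    default) and keeps the two components touching the two opposite axial
    faces; smaller components (surgical debris) are discarded.  Returns an
    int8 volume with 1 = proximal (z=0 face) and 2 = distal fragment.
    """
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")
    binary = postop.values >= threshold
    labelled, _ = ndimage.label(binary, structure=structure)
    bottom = set(np.unique(labelled[:, :, 0])) - {0}
    top = set(np.unique(labelled[:, :, -1])) - {0}
    if bottom & top:
        raise ValueError(
            "defect not resolvable: a single component bridges both axial faces"
        )
    if not bottom or not top:
        raise ValueError(
            f"defect not resolvable: found {len(bottom)} proximal and {len(top)} distal "
            "face-touching components (need one of each)"
        )
    # if several components touch one face, take the largest
    counts = np.bincount(labelled.ravel())
    prox = max(bottom, key=lambda l: counts[l])
    dist = max(top, key=lambda l: counts[l])
    out = np.zeros(postop.shape, dtype=np.int8)
    out[labelled == prox] = 1
    out[labelled == dist] = 2
    return out


def fill_marrow(fragments: np.ndarray) -> np.ndarray:
    """FC mask: fragments with marrow cavities flood-filled slice by slice.

    Each axial (2D) slice is filled from outside; interior voxels a 2D flood
    cannot reach are marrow and are unioned with the cortex.
    """
    fc = fragments > 0
    out = np.zeros_like(fc)
    for k in range(fc.shape[2]):
        out[:, :, k] = ndimage.binary_fill_holes(fc[:, :, k])
    return out


def _signed_distance_2d(shape: np.ndarray) -> np.ndarray:
    # negative inside, positive outside; never exactly zero
    if not shape.any():
        return np.full(shape.shape, np.inf)
    return ndimage.distance_transform_edt(~shape) - ndimage.distance_transform_edt(shape)


def _gap_extent(fc: np.ndarray) -> tuple[int, int] | None:
    occupied = fc.any(axis=(0, 1))
    if occupied.all():
        return None
    ks = np.nonzero(occupied)[0]
    if ks.size == 0:
        raise ValueError("FC mask is empty")
    empty = np.nonzero(~occupied)[0]
    inner = empty[(empty > ks.min()) & (empty < ks.max())]
    if inner.size == 0:
        return None
    return int(inner.min()), int(inner.max())


def interpolate_periosteum(fc: np.ndarray, min_area_fraction: float = 0.9) -> np.ndarray:
    """Virtual periosteal surface across the gap (solid cross-sections).

    For each gap slice the last intact proximal and first intact distal FC
    cross-sections are blended linearly through their signed distance maps
    and thresholded at zero.  "Intact" means the slice's filled area reaches
    ``min_area_fraction`` of its fragment's median slice area, which keeps
    the endpoints stable when noise or smoothing erodes the cut ends.
    Returns an all-False volume (with a warning) when the fragments touch.
    """
    gap = _gap_extent(fc)
    out = np.zeros_like(fc)
    if gap is None:
        warnings.warn("no gap between fragments; virtual surface is empty", stacklevel=2)
        return out
    k0, k1 = gap
    areas = fc.sum(axis=(0, 1))

    def intact_slice(ks):
        ref = np.median(areas[ks][areas[ks] > 0])
        for k in ks:
            if areas[k] >= min_area_fraction * ref:
                return k
        return ks[0]

    kp = intact_slice(np.arange(k0 - 1, -1, -1))
    kd = intact_slice(np.arange(k1 + 1, fc.shape[2]))
    sd_p = _signed_distance_2d(fc[:, :, kp])
    sd_d = _signed_distance_2d(fc[:, :, kd])
    n = k1 - k0 + 1
    for i, k in enumerate(range(k0, k1 + 1)):
        w = 0.5 if n == 1 else i / (n - 1)
        out[:, :, k] = (1.0 - w) * sd_p + w * sd_d < 0.0
    return out


def raycast_partition(fc: np.ndarray, virtual: np.ndarray, voxel_size: float) -> VOISet:
    """Partition the image into DC/DP/FC/FP by boundary ray casting.

    Rays traverse every transverse grid line from the four in-plane image
    boundaries.  Voxels between the boundary and the first struck surface
    join FP when the strike is cortical/fragment material and DP when it is
    the virtual periosteal surface; rays that miss leave their voxels for
    DC, which is the complement of the other three VOIs.
    """
    if fc.shape != virtual.shape:
        raise ValueError(f"shape mismatch: {fc.shape} vs {virtual.shape}")
    fp = np.zeros_like(fc)
    dp = np.zeros_like(fc)
    obstacle = fc | virtual
    for axis in (0, 1):
        for reverse in (False, True):
            obs = np.flip(obstacle, axis=axis) if reverse else obstacle
            fcv = np.flip(fc, axis=axis) if reverse else fc
            n = obs.shape[axis]
            hit_any = obs.any(axis=axis)
            first = np.argmax(obs, axis=axis)  # index of first obstacle along ray
            first = np.where(hit_any, first, 0)
            idx = np.arange(n).reshape([-1 if a == axis else 1 for a in range(3)])
            before = idx < np.expand_dims(first, axis)
            hit_fc = np.take_along_axis(fcv, np.expand_dims(first, axis), axis=axis)
            hit_fc = hit_fc & np.expand_dims(hit_any, axis)
            fp_dir = before & hit_fc
            dp_dir = before & ~hit_fc & np.expand_dims(hit_any, axis)
            if reverse:
                fp_dir = np.flip(fp_dir, axis=axis)
                dp_dir = np.flip(dp_dir, axis=axis)
            fp |= fp_dir
            dp |= dp_dir
    fp &= ~fc
    dp &= ~fc & ~fp
    dc = ~(fc | fp | dp)
    return VOISet(dc=dc, dp=dp, fc=fc, fp=fp, voxel_size=voxel_size)


def define_vois(
    postop: DensityImage,
    threshold: float = DEBRIS_THRESHOLD,
    connectivity: int = 26,
) -> VOISet:
    """Full VOI pipeline: fragments -> marrow fill -> periosteum -> raycast."""
    fragments = find_fragments(postop, threshold=threshold, connectivity=connectivity)
    fc = fill_marrow(fragments)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        virtual = interpolate_periosteum(fc)
    return raycast_partition(fc, virtual, postop.voxel_size)
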