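"""Density-image preprocessing: smoothing, threshold ladder, registration, overlays.

All images in a study are 3D scalar fields of hydroxyapatite-equivalent
mineral density (mg HA/cm^3) on an isotropic voxel grid.  The fragment axis
is the last array axis by convention.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "DensityImage",
    "ThresholdLadder",
    "BinaryMask",
    "OverlayLabels",
    "LABEL_BACKGROUND",
    "LABEL_QUIESCENCE",
    "LABEL_FORMATION",
    "LABEL_RESORPTION",
    "gaussian_smooth",
    "apply_ladder",
    "register_translation",
    "apply_offset",
    "overlay",
]

# Overlay label codes (stored in a uint8 volume).
LABEL_BACKGROUND = 0
LABEL_QUIESCENCE = 1
LABEL_FORMATION = 2
LABEL_RESORPTION = 3


@dataclass
class DensityImage:
    """3D mineral-density field with voxel-size metadata.

    Parameters
    ----------
    values
        Densities in mg HA/cm^3, shape ``(nx, ny, nz)``; must be >= 0.
    voxel_size
        Isotropic voxel edge length in micrometres.
    frame
        Integer time index of the acquisition (weeks).
    """

    values: np.ndarray
    voxel_size: float = 10.5
    frame: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.values.shape}")
        if self.voxel_size <= 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if np.any(self.values < 0):
            raise ValueError("density values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size / 1000.0

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_size_mm**3

    def copy(self, **changes) -> "DensityImage":
        kwargs = dict(values=self.values.copy(), voxel_size=self.voxel_size, frame=self.frame)
        kwargs.update(changes)
        return DensityImage(**kwargs)


@dataclass(frozen=True)
class ThresholdLadder:
    """Strictly increasing sequence of binarisation thresholds (mg HA/cm^3).

    The default ladder spans 395 to 720 in steps of 25 (14 levels).
    """

    thresholds: tuple[float, ...] = tuple(float(t) for t in range(395, 721, 25))

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        if t.size == 0:
            raise ValueError("ladder must contain at least one threshold")
        if np.any(np.diff(t) <= 0):
            raise ValueError("ladder thresholds must be strictly increasing")
        object.__setattr__(self, "thresholds", tuple(float(x) for x in t))

    @classmethod
    def from_spec(cls, spec: str) -> "ThresholdLadder":
        """Parse a ``"start:stop:step"`` string (inclusive endpoints)."""
        try:
            start, stop, step = (float(x) for x in spec.split(":"))
        except ValueError as exc:
            raise ValueError(f"bad ladder spec {spec!r}, expected 'start:stop:step'") from exc
        n = int(round((stop - start) / step)) + 1
        return cls(tuple(start + i * step for i in range(n)))

    @property
    def lowest(self) -> float:
        return self.thresholds[0]

    @property
    def highest(self) -> float:
        return self.thresholds[-1]

    def __len__(self) -> int:
        return len(self.thresholds)

    def __iter__(self) -> Iterator[float]:
        return iter(self.thresholds)


@dataclass
class BinaryMask:
    """Binarised image at one ladder threshold."""

    values: np.ndarray
    threshold: float
    frame: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {self.values.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def volume_voxels(self) -> int:
        return int(self.values.sum())


@dataclass
class OverlayLabels:
    """Voxelwise formation/quiescence/resorption/background labels.

    Built from two consecutive binary masks at the same threshold:
    ``F = t1 & ~t``, ``R = t & ~t1``, ``Q = t & t1``, ``B = ~t & ~t1``.
    """

    labels: np.ndarray
    threshold: float
    frames: tuple[int, int] = (0, 1)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise ValueError(f"expected a 3D label volume, got shape {self.labels.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def formation(self) -> np.ndarray:
        return self.labels == LABEL_FORMATION

    @property
    def quiescence(self) -> np.ndarray:
        return self.labels == LABEL_QUIESCENCE

    @property
    def resorption(self) -> np.ndarray:
        return self.labels == LABEL_RESORPTION

    @property
    def background(self) -> np.ndarray:
        return self.labels == LABEL_BACKGROUND

    def bone_before(self) -> np.ndarray:
        """Bone mask at the earlier frame: Q | R."""
        return self.quiescence | self.resorption

    def bone_after(self) -> np.ndarray:
        """Bone mask at the later frame: Q | F."""
        return self.quiescence | self.formation


def _gaussian_kernel_1d(sigma: float, support: int) -> np.ndarray:
    d = np.arange(-support, support + 1, dtype=float)
    g = np.exp(-(d**2) / (2.0 * sigma**2))
    return g / g.sum()


def gaussian_smooth(image: DensityImage, sigma: float = 1.2, support: int = 1) -> DensityImage:
    """Smooth with a normalised truncated Gaussian kernel.

    ``support`` is the truncation radius in voxels, i.e. the kernel covers
    ``(2*support + 1)**3`` voxels.  Boundaries are handled by reflection.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    support = int(support)
    if support < 1:
        raise ValueError(f"support must be >= 1, got {support}")
    k = _gaussian_kernel_1d(sigma, support)
    out = image.values
    for axis in range(3):
        out = ndimage.correlate1d(out, k, axis=axis, mode="reflect")
    return DensityImage(out, voxel_size=image.voxel_size, frame=image.frame)


def apply_ladder(image: DensityImage, ladder: ThresholdLadder) -> list[BinaryMask]:
    """Binarise at every ladder threshold (inclusive: ``values >= tau``)."""
    return [
        BinaryMask(image.values >= tau, threshold=tau, frame=image.frame)
        for tau in ladder
    ]


def register_translation(moving: DensityImage, fixed: DensityImage) -> np.ndarray:
    """Integer translation maximising the cross-correlation of the two images.

    Returns an offset ``d`` (3-vector of voxels) such that
    ``apply_offset(moving, d)`` aligns the moving image to the fixed one.
    Correlation is computed circularly via FFT on mean-subtracted images;
    with circular shifts this is proportional to the normalised
    cross-correlation at every offset.
    """
    f = fixed.values - fixed.values.mean()
    m = moving.values - moving.values.mean()
    if not np.any(f) or not np.any(m):
        raise ValueError("cannot register a constant (zero-variance) image")
    if f.shape != m.shape:
        raise ValueError(f"shape mismatch: {f.shape} vs {m.shape}")
    corr = np.fft.ifftn(np.fft.fftn(f) * np.conj(np.fft.fftn(m))).real
    idx = np.unravel_index(np.argmax(corr), corr.shape)
    offset = np.array(idx, dtype=np.int64)
    # Wrap to signed offsets in (-n/2, n/2].
    for ax, n in enumerate(corr.shape):
        if offset[ax] > n // 2:
            offset[ax] -= n
    return offset


def apply_offset(image: DensityImage, offset: Sequence[int]) -> DensityImage:
    """Apply an integer translation (circular shift) to an image."""
    shifted = np.roll(image.values, tuple(int(o) for o in offset), axis=(0, 1, 2))
    return DensityImage(shifted, voxel_size=image.voxel_size, frame=image.frame)


def overlay(mask_t: BinaryMask, mask_t1: BinaryMask) -> OverlayLabels:
    """Overlay two consecutive binary masks into F/Q/R/B labels."""
    if mask_t.threshold != mask_t1.threshold:
        raise ValueError(
            f"overlay requires matching thresholds, got {mask_t.threshold} and {mask_t1.threshold}"
        )
    if mask_t.shape != mask_t1.shape:
        raise ValueError(f"shape mismatch: {mask_t.shape} vs {mask_t1.shape}")
    a, b = mask_t.values, mask_t1.values
    labels = np.full(a.shape, LABEL_BACKGROUND, dtype=np.uint8)
    labels[b & ~a] = LABEL_FORMATION
    labels[a & ~b] = LABEL_RESORPTION
    labels[a & b] = LABEL_QUIESCENCE
    return OverlayLabels(labels, threshold=mask_t.threshold, frames=(mask_t.frame, mask_t1.frame))
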