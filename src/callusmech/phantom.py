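"""Synthetic time-lapsed healing phantom with event-level ground truth.

Two hollow elliptical-cylinder cortical fragments separated by a gap are
rasterised onto a voxel grid; weekly "healing" steps then apply an explicit
generative mechanostat rule: soft tissue above an effective-strain threshold
mineralises (within a conduction radius of existing bone), bone surface below
a lower threshold resorbs, and surviving bone matures in density.  Every
event and the strain field that preceded it are logged, so downstream
statistics can be checked against known truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imageproc import DensityImage, ThresholdLadder
from .microfe import (
    BCSpec,
    MaterialMap,
    VoxelFEModel,
    coarsen_material,
)

__all__ = [
    "PhantomGeometry",
    "HealingRule",
    "HealingLoading",
    "EventLog",
    "build_phantom",
    "simulate_healing",
    "add_image_noise",
]


@dataclass(frozen=True)
class PhantomGeometry:
    """Geometry of the two-fragment defect phantom.

    Axis lengths are full (tip-to-tip) ellipse axes in mm; the fragment axis
    is the image z axis.  Defaults are scaled to fit the default
    96 x 96 x 160 grid at 10.5 um (~1 x 1 x 1.7 mm).
    """

    grid_shape: tuple[int, int, int] = (96, 96, 160)
    voxel_size: float = 10.5  # um
    outer_major_axis: float = 0.8  # mm, along image x
    outer_minor_axis: float = 0.6  # mm, along image y
    cortical_thickness: float = 0.15  # mm
    gap_length: float = 0.85  # mm
    cortical_density: float = 900.0  # mg HA/cm^3

    def __post_init__(self) -> None:
        if self.gap_length <= 0:
            raise ValueError(f"gap_length must be positive, got {self.gap_length}")
        if self.cortical_thickness > min(self.outer_major_axis, self.outer_minor_axis) / 2.0:
            raise ValueError(
                "cortical_thickness exceeds the semi-minor axis "
                f"({self.cortical_thickness} > {min(self.outer_major_axis, self.outer_minor_axis) / 2})"
            )
        if self.cortical_density <= 720.0:
            raise ValueError("cortical_density must exceed the highest segmentation threshold (720)")

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size / 1000.0

    @property
    def gap_voxels(self) -> int:
        return int(round(self.gap_length / self.voxel_size_mm))


@dataclass(frozen=True)
class HealingRule:
    """Generative mechanoregulation rule for the synthetic series."""

    strain_threshold_form: float = 0.30  # eps_eff above which soft tissue mineralises
    strain_threshold_res: float = 0.0  # eps_eff below which surface bone resorbs
    seed_density: float = 450.0  # mg HA/cm^3 of newly mineralised voxels
    maturation_rate: float = 100.0  # mg HA/cm^3 per step
    max_density: float = 900.0
    flip_noise: float = 0.0  # probability a voxel disobeys the rule
    conduction_radius: float = 2.0  # voxels; np.inf disables the constraint
    bone_threshold: float = 395.0  # density defining "bone" for the rule
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.flip_noise <= 1.0):
            raise ValueError(f"flip_noise must be in [0, 1], got {self.flip_noise}")
        if self.strain_threshold_res >= self.strain_threshold_form:
            raise ValueError("resorption threshold must be below the formation threshold")
        if self.seed_density < self.bone_threshold:
            raise ValueError("seed_density must be at least the bone threshold")


@dataclass(frozen=True)
class HealingLoading:
    """Loading applied at every simulated step.

    ``displacement`` mode prescribes a fixed axial closing displacement on
    the axial faces; ``force`` mode derives the displacement each step from
    a two-spring fixator/callus balance (slower: one extra stiffness probe
    per step).
    """

    mode: str = "displacement"
    axial_displacement: float = 0.2  # mm total closing (displacement mode)
    axial_force: float = 10.0  # N (force mode)
    k_fixator: float = 50.0  # N/mm (force mode)
    fe_tolerance: float = 1e-6
    fe_coarsen: int = 1  # block size for the FE material grid
    nu: float = 0.3
    material_mode: str = "banded"

    def __post_init__(self) -> None:
        if self.mode not in ("displacement", "force"):
            raise ValueError(f"unknown loading mode {self.mode!r}")
        if self.fe_coarsen < 1:
            raise ValueError("fe_coarsen must be >= 1")


@dataclass
class StepEvents:
    """Ground-truth events of one healing step (flat voxel indices)."""

    formed: np.ndarray
    resorbed: np.ndarray
    matured: np.ndarray
    eff_strain: np.ndarray  # (nx, ny, nz) float32, field preceding the step


@dataclass
class EventLog:
    """Per-step ground truth of a simulated healing series."""

    steps: list[StepEvents] = field(default_factory=list)
    rule: HealingRule | None = None
    loading: HealingLoading | None = None

    def __len__(self) -> int:
        return len(self.steps)


def build_phantom(geometry: PhantomGeometry) -> DensityImage:
    """Rasterise the two-fragment phantom onto the voxel grid.

    The fragments touch the two axial image faces; everything outside them
    has density 0.
    """
    nx, ny, nz = geometry.grid_shape
    h = geometry.voxel_size_mm
    a = geometry.outer_major_axis / 2.0
    b = geometry.outer_minor_axis / 2.0
    if 2.0 * a > nx * h:
        raise ValueError(f"outer_major_axis {geometry.outer_major_axis} mm exceeds grid x extent {nx * h:.3f} mm")
    if 2.0 * b > ny * h:
        raise ValueError(f"outer_minor_axis {geometry.outer_minor_axis} mm exceeds grid y extent {ny * h:.3f} mm")
    gap = geometry.gap_voxels
    if gap >= nz:
        raise ValueError(f"gap_length {geometry.gap_length} mm ({gap} voxels) exceeds grid z extent ({nz} voxels)")

    x = (np.arange(nx) + 0.5) * h - nx * h / 2.0
    y = (np.arange(ny) + 0.5) * h - ny * h / 2.0
    xx, yy = np.meshgrid(x, y, indexing="ij")
    outer = (xx / a) ** 2 + (yy / b) ** 2 <= 1.0
    ai, bi = a - geometry.cortical_thickness, b - geometry.cortical_thickness
    if ai > 0 and bi > 0:
        inner = (xx / ai) ** 2 + (yy / bi) ** 2 <= 1.0
    else:
        inner = np.zeros_like(outer)
    ring = outer & ~inner

    values = np.zeros(geometry.grid_shape)
    n_frag = nz - gap
    n_prox = n_frag // 2
    n_dist = n_frag - n_prox
    values[:, :, :n_prox][ring] = geometry.cortical_density
    values[:, :, nz - n_dist:][ring] = geometry.cortical_density
    return DensityImage(values, voxel_size=geometry.voxel_size, frame=0)


def add_image_noise(image: DensityImage, sigma: float, rng_seed: int = 0) -> DensityImage:
    """Additive zero-mean Gaussian noise, clipped at zero density."""
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    if sigma == 0:
        return image.copy()
    rng = np.random.default_rng(rng_seed)
    noisy = image.values + rng.normal(0.0, sigma, size=image.shape)
    return DensityImage(np.clip(noisy, 0.0, None), voxel_size=image.voxel_size, frame=image.frame)


def _ball_structure(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    z = np.arange(-r, r + 1)
    xx, yy, zz = np.meshgrid(z, z, z, indexing="ij")
    return xx**2 + yy**2 + zz**2 <= radius**2


_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)


def _step_strain(
    image: DensityImage, loading: HealingLoading, ladder: ThresholdLadder, x0=None
):
    """Solve the FE model for one frame; returns (eps_eff per fine voxel, displacement)."""
    material = MaterialMap.from_image(image, ladder, nu=loading.nu, mode=loading.material_mode)
    if loading.fe_coarsen > 1:
        material = coarsen_material(material, loading.fe_coarsen)
    model = VoxelFEModel(material)
    if loading.mode == "displacement":
        delta = loading.axial_displacement
    else:
        from .microfe import axial_stiffness

        k_callus = axial_stiffness(material, tol=loading.fe_tolerance)
        delta = loading.axial_force / (loading.k_fixator + k_callus)
    bc = BCSpec.axial_compression(material.shape, material.h_mm, delta)
    fld = model.solve(bc, tol=loading.fe_tolerance, x0=x0)
    eff = fld.eff_strain
    f = loading.fe_coarsen
    if f > 1:
        eff = np.repeat(np.repeat(np.repeat(eff, f, axis=0), f, axis=1), f, axis=2)
    return eff, fld.displacement.ravel()


def simulate_healing(
    phantom: DensityImage,
    rule: HealingRule,
    loading: HealingLoading | None = None,
    n_steps: int = 5,
    ladder: ThresholdLadder | None = None,
) -> tuple[list[DensityImage], EventLog]:
    """Run ``n_steps`` healing transitions; returns ``n_steps + 1`` frames.

    Per step: the strain field of the current frame is solved; candidate
    soft-tissue voxels (within ``conduction_radius`` of bone) mineralise to
    ``seed_density`` iff their effective strain exceeds the formation
    threshold, XOR a Bernoulli(flip_noise) flip; bone surface voxels below
    the resorption threshold resorb under the same flip rule; surviving bone
    matures by ``maturation_rate`` up to ``max_density``.
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    loading = loading or HealingLoading()
    ladder = ladder or ThresholdLadder()
    rng = np.random.default_rng(rule.rng_seed)
    log = EventLog(rule=rule, loading=loading)
    frames = [phantom.copy(frame=0)]
    current = phantom.values.copy()
    warm = None

    for step in range(n_steps):
        img = DensityImage(current, voxel_size=phantom.voxel_size, frame=step)
        try:
            eff, warm = _step_strain(img, loading, ladder, x0=warm)
        except Exception as exc:
            raise RuntimeError(f"FE solve failed at healing step {step}: {exc}") from exc

        bone = current >= rule.bone_threshold
        soft = ~bone
        if np.isfinite(rule.conduction_radius):
            reach = ndimage.binary_dilation(bone, structure=_ball_structure(rule.conduction_radius))
            candidates = soft & reach
        else:
            candidates = soft
        cand_idx = np.flatnonzero(candidates)
        should_form = eff.ravel()[cand_idx] > rule.strain_threshold_form
        flips = rng.random(cand_idx.size) < rule.flip_noise
        formed_idx = cand_idx[should_form ^ flips]

        surface = bone & ndimage.binary_dilation(soft, structure=_FACE_STRUCTURE)
        surf_idx = np.flatnonzero(surface)
        should_resorb = eff.ravel()[surf_idx] < rule.strain_threshold_res
        flips_r = rng.random(surf_idx.size) < rule.flip_noise
        resorbed_idx = surf_idx[should_resorb ^ flips_r]

        nxt = current.copy()
        flat = nxt.ravel()
        matured_mask = bone.copy()
        matured_mask.ravel()[resorbed_idx] = False
        matured_idx = np.flatnonzero(matured_mask)
        flat[matured_idx] = np.minimum(flat[matured_idx] + rule.maturation_rate, rule.max_density)
        flat[resorbed_idx] = 0.0
        flat[formed_idx] = rule.seed_density

        log.steps.append(
            StepEvents(
                formed=formed_idx,
                resorbed=resorbed_idx,
                matured=matured_idx,
                eff_strain=eff.astype(np.float32),
            )
        )
        current = nxt
        frames.append(DensityImage(current.copy(), voxel_size=phantom.voxel_size, frame=step + 1))

    return frames, log
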