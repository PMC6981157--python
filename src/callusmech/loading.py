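"""Physiological load estimation and translation to image-edge displacements.

``estimate_load`` finds the non-negative combination of unit load cases
whose superposed strain field best matches a homogeneous target
strain-energy density over the bone elements.  The organ-scale load is then
converted to an axial closing displacement of the defect through a lumped
two-spring fixator/callus model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .microfe import BCSpec, MaterialMap, StrainField, _elastic_matrix

__all__ = [
    "LoadCase",
    "LoadEstimate",
    "SpringModel",
    "estimate_load",
    "boundary_displacements",
    "DEFAULT_U_TARGET",
    "DEFAULT_K_FIXATOR",
]

# Homogeneous tissue-loading target (MPa) and fixator axial stiffness (N/mm);
# both are configuration-level assumptions, reported in every output.
DEFAULT_U_TARGET = 0.02
DEFAULT_K_FIXATOR = 50.0


@dataclass
class LoadCase:
    """A unit load case solved on the intact-shaft model.

    ``kind`` is ``"axial"`` (1 N) or ``"bending"`` (1 N mm about the minor
    ellipticity axis); ``field`` must be solved with ``store_tensors=True``.
    """

    kind: str
    magnitude: float
    field: StrainField

    def __post_init__(self) -> None:
        if self.field.strain_voigt is None:
            raise ValueError("load-case strain field must carry strain tensors")


@dataclass
class LoadEstimate:
    """Recovered physiological loads (axial N, bending N mm)."""

    f_axial: float
    m_bend: float
    residual: float
    u_target: float
    scales: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.f_axial < 0:
            raise ValueError("axial load must be non-negative (compressive)")


@dataclass
class SpringModel:
    """Two-spring fixator/callus load-sharing surrogate."""

    k_fixator_axial: float  # N/mm
    k_callus: float  # N/mm, from microfe.axial_stiffness
    defect_length: float = 0.85  # mm

    def __post_init__(self) -> None:
        if self.k_fixator_axial <= 0 or self.k_callus <= 0:
            raise ValueError("spring stiffnesses must be positive")


def _case_quadratics(cases: list[LoadCase], bone_mask: np.ndarray, material: MaterialMap):
    """Per-element SED quadratic forms Q_e with U_e(s) = s^T Q_e s."""
    d0 = _elastic_matrix(material.nu)
    eps = [c.field.strain_voigt[bone_mask] for c in cases]  # (n_bone, 6) each
    e_mod = material.youngs[bone_mask]
    nc = len(cases)
    q = np.empty((eps[0].shape[0], nc, nc))
    for a in range(nc):
        sa = eps[a] @ d0
        for b in range(nc):
            q[:, a, b] = 0.5 * e_mod * np.einsum("ij,ij->i", sa, eps[b])
    return q


def estimate_load(
    unit_cases: list[LoadCase],
    bone_mask: np.ndarray,
    material: MaterialMap,
    u_target: float = DEFAULT_U_TARGET,
    n_starts: int = 4,
    rng_seed: int = 0,
) -> LoadEstimate:
    """Least-squares fit of load-case scales to a homogeneous SED target.

    Minimises ``sum_e (U_e(s) - u_target)^2`` over scales ``s >= 0`` where
    the combined strain tensor is the s-weighted superposition of the unit
    cases.  Multiple bounded quasi-Newton starts; ties resolved by the
    smallest-norm solution.
    """
    if not unit_cases:
        raise ValueError("need at least one unit load case")
    shapes = {c.field.shape for c in unit_cases}
    if len(shapes) != 1 or shapes.pop() != material.shape:
        raise ValueError("all load cases must be solved on the material's mesh")
    if not bone_mask.any():
        raise ValueError("bone mask is empty")
    q = _case_quadratics(unit_cases, bone_mask, material)
    if not np.any(q):
        raise ValueError("degenerate load cases: all strain fields are zero")
    nc = len(unit_cases)
    qsym = 0.5 * (q + np.swapaxes(q, 1, 2))

    def objective(s):
        u = np.einsum("a,eab,b->e", s, qsym, s)
        r = u - u_target
        f = float(r @ r)
        grad = 4.0 * np.einsum("e,eab,b->a", r, qsym, s)
        return f, grad

    rng = np.random.default_rng(rng_seed)
    u_scale = float(np.mean(np.einsum("eaa->e", qsym)))  # rough SED per unit scale
    s0_base = np.full(nc, np.sqrt(max(u_target, 1e-30) / max(u_scale, 1e-30)))
    best = None
    for trial in range(n_starts):
        s0 = s0_base if trial == 0 else s0_base * rng.uniform(0.1, 3.0, size=nc)
        res = optimize.minimize(
            objective, s0, jac=True, method="L-BFGS-B",
            bounds=[(0.0, None)] * nc, options={"maxiter": 500, "ftol": 1e-15, "gtol": 1e-12},
        )
        key = (res.fun, float(np.linalg.norm(res.x)))
        if best is None or key < best[0]:
            best = (key, res)
    res = best[1]
    scales = {c.kind: float(s * c.magnitude) for c, s in zip(unit_cases, res.x)}
    return LoadEstimate(
        f_axial=abs(scales.get("axial", 0.0)),
        m_bend=abs(scales.get("bending", 0.0)),
        residual=float(res.fun),
        u_target=u_target,
        scales=scales,
    )


def boundary_displacements(
    estimate: LoadEstimate,
    spring: SpringModel,
    grid_shape: tuple[int, int, int],
    h_mm: float,
) -> BCSpec:
    """Image-edge displacement BC from the two-spring load sharing.

    The interface closing displacement
    ``u = F_axial / (k_fixator + k_callus)`` is applied as equal-and-opposite
    axial displacements on the two axial faces.  Bending transfer is omitted
    (the callus bending stiffness is uncontrolled in the surrogate).
    """
    denom = spring.k_fixator_axial + spring.k_callus
    if denom <= 0:
        raise ValueError("sum of spring stiffnesses must be positive")
    u = estimate.f_axial / denom
    bc = BCSpec.axial_compression(grid_shape, h_mm, u)
    bc.meta["closing_displacement"] = u
    bc.meta["spring"] = {
        "k_fixator_axial": spring.k_fixator_axial,
        "k_callus": spring.k_callus,
    }
    return bc
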