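"""Mechanoregulation statistics.

Two engines: (a) ROC association between the effective strain preceding a
time step and voxel mineralisation in the defect, and (b) a two-threshold
(mechanostat) classifier of surface remodelling events scored with a
category-normalised confusion matrix and its mean diagonal (the correct
classification rate, CCR), swept over a (T_R, T_F) grid into a heat map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imageproc import OverlayLabels

__all__ = [
    "STATE_FORMATION",
    "STATE_QUIESCENCE",
    "STATE_RESORPTION",
    "ROCResult",
    "SurfaceStateMap",
    "ThresholdPair",
    "ConfusionMatrix",
    "RemodelHeatmap",
    "roc_analysis",
    "extract_surface_states",
    "classify_surface",
    "confusion_ccr",
    "ccr_heatmap",
]

# Surface-state codes; also the row/column order of the confusion matrix.
STATE_FORMATION = 0
STATE_QUIESCENCE = 1
STATE_RESORPTION = 2
STATE_NAMES = ("formation", "quiescence", "resorption")

_FACE = ndimage.generate_binary_structure(3, 1)  # von Neumann radius 1


@dataclass
class ROCResult:
    """ROC sweep over effective strain for mineralisation prediction."""

    thresholds: np.ndarray  # descending; classification is signal >= threshold
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    t_opt: float
    tpr_opt: float
    fpr_opt: float
    n_pos: int
    n_neg: int
    meta: dict = field(default_factory=dict)

    @property
    def youden(self) -> float:
        return self.tpr_opt - self.fpr_opt


@dataclass
class SurfaceStateMap:
    """Bone-surface voxels with ground-truth state and sampled signal."""

    indices: np.ndarray  # (n, 3) voxel coordinates
    states: np.ndarray  # (n,) codes in {0, 1, 2}
    signal: np.ndarray  # (n,) effective strain
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.states.shape[0]
        if self.indices.shape != (n, 3) or self.signal.shape != (n,):
            raise ValueError("inconsistent surface map arrays")

    def __len__(self) -> int:
        return int(self.states.shape[0])


@dataclass(frozen=True)
class ThresholdPair:
    """Lower (resorption) and upper (formation) strain thresholds."""

    t_r: float
    t_f: float

    def __post_init__(self) -> None:
        if not self.t_r < self.t_f:
            raise ValueError(f"thresholds cannot overlap: T_R={self.t_r} >= T_F={self.t_f}")


@dataclass
class ConfusionMatrix:
    """3x3 category-normalised confusion matrix (rows predicted, cols true)."""

    matrix: np.ndarray
    ccr: float
    counts: np.ndarray  # raw (3, 3) integer counts
    empty_categories: tuple[str, ...] = ()


@dataclass
class RemodelHeatmap:
    """CCR over a (T_R, T_F) grid; only the strict lower triangle T_R < T_F."""

    t_r_grid: np.ndarray
    t_f_grid: np.ndarray
    ccr: np.ndarray  # (len(t_r_grid), len(t_f_grid)), NaN where T_R >= T_F
    best_pair: ThresholdPair
    max_ccr: float
    meta: dict = field(default_factory=dict)


def _roc_curve(signal: np.ndarray, positive: np.ndarray):
    """Sweep thresholds over all distinct values; returns descending
    thresholds, fpr, tpr, and exact integer (fp, tp) counts."""
    order = np.argsort(-signal, kind="stable")
    s = signal[order]
    y = positive[order].astype(np.int64)
    distinct = np.nonzero(np.diff(s))[0]
    last = np.r_[distinct, s.size - 1]
    tp = np.cumsum(y)[last]
    fp = (last + 1) - tp
    return s[last], fp, tp


def roc_analysis(
    eff_strain: np.ndarray,
    labels: OverlayLabels,
    voi_mask: np.ndarray | None = None,
) -> ROCResult:
    """ROC of preceding effective strain vs voxel mineralisation.

    Candidates are the voxels that are not bone at the earlier frame
    (formation or background labels) within ``voi_mask``; newly mineralised
    voxels are condition positive.  The curve sweeps every distinct signal
    value (classification ``signal >= threshold``) plus the (0,0)/(1,1)
    endpoints; AUC by trapezoid; the optimal point maximises TPR - FPR
    (furthest from the 45-degree chance line), ties resolved towards the
    lowest threshold.
    """
    if eff_strain.shape != labels.shape:
        raise ValueError(f"shape mismatch: {eff_strain.shape} vs {labels.shape}")
    candidates = labels.formation | labels.background
    if voi_mask is not None:
        candidates &= voi_mask
    positive = labels.formation[candidates]
    signal = np.asarray(eff_strain, dtype=np.float64)[candidates]
    n_pos = int(positive.sum())
    n_neg = int(positive.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"AUC undefined: {n_pos} condition-positive and {n_neg} condition-negative voxels"
        )
    thr, fp, tp = _roc_curve(signal, positive)
    fpr = np.r_[0.0, fp / n_neg, 1.0]
    tpr = np.r_[0.0, tp / n_pos, 1.0]
    auc = float(np.trapezoid(tpr, fpr))
    # exact integer Youden comparison; ties -> lowest threshold (= last index)
    j_num = tp * n_neg - fp * n_pos
    best = np.flatnonzero(j_num == j_num.max())[-1]
    return ROCResult(
        thresholds=thr,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        t_opt=float(thr[best]),
        tpr_opt=float(tp[best] / n_pos),
        fpr_opt=float(fp[best] / n_neg),
        n_pos=n_pos,
        n_neg=n_neg,
        meta={"threshold": labels.threshold, "frames": labels.frames},
    )


def extract_surface_states(
    labels: OverlayLabels,
    eff_strain: np.ndarray | None = None,
    sample: str = "bone",
) -> SurfaceStateMap:
    """Surface voxels of bone(t) with their remodelling state and signal.

    Face-adjacency (6-neighbour) interface definitions, with precedence
    formation > resorption > quiescence:

    * formation  — quiescent voxel with a newly-formed face neighbour,
    * resorption — resorbed voxel with a background face neighbour,
    * quiescence — quiescent voxel with a background face neighbour and no
      newly-formed one.

    ``sample="bone"`` reads the signal at the surface voxel itself;
    ``sample="soft"`` averages its non-bone face neighbours.
    """
    f, q, r, b = labels.formation, labels.quiescence, labels.resorption, labels.background
    if not (q.any() or r.any()):
        warnings.warn("no bone at the earlier frame; surface map is empty", stacklevel=2)
        return SurfaceStateMap(np.empty((0, 3), np.int64), np.empty(0, np.int64), np.empty(0))
    has_f = ndimage.binary_dilation(f, structure=_FACE)
    has_b = ndimage.binary_dilation(b, structure=_FACE)
    formation = q & has_f
    resorption = r & has_b
    quiescence = q & has_b & ~has_f
    state = np.full(labels.shape, -1, dtype=np.int64)
    state[quiescence] = STATE_QUIESCENCE
    state[resorption] = STATE_RESORPTION
    state[formation] = STATE_FORMATION
    surf = state >= 0
    idx = np.argwhere(surf)
    states = state[surf]
    if eff_strain is None:
        signal = np.zeros(idx.shape[0])
    elif sample == "bone":
        signal = np.asarray(eff_strain, dtype=np.float64)[surf]
    elif sample == "soft":
        soft = ~(q | r)
        num = ndimage.correlate(
            np.where(soft, np.asarray(eff_strain, dtype=np.float64), 0.0),
            _FACE.astype(float), mode="constant",
        )
        den = ndimage.correlate(soft.astype(float), _FACE.astype(float), mode="constant")
        mean = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
        signal = mean[surf]
    else:
        raise ValueError(f"unknown sampling mode {sample!r}")
    return SurfaceStateMap(
        indices=idx,
        states=states,
        signal=signal,
        meta={"threshold": labels.threshold, "frames": labels.frames, "sample": sample},
    )


def classify_surface(surface: SurfaceStateMap, pair: ThresholdPair) -> np.ndarray:
    """Mechanostat prediction: S > T_F formation, S < T_R resorption,
    quiescence otherwise (boundary values fall in the closed middle band)."""
    s = surface.signal
    out = np.full(s.shape, STATE_QUIESCENCE, dtype=np.int64)
    out[s > pair.t_f] = STATE_FORMATION
    out[s < pair.t_r] = STATE_RESORPTION
    return out


def confusion_ccr(predicted: np.ndarray, truth: np.ndarray) -> ConfusionMatrix:
    """Category-normalised confusion matrix and mean correct classification rate.

    ``C[i, j] = |{pred = i and true = j}| / |{true = j}|`` (columns sum to 1
    for non-empty true categories); ``CCR = trace(C) / 3``.  Empty truth
    categories contribute 0 to the trace and are flagged.
    """
    predicted = np.asarray(predicted, dtype=np.int64)
    truth = np.asarray(truth, dtype=np.int64)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have the same length")
    counts = np.bincount(predicted * 3 + truth, minlength=9).reshape(3, 3)
    col = counts.sum(axis=0)
    if not col.any():
        raise ValueError("all truth categories are empty")
    matrix = np.divide(counts, col[None, :], out=np.zeros((3, 3)), where=col[None, :] > 0)
    ccr = (matrix[0, 0] + matrix[1, 1] + matrix[2, 2]) / 3.0
    empty = tuple(STATE_NAMES[j] for j in range(3) if col[j] == 0)
    return ConfusionMatrix(matrix=matrix, ccr=float(ccr), counts=counts, empty_categories=empty)


def ccr_heatmap(
    surface: SurfaceStateMap,
    grid: int | np.ndarray = 64,
) -> RemodelHeatmap:
    """CCR over every admissible (T_R, T_F) pair of a threshold grid.

    ``grid`` is either an explicit threshold array or a count of
    quantile-spaced thresholds over the signal range.  Only pairs with
    T_R < T_F are evaluated; the argmax is recorded with lexicographically
    smallest (T_R, T_F) on ties.
    """
    if len(surface) == 0:
        raise ValueError("empty surface map")
    if isinstance(grid, (int, np.integer)):
        qs = np.linspace(0.0, 1.0, int(grid))
        thresholds = np.unique(np.quantile(surface.signal, qs))
    else:
        thresholds = np.unique(np.asarray(grid, dtype=np.float64))
    m = thresholds.size
    s = surface.signal
    g = surface.states
    per_state_sorted = [np.sort(s[g == st]) for st in range(3)]
    n_per = np.array([a.size for a in per_state_sorted], dtype=np.int64)
    if not n_per.any():
        raise ValueError("all truth categories are empty")

    def count_below(arr, t, strict):
        return np.searchsorted(arr, t, side="left" if strict else "right")

    # diagonal entries as functions of one threshold each
    sf, sq, sr = per_state_sorted
    nf, nq, nr = n_per
    f_correct = nf - count_below(sf, thresholds, strict=False)  # S > T_F
    r_correct = count_below(sr, thresholds, strict=True)  # S < T_R
    q_le = count_below(sq, thresholds, strict=False)  # S <= t
    q_lt = count_below(sq, thresholds, strict=True)  # S < t

    c_ff = (f_correct / nf) if nf else np.zeros(m)
    c_rr = (r_correct / nr) if nr else np.zeros(m)
    # quiescent correct: T_R <= S <= T_F -> (#S<=T_F) - (#S<T_R)
    if nq:
        c_qq = (q_le[None, :] - q_lt[:, None]) / nq  # [i_tr, i_tf]
    else:
        c_qq = np.zeros((m, m))
    ccr = (c_ff[None, :] + c_qq + c_rr[:, None]) / 3.0
    ccr = np.where(thresholds[:, None] < thresholds[None, :], ccr, np.nan)

    flat = np.where(np.isnan(ccr), -np.inf, ccr)
    best_flat = int(np.argmax(flat))  # first max in C order = smallest (T_R, T_F)
    i, j = divmod(best_flat, m)
    if not np.isfinite(flat[i, j]):
        raise ValueError("threshold grid admits no pair with T_R < T_F")
    pair = ThresholdPair(float(thresholds[i]), float(thresholds[j]))
    return RemodelHeatmap(
        t_r_grid=thresholds,
        t_f_grid=thresholds,
        ccr=ccr,
        best_pair=pair,
        max_ccr=float(ccr[i, j]),
        meta=dict(surface.meta),
    )
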