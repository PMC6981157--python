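"""Bone-volume time courses and formation/resorption rates per VOI and
density threshold, as tidy tables (one row per frame x threshold x VOI)."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .imageproc import BinaryMask, OverlayLabels
from .voi import VOISet

__all__ = ["bvtv_timecourse", "remodelling_rates", "plot_timecourse", "plot_rates"]

VOI_NAMES = ("DC", "DP", "FC", "FP")


def bvtv_timecourse(
    mask_series: Mapping[float, Sequence[BinaryMask]],
    vois: VOISet,
) -> pd.DataFrame:
    """BV and BV/TV per frame, threshold and VOI.

    ``mask_series`` maps each ladder threshold to its time-ordered masks
    (already registered to the VOI frame).  TV is the defect TV for DC/DP
    and the fragment TV for FC/FP.
    """
    vox3 = vois.voxel_volume_mm3
    rows = []
    for tau, masks in mask_series.items():
        for mask in masks:
            if mask.shape != vois.dc.shape:
                raise ValueError(f"mask shape {mask.shape} does not match VOIs {vois.dc.shape}")
            for name in VOI_NAMES:
                voi = vois.mask(name)
                bv = float(np.count_nonzero(mask.values & voi)) * vox3
                tv = vois.tv_for(name)
                rows.append(
                    {
                        "frame": mask.frame,
                        "threshold": tau,
                        "voi": name,
                        "bv_mm3": bv,
                        "tv_mm3": tv,
                        "bvtv": bv / tv,
                    }
                )
    return pd.DataFrame(rows).sort_values(["threshold", "voi", "frame"]).reset_index(drop=True)


def remodelling_rates(
    overlay_series: Mapping[float, Sequence[OverlayLabels]],
    vois: VOISet,
) -> pd.DataFrame:
    """Formed/resorbed volume per week, per threshold and VOI.

    Rates are reported both as absolute mm^3 per week and as a fraction of
    the VOI's TV per week (frame spacing is one week).  The conservation
    identity BV(t+1) = BV(t) + formed - resorbed holds exactly by
    construction of the overlay.
    """
    vox3 = vois.voxel_volume_mm3
    rows = []
    for tau, overlays in overlay_series.items():
        for ov in overlays:
            if ov.threshold != tau:
                raise ValueError(
                    f"overlay threshold {ov.threshold} does not match series key {tau}"
                )
            if ov.shape != vois.dc.shape:
                raise ValueError(f"overlay shape {ov.shape} does not match VOIs {vois.dc.shape}")
            for name in VOI_NAMES:
                voi = vois.mask(name)
                formed = float(np.count_nonzero(ov.formation & voi)) * vox3
                resorbed = float(np.count_nonzero(ov.resorption & voi)) * vox3
                tv = vois.tv_for(name)
                rows.append(
                    {
                        "frame_from": ov.frames[0],
                        "frame_to": ov.frames[1],
                        "threshold": tau,
                        "voi": name,
                        "formed_mm3": formed,
                        "resorbed_mm3": resorbed,
                        "formed_rate": formed / tv,
                        "resorbed_rate": resorbed / tv,
                    }
                )
    return (
        pd.DataFrame(rows)
        .sort_values(["threshold", "voi", "frame_from"])
        .reset_index(drop=True)
    )


def plot_timecourse(df: pd.DataFrame, path: str) -> None:
    """Four-panel BV/TV time-course figure (one panel per VOI)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    for ax, name in zip(axes.ravel(), VOI_NAMES):
        sub = df[df["voi"] == name]
        for tau, grp in sub.groupby("threshold"):
            ax.plot(grp["frame"], grp["bvtv"], marker="o", ms=3, label=f"{tau:g}")
        ax.set_title(name)
        ax.set_xlabel("frame (weeks)")
        ax.set_ylabel("BV/TV")
    axes[0, 0].legend(fontsize=6, title="mg HA/cm$^3$", ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_rates(df: pd.DataFrame, path: str) -> None:
    """Formation/resorption rate panels per VOI (resorption plotted negative)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    for ax, name in zip(axes.ravel(), VOI_NAMES):
        sub = df[df["voi"] == name]
        for tau, grp in sub.groupby("threshold"):
            ax.plot(grp["frame_to"], grp["formed_rate"], marker="^", ms=3, label=f"{tau:g}")
            ax.plot(grp["frame_to"], -grp["resorbed_rate"], marker="v", ms=3)
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_title(name)
        ax.set_xlabel("frame (weeks)")
        ax.set_ylabel("rate (TV fraction / week)")
    axes[0, 0].legend(fontsize=6, title="mg HA/cm$^3$", ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
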