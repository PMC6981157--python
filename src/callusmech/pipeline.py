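"""End-to-end study runner: phantom -> preprocessing -> VOIs -> FE ->
mechanoregulation statistics -> kinetics -> report.

A study is described by a single :class:`StudyConfig` (YAML-serialisable).
Every constant of the analysis appears in the config and is echoed into the
run manifest; nothing numeric is hard-coded at run time.  A single global
seed is fanned out to the per-stage generators through
``numpy.random.SeedSequence(seed).spawn()`` in a fixed order (0: healing
rule, 1: image noise), so any stage can be replayed in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging

import h5py
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .imageproc import (
    DensityImage,
    ThresholdLadder,
    apply_ladder,
    apply_offset,
    gaussian_smooth,
    overlay,
    register_translation,
)
from .kinetics import bvtv_timecourse, plot_rates, plot_timecourse, remodelling_rates
from .mechreg import ccr_heatmap, extract_surface_states, roc_analysis
from .phantom import (
    HealingLoading,
    HealingRule,
    PhantomGeometry,
    add_image_noise,
    build_phantom,
    simulate_healing,
)
from .voi import define_vois

__all__ = ["StudyConfig", "StageError", "run_study", "make_report"]

logger = logging.getLogger("callusmech")


class StageError(RuntimeError):
    """A pipeline stage failed; artefacts of completed stages are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _require(d: dict, key: str, ctx: str):
    if key not in d:
        raise ValueError(f"config error: missing required key {key!r} in {ctx}")
    return d[key]


@dataclass
class StudyConfig:
    """Complete, validated description of one study run."""

    seed: int = 1
    n_frames: int = 6
    out_dir: str = "results"
    geometry: PhantomGeometry = field(default_factory=PhantomGeometry)
    rule: HealingRule = field(default_factory=HealingRule)
    loading: HealingLoading = field(default_factory=HealingLoading)
    ladder: ThresholdLadder = field(default_factory=ThresholdLadder)
    noise_sigma: float = 0.0
    smoothing_enabled: bool = True
    smoothing_sigma: float = 1.2
    smoothing_support: int = 1
    registration_enabled: bool = False
    soft_modulus: float = 3.0
    voi_threshold: float = 645.0
    voi_connectivity: int = 26
    roc_vois: tuple[str, ...] = ("DC", "DP")
    roc_thresholds: tuple[float, ...] | None = None  # None = full ladder
    heatmap_thresholds: tuple[float, ...] = (395.0,)
    heatmap_grid: int = 64
    image_format: str = "mha"

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        raw = dict(raw)
        material = _require(raw, "material", "study config")
        soft = _require(material, "soft_modulus", "material")
        loading_raw = dict(_require(raw, "loading", "study config"))
        smoothing = raw.get("smoothing", {})
        phantom_raw = raw.get("phantom", {})
        geometry_raw = dict(phantom_raw.get("geometry", {}))
        if "grid_shape" in geometry_raw:
            geometry_raw["grid_shape"] = tuple(geometry_raw["grid_shape"])
        rule_raw = dict(phantom_raw.get("rule", {}))
        ladder_spec = raw.get("ladder", "395:720:25")
        loading_raw.setdefault("nu", material.get("nu", 0.3))
        loading_raw.setdefault("material_mode", material.get("mode", "banded"))
        cfg = cls(
            seed=int(raw.get("seed", 1)),
            n_frames=int(_require(raw, "n_frames", "study config")),
            out_dir=str(raw.get("out_dir", "results")),
            geometry=PhantomGeometry(**geometry_raw),
            rule=HealingRule(**rule_raw),
            loading=HealingLoading(**loading_raw),
            ladder=ThresholdLadder.from_spec(ladder_spec)
            if isinstance(ladder_spec, str)
            else ThresholdLadder(tuple(ladder_spec)),
            noise_sigma=float(raw.get("noise_sigma", 0.0)),
            smoothing_enabled=bool(smoothing.get("enabled", True)),
            smoothing_sigma=float(smoothing.get("sigma", 1.2)),
            smoothing_support=int(smoothing.get("support", 1)),
            registration_enabled=bool(raw.get("registration_enabled", False)),
            soft_modulus=float(soft),
            voi_threshold=float(raw.get("voi", {}).get("threshold", 645.0)),
            voi_connectivity=int(raw.get("voi", {}).get("connectivity", 26)),
            roc_vois=tuple(raw.get("mechreg", {}).get("roc_vois", ("DC", "DP"))),
            roc_thresholds=tuple(raw.get("mechreg", {}).get("roc_thresholds"))
            if raw.get("mechreg", {}).get("roc_thresholds")
            else None,
            heatmap_thresholds=tuple(raw.get("mechreg", {}).get("heatmap_thresholds", (395.0,))),
            heatmap_grid=int(raw.get("mechreg", {}).get("heatmap_grid", 64)),
            image_format=str(raw.get("image_format", "mha")),
        )
        if cfg.n_frames < 1:
            raise ValueError("config error: n_frames must be >= 1")
        if cfg.noise_sigma < 0:
            raise ValueError("config error: noise_sigma must be >= 0")
        return cfg

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_frames": self.n_frames,
            "out_dir": self.out_dir,
            "phantom": {
                "geometry": dataclasses.asdict(self.geometry),
                "rule": dataclasses.asdict(self.rule),
            },
            "loading": dataclasses.asdict(self.loading),
            "ladder": list(self.ladder.thresholds),
            "noise_sigma": self.noise_sigma,
            "smoothing": {
                "enabled": self.smoothing_enabled,
                "sigma": self.smoothing_sigma,
                "support": self.smoothing_support,
            },
            "registration_enabled": self.registration_enabled,
            "material": {
                "soft_modulus": self.soft_modulus,
                "nu": self.loading.nu,
                "mode": self.loading.material_mode,
            },
            "voi": {"threshold": self.voi_threshold, "connectivity": self.voi_connectivity},
            "mechreg": {
                "roc_vois": list(self.roc_vois),
                "roc_thresholds": list(self.roc_thresholds) if self.roc_thresholds else None,
                "heatmap_thresholds": list(self.heatmap_thresholds),
                "heatmap_grid": self.heatmap_grid,
            },
            "image_format": self.image_format,
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> Path:
    """Run the full study; returns the results directory.

    Deterministic under a fixed seed.  Any stage failure raises
    :class:`StageError` naming the stage; artefacts written by completed
    stages remain on disk.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "images").mkdir(exist_ok=True)
    (out / "strain").mkdir(exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stage = "setup"
    try:
        ss = np.random.SeedSequence(config.seed)
        child_rule, child_noise = ss.spawn(2)
        rule = dataclasses.replace(
            config.rule, rng_seed=int(child_rule.generate_state(1)[0])
        )
        noise_seeds = child_noise.generate_state(config.n_frames)

        stage = "phantom"
        logger.info("building phantom and simulating %d frames", config.n_frames)
        baseline = build_phantom(config.geometry)
        if config.n_frames > 1:
            frames, log = simulate_healing(
                baseline, rule, config.loading, n_steps=config.n_frames - 1, ladder=config.ladder
            )
            io.write_event_log(log, out / "events.h5")
        else:
            frames, log = [baseline], None

        if config.noise_sigma > 0:
            frames = [
                add_image_noise(f, config.noise_sigma, rng_seed=int(noise_seeds[i]))
                for i, f in enumerate(frames)
            ]

        stage = "imageproc"
        if config.smoothing_enabled:
            processed = [
                gaussian_smooth(f, sigma=config.smoothing_sigma, support=config.smoothing_support)
                for f in frames
            ]
        else:
            processed = [f.copy() for f in frames]
        if config.registration_enabled:
            for i in range(1, len(processed)):
                off = register_translation(processed[i], processed[0])
                if np.any(off):
                    logger.info("frame %d registered with offset %s", i, off.tolist())
                    processed[i] = apply_offset(processed[i], off)
        for i, f in enumerate(processed):
            io.write_image(f, out / "images" / f"frame_{i:03d}.{config.image_format}")
        per_frame = [apply_ladder(f, config.ladder) for f in processed]
        masks = {tau: [pf[j] for pf in per_frame] for j, tau in enumerate(config.ladder)}

        stage = "voi"
        vois = define_vois(
            processed[0], threshold=config.voi_threshold, connectivity=config.voi_connectivity
        )
        io.write_voi_set(vois, out / f"voi.{config.image_format}")

        stage = "microfe"
        from .phantom import _step_strain

        strain_fields = []
        warm = None
        for i, f in enumerate(processed):
            eff, warm = _step_strain(f, config.loading, config.ladder, x0=warm)
            strain_fields.append(eff)
            with h5py.File(out / "strain" / f"frame_{i:03d}.h5", "w") as h5:
                h5.create_dataset("eff_strain", data=eff.astype(np.float32), compression="gzip")
        logger.info("solved %d FE frames", len(strain_fields))

        stage = "mechreg"
        roc_taus = config.roc_thresholds or tuple(config.ladder)
        roc_mask = np.zeros(vois.dc.shape, dtype=bool)
        for name in config.roc_vois:
            roc_mask |= vois.mask(name)
        roc_rows, ccr_rows = [], []
        overlays = {tau: [] for tau in config.ladder}
        for t in range(len(processed) - 1):
            for tau in config.ladder:
                ov = overlay(masks[tau][t], masks[tau][t + 1])
                overlays[tau].append(ov)
                if tau in roc_taus:
                    try:
                        roc = roc_analysis(strain_fields[t], ov, roc_mask)
                        roc_rows.append(
                            {
                                "frame_from": t,
                                "frame_to": t + 1,
                                "threshold": tau,
                                "voi": "+".join(config.roc_vois),
                                "auc": roc.auc,
                                "tpr_opt": roc.tpr_opt,
                                "fpr_opt": roc.fpr_opt,
                                "t_opt": roc.t_opt,
                                "n_pos": roc.n_pos,
                                "n_neg": roc.n_neg,
                            }
                        )
                    except ValueError as exc:
                        logger.warning("ROC skipped (t=%d tau=%g): %s", t, tau, exc)
                if tau in config.heatmap_thresholds:
                    surf = extract_surface_states(ov, strain_fields[t])
                    if len(surf):
                        hm = ccr_heatmap(surf, grid=config.heatmap_grid)
                        ccr_rows.append(
                            {
                                "frame_from": t,
                                "frame_to": t + 1,
                                "threshold": tau,
                                "max_ccr": hm.max_ccr,
                                "t_r_opt": hm.best_pair.t_r,
                                "t_f_opt": hm.best_pair.t_f,
                                "n_surface": len(surf),
                            }
                        )
        roc_cols = ["frame_from", "frame_to", "threshold", "voi", "auc", "tpr_opt",
                    "fpr_opt", "t_opt", "n_pos", "n_neg"]
        ccr_cols = ["frame_from", "frame_to", "threshold", "max_ccr", "t_r_opt",
                    "t_f_opt", "n_surface"]
        _csv(pd.DataFrame(roc_rows, columns=roc_cols), out / "roc.csv")
        _csv(pd.DataFrame(ccr_rows, columns=ccr_cols), out / "ccr.csv")

        stage = "kinetics"
        bvtv = bvtv_timecourse(masks, vois)
        _csv(bvtv, out / "kinetics_bvtv.csv")
        rate_cols = ["frame_from", "frame_to", "threshold", "voi", "formed_mm3",
                     "resorbed_mm3", "formed_rate", "resorbed_rate"]
        if any(len(v) for v in overlays.values()):
            rates = remodelling_rates(overlays, vois)
        else:
            rates = pd.DataFrame(columns=rate_cols)
        _csv(rates, out / "kinetics_rates.csv")

        stage = "manifest"
        manifest = {
            "version": __version__,
            "config": config.to_dict(),
            "effective_rule_seed": rule.rng_seed,
            "tv_defect_mm3": vois.tv_defect,
            "tv_fragment_mm3": vois.tv_fragment,
            "n_frames": len(processed),
            "stages": ["phantom", "imageproc", "voi", "microfe", "mechreg", "kinetics"],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        logger.info("study complete: %s", out)
        return out
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise StageError(stage, exc) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()


def make_report(results_dir: str | Path) -> Path:
    """Render figures and a summary document from a completed run.

    Every number shown is read from the run's CSV tables; regeneration is
    idempotent.  Missing tables are reported as explicit gaps; an empty
    directory is an error.
    """
    results = Path(results_dir)
    if not results.is_dir() or not any(results.iterdir()):
        raise ValueError(f"no results found in {results_dir}")
    lines = ["# Study report", ""]
    figures = []

    bvtv_path = results / "kinetics_bvtv.csv"
    if bvtv_path.exists():
        bvtv = pd.read_csv(bvtv_path)
        if len(bvtv):
            plot_timecourse(bvtv, str(results / "fig_bvtv.png"))
            figures.append("fig_bvtv.png")
        lines += ["## BV/TV time course", "", f"{len(bvtv)} rows (kinetics_bvtv.csv)", ""]
    else:
        lines += ["## BV/TV time course", "", "MISSING: kinetics_bvtv.csv", ""]

    rates_path = results / "kinetics_rates.csv"
    if rates_path.exists():
        rates = pd.read_csv(rates_path)
        if len(rates):
            plot_rates(rates, str(results / "fig_rates.png"))
            figures.append("fig_rates.png")
        lines += ["## Mineralisation kinetics", "", f"{len(rates)} rows (kinetics_rates.csv)", ""]
    else:
        lines += ["## Mineralisation kinetics", "", "MISSING: kinetics_rates.csv", ""]

    roc_path = results / "roc.csv"
    if roc_path.exists():
        roc = pd.read_csv(roc_path)
        lines += ["## Strain vs mineralisation (ROC)", ""]
        if len(roc):
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
            for tau, grp in roc.groupby("threshold"):
                axes[0].plot(grp["frame_to"], grp["auc"], marker="o", ms=3, label=f"{tau:g}")
                axes[1].plot(grp["frame_to"], grp["tpr_opt"], marker="o", ms=3)
                axes[2].plot(grp["frame_to"], grp["t_opt"], marker="o", ms=3)
            for ax, ttl in zip(axes, ("AUC", "TPR at optimum", "optimal eff. strain")):
                ax.set_xlabel("frame")
                ax.set_title(ttl)
            axes[0].legend(fontsize=6, title="mg HA/cm$^3$")
            fig.tight_layout()
            fig.savefig(results / "fig_roc.png", dpi=150)
            plt.close(fig)
            figures.append("fig_roc.png")
            lines += [roc.to_markdown(index=False), ""]
        else:
            lines += ["(no ROC rows)", ""]
    else:
        lines += ["## Strain vs mineralisation (ROC)", "", "MISSING: roc.csv", ""]

    ccr_path = results / "ccr.csv"
    if ccr_path.exists():
        ccr = pd.read_csv(ccr_path)
        lines += ["## Surface remodelling classification (CCR)", ""]
        lines += [ccr.to_markdown(index=False) if len(ccr) else "(no CCR rows)", ""]
    else:
        lines += ["## Surface remodelling classification (CCR)", "", "MISSING: ccr.csv", ""]

    if figures:
        lines += ["## Figures", ""] + [f"![{f}]({f})" for f in figures] + [""]
    report = results / "report.md"
    report.write_text("\n".join(lines))
    return report
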