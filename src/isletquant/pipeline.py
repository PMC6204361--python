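"""End-to-end orchestration: synthesize, measure, analyze, compare, report.

``run_pipeline`` executes the stages in order — phantom generation →
morphometry → perifusion simulation → secretion metrics → qPCR folds →
group statistics — writing CSV tables, a JSON summary with provenance
(seed, thresholds actually applied, package version), and a review
manifest of QC-flagged images.  All outputs are pure functions of
(config, seed): rerunning with the same config reproduces them
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .io import particles_to_frame, write_json
from .morphometry import (
    ellipsoid_volume,
    equivalent_diameter,
    measure_stack,
    summarize_morphometry,
)
from .perifusion import build_sampling_grid, compare_groups_ratio, secretion_metrics
from .qpcr import fold_vs_reference_group
from .stats import compare_two_groups
from .synthetic import (
    GLUCOSE_PRESETS,
    PhantomObject,
    PhantomSpec,
    generate_phantom_stack,
    generate_qpcr_fixture,
    simulate_perifusion_trace,
)

__all__ = ["run_pipeline"]

#: Size regimes emulated by the morphometry stage: cultured-intact islets
#: vary widely (major axis 140-310 um); pseudoislets are uniform (~205 um).
_PHANTOM_GROUPS = {
    "cultured": dict(major_range=(140.0, 310.0), aspect_range=(0.6, 1.0)),
    "pseudoislet": dict(major_range=(196.0, 214.0), aspect_range=(0.9, 1.0)),
}


def _derive_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def _morphometry_stage(cfg: RunConfig, rng: np.random.Generator, out: Path):
    m = cfg.morphometry
    rows, flagged_rows, group_summaries = [], [], []
    nz, ny, nx = cfg.synth.image_shape
    pixel_size = m.pixel_size_um or 1.0
    for group, regime in _PHANTOM_GROUPS.items():
        islets = []
        for i in range(cfg.synth.n_phantoms_per_group):
            major = float(rng.uniform(*regime["major_range"]))
            minor = major * float(rng.uniform(*regime["aspect_range"]))
            obj = PhantomObject(
                center_xy=(nx / 2.0, ny / 2.0),
                major_axis_um=major,
                minor_axis_um=minor,
                orientation_rad=float(rng.uniform(0, np.pi)),
            )
            spec = PhantomSpec(
                image_shape=(nz, ny, nx),
                pixel_size_um=pixel_size,
                objects=(obj,),
                n_debris=cfg.synth.n_debris,
                noise_sd=cfg.synth.phantom_noise_sd,
                seed=_derive_seed(rng),
            )
            stack, _ = generate_phantom_stack(spec)
            particles, mask = measure_stack(
                stack,
                threshold_method=m.threshold_method,
                manual_threshold=m.manual_threshold,
                n_erode=m.n_erode,
                n_dilate=m.n_dilate,
                selem_radius=m.selem_radius,
                circ_min=m.circ_min,
                circ_max=m.circ_max,
                max_area_fraction=m.max_area_fraction,
            )
            name = f"{group}_{i + 1:02d}"
            frame = particles_to_frame(particles, image=name)
            frame.insert(1, "group", group)
            frame.insert(2, "threshold_used", mask.threshold)
            rows.append(frame)
            accepted = [p for p in particles if p.qc_status == "accepted"]
            if accepted:
                islets.append(max(accepted, key=lambda p: p.area_mm2))
            for p in particles:
                if p.qc_status == "flagged":
                    flagged_rows.append(
                        {"image": name, "group": group, "label": p.label,
                         "reason": p.flag_reason}
                    )
        if len(islets) >= 2:
            summary = summarize_morphometry(islets)
            for metric, s in summary.metrics.items():
                group_summaries.append(
                    {"group": group, "metric": metric, "n": summary.n,
                     "mean": s.mean, "sd": s.sd, "cv_percent": s.cv_percent}
                )
    measurements = pd.concat(rows, ignore_index=True)
    summary_df = pd.DataFrame(group_summaries)
    manifest = pd.DataFrame(flagged_rows, columns=["image", "group", "label", "reason"])
    measurements.to_csv(out / "morphometry_measurements.csv", index=False)
    summary_df.to_csv(out / "morphometry_summary.csv", index=False)
    manifest.to_csv(out / "review_manifest.csv", index=False)
    return measurements, summary_df, manifest


def _perifusion_stage(cfg: RunConfig, rng: np.random.Generator, out: Path):
    grid = build_sampling_grid(
        cfg.perifusion.run_length_min, cfg.perifusion.flow_rate_ul_min
    )
    rows = []
    for group, preset in GLUCOSE_PRESETS.items():
        for donor in range(cfg.synth.n_donors_per_group):
            spec = replace(
                preset, noise_cv=cfg.synth.trace_noise_cv, seed=_derive_seed(rng)
            )
            trace, gt = simulate_perifusion_trace(spec, grid)
            metrics = secretion_metrics(trace)
            rows.append(
                {
                    "group": group,
                    "donor": f"{group}_{donor + 1:02d}",
                    "basal_mean": metrics.basal_mean,
                    "si_first": metrics.si_first,
                    "si_second": metrics.si_second,
                    "first_second_ratio": metrics.first_second_ratio,
                    "auc_ramp": metrics.auc_ramp,
                    "true_ratio": gt.first_second_ratio,
                }
            )
    metrics_df = pd.DataFrame(rows)
    ratios = {
        g: sub["first_second_ratio"].tolist() for g, sub in metrics_df.groupby("group")
    }
    percent = compare_groups_ratio(ratios, reference_group="fresh")
    ratio_df = (
        metrics_df.groupby("group")["first_second_ratio"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    ratio_df["percent_of_fresh"] = ratio_df["group"].map(percent)
    metrics_df.to_csv(out / "secretion_metrics.csv", index=False)
    ratio_df.to_csv(out / "si_ratio_summary.csv", index=False)
    return metrics_df, ratio_df


def _qpcr_stage(cfg: RunConfig, rng: np.random.Generator, out: Path):
    table = generate_qpcr_fixture(
        n_samples=cfg.synth.qpcr_n_samples,
        groups=("fresh", "cultured", "pseudoislet"),
        effect_map={"pseudoislet": {"SST": 2.3}, "cultured": {"INS": 0.7}},
        seed=_derive_seed(rng),
    )
    folds = fold_vs_reference_group(table, reference_group="fresh")
    folds.to_csv(out / "qpcr_folds.csv", index=False)
    return folds


def _stats_stage(cfg: RunConfig, metrics_df: pd.DataFrame, out: Path):
    rows = []
    groups = list(metrics_df["group"].unique())
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            res = compare_two_groups(
                metrics_df.loc[metrics_df["group"] == a, "first_second_ratio"],
                metrics_df.loc[metrics_df["group"] == b, "first_second_ratio"],
                alpha=cfg.stats.alpha,
            )
            rows.append(
                {"group_a": a, "group_b": b, "metric": "first_second_ratio",
                 "test_used": res.test_used, "f_pvalue": res.f_pvalue,
                 "t_statistic": res.t_statistic, "t_pvalue": res.t_pvalue,
                 "significant": res.significant}
            )
    stats_df = pd.DataFrame(rows)
    stats_df.to_csv(out / "group_comparisons.csv", index=False)
    return stats_df


def run_pipeline(cfg: RunConfig) -> Dict[str, object]:
    """Run every stage on synthetic inputs and write the report bundle."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    measurements, morph_summary, manifest = _morphometry_stage(cfg, rng, out)
    metrics_df, ratio_df = _perifusion_stage(cfg, rng, out)
    folds = _qpcr_stage(cfg, rng, out)
    stats_df = _stats_stage(cfg, metrics_df, out)

    islet_rows = morph_summary[morph_summary["metric"] == "area_mm2"]
    summary = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.model_dump(mode="json"),
        "cv_area_percent_by_group": dict(
            zip(islet_rows["group"], islet_rows["cv_percent"])
        ),
        "si_ratio_percent_of_fresh": dict(
            zip(ratio_df["group"], ratio_df["percent_of_fresh"])
        ),
        "n_flagged_images": int(manifest["image"].nunique()) if len(manifest) else 0,
    }
    write_json(summary, out / "summary.json")
    return {
        "measurements": measurements,
        "morphometry_summary": morph_summary,
        "review_manifest": manifest,
        "secretion_metrics": metrics_df,
        "si_ratio_summary": ratio_df,
        "qpcr_folds": folds,
        "group_comparisons": stats_df,
        "summary": summary,
        "out_dir": out,
    }
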