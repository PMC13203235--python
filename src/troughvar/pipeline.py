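"""End-to-end analysis runner and report assembly.

``run_analysis`` executes, in order: cohort accounting (before/after the
minimum-measurement filter), per-patient metrics, the two-cohort comparison
table, zone distributions, pooled transition matrices, exploratory predictor
correlations, and optional sensitivity (k=2) and loading-dose-stratified
reruns.  A stage failure is recorded and aborts only the stages that depend
on it.  The JSON summary keeps full precision and is a pure function of
(input, config); timestamps appear only in the log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from . import __version__
from .data import (
    Cohort,
    PatientCovariates,
    filter_min_measurements,
    read_covariates_table,
    read_trough_table,
    write_covariates_table,
    write_trough_table,
)
from .errors import InsufficientDataError, TroughVarError
from .metrics import (
    profile_cohort,
    profiles_to_frame,
    summarize_profiles,
)
from .simulate import preset_configs, simulate_cohort
from .stats import (
    build_comparison_table,
    comparison_to_frame,
    comparison_to_markdown,
    explore_predictors,
)
from .zones import pooled_transition_matrix, zone_distribution

logger = logging.getLogger("troughvar")


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a full analysis run."""

    input_path: str | None = None
    covariates_path: str | None = None
    preset: str | None = None
    min_measurements: int = 3
    zone_low: float = 15.0
    zone_high: float = 20.0
    stability_threshold: float = 20.0
    seed: int = 0
    out_dir: str | None = None
    sensitivity: bool = False
    loading_dose_stratified: bool = False
    exact_limit: int = 400
    make_figures: bool = False

    def __post_init__(self):
        if self.zone_low >= self.zone_high:
            raise TroughVarError("zone_low must be < zone_high")
        if self.min_measurements < 1:
            raise TroughVarError("min_measurements must be >= 1")
        if self.input_path is None and self.preset is None:
            raise TroughVarError("either input_path or preset is required")


def _summary_dict(summary) -> dict:
    return {
        "median": summary.median,
        "q1": summary.q1,
        "q3": summary.q3,
    }


def _comparison_records(rows) -> list[dict]:
    return [dataclasses.asdict(r) for r in rows]


def load_inputs(
    config: RunConfig,
) -> tuple[dict[str, Cohort], dict[str, PatientCovariates]]:
    """Read cohorts + covariates from disk or generate them from a preset."""
    if config.preset is not None:
        pre_cfg, post_cfg = preset_configs(config.preset, config.seed)
        pre, cov_pre = simulate_cohort(pre_cfg)
        post, cov_post = simulate_cohort(post_cfg)
        covariates = {**cov_pre, **cov_post}
        return {pre.label: pre, post.label: post}, covariates
    cohorts = read_trough_table(config.input_path)
    covariates: dict[str, PatientCovariates] = {}
    if config.covariates_path:
        covariates = read_covariates_table(config.covariates_path)
    return cohorts, covariates


def _analyze_pair(
    cohorts: Mapping[str, Cohort],
    covariates: Mapping[str, PatientCovariates],
    config: RunConfig,
    k: int,
    errors: dict,
    stage_prefix: str = "",
) -> dict:
    """One accounting/metrics/comparison/zone pass at a given filter k."""
    out: dict = {"min_measurements": k}
    filtered = {
        label: filter_min_measurements(c, k) for label, c in cohorts.items()
    }
    out["accounting"] = {
        label: {
            "patients_before": cohorts[label].n_patients,
            "measurements_before": cohorts[label].n_measurements,
            "patients_after": filtered[label].n_patients,
            "measurements_after": filtered[label].n_measurements,
        }
        for label in cohorts
    }
    out["total_measurements_after"] = sum(
        c.n_measurements for c in filtered.values()
    )

    profiles = {}
    for label, cohort in filtered.items():
        try:
            profiles[label] = profile_cohort(
                cohort,
                stability_threshold=config.stability_threshold,
                zone_low=config.zone_low,
                zone_high=config.zone_high,
            )
        except TroughVarError as exc:
            errors[f"{stage_prefix}profiles:{label}"] = str(exc)
    out["metric_summaries"] = {
        label: {m: _summary_dict(s) for m, s in summarize_profiles(p).items()}
        for label, p in profiles.items()
        if p
    }

    labels = list(cohorts)
    if len(labels) == 2 and all(profiles.get(l) for l in labels):
        try:
            rows = build_comparison_table(
                profiles[labels[0]], profiles[labels[1]],
                exact_limit=config.exact_limit,
            )
            out["comparison"] = {
                "pre_label": labels[0],
                "post_label": labels[1],
                "rows": _comparison_records(rows),
            }
            out["_comparison_rows"] = rows
        except TroughVarError as exc:
            errors[f"{stage_prefix}comparison"] = str(exc)
            logger.warning("comparison stage failed: %s", exc)
    else:
        logger.info(
            "comparison stage skipped: need exactly two nonempty cohorts, "
            "have %s", {l: filtered[l].n_patients for l in labels},
        )
        out["comparison"] = None

    out["zone_distribution"] = {}
    out["transition_matrices"] = {}
    for label, cohort in filtered.items():
        if cohort.n_patients == 0:
            errors[f"{stage_prefix}zones:{label}"] = "empty cohort after filtering"
            continue
        dist = zone_distribution(cohort, config.zone_low, config.zone_high)
        out["zone_distribution"][label] = {
            "counts": {z.label: dist.counts[z] for z in dist.counts},
            "percentages": {z.label: dist.percentages[z] for z in dist.counts},
            "n_total": dist.n_total,
        }
        tm = pooled_transition_matrix(cohort, config.zone_low, config.zone_high)
        out["transition_matrices"][label] = tm.to_dict()
        out.setdefault("_matrices", {})[label] = tm

    out["_profiles"] = profiles
    return out


def run_analysis(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and optionally writes) the summary."""
    out_dir = Path(config.out_dir) if config.out_dir else None
    handler = None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out_dir / "run.log", mode="w")
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run_analysis(config, out_dir)
    finally:
        if handler is not None:
            logger.removeHandler(handler)
            handler.close()


def _run_analysis(config: RunConfig, out_dir: Path | None) -> dict:
    errors: dict[str, str] = {}

    cfg_record = dataclasses.asdict(config)
    logger.info("run configuration: %s", cfg_record)
    summary: dict = {"version": __version__, "config": cfg_record, "errors": errors}

    try:
        cohorts, covariates = load_inputs(config)
    except TroughVarError as exc:
        errors["load"] = str(exc)
        summary["errors"] = errors
        logger.error("input stage failed: %s", exc)
        if out_dir:
            _write_summary(summary, out_dir)
        return summary

    primary = _analyze_pair(
        cohorts, covariates, config, config.min_measurements, errors
    )
    summary["primary"] = {k: v for k, v in primary.items() if not k.startswith("_")}

    # exploratory predictor correlations, per cohort with matched covariates
    if covariates:
        correlations = {}
        for label, profs in primary["_profiles"].items():
            try:
                results, n_unmatched = explore_predictors(profs, covariates)
                correlations[label] = {
                    "n_unmatched": n_unmatched,
                    "results": [dataclasses.asdict(r) for r in results],
                }
            except InsufficientDataError as exc:
                errors[f"correlations:{label}"] = str(exc)
        summary["correlations"] = correlations

    if config.sensitivity:
        sens = _analyze_pair(cohorts, covariates, config, 2, errors, "sensitivity:")
        summary["sensitivity"] = {
            k: v for k, v in sens.items() if not k.startswith("_")
        }

    if config.loading_dose_stratified and covariates:
        strat = {}
        for label, cohort in cohorts.items():
            filtered = filter_min_measurements(cohort, config.min_measurements)
            try:
                rows = stratified_rerun(
                    filtered, covariates, "loading_dose_given", config=config
                )
                strat[label] = _comparison_records(rows)
            except TroughVarError as exc:
                errors[f"stratified:{label}"] = str(exc)
        summary["loading_dose_stratified"] = strat

    summary = _sanitize_nans(summary)
    if out_dir:
        _write_outputs(summary, primary, cohorts, covariates, out_dir, config)
    return summary


def stratified_rerun(
    cohort: Cohort,
    covariates: Mapping[str, PatientCovariates],
    stratum_field: str,
    levels: tuple | None = None,
    config: RunConfig | None = None,
) -> list:
    """Within-cohort comparison of variability metrics between two strata."""
    config = config or RunConfig(preset="primary")
    groups: dict = {}
    for traj in cohort.trajectories:
        cov = covariates.get(traj.patient_id)
        if cov is None:
            continue
        value = getattr(cov, stratum_field)
        if value is None:
            continue
        groups.setdefault(value, []).append(traj)
    if levels is None:
        levels = tuple(sorted(groups, key=str))
    if len(levels) != 2:
        raise InsufficientDataError(
            f"stratum field {stratum_field!r} must have exactly two levels, "
            f"found {sorted(groups, key=str)}"
        )
    for level in levels:
        if len(groups.get(level, [])) < 2:
            raise InsufficientDataError(
                f"stratum {stratum_field}={level!r} has fewer than 2 patients"
            )
    profiled = {
        level: profile_cohort(
            Cohort(cohort.label, tuple(groups[level])),
            stability_threshold=config.stability_threshold,
            zone_low=config.zone_low,
            zone_high=config.zone_high,
        )
        for level in levels
    }
    return build_comparison_table(
        profiled[levels[0]], profiled[levels[1]], exact_limit=config.exact_limit
    )


def _write_summary(summary: dict, out_dir: Path) -> None:
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, allow_nan=False, default=_json_default)
        + "\n"
    )


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _sanitize_nans(obj):
    """Replace NaN floats by None so the summary stays strict JSON."""
    import math

    if isinstance(obj, float) and math.isnan(obj):
        return None
    if isinstance(obj, dict):
        return {k: _sanitize_nans(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize_nans(v) for v in obj]
    return obj


def _write_outputs(summary, primary, cohorts, covariates, out_dir: Path, config) -> None:
    _write_summary(summary, out_dir)

    write_trough_table(cohorts, out_dir / "troughs.csv")
    if covariates:
        write_covariates_table(covariates, out_dir / "covariates.csv")

    all_profiles = [p for profs in primary["_profiles"].values() for p in profs]
    if all_profiles:
        profiles_to_frame(all_profiles).to_csv(out_dir / "metrics.csv", index=False)

    rows = primary.get("_comparison_rows")
    if rows:
        comparison_to_frame(rows).to_csv(out_dir / "comparison.csv", index=False)
        (out_dir / "comparison.md").write_text(comparison_to_markdown(rows))

    for label, tm in primary.get("_matrices", {}).items():
        tm.to_json(out_dir / f"transition_{label}.json")
        tm.to_frame().to_csv(out_dir / f"transition_{label}_counts.csv")

    dist_frames = []
    for label in primary.get("zone_distribution", {}):
        cohort = filter_min_measurements(cohorts[label], primary["min_measurements"])
        frame = zone_distribution(cohort, config.zone_low, config.zone_high).to_frame()
        frame.insert(0, "cohort", label)
        dist_frames.append(frame)
    if dist_frames:
        import pandas as pd

        pd.concat(dist_frames, ignore_index=True).to_csv(
            out_dir / "zone_distribution.csv", index=False
        )

    if config.make_figures:
        try:
            _make_figures(primary, out_dir)
        except Exception as exc:  # figures are strictly optional
            logger.warning("figure generation failed: %s", exc)


def _make_figures(primary, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    profiles = primary["_profiles"]
    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    for ax, metric in zip(axes, ("cv_pct", "swing_index", "trough_range")):
        data = [[getattr(p, metric) for p in profs] for profs in profiles.values()]
        ax.boxplot(data, tick_labels=list(profiles))
        ax.set_title(metric)
    fig.tight_layout()
    fig.savefig(out_dir / "variability_boxplots.png", dpi=150)
    plt.close(fig)

    matrices = primary.get("_matrices", {})
    if matrices:
        fig, axes = plt.subplots(1, len(matrices), figsize=(5 * len(matrices), 4))
        if len(matrices) == 1:
            axes = [axes]
        for ax, (label, tm) in zip(axes, matrices.items()):
            ax.imshow(tm.probabilities, vmin=0, vmax=1, cmap="Blues")
            ax.set_title(f"{label} (n={tm.n_transitions})")
            ax.set_xticks(range(3))
            ax.set_yticks(range(3))
        fig.tight_layout()
        fig.savefig(out_dir / "transition_matrices.png", dpi=150)
        plt.close(fig)
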