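"""End-to-end run: simulate (or load) -> preprocess -> grid-fit -> associate.

A run is fully described by a :class:`RunConfig` (input mode, cohort config
when synthetic, output directory, seed, plotting switch).  All stage outputs
are written as CSV/JSON into the run directory together with a manifest that
records the seed and a hash of the config, so two runs with the same config
and seed produce identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import FeatureRegression
from .preprocess import (
    MinuteSeries,
    WINDOW_HOURS,
    aggregate_hourly,
    apply_exclusion_rule,
    detect_nonwear,
    impute_short_gaps,
)
from .selection import GridResult, SarimaGridSearch, extract_features, features_frame
from .synthetic import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "model_membership_summary",
           "format_percent"]


class PipelineError(RuntimeError):
    """Stage failure carrying the stage name and participant id."""

    def __init__(self, stage: str, participant_id: str, cause: Exception):
        super().__init__(f"stage {stage!r}, participant {participant_id!r}: {cause}")
        self.stage = stage
        self.participant_id = participant_id
        self.cause = cause


@dataclass
class RunConfig:
    """One reproducible pipeline run."""

    outdir: Path
    seed: int = 0
    mode: str = "synthetic"            # "synthetic" | "csv"
    cohort: CohortConfig | None = None
    input_dir: Path | None = None      # csv mode: minute CSVs + scores.csv
    scores_csv: Path | None = None
    n_hours: int = WINDOW_HOURS
    plots: bool = False

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.mode not in ("synthetic", "csv"):
            raise ValueError("mode must be 'synthetic' or 'csv'")
        if self.mode == "synthetic":
            if self.cohort is None:
                self.cohort = dataclasses.replace(CohortConfig(), seed=self.seed)
            self.n_hours = self.cohort.n_hours
        elif self.input_dir is None:
            raise ValueError("csv mode requires input_dir")

    def config_hash(self) -> str:
        payload = {
            "mode": self.mode,
            "seed": self.seed,
            "n_hours": self.n_hours,
            "cohort": self.cohort.to_dict() if self.cohort else None,
            "input_dir": str(self.input_dir) if self.input_dir else None,
        }
        return hashlib.sha256(
            yaml.safe_dump(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def format_percent(count: int, total: int) -> float:
    """Share of analyzed participants, printed to 1 decimal (9/44 -> 20.5)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, 1)


def model_membership_summary(results: list[GridResult]) -> pd.DataFrame:
    """Counts and 1-d.p. percentages of participants per selected model.

    Rows are the distinct selected specs ordered by descending count (ties
    by model number); the aggregate P=0 / P=1 split is available via
    :func:`seasonal_ar_split`.
    """
    if not results:
        raise ValueError("no analyzed participants")
    counts: dict[int, list] = {}
    for res in results:
        entry = counts.setdefault(res.best_number, [res.best_spec.label(), 0])
        entry[1] += 1
    n = len(results)
    rows = [
        {"model": num, "spec": label, "count": cnt,
         "percent": format_percent(cnt, n)}
        for num, (label, cnt) in counts.items()
    ]
    df = pd.DataFrame(rows).sort_values(
        ["count", "model"], ascending=[False, True]
    ).reset_index(drop=True)
    return df


def seasonal_ar_split(results: list[GridResult]) -> dict[str, float]:
    """Share of participants whose selected model has P = 0 vs P = 1."""
    n = len(results)
    n_p1 = sum(res.best_spec.P for res in results)
    return {
        "n_analyzed": n,
        "n_P0": n - n_p1,
        "n_P1": n_p1,
        "percent_P0": format_percent(n - n_p1, n),
        "percent_P1": format_percent(n_p1, n),
    }


def _preprocess_participant(minutes: MinuteSeries, n_hours: int):
    flagged = detect_nonwear(minutes)
    report = apply_exclusion_rule(flagged)
    if report.excluded:
        return report, None
    imputed = impute_short_gaps(flagged)
    hourly = aggregate_hourly(imputed, n_hours=n_hours)
    return report, hourly


def _load_csv_inputs(config: RunConfig):
    input_dir = Path(config.input_dir)
    minute_files = sorted((input_dir / "minutes").glob("*.csv")) or sorted(
        input_dir.glob("*.csv")
    )
    series = [MinuteSeries.from_csv(f) for f in minute_files]
    scores_path = config.scores_csv or (input_dir / "scores.csv")
    scores = pd.read_csv(scores_path) if Path(scores_path).exists() else None
    return series, scores


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run manifest (also written to disk)."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- stage 1: inputs ---------------------------------------------------
    if config.mode == "synthetic":
        cohort = dataclasses.replace(config.cohort, seed=config.seed)
        generated = generate_cohort(cohort)
        series_list = [p.minute_series for p in generated.participants]
        scores = generated.scores_frame()
        generated.true_features_frame().to_csv(outdir / "true_features.csv", index=False)
        cohort.to_yaml(outdir / "cohort_config.yaml")
    else:
        series_list, scores = _load_csv_inputs(config)

    # ---- stage 2: preprocessing -------------------------------------------
    reports, hourly_list = [], []
    for minutes in series_list:
        try:
            report, hourly = _preprocess_participant(minutes, config.n_hours)
        except Exception as exc:  # propagate with stage context
            raise PipelineError("preprocess", minutes.participant_id, exc) from exc
        reports.append(report)
        if hourly is not None:
            hourly_list.append(hourly)
    excl_df = pd.DataFrame([r.to_dict() for r in reports])
    excl_df.to_csv(outdir / "exclusion_report.csv", index=False)
    n_excluded = int(excl_df["excluded"].sum())
    logger.info("preprocess: %d participants, %d excluded, %d analyzed",
                len(reports), n_excluded, len(hourly_list))

    hourly_df = pd.DataFrame(
        [
            {"participant_id": h.participant_id, "hour_index": i,
             "met_minutes": v}
            for h in hourly_list
            for i, v in enumerate(h.values)
        ]
    )
    hourly_df.to_csv(outdir / "hourly.csv", index=False)

    # ---- stage 3: grid search ---------------------------------------------
    grid_results = []
    for hourly in hourly_list:
        try:
            res = SarimaGridSearch(hourly, hourly.participant_id).fit()
        except Exception as exc:
            raise PipelineError("grid_search", hourly.participant_id, exc) from exc
        logger.info("grid: %s best %s (#%d), %d/%d converged",
                    hourly.participant_id, res.best_spec.label(),
                    res.best_number, res.n_converged, len(res.fits))
        grid_results.append(res)
    feat_df = features_frame(grid_results)
    feat_df.to_csv(outdir / "features.csv", index=False)

    membership = model_membership_summary(grid_results)
    membership.to_csv(outdir / "model_membership.csv", index=False)
    split = seasonal_ar_split(grid_results)

    # ---- stage 4: association ----------------------------------------------
    association_summary = None
    if scores is not None:
        scores.to_csv(outdir / "scores.csv", index=False)
        try:
            model = FeatureRegression(feat_df, scores, drop_constant=True)
            if model.dropped:
                logger.warning(
                    "association: dropping constant feature columns %s "
                    "(no selected model used these orders)", model.dropped
                )
            results = model.fit()
        except Exception as exc:
            raise PipelineError("association", "<cohort>", exc) from exc
        table = results.summary_table()
        table.to_csv(outdir / "association_table.csv")
        association_summary = {
            "_dropped_constant_features": model.dropped,
        }
        association_summary |= {
            scale: {
                "r2": round(rep.r2, 4),
                "f_stat": round(rep.f_stat, 4),
                "f_p_value": round(rep.f_p_value, 6),
                "significant": bool(rep.significant),
            }
            for scale, rep in results.reports.items()
        }

    # ---- stage 5: plots ----------------------------------------------------
    if config.plots:
        from .plotting import plot_model_membership

        plot_model_membership(hourly_list, grid_results, outdir / "figures")

    manifest = {
        "actirhythm_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "mode": config.mode,
        "n_participants": len(reports),
        "n_excluded": n_excluded,
        "n_analyzed": len(hourly_list),
        "model_membership": membership.to_dict(orient="records"),
        "seasonal_ar_split": split,
        "association": association_summary,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
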