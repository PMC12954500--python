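"""Transition-matrix and confidence-interval reports, plus the end-to-end run.

Tabular outputs are the source of truth; heatmap / annotated figures are
derived artifacts rendered only on request, and no number appears in a
figure that is not in a tabular output.  Probabilities are printed as
percentages to one decimal, interval bounds to two, matching the mixed
reporting style of surveillance matrices.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd
import seaborn as sns

from . import __version__
from .markov import MarkovTransitionEstimator, scenario_table
from .preprocessing import InjuryPreprocessor, NormalizationMap, normalize_labels
from .records import RecordSet, read_records, validate_records, write_records
from .sequences import transitions_from_recordset
from .stats import cohort_summary

__all__ = ["AnalysisConfig", "matrix_report", "ci_report", "run_pipeline"]

logger = logging.getLogger("injurychain")


def matrix_report(
    estimates: pd.DataFrame,
    scenario: str = "any",
    out_csv: str | Path | None = None,
    plot: bool = False,
    out_fig: str | Path | None = None,
    title: str | None = None,
) -> pd.DataFrame:
    """Square from-state x to-state matrix of probabilities in percent.

    Cells absent from the (already thresholded) estimate table are blank
    (NaN).  Optionally written as CSV and rendered as a monotone heatmap.
    """
    est = scenario_table(estimates, scenario) if "scenario" in estimates.columns else estimates
    if len(est) == 0:
        warnings.warn("no estimates to report: empty matrix", stacklevel=2)
        table = pd.DataFrame()
    else:
        table = est.pivot(index="from_state", columns="to_state", values="p") * 100.0
        table = table.round(1).sort_index(axis=0).sort_index(axis=1)
    if out_csv is not None:
        table.to_csv(out_csv)
    if plot and len(table):
        fig, ax = plt.subplots(figsize=(2 + 0.6 * len(table.columns), 1.5 + 0.5 * len(table)))
        sns.heatmap(table, annot=True, fmt=".1f", cmap="Blues", cbar_kws={"label": "probability (%)"}, ax=ax)
        ax.set_xlabel("subsequent injury state")
        ax.set_ylabel("initial injury state")
        if title:
            ax.set_title(title)
        fig.tight_layout()
        fig.savefig(out_fig or "transition_matrix.png", dpi=150)
        plt.close(fig)
    return table


def format_ci_row(low: float, p: float, high: float) -> str:
    """Render an interval as "low / point / high" in percent, two decimals."""
    return f"{low * 100:.2f} / {p * 100:.2f} / {high * 100:.2f}"


def ci_report(
    estimates: pd.DataFrame,
    out_csv: str | Path | None = None,
    plot: bool = False,
    out_fig: str | Path | None = None,
) -> pd.DataFrame:
    """Per-pair table of interval bounds (percent) around the point estimate."""
    if len(estimates) == 0:
        warnings.warn("no estimates to report: empty CI table", stacklevel=2)
        table = pd.DataFrame(columns=["from_state", "to_state", "low_pct", "p_pct", "high_pct", "interval"])
    else:
        table = estimates[["from_state", "to_state"]].copy()
        table["low_pct"] = (estimates["ci_low"] * 100).round(2)
        table["p_pct"] = (estimates["p"] * 100).round(2)
        table["high_pct"] = (estimates["ci_high"] * 100).round(2)
        table["interval"] = [
            format_ci_row(lo, p, hi)
            for lo, p, hi in zip(estimates["ci_low"], estimates["p"], estimates["ci_high"])
        ]
        table = table.sort_values(["from_state", "to_state"]).reset_index(drop=True)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    if plot and len(table):
        fig, ax = plt.subplots(figsize=(8, 0.3 * len(table) + 1.5))
        y = range(len(table))
        ax.hlines(y, table["low_pct"], table["high_pct"], color="lightgray")
        ax.plot(table["low_pct"], y, "<", color="red", label="low")
        ax.plot(table["p_pct"], y, "o", color="blue", label="point")
        ax.plot(table["high_pct"], y, ">", color="green", label="high")
        ax.set_yticks(list(y))
        ax.set_yticklabels(table["from_state"] + " → " + table["to_state"], fontsize=7)
        ax.set_xlabel("transition probability (%)")
        ax.legend(loc="lower right", fontsize=7)
        fig.tight_layout()
        fig.savefig(out_fig or "ci_report.png", dpi=150)
        plt.close(fig)
    return table


@dataclass
class AnalysisConfig:
    """Everything one end-to-end run needs."""

    input: str | Path
    outdir: str | Path
    level: str = "part_nature"
    denominator: str = "global"
    scenario: str = "any"
    min_p: float = 0.002
    ci_method: str = "wald"
    confidence: float = 0.95
    season_start_month: int = 7
    strict_names: bool = False
    drop_unknown_contact: bool = False
    drop_exacerbations: bool = False
    star_semantics: bool = False
    normalization_map: str | Path | None = None
    dialect: str = "delimited"
    sep: str = ","
    plots: bool = False
    excluded_categories: tuple[str, ...] = ("Unsure", "Others")

    def __post_init__(self):
        if self.level not in ("part_nature", "categorization"):
            raise ValueError(f"unknown level: {self.level!r}")
        if self.denominator not in ("global", "row"):
            raise ValueError(f"unknown denominator: {self.denominator!r}")
        if not 0.0 <= self.min_p <= 1.0:
            raise ValueError("min_p must lie in [0, 1]")


def run_pipeline(cfg: AnalysisConfig) -> dict[str, Path]:
    """Read, clean, sequence, estimate and report; return the artifact paths.

    Deterministic for a fixed input and config.  Writes per-stage record
    counts to the log, every artifact under ``cfg.outdir``, and a manifest of
    parameters and stage counts.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "log.txt"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    artifacts: dict[str, Path] = {"log": log_path}
    try:
        rs_raw = read_records(cfg.input, dialect=cfg.dialect, sep=cfg.sep)
        logger.info(
            "read: %d rows, %d accepted, %d rejected",
            rs_raw.provenance.rows_read, rs_raw.provenance.rows_accepted, rs_raw.provenance.rows_rejected,
        )
        report = validate_records(rs_raw)
        if report.violations:
            logger.info("validation: %s", report.counts)

        nmap = None
        if cfg.normalization_map is not None:
            nmap = NormalizationMap.from_file(cfg.normalization_map, strict=cfg.strict_names)
        pre = InjuryPreprocessor(
            normalization_map=nmap,
            drop_unknown_contact=cfg.drop_unknown_contact,
            drop_exacerbations=cfg.drop_exacerbations,
            season_start_month=cfg.season_start_month,
        )
        rs_clean = pre.fit_transform(rs_raw)
        logger.info("preprocess: %d -> %d, removed %s", pre.report_.n_before, pre.report_.n_after, pre.report_.removed)
        artifacts["records_clean"] = write_records(rs_clean, outdir / "records_clean.csv")
        with open(outdir / "preprocess_report.json", "w") as fh:
            json.dump(
                {"n_before": pre.report_.n_before, "n_after": pre.report_.n_after,
                 "removed": pre.report_.removed, "warnings": pre.report_.warnings},
                fh, indent=2,
            )
        artifacts["preprocess_report"] = outdir / "preprocess_report.json"

        transitions = transitions_from_recordset(
            rs_clean, season_start_month=cfg.season_start_month, first_only=cfg.star_semantics
        )
        logger.info("transitions: %d pairs", len(transitions))
        transitions.to_csv(outdir / "transitions.csv", index=False)
        artifacts["transitions"] = outdir / "transitions.csv"

        model = MarkovTransitionEstimator(
            level=cfg.level,
            denominator=cfg.denominator,
            min_p=cfg.min_p,
            ci_method=cfg.ci_method,
            confidence=cfg.confidence,
            excluded_categories=cfg.excluded_categories,
            first_transition_only=cfg.star_semantics,
            season_start_month=cfg.season_start_month,
        ).fit(transitions)
        logger.info("model: %d states, %d transitions counted", len(model.states_), model.n_transitions_)

        est = model.estimates(scenario=cfg.scenario if cfg.level == "part_nature" else "any", filtered=True)
        est.to_csv(outdir / "estimates.csv", index=False)
        est.to_json(outdir / "estimates.json", orient="records", indent=2)
        artifacts["estimates"] = outdir / "estimates.csv"

        matrix_report(
            est, scenario="any",
            out_csv=outdir / "matrix.csv",
            plot=cfg.plots, out_fig=outdir / "matrix.png",
        )
        artifacts["matrix"] = outdir / "matrix.csv"
        ci_report(est, out_csv=outdir / "ci_table.csv", plot=cfg.plots, out_fig=outdir / "ci_table.png")
        artifacts["ci_table"] = outdir / "ci_table.csv"

        # body-part distribution over all recorded injuries, with consistent naming
        rs_for_summary = normalize_labels(rs_raw, nmap) if nmap is not None else rs_raw
        summary = cohort_summary(rs_for_summary, rs_clean, transitions)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary.as_dict(), fh, indent=2)
        artifacts["summary"] = outdir / "summary.json"

        manifest = {
            "package": "injurychain",
            "version": __version__,
            "stages": ["read", "validate", "preprocess", "sequences", "estimate", "report"],
            "config": {k: str(v) if isinstance(v, Path) else v for k, v in vars(cfg).items()},
            "counts": {
                "rows_read": rs_raw.provenance.rows_read,
                "records_clean": len(rs_clean),
                "transitions": len(transitions),
                "transitions_counted": model.n_transitions_,
                "states": len(model.states_),
                "estimates_reported": len(est),
            },
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        artifacts["manifest"] = outdir / "manifest.json"
        logger.info("done: %d artifacts", len(artifacts))
    finally:
        logger.removeHandler(handler)
        handler.close()
    return artifacts
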