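"""End-to-end orchestration: filter -> detect -> summarise -> model -> report.

``run_pipeline`` takes a cohort (read from disk or freshly simulated),
applies the minimum-data inclusion rule, detects sudden gains, builds
the around-gain table, fits the outcome and process models, and writes
the report bundle:

* ``gains.csv``      — every detected gain with reversal and primary flags
* ``summary.json``   — cohort-level gain statistics and the duration test
* ``outcome_model.csv`` — raw endpoint cells plus adjusted group differences
* ``contrasts.csv``  — consecutive around-gain contrasts per measure
* ``figures/``       — mean LSAS around gains, pre-gain-week histogram,
  group trajectories, process panel

Every CSV starts with ``#``-prefixed header comments recording the
package version, seed and detection criteria so a report is
self-describing; outputs are a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .around import extract_window
from .detection import (
    GainCriteria, compare_duration, detect_cohort, summarize_cohort,
)
from .measures import LSAS, PROCESS_MEASURES
from .models import contrast_table, fit_outcome_model
from .trajectory import Cohort, apply_inclusion_filter

logger = logging.getLogger("suddengain")


@dataclass
class RunConfig:
    out_dir: Path
    criteria: GainCriteria = field(default_factory=GainCriteria)
    min_lsas_points: int = 8
    seed: int | None = None
    make_figures: bool = True
    x_max_weeks: int = 14      # cohort panels clip at the median end of treatment


def _header(config: RunConfig) -> str:
    c = config.criteria
    return (
        f"# suddengain v{__version__}\n"
        f"# seed={config.seed} cutoff={c.cutoff} pct={c.pct} "
        f"alpha={c.stability_alpha} min_window={c.min_window} "
        f"min_lsas_points={config.min_lsas_points}\n"
    )


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, index=False, float_format="%.6g")


def endpoint_table(cohort: Cohort, gains: pd.DataFrame) -> pd.DataFrame:
    """Long endpoint data for the outcome model.

    One row per participant per available timepoint (post-intervention
    and 3-month follow-up) with gain status and baseline LSAS; rows
    lacking the endpoint or the baseline are omitted.
    """
    with_gain = set(gains["participant_id"]) if not gains.empty else set()
    rows = []
    for pid in cohort.participants:
        base = cohort.baseline_lsas(pid)
        if base is None:
            continue
        sg = pid in with_gain
        for time, value in (("post", cohort.post_lsas(pid)),
                            ("followup", cohort.followup_lsas(pid))):
            if value is not None:
                rows.append({"participant_id": pid, "time": time, "lsas": value,
                             "sg": sg, "baseline_lsas": base})
    return pd.DataFrame(rows, columns=["participant_id", "time", "lsas", "sg",
                                       "baseline_lsas"])


def run_pipeline(cohort: Cohort, config: RunConfig) -> dict:
    """Run the full analysis; returns the bundle of in-memory results."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    included, excluded, filter_report = apply_inclusion_filter(
        cohort, config.min_lsas_points
    )
    logger.info("inclusion filter: %d included, %d excluded",
                filter_report["n_included"], filter_report["n_excluded"])

    gains = detect_cohort(included, config.criteria)
    logger.info("detected %d gains in %d participants",
                len(gains), gains["participant_id"].nunique() if not gains.empty else 0)
    _write_csv(gains, out / "gains.csv", config)

    summary = summarize_cohort(gains, included)
    summary_dict = {
        "version": __version__,
        "seed": config.seed,
        "criteria": {
            "cutoff": config.criteria.cutoff,
            "pct": config.criteria.pct,
            "stability_alpha": config.criteria.stability_alpha,
            "min_window": config.criteria.min_window,
        },
        "inclusion": filter_report,
        **summary.to_dict(),
    }

    meta = included.metadata()
    with_gain = set(gains["participant_id"]) if not gains.empty else set()
    sg_weeks = meta.loc[meta["participant_id"].isin(with_gain), "n_weeks"]
    nosg_weeks = meta.loc[~meta["participant_id"].isin(with_gain), "n_weeks"]
    if len(sg_weeks) and len(nosg_weeks):
        summary_dict["duration_test"] = compare_duration(sg_weeks, nosg_weeks)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary_dict, fh, indent=2)

    results: dict = {"gains": gains, "summary": summary_dict,
                     "included": included, "excluded": excluded}

    primaries = gains[gains["is_primary"]] if not gains.empty else gains
    if not primaries.empty:
        around = extract_window(included, primaries, PROCESS_MEASURES)
        contrasts = contrast_table(around, PROCESS_MEASURES)
        _write_csv(contrasts, out / "contrasts.csv", config)
        results["around"] = around
        results["contrasts"] = contrasts

    endpoints = endpoint_table(included, gains)
    if not endpoints.empty and endpoints["sg"].nunique() == 2:
        outcome = fit_outcome_model(endpoints)
        table = outcome.cell_stats.copy()
        table["kind"] = "cell"
        diffs = outcome.differences.copy()
        diffs["kind"] = "adjusted_difference"
        outcome_df = pd.concat([table, diffs], ignore_index=True)
        _write_csv(outcome_df, out / "outcome_model.csv", config)
        results["outcome"] = outcome

    if config.make_figures:
        fig_dir = out / "figures"
        fig_dir.mkdir(exist_ok=True)
        make_figures(included, gains, results.get("around"), fig_dir, config)
        results["figures_dir"] = fig_dir

    logger.info("report bundle written to %s", out)
    return results


# -- figures ---------------------------------------------------------------

def make_figures(cohort: Cohort, gains: pd.DataFrame,
                 around: pd.DataFrame | None, fig_dir: Path,
                 config: RunConfig) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # mean LSAS around gains
    if around is not None:
        sub = around[around["measure"] == LSAS]
        order = ["n-2", "n-1", "n", "n+1", "n+2", "n+3"]
        means = sub.groupby("timepoint")["value"].mean().reindex(order)
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(order, means.values, marker="o")
        ax.set_xlabel("timepoint around gain")
        ax.set_ylabel("mean LSAS")
        ax.set_title("Mean LSAS around sudden gains")
        fig.tight_layout()
        fig.savefig(fig_dir / "lsas_around_gains.png", dpi=120)
        plt.close(fig)

    # pre-gain-week histogram
    if not gains.empty:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        weeks = gains["n"].astype(int)
        bins = np.arange(weeks.min() - 0.5, weeks.max() + 1.5)
        ax.hist(weeks, bins=bins, edgecolor="black")
        ax.set_xlabel("pre-gain week (n)")
        ax.set_ylabel("number of gains")
        ax.set_title("Distribution of pre-gain weeks")
        fig.tight_layout()
        fig.savefig(fig_dir / "pre_gain_week_histogram.png", dpi=120)
        plt.close(fig)

    # group mean trajectories (clipped at the median end of treatment)
    with_gain = set(gains["participant_id"]) if not gains.empty else set()
    lsas = cohort.data[cohort.data["measure"] == LSAS].copy()
    lsas["group"] = np.where(lsas["participant_id"].isin(with_gain), "gain", "no gain")
    lsas = lsas[lsas["week"] <= config.x_max_weeks]
    prof = lsas.groupby(["group", "week"])["value"].mean().reset_index()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for group, part in prof.groupby("group"):
        ax.plot(part["week"], part["value"], marker="o", label=group)
    ax.set_xlabel("week")
    ax.set_ylabel("mean LSAS")
    ax.set_title("Symptom trajectories by gain status")
    ax.legend()
    fig.tight_layout()
    fig.savefig(fig_dir / "group_trajectories.png", dpi=120)
    plt.close(fig)

    # process panel
    if around is not None:
        order = ["n-2", "n-1", "n", "n+1", "n+2", "n+3"]
        measures = [m for m in around["measure"].unique()]
        ncols = 3
        nrows = int(np.ceil(len(measures) / ncols))
        fig, axes = plt.subplots(nrows, ncols, figsize=(11, 3 * nrows),
                                 squeeze=False)
        for ax, measure in zip(axes.flat, measures):
            sub = around[around["measure"] == measure]
            means = sub.groupby("timepoint")["value"].mean().reindex(order)
            ax.plot(order, means.values, marker="o")
            ax.set_title(measure)
        for ax in axes.flat[len(measures):]:
            ax.set_visible(False)
        fig.suptitle("Process measures around the gain")
        fig.tight_layout()
        fig.savefig(fig_dir / "process_panel.png", dpi=120)
        plt.close(fig)
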