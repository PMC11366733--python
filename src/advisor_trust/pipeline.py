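"""End-to-end orchestration: simulate -> metrics -> filter -> fit -> report.

Writes the analysis artefacts as plain CSV/JSON so that downstream
plotting or statistics can be done in any environment:

* ``trials.csv``            raw trial table
* ``metrics.csv``           per-trial shift / distance / WOA / deviances
* ``table1_summary.csv``    per-phase deviance and WOA summary
* ``table2_counts.csv``     paired pre x post preferred-model counts
* ``fig3_histograms.csv``   winsorized and raw WOA histogram bins per phase
* ``fig4_scatter.csv``      shift vs advice distance (filtered trials)
* ``fig5_probs.csv``        posterior model probabilities per participant x phase
* ``fits.csv``              per participant x phase x model fit details
* ``manifest.json``         config echo, seeds, version, file checksums

Outputs are deterministic: rerunning with the same manifest inputs yields
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .comparison import MODELS, fit_all_participants, preferred_model_counts
from .io import write_frame_csv, write_trials_csv
from .mcmc import McmcSettings
from .metrics import (
    PHASE_ORDER,
    leap_of_faith_contrast,
    metrics_table,
    model_fit_filter,
    phase_summary,
    woa_histogram,
)
from .simulator import SessionDesign, StrategyProfile, generate_cohort

log = logging.getLogger("advisor_trust")

__all__ = ["PipelineReport", "run_full_pipeline", "write_report"]


@dataclass
class PipelineReport:
    out_dir: Path
    trials: pd.DataFrame
    metrics: pd.DataFrame
    summary: pd.DataFrame
    comparisons: list
    fits: pd.DataFrame
    probs: pd.DataFrame
    counts: pd.DataFrame
    files: dict[str, str]  # name -> sha256


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _histogram_frame(trials: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for phase in PHASE_ORDER:
        sub = trials[trials["phase"] == phase]
        if sub.empty or not sub["has_advice"].any():
            continue
        for kind, winsorized in (("winsorized", True), ("raw", False)):
            counts, edges = woa_histogram(sub, winsorized=winsorized)
            for c, lo, hi in zip(counts, edges[:-1], edges[1:]):
                rows.append(
                    {"phase": phase, "kind": kind, "bin_left": lo, "bin_right": hi, "count": int(c)}
                )
    return pd.DataFrame(rows)


def run_full_pipeline(
    design: SessionDesign,
    profiles: Sequence[StrategyProfile],
    n_participants: int,
    seed: int,
    out_dir: str | Path,
    method: str = "quadrature",
    settings: McmcSettings | None = None,
) -> PipelineReport:
    """Run the whole analysis on a simulated cohort and write artefacts."""
    if not profiles:
        raise ValueError("profile list must be non-empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        log.info("simulating %d participants (seed %d)", n_participants, seed)
        trials = generate_cohort(n_participants, list(profiles), design, seed=seed)

        stage = "metrics"
        metrics = metrics_table(trials)
        summary = phase_summary(trials, by_participant=True)
        leap_pairs, leap_means = leap_of_faith_contrast(trials)

        stage = "filter"
        filtered = model_fit_filter(trials)

        stage = "fit"
        log.info("fitting %s models by %s", "x".join(MODELS), method)
        comparisons, fits = fit_all_participants(filtered, method=method, settings=settings)

        stage = "report"
        fits_frame = pd.DataFrame(
            [
                {
                    "participant_id": pid,
                    "phase": phase,
                    "model": f.model,
                    "log_marginal": f.log_marginal,
                    "slope_mean": f.slope_mean,
                    "slope_sd": f.slope_sd,
                    "sigma_mean": f.sigma_mean,
                    "method": f.method,
                    "n_obs": f.n_obs,
                    "rhat_max": f.rhat_max,
                }
                for pid, phase, f in fits
            ]
        )
        probs_frame = pd.DataFrame(
            [
                {
                    "participant_id": c.participant_id,
                    "phase": c.phase,
                    **{f"p_{m}": c.probs[m] for m in MODELS},
                    "preferred": c.preferred,
                }
                for c in comparisons
            ]
        )
        counts = preferred_model_counts(comparisons)

        files = {}
        files["trials.csv"] = write_trials_csv(trials, out_dir / "trials.csv")
        files["metrics.csv"] = write_frame_csv(metrics, out_dir / "metrics.csv")
        files["table1_summary.csv"] = write_frame_csv(summary, out_dir / "table1_summary.csv")
        files["table2_counts.csv"] = write_frame_csv(counts, out_dir / "table2_counts.csv", index=True)
        files["fig3_histograms.csv"] = write_frame_csv(_histogram_frame(trials), out_dir / "fig3_histograms.csv")
        files["fig4_scatter.csv"] = write_frame_csv(
            metrics_table(filtered)[
                ["participant_id", "trial_index", "phase", "advice_distance", "shift"]
            ],
            out_dir / "fig4_scatter.csv",
        )
        files["fig5_probs.csv"] = write_frame_csv(probs_frame, out_dir / "fig5_probs.csv")
        files["fits.csv"] = write_frame_csv(fits_frame, out_dir / "fits.csv")
        files["leap_of_faith.csv"] = write_frame_csv(leap_pairs, out_dir / "leap_of_faith.csv")

        checksums = {name: _sha256(Path(p)) for name, p in files.items()}
        manifest = {
            "package": "advisor-trust",
            "version": __version__,
            "seed": seed,
            "n_participants": n_participants,
            "method": method,
            "design": design.to_dict(),
            "profiles": [p.to_dict() for p in profiles],
            "leap_of_faith_means": leap_means,
            "files": checksums,
        }
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    except Exception:
        (out_dir / "FAILED").write_text(f"pipeline failed during stage: {stage}\n")
        log.exception("pipeline failed during stage %s", stage)
        raise

    return PipelineReport(
        out_dir=out_dir,
        trials=trials,
        metrics=metrics,
        summary=summary,
        comparisons=comparisons,
        fits=fits_frame,
        probs=probs_frame,
        counts=counts,
        files=checksums,
    )


def write_report(report: PipelineReport, out_dir: str | Path) -> dict[str, str]:
    """Re-emit a report's artefacts into another directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    files["trials.csv"] = write_trials_csv(report.trials, out_dir / "trials.csv")
    files["metrics.csv"] = write_frame_csv(report.metrics, out_dir / "metrics.csv")
    files["table1_summary.csv"] = write_frame_csv(report.summary, out_dir / "table1_summary.csv")
    files["table2_counts.csv"] = write_frame_csv(report.counts, out_dir / "table2_counts.csv", index=True)
    files["fig5_probs.csv"] = write_frame_csv(report.probs, out_dir / "fig5_probs.csv")
    files["fits.csv"] = write_frame_csv(report.fits, out_dir / "fits.csv")
    return {name: _sha256(Path(p)) for name, p in files.items()}
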