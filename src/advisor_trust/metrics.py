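"""Per-trial and per-phase trust measures.

The central quantity is the *weight of advice*

    WOA = (B - A) / (R - A)

where A is the first response, R the recommendation and B the second
response. WOA is 0 when the advice is ignored, 1 when it is adopted in
full, and 0.5 for an even compromise. Raw weights can fall outside [0, 1]
(motor noise on a continuous slider); the conventional summary winsorizes
them to [0, 1]. WOA is undefined on no-advice trials and on trials where
the recommendation coincides exactly with the first response; undefined
values are carried as ``nan`` and excluded from all means.

Also provided: shift (B - A) and advice distance (R - A) used for
strategy visualisation and model fitting, absolute deviances from the
truth, Table-1 style phase summaries, winsorized/raw WOA histograms, the
fraction of raw weights outside the unit interval, the pre-fit trial
filter, and the leap-of-faith contrast around the onset of the
degraded-advice phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AdviceTrialMetrics",
    "weight_of_advice",
    "winsorize_woa",
    "compute_metrics",
    "metrics_table",
    "phase_summary",
    "woa_histogram",
    "outside_unit_fraction",
    "model_fit_filter",
    "leap_of_faith_contrast",
]

PHASE_ORDER = ("pre", "adjusted", "post")


@dataclass(frozen=True)
class AdviceTrialMetrics:
    """Derived quantities for one post-practice trial (nan = undefined)."""

    shift: float
    advice_distance: float
    woa_raw: float
    woa_winsorized: float
    deviance_first: float
    deviance_rec: float
    deviance_second: float


def weight_of_advice(a: float, r: float, b: float) -> float:
    """(B - A) / (R - A); nan when R equals A or the advice is absent.

    Undefined is an in-band sentinel, not an error: zero-denominator and
    no-advice trials are recorded as nan and excluded from means.
    """
    if np.isnan(r) or r == a:
        return float("nan")
    return (b - a) / (r - a)


def winsorize_woa(w):
    """Clamp weights of advice to [0, 1]; nan propagates; idempotent."""
    return np.clip(w, 0.0, 1.0)


def compute_metrics(trial) -> AdviceTrialMetrics:
    """Metrics for a single trial (TrialRecord, Series or mapping).

    Raises on practice trials, which have no second response and are
    excluded from every downstream measure.
    """
    if not isinstance(trial, Mapping):
        trial = vars(trial) if hasattr(trial, "__dataclass_fields__") else dict(trial)
    if trial["phase"] == "practice":
        raise ValueError("practice trials have no advice metrics")
    a, r, b, t = (
        float(trial["first_response"]),
        float(trial["recommendation"]),
        float(trial["second_response"]),
        float(trial["truth"]),
    )
    raw = weight_of_advice(a, r, b)
    return AdviceTrialMetrics(
        shift=b - a,
        advice_distance=r - a,
        woa_raw=raw,
        woa_winsorized=float(winsorize_woa(raw)),
        deviance_first=abs(a - t),
        deviance_rec=abs(r - t),
        deviance_second=abs(b - t),
    )


def metrics_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Vectorised per-trial metrics for every post-practice trial."""
    t = trials.loc[trials["phase"] != "practice"].copy()
    a = t["first_response"].to_numpy(float)
    r = t["recommendation"].to_numpy(float)
    b = t["second_response"].to_numpy(float)
    truth = t["truth"].to_numpy(float)
    dist = r - a
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(dist != 0, (b - a) / dist, np.nan)
    out = t[["participant_id", "trial_index", "phase", "has_advice"]].copy()
    out["shift"] = b - a
    out["advice_distance"] = dist
    out["woa_raw"] = raw
    out["woa_winsorized"] = winsorize_woa(raw)
    out["deviance_first"] = np.abs(a - truth)
    out["deviance_rec"] = np.abs(r - truth)
    out["deviance_second"] = np.abs(b - truth)
    return out.reset_index(drop=True)


def phase_summary(trials: pd.DataFrame, by_participant: bool = True) -> pd.DataFrame:
    """Table-1 style summary per phase.

    With ``by_participant`` (the default) each mean is the mean of
    participants' means; otherwise trials are pooled. Means are taken
    over defined values only (e.g. recommendation deviance over advice
    trials, WOA over trials with a defined weight); phases with no advice
    trials are omitted rather than reported as zero.
    """
    m = metrics_table(trials)
    rows = []
    for phase in PHASE_ORDER:
        mp = m[m["phase"] == phase]
        if mp.empty or not mp["has_advice"].any():
            continue
        cols = [
            "deviance_first",
            "deviance_rec",
            "deviance_second",
            "woa_winsorized",
        ]
        if by_participant:
            per = mp.groupby("participant_id")[cols].mean()
            means = per.mean()
            frac = (
                mp[np.isfinite(mp["woa_raw"])]
                .groupby("participant_id")["woa_raw"]
                .apply(lambda w: float(np.mean((w < 0) | (w > 1))))
                .mean()
            )
        else:
            means = mp[cols].mean()
            raw = mp["woa_raw"].to_numpy(float)
            raw = raw[np.isfinite(raw)]
            frac = float(np.mean((raw < 0) | (raw > 1))) if raw.size else float("nan")
        rows.append(
            {
                "phase": phase,
                "mean_deviance_first": means["deviance_first"],
                "mean_deviance_rec": means["deviance_rec"],
                "mean_deviance_second": means["deviance_second"],
                "mean_woa_winsorized": means["woa_winsorized"],
                "n_trials": int(len(mp)),
                "fraction_outside_unit": frac,
            }
        )
    return pd.DataFrame(rows)


def woa_histogram(
    trials: pd.DataFrame, winsorized: bool = True, bin_width: float = 0.05
):
    """Histogram of all defined weights of advice, pooled over participants.

    Winsorized histograms use fixed bins on [0, 1]; raw histograms span
    the observed data range on a grid aligned to multiples of
    ``bin_width``. Returns ``(counts, edges)`` with half-open bins,
    right-closed at the maximum.
    """
    m = metrics_table(trials)
    w = m["woa_winsorized" if winsorized else "woa_raw"].to_numpy(float)
    w = w[np.isfinite(w)]
    if w.size == 0:
        raise ValueError("no defined weights of advice in the table")
    if winsorized:
        edges = np.linspace(0.0, 1.0, round(1.0 / bin_width) + 1)
    else:
        lo = np.floor(w.min() / bin_width) * bin_width
        hi = np.ceil(w.max() / bin_width) * bin_width
        hi = hi if hi > lo else lo + bin_width
        edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(w, bins=edges)
    return counts, edges


def outside_unit_fraction(trials: pd.DataFrame) -> float:
    """Fraction of defined raw weights of advice below 0 or above 1."""
    m = metrics_table(trials)
    raw = m["woa_raw"].to_numpy(float)
    raw = raw[np.isfinite(raw)]
    if raw.size == 0:
        raise ValueError("no defined weights of advice in the table")
    return float(np.mean((raw < 0) | (raw > 1)))


def _filter_one(g: pd.DataFrame) -> pd.DataFrame:
    g = g.sort_values("trial_index")
    prac = g.loc[g["phase"] == "practice", "trial_index"]
    prac_max = int(prac.max()) if len(prac) else 0
    keep = (g["phase"] != "practice") & (g["trial_index"] > prac_max + 10)

    pre_idx = g.loc[g["phase"] == "pre", "trial_index"]
    adj_idx = g.loc[g["phase"] == "adjusted", "trial_index"]
    if len(adj_idx):
        adj_start = int(pre_idx.max()) + 1 if len(pre_idx) else int(adj_idx.min())
        keep &= ~((g["phase"] == "adjusted") & (g["trial_index"] <= adj_start + 4))
        post_start = int(adj_idx.max()) + 1
    else:
        post = g.loc[g["phase"] == "post", "trial_index"]
        post_start = int(post.min()) if len(post) else 0
    keep &= ~((g["phase"] == "post") & (g["trial_index"] <= post_start + 4))

    g = g.loc[keep]
    g = g.loc[g["has_advice"]]
    g = g.loc[(g["recommendation"] - g["first_response"]) != 0]
    return g


def model_fit_filter(trials: pd.DataFrame) -> pd.DataFrame:
    """Trial exclusions applied before model fitting.

    Per participant: drop the first 10 post-practice observations of the
    session and the first 5 observations of the adjusted and post phases
    (settling-in periods after each change in advice accuracy), then drop
    no-advice trials and zero-advice-distance trials, whose weight of
    advice is undefined.

    The drop rules are trial-index predicates anchored at phase
    boundaries inferred from the retained leading rows of each phase, so
    the filter is idempotent on its own output.
    """
    pieces = []
    for pid, g in trials.groupby("participant_id", sort=False):
        f = _filter_one(g)
        if f.empty:
            warnings.warn(f"model_fit_filter: no trials left for participant {pid}")
        pieces.append(f)
    if not pieces:
        return trials.iloc[0:0]
    return pd.concat(pieces).reset_index(drop=True)


def leap_of_faith_contrast(trials: pd.DataFrame):
    """Winsorized WOA just before vs at the onset of degraded advice.

    For each participant, pairs the last pre-phase advice trial with the
    first adjusted-phase advice trial — the one trial where a wildly
    discrepant recommendation arrives before any feedback could reveal
    the advisor's change in accuracy. Participants lacking either trial
    (or with undefined WOA on it) are skipped. Returns ``(pairs, means)``
    where pairs has columns ``participant_id, woa_before,
    woa_first_adjusted`` and means holds the two cohort averages.
    """
    m = metrics_table(trials)
    m = m[np.isfinite(m["woa_winsorized"])]
    rows = []
    for pid, g in m.groupby("participant_id", sort=False):
        pre = g[g["phase"] == "pre"].sort_values("trial_index")
        adj = g[g["phase"] == "adjusted"].sort_values("trial_index")
        if pre.empty or adj.empty:
            continue
        rows.append(
            {
                "participant_id": pid,
                "woa_before": float(pre["woa_winsorized"].iloc[-1]),
                "woa_first_adjusted": float(adj["woa_winsorized"].iloc[0]),
            }
        )
    pairs = pd.DataFrame(rows, columns=["participant_id", "woa_before", "woa_first_adjusted"])
    means = {
        "woa_before": float(pairs["woa_before"].mean()) if len(pairs) else float("nan"),
        "woa_first_adjusted": float(pairs["woa_first_adjusted"].mean())
        if len(pairs)
        else float("nan"),
    }
    return pairs, means
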