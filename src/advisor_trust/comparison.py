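"""Per-participant Bayesian comparison of advice-distance models.

Three accounts of how the shift (B - A) depends on advice distance
D = R - A are compared for each participant in each phase:

* ``linear``      shift = beta * D                  (averaging; stay and
  adopt are the slope-0 and slope-1 special cases)
* ``self_doubt``  shift = beta * sign(D) * D^2      (distant advice is
  weighted proportionally more)
* ``agent_doubt`` shift = beta * sign(D) * sqrt|D|  (distant advice is
  weighted proportionally less)

Each is a no-intercept JZS regression (see :mod:`.jzs`); marginal
likelihoods come from deterministic quadrature (default) or MCMC with
Warp-III bridge sampling, and equal-prior posterior model probabilities
are reported per participant x phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .jzs import DEFAULT_RSCALE, fit_jzs_quadrature
from .mcmc import McmcSettings, jzs_log_marginal_bridge
from .metrics import PHASE_ORDER

__all__ = [
    "MODELS",
    "RegressionData",
    "ModelFitResult",
    "ModelComparisonResult",
    "transform_predictor",
    "regression_data",
    "posterior_model_probabilities",
    "preferred_model",
    "fit_participant_phase",
    "fit_all_participants",
    "preferred_model_counts",
    "MIN_TRIALS_PER_FIT",
]

#: Fixed model order; also the tie-break order for ``preferred_model``.
MODELS = ("linear", "self_doubt", "agent_doubt")

#: Fits with fewer filtered trials are marked unidentifiable.
MIN_TRIALS_PER_FIT = 8


@dataclass(frozen=True)
class RegressionData:
    """Shifts and advice distances for one participant x phase."""

    y: np.ndarray  # shifts, percent points
    d: np.ndarray  # advice distances, percent points
    n: int

    def __post_init__(self) -> None:
        if self.y.shape != self.d.shape or self.y.ndim != 1:
            raise ValueError("y and d must be 1-D arrays of equal length")
        if np.any(self.d == 0):
            raise ValueError("zero advice distances must be filtered out before fitting")


@dataclass(frozen=True)
class ModelFitResult:
    model: str
    log_marginal: float
    slope_mean: float
    slope_sd: float
    sigma_mean: float
    method: str  # "quadrature" | "bridge"
    n_obs: int
    rhat_max: float | None = None  # present iff method == "bridge"


@dataclass(frozen=True)
class ModelComparisonResult:
    participant_id: str
    phase: str
    probs: dict[str, float]  # over MODELS, sums to 1
    preferred: str


def transform_predictor(model: str, d) -> np.ndarray:
    """Map advice distance onto each model's predictor axis."""
    d = np.asarray(d, dtype=float)
    if model == "linear":
        return d
    if model == "self_doubt":
        return np.sign(d) * d**2
    if model == "agent_doubt":
        return np.sign(d) * np.sqrt(np.abs(d))
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


def regression_data(trials: pd.DataFrame) -> RegressionData:
    """Build (shift, advice distance) arrays from filtered advice trials."""
    a = trials["first_response"].to_numpy(float)
    r = trials["recommendation"].to_numpy(float)
    b = trials["second_response"].to_numpy(float)
    return RegressionData(y=b - a, d=r - a, n=len(trials))


def posterior_model_probabilities(log_marginals, prior_probs=None) -> np.ndarray:
    """Equal-prior (by default) posterior model probabilities.

    Softmax of log marginal likelihoods plus log priors, computed with
    max-subtraction; invariant to adding a constant to all log marginals.
    """
    lm = np.asarray(
        [log_marginals[m] for m in MODELS]
        if isinstance(log_marginals, dict)
        else log_marginals,
        dtype=float,
    )
    if not np.all(np.isfinite(lm)):
        raise ValueError("log marginal likelihoods must be finite")
    if prior_probs is None:
        prior_probs = np.full(lm.size, 1.0 / lm.size)
    prior_probs = np.asarray(prior_probs, dtype=float)
    if np.any(prior_probs < 0) or not np.isclose(prior_probs.sum(), 1.0):
        raise ValueError("prior_probs must be a probability simplex")
    with np.errstate(divide="ignore"):
        a = lm + np.log(prior_probs)
    a -= a.max()
    w = np.exp(a)
    return w / w.sum()


def preferred_model(probs) -> str:
    """Argmax model; exact ties break in the fixed order of ``MODELS``."""
    if isinstance(probs, dict):
        probs = [probs[m] for m in MODELS]
    best, best_p = MODELS[0], -np.inf
    for m, p in zip(MODELS, probs):
        if p > best_p:  # strict: earlier models win ties
            best, best_p = m, p
    return best


def _fit_one_model(model, data: RegressionData, method, settings, rscale, rng):
    x = transform_predictor(model, data.d)
    if method == "quadrature":
        q = fit_jzs_quadrature(data.y, x, rscale=rscale)
        return ModelFitResult(
            model=model,
            log_marginal=q.log_marginal,
            slope_mean=q.slope_mean,
            slope_sd=q.slope_sd,
            sigma_mean=q.sigma_mean,
            method="quadrature",
            n_obs=data.n,
        )
    if method == "bridge":
        logml, rhat, samples = jzs_log_marginal_bridge(
            data.y, x, settings=settings, rscale=rscale, rng=rng
        )
        return ModelFitResult(
            model=model,
            log_marginal=logml,
            slope_mean=float(samples.beta.mean()),
            slope_sd=float(samples.beta.std(ddof=1)),
            sigma_mean=float(np.sqrt(samples.sigma2.mean())),
            method="bridge",
            n_obs=data.n,
            rhat_max=rhat,
        )
    raise ValueError(f"unknown method {method!r}; expected 'quadrature' or 'bridge'")


def fit_participant_phase(
    filtered_trials: pd.DataFrame,
    participant_id: str,
    phase: str,
    method: str = "quadrature",
    settings: McmcSettings | None = None,
    rscale: float = DEFAULT_RSCALE,
    min_trials: int = MIN_TRIALS_PER_FIT,
    rng: np.random.Generator | None = None,
):
    """Fit all three models to one participant x phase.

    ``filtered_trials`` must already have passed
    :func:`~advisor_trust.metrics.model_fit_filter`. Returns
    ``(ModelComparisonResult, [ModelFitResult x3])`` or ``(None, [])``
    when fewer than ``min_trials`` trials remain (unidentifiable; such
    cells are excluded from count tables).
    """
    sub = filtered_trials[
        (filtered_trials["participant_id"] == participant_id)
        & (filtered_trials["phase"] == phase)
    ]
    if len(sub) < min_trials:
        warnings.warn(
            f"participant {participant_id}, phase {phase}: only {len(sub)} trials "
            f"(< {min_trials}); marked unidentifiable"
        )
        return None, []
    data = regression_data(sub)
    fits = [_fit_one_model(m, data, method, settings, rscale, rng) for m in MODELS]
    probs = posterior_model_probabilities([f.log_marginal for f in fits])
    result = ModelComparisonResult(
        participant_id=participant_id,
        phase=phase,
        probs={m: float(p) for m, p in zip(MODELS, probs)},
        preferred=preferred_model(probs),
    )
    return result, fits


def fit_all_participants(
    filtered_trials: pd.DataFrame,
    method: str = "quadrature",
    settings: McmcSettings | None = None,
    rscale: float = DEFAULT_RSCALE,
    min_trials: int = MIN_TRIALS_PER_FIT,
    rng: np.random.Generator | None = None,
):
    """Fit every participant x phase; returns (comparisons, fits) lists."""
    comparisons: list[ModelComparisonResult] = []
    all_fits: list[tuple[str, str, ModelFitResult]] = []
    pids = filtered_trials["participant_id"].unique()
    for pid in pids:
        for phase in PHASE_ORDER:
            if not (
                (filtered_trials["participant_id"] == pid)
                & (filtered_trials["phase"] == phase)
            ).any():
                continue
            res, fits = fit_participant_phase(
                filtered_trials,
                pid,
                phase,
                method=method,
                settings=settings,
                rscale=rscale,
                min_trials=min_trials,
                rng=rng,
            )
            if res is None:
                continue
            comparisons.append(res)
            all_fits.extend((pid, phase, f) for f in fits)
    return comparisons, all_fits


def preferred_model_counts(comparisons) -> pd.DataFrame:
    """Paired pre x post contingency table of preferred models.

    Rows are pre-phase preferences, columns post-phase preferences, with
    'Total' margins. Participants lacking either phase are excluded.
    """
    pref: dict[str, dict[str, str]] = {}
    for c in comparisons:
        pref.setdefault(c.participant_id, {})[c.phase] = c.preferred
    table = pd.DataFrame(0, index=list(MODELS), columns=list(MODELS), dtype=int)
    for phases in pref.values():
        if "pre" in phases and "post" in phases:
            table.loc[phases["pre"], phases["post"]] += 1
    table["Total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    table.index.name = "preferred_pre"
    table.columns.name = "preferred_post"
    return table
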