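"""Synthetic judge-advisor sessions.

This module simulates a perceptual judge-advisor task. On each trial a
participant views a stimulus whose true colour proportion lies between
``truth_min`` and ``truth_max`` percent, places a first response *A* on a
slider spanning ``scale_min``-``scale_max``, receives a machine
recommendation *R* drawn uniformly around the truth, and places a second
response *B* that combines their own judgement with the advice.

A session has four phases. The opening ``practice`` trials solicit a first
response only. The remaining trials are split into ``pre``, ``adjusted``
and ``post`` phases by an adjustment window during which the
recommendation noise is degraded (half-width ``degraded_half_width``
instead of ``accurate_half_width``). A fixed fraction of post-practice
trials carry no recommendation but still solicit a second response.

Synthetic participants follow an advice-taking strategy
(:class:`StrategyProfile`): keeping their first response (*stay*), adopting
the recommendation (*adopt*), linear weighted averaging (*compromise*),
weighting distant advice more (*self_doubt*, shift proportional to the
signed square of advice distance), weighting distant advice less
(*agent_doubt*, signed square root), or a per-trial mixture of
stay/adopt/compromise. Perceptual noise perturbs the first response around
the truth and motor noise perturbs the placement of the second response,
which is what produces raw weights of advice outside [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "PHASES",
    "STRATEGY_KINDS",
    "ADJUSTMENT_WINDOWS",
    "SessionDesign",
    "StrategyProfile",
    "TrialRecord",
    "generate_truth",
    "generate_recommendation",
    "generate_first_response",
    "generate_second_response",
    "generate_session",
    "generate_cohort",
]

PHASES = ("practice", "pre", "adjusted", "post")
STRATEGY_KINDS = ("stay", "adopt", "compromise", "self_doubt", "agent_doubt", "mixture")

#: The three between-subjects placements of the degraded-advice window.
ADJUSTMENT_WINDOWS = {"early": (21, 40), "middle": (41, 60), "late": (61, 80)}

_MIXTURE_COMPONENTS = ("stay", "adopt", "compromise")


@dataclass(frozen=True)
class SessionDesign:
    """Parameters of one experimental session.

    Defaults reproduce the task design: 110 trials, 5 practice trials, 20%
    no-advice trials, a 35-65% response scale, truth uniform on 40-60%,
    recommendation half-widths 1.5 (accurate) and 10 (degraded) percent
    points, and a middle adjustment window (trials 41-60).
    """

    n_trials_total: int = 110
    n_practice: int = 5
    no_advice_fraction: float = 0.2
    scale_min: float = 35.0
    scale_max: float = 65.0
    truth_min: float = 40.0
    truth_max: float = 60.0
    accurate_half_width: float = 1.5
    degraded_half_width: float = 10.0
    adjustment_window: tuple[int, int] = ADJUSTMENT_WINDOWS["middle"]
    clip_recommendations: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.scale_min < self.truth_min <= self.truth_max < self.scale_max):
            raise ValueError(
                "require scale_min < truth_min <= truth_max < scale_max, got "
                f"{self.scale_min}, {self.truth_min}, {self.truth_max}, {self.scale_max}"
            )
        if not 0.0 <= self.no_advice_fraction < 1.0:
            raise ValueError("no_advice_fraction must lie in [0, 1)")
        if not 0 <= self.n_practice < self.n_trials_total:
            raise ValueError("need 0 <= n_practice < n_trials_total")
        lo, hi = self.adjustment_window
        if not (isinstance(lo, (int, np.integer)) and isinstance(hi, (int, np.integer))):
            raise ValueError("adjustment_window must be a pair of trial indices")
        if not (self.n_practice < lo <= hi <= self.n_trials_total):
            raise ValueError(
                "adjustment_window must lie after the practice trials and "
                "within [1, n_trials_total]"
            )
        if self.accurate_half_width < 0 or self.degraded_half_width < 0:
            raise ValueError("recommendation half-widths must be >= 0")

    # -- derived design quantities -------------------------------------

    @property
    def n_second_judgement(self) -> int:
        """Trials soliciting a second response (105 at the defaults)."""
        return self.n_trials_total - self.n_practice

    @property
    def n_no_advice(self) -> int:
        """No-advice trial count: round(fraction x post-practice trials)."""
        return round(self.no_advice_fraction * self.n_second_judgement)

    def phase_of(self, trial_index: int) -> str:
        """Phase label of a 1-based trial index."""
        if not 1 <= trial_index <= self.n_trials_total:
            raise ValueError(f"trial_index {trial_index} outside session")
        if trial_index <= self.n_practice:
            return "practice"
        lo, hi = self.adjustment_window
        if trial_index < lo:
            return "pre"
        if trial_index <= hi:
            return "adjusted"
        return "post"

    def half_width_for(self, phase: str) -> float:
        return self.degraded_half_width if phase == "adjusted" else self.accurate_half_width

    # -- (de)serialisation ---------------------------------------------

    def to_dict(self) -> dict:
        d = {
            f.name: getattr(self, f.name)
            for f in self.__dataclass_fields__.values()  # type: ignore[attr-defined]
        }
        d["adjustment_window"] = list(self.adjustment_window)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SessionDesign":
        d = dict(d)
        if "adjustment_window" in d:
            d["adjustment_window"] = tuple(int(v) for v in d["adjustment_window"])
        return cls(**d)


WeightSpec = Union[float, Mapping[str, float]]


@dataclass(frozen=True)
class StrategyProfile:
    """A synthetic participant's advice-taking rule and noise levels.

    ``trust_weight`` is the compromise weight *w* for ``compromise`` and
    the slope coefficient for ``self_doubt`` / ``agent_doubt``; it may be a
    single number or a mapping from phase label to number, letting a
    profile lower its weight during the degraded-advice phase. It is
    ignored by ``stay`` and ``adopt``. ``mixture_probs`` gives
    (p_stay, p_adopt, p_compromise) for the ``mixture`` kind.
    """

    kind: str
    trust_weight: WeightSpec = 1.0
    mixture_probs: tuple[float, float, float] | None = None
    perceptual_noise_sd: float = 3.0
    motor_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in STRATEGY_KINDS:
            raise ValueError(f"unknown strategy kind {self.kind!r}; expected one of {STRATEGY_KINDS}")
        if self.perceptual_noise_sd < 0 or self.motor_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.kind == "mixture":
            if self.mixture_probs is None:
                raise ValueError("mixture strategy requires mixture_probs")
            p = np.asarray(self.mixture_probs, dtype=float)
            if p.shape != (3,) or np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
                raise ValueError("mixture_probs must be 3 non-negative values summing to 1")

    def weight_for(self, phase: str) -> float:
        if isinstance(self.trust_weight, Mapping):
            try:
                return float(self.trust_weight[phase])
            except KeyError as exc:
                raise KeyError(f"no trust_weight configured for phase {phase!r}") from exc
        return float(self.trust_weight)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "trust_weight": dict(self.trust_weight)
            if isinstance(self.trust_weight, Mapping)
            else self.trust_weight,
            "mixture_probs": list(self.mixture_probs) if self.mixture_probs else None,
            "perceptual_noise_sd": self.perceptual_noise_sd,
            "motor_noise_sd": self.motor_noise_sd,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StrategyProfile":
        d = dict(d)
        if d.get("mixture_probs") is not None:
            d["mixture_probs"] = tuple(float(v) for v in d["mixture_probs"])
        return cls(**d)


@dataclass(frozen=True)
class TrialRecord:
    """One judge-advisor trial. Absent values are ``nan``."""

    participant_id: str
    trial_index: int
    phase: str
    has_advice: bool
    truth: float
    first_response: float
    recommendation: float  # nan when no advice was shown
    second_response: float  # nan on practice trials


# ---------------------------------------------------------------------
# elementary generators


def generate_truth(design: SessionDesign, rng: np.random.Generator) -> float:
    """Draw a stimulus proportion uniformly on [truth_min, truth_max]."""
    return float(rng.uniform(design.truth_min, design.truth_max))


def generate_recommendation(
    truth: float,
    half_width: float,
    design: SessionDesign,
    rng: np.random.Generator,
) -> float:
    """Draw a recommendation uniformly on truth +/- half_width.

    With ``design.clip_recommendations`` the draw is clipped to the
    response scale; by default it is not, so degraded-phase advice may
    fall slightly outside the scale, keeping its mean absolute deviance at
    exactly half_width / 2.
    """
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    r = float(rng.uniform(truth - half_width, truth + half_width))
    if design.clip_recommendations:
        r = float(np.clip(r, design.scale_min, design.scale_max))
    return r


def generate_first_response(
    truth: float,
    profile: StrategyProfile,
    design: SessionDesign,
    rng: np.random.Generator,
) -> float:
    """First response: truth plus perceptual noise, clipped to the scale."""
    a = truth + rng.normal(0.0, profile.perceptual_noise_sd)
    return float(np.clip(a, design.scale_min, design.scale_max))


def _noiseless_target(kind: str, a: float, r: float, w: float) -> float:
    d = r - a
    if kind == "stay":
        return a
    if kind == "adopt":
        return r
    if kind == "compromise":
        return a + w * d
    if kind == "self_doubt":
        return a + w * math.copysign(d * d, d)
    if kind == "agent_doubt":
        return a + w * math.copysign(math.sqrt(abs(d)), d)
    raise ValueError(f"unknown strategy kind {kind!r}")


def generate_second_response(
    a: float,
    r: float,
    profile: StrategyProfile,
    phase: str,
    rng: np.random.Generator,
    design: SessionDesign | None = None,
) -> float:
    """Second response under the profile's strategy, plus motor noise.

    The noiseless target is A (stay), R (adopt), A + w(R-A) (compromise),
    A + w sign(D) D^2 (self_doubt) or A + w sign(D) sqrt|D| (agent_doubt)
    with D = R - A; mixtures draw one of stay/adopt/compromise per trial.
    Motor noise N(0, motor_noise_sd) is added and the result clipped to
    the response scale.
    """
    lo, hi = (design.scale_min, design.scale_max) if design is not None else (35.0, 65.0)
    kind = profile.kind
    if kind == "mixture":
        assert profile.mixture_probs is not None
        kind = _MIXTURE_COMPONENTS[rng.choice(3, p=np.asarray(profile.mixture_probs, float))]
    b = _noiseless_target(kind, a, r, profile.weight_for(phase))
    b += rng.normal(0.0, profile.motor_noise_sd)
    return float(np.clip(b, lo, hi))


# ---------------------------------------------------------------------
# sessions and cohorts


def generate_session(
    design: SessionDesign,
    profile: StrategyProfile,
    participant_id: str = "p001",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one full session as a trial table.

    Returns a DataFrame with columns ``participant_id, trial_index, phase,
    has_advice, truth, first_response, recommendation, second_response``.
    Practice trials carry neither recommendation nor second response.
    No-advice trials (count = round(no_advice_fraction x post-practice
    trials), placed uniformly at random) carry a second response but no
    recommendation; the participant then simply re-places their first
    response subject to motor noise.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    post_practice = np.arange(design.n_practice + 1, design.n_trials_total + 1)
    no_advice = set(
        rng.choice(post_practice, size=design.n_no_advice, replace=False).tolist()
    )

    records: list[TrialRecord] = []
    for i in range(1, design.n_trials_total + 1):
        phase = design.phase_of(i)
        truth = generate_truth(design, rng)
        a = generate_first_response(truth, profile, design, rng)
        if phase == "practice":
            rec, b, has_advice = math.nan, math.nan, False
        elif i in no_advice:
            rec, has_advice = math.nan, False
            b = float(
                np.clip(
                    a + rng.normal(0.0, profile.motor_noise_sd),
                    design.scale_min,
                    design.scale_max,
                )
            )
        else:
            has_advice = True
            rec = generate_recommendation(truth, design.half_width_for(phase), design, rng)
            b = generate_second_response(a, rec, profile, phase, rng, design)
        records.append(
            TrialRecord(participant_id, i, phase, has_advice, truth, a, rec, b)
        )
    return pd.DataFrame(records)


ProfileSpec = Union[
    StrategyProfile,
    Sequence[StrategyProfile],
    Callable[[np.random.Generator], StrategyProfile],
]


def generate_cohort(
    n_participants: int,
    profiles: ProfileSpec,
    design: SessionDesign,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a cohort and return the concatenated trial table.

    ``profiles`` may be a single profile, a sequence (cycled over
    participants), or a callable drawing a profile from a Generator.
    Each participant gets an independent child RNG derived from
    ``(seed, participant index)`` so cohorts are reproducible and a
    participant's stream does not depend on cohort size.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    frames = []
    for i in range(n_participants):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        if callable(profiles) and not isinstance(profiles, StrategyProfile):
            profile = profiles(rng)
        elif isinstance(profiles, StrategyProfile):
            profile = profiles
        else:
            profile = profiles[i % len(profiles)]
        frames.append(generate_session(design, profile, f"p{i + 1:03d}", rng))
    return pd.concat(frames, ignore_index=True)
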