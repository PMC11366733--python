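"""Task generator: stimulus, recommendation, strategies, sessions, cohorts."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import advisor_trust as at
from advisor_trust.io import read_trials_csv, write_trials_csv


class TestTruth:
    def test_draws_stay_inside_stimulus_range(self, design, rng):
        draws = np.array([at.generate_truth(design, rng) for _ in range(2000)])
        assert draws.min() >= 40.0 and draws.max() <= 60.0

    def test_degenerate_interval_is_constant(self, rng):
        design = at.SessionDesign(truth_min=50, truth_max=50)
        assert all(at.generate_truth(design, rng) == 50.0 for _ in range(10))

    def test_uniform_moments(self, design, rng):
        n = 100_000
        draws = np.array([at.generate_truth(design, rng) for _ in range(n)])
        se = draws.std(ddof=1) / math.sqrt(n)
        assert abs(draws.mean() - 50.0) < 3 * se
        assert draws.min() < 40.2 and draws.max() > 59.8


class TestRecommendation:
    def test_zero_half_width_returns_truth(self, design, rng):
        assert at.generate_recommendation(47.3, 0.0, design, rng) == 47.3

    @pytest.mark.parametrize("half_width", [1.5, 10.0])
    def test_support_is_truth_plus_minus_half_width(self, design, rng, half_width):
        devs = np.array(
            [abs(at.generate_recommendation(50.0, half_width, design, rng) - 50.0) for _ in range(5000)]
        )
        assert devs.max() <= half_width

    def test_mean_absolute_deviance_is_half_the_half_width(self, design, rng):
        n = 20_000
        devs = np.array(
            [abs(at.generate_recommendation(50.0, 1.5, design, rng) - 50.0) for _ in range(n)]
        )
        se = devs.std(ddof=1) / math.sqrt(n)
        assert abs(devs.mean() - 0.75) < 3 * se

    def test_clipping_flag_restricts_to_scale(self, rng):
        design = at.SessionDesign(clip_recommendations=True)
        recs = np.array(
            [at.generate_recommendation(60.0, 10.0, design, rng) for _ in range(2000)]
        )
        assert recs.max() <= design.scale_max
        unclipped = at.SessionDesign()
        recs = np.array(
            [at.generate_recommendation(60.0, 10.0, unclipped, rng) for _ in range(2000)]
        )
        assert recs.max() > design.scale_max  # degraded advice may leave the scale

    def test_negative_half_width_rejected(self, design, rng):
        with pytest.raises(ValueError):
            at.generate_recommendation(50.0, -1.0, design, rng)


class TestSecondResponse:
    @pytest.mark.parametrize(
        ("kind", "weight", "a", "r", "expected"),
        [
            ("adopt", 1.0, 48.0, 53.0, 53.0),
            ("stay", 1.0, 48.0, 53.0, 48.0),
            ("compromise", 0.5, 48.0, 52.0, 50.0),
            ("self_doubt", 0.1, 50.0, 46.0, 48.4),  # 50 + 0.1 * sign(-4) * 16
            ("agent_doubt", 1.0, 50.0, 59.0, 53.0),  # 50 + 1 * sqrt(9)
        ],
    )
    def test_noiseless_targets(self, rng, kind, weight, a, r, expected):
        profile = at.StrategyProfile(kind=kind, trust_weight=weight, motor_noise_sd=0.0)
        b = at.generate_second_response(a, r, profile, "pre", rng)
        assert b == pytest.approx(expected, abs=1e-12)

    def test_per_phase_trust_weight(self, rng):
        profile = at.StrategyProfile(
            kind="compromise", trust_weight={"pre": 0.8, "adjusted": 0.2, "post": 0.5},
            motor_noise_sd=0.0,
        )
        assert at.generate_second_response(50, 54, profile, "pre", rng) == pytest.approx(53.2)
        assert at.generate_second_response(50, 54, profile, "adjusted", rng) == pytest.approx(50.8)

    def test_mixture_components_and_rates(self, rng):
        profile = at.StrategyProfile(
            kind="mixture", mixture_probs=(0.7, 0.3, 0.0), motor_noise_sd=0.0
        )
        draws = np.array(
            [at.generate_second_response(50.0, 54.0, profile, "pre", rng) for _ in range(4000)]
        )
        assert set(np.unique(draws)) == {50.0, 54.0}
        assert np.mean(draws == 54.0) == pytest.approx(0.3, abs=0.03)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            at.StrategyProfile(kind="oracle")

    def test_mixture_requires_simplex(self):
        with pytest.raises(ValueError):
            at.StrategyProfile(kind="mixture", mixture_probs=(0.5, 0.2, 0.2))
        with pytest.raises(ValueError):
            at.StrategyProfile(kind="mixture")


class TestDesignValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"truth_min": 30.0},  # truth range must sit inside the scale
            {"no_advice_fraction": 1.0},
            {"n_practice": 110},
            {"adjustment_window": (3, 40)},  # overlaps practice
            {"adjustment_window": (90, 120)},  # beyond the session
            {"accurate_half_width": -1.0},
        ],
    )
    def test_invalid_designs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            at.SessionDesign(**kwargs)

    def test_phase_labels_follow_the_window(self):
        d = at.SessionDesign(adjustment_window=at.ADJUSTMENT_WINDOWS["early"])
        assert d.phase_of(5) == "practice"
        assert d.phase_of(6) == "pre"
        assert d.phase_of(21) == "adjusted"
        assert d.phase_of(40) == "adjusted"
        assert d.phase_of(41) == "post"


class TestSession:
    def test_structure_at_defaults(self, design):
        trials = at.generate_session(design, at.StrategyProfile(kind="adopt"), rng=np.random.default_rng(0))
        assert len(trials) == 110
        practice = trials[trials.phase == "practice"]
        assert len(practice) == 5
        assert practice.recommendation.isna().all() and practice.second_response.isna().all()
        second = trials[trials.phase != "practice"]
        assert len(second) == 105 and second.second_response.notna().all()
        assert (~second.has_advice).sum() == 21
        no_advice = second[~second.has_advice]
        assert no_advice.recommendation.isna().all()

    @pytest.mark.parametrize("window", list(at.ADJUSTMENT_WINDOWS))
    def test_phase_partition(self, window):
        design = at.SessionDesign(adjustment_window=at.ADJUSTMENT_WINDOWS[window])
        trials = at.generate_session(design, at.StrategyProfile(kind="stay"), rng=np.random.default_rng(1))
        counts = trials.phase.value_counts()
        assert counts["practice"] == 5
        assert counts[["pre", "adjusted", "post"]].sum() == 105
        lo, hi = design.adjustment_window
        assert counts["adjusted"] == hi - lo + 1

    def test_recommendation_accuracy_degrades_in_window(self, design):
        trials = at.generate_session(design, at.StrategyProfile(kind="stay"), rng=np.random.default_rng(2))
        adv = trials[trials.has_advice]
        dev = (adv.recommendation - adv.truth).abs()
        assert dev[adv.phase == "adjusted"].max() <= 10.0
        assert dev[adv.phase != "adjusted"].max() <= 1.5
        assert dev[adv.phase == "adjusted"].max() > 1.5  # actually degraded

    def test_determinism_and_byte_identical_csv(self, design, tmp_path):
        profile = at.StrategyProfile(kind="compromise", trust_weight=0.5)
        t1 = at.generate_session(design, profile, rng=np.random.default_rng(11))
        t2 = at.generate_session(design, profile, rng=np.random.default_rng(11))
        pd.testing.assert_frame_equal(t1, t2)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_trials_csv(t1, p1)
        write_trials_csv(t2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_csv_round_trip(self, design, tmp_path):
        trials = at.generate_session(design, at.StrategyProfile(kind="adopt"), rng=np.random.default_rng(4))
        path = write_trials_csv(trials, tmp_path / "t.csv")
        back = read_trials_csv(path)
        assert list(back.columns) == list(trials.columns)
        assert back.phase.tolist() == trials.phase.tolist()
        np.testing.assert_allclose(back.truth, trials.truth, rtol=1e-9)


class TestCohort:
    def test_reproducible_with_distinct_streams(self, design):
        profile = at.StrategyProfile(kind="compromise", trust_weight=0.4)
        c1 = at.generate_cohort(2, profile, design, seed=9)
        c2 = at.generate_cohort(2, profile, design, seed=9)
        pd.testing.assert_frame_equal(c1, c2)
        a = c1[c1.participant_id == "p001"].truth.to_numpy()
        b = c1[c1.participant_id == "p002"].truth.to_numpy()
        assert not np.allclose(a, b)

    def test_cohort_shape_matches_study(self, design):
        cohort = at.generate_cohort(
            89, at.StrategyProfile(kind="stay", perceptual_noise_sd=3.0), design, seed=1
        )
        assert len(cohort) == 89 * 110
        assert cohort.participant_id.nunique() == 89

    def test_pure_adopt_zero_noise_reproduces_recommendations(self, design):
        profile = at.StrategyProfile(kind="adopt", motor_noise_sd=0.0)
        cohort = at.generate_cohort(3, profile, design, seed=5)
        adv = cohort[cohort.has_advice]
        # the slider is bounded: B = R exactly wherever R lies on the scale
        on_scale = adv.recommendation.between(design.scale_min, design.scale_max)
        np.testing.assert_allclose(
            adv.second_response[on_scale], adv.recommendation[on_scale]
        )
        np.testing.assert_allclose(
            adv.second_response[~on_scale],
            adv.recommendation[~on_scale].clip(design.scale_min, design.scale_max),
        )

    def test_rejects_empty_cohort(self, design):
        with pytest.raises(ValueError):
            at.generate_cohort(0, at.StrategyProfile(kind="stay"), design)


@given(st.integers(0, 2**31 - 1))
def test_session_is_deterministic_under_any_seed(seed):
    design = at.SessionDesign()
    profile = at.StrategyProfile(kind="compromise", trust_weight=0.5)
    t1 = at.generate_session(design, profile, rng=np.random.default_rng(seed))
    t2 = at.generate_session(design, profile, rng=np.random.default_rng(seed))
    assert t1.equals(t2)
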