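"""Validation metrics against independent brute-force oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize, minimize_scalar

from t2dsim.engine import simulate_cohort
from t2dsim.errors import ConfigError
from t2dsim.metrics import (
    ObservedOutcome,
    brier,
    build_validation_report,
    calibration,
    cox_hr,
    cumulative_incidence,
    harrell_c,
    observed_frame,
    proportion_pct,
    relative_risk,
    round_half_up,
)

from conftest import make_participant, constant_hazard_set


def outcomes(times, events, arms, endpoint="ep"):
    return [
        ObservedOutcome(id=f"s{i}", arm=a, endpoint=endpoint, event=bool(e), time=float(t))
        for i, (t, e, a) in enumerate(zip(times, events, arms))
    ]


class TestRelativeRisk:
    def test_identical_arms_give_exactly_one(self):
        assert relative_risk(123, 4000, 123, 4000) == 1.00

    def test_rounding_is_half_up(self):
        # 0.985 rounds up to 0.99, not banker's 0.98
        assert round_half_up(0.985, 2) == 0.99
        assert proportion_pct(105, 1000) == 10.5

    def test_zero_placebo_events_is_undefined_not_infinite(self):
        assert relative_risk(5, 100, 0, 100) is None

    def test_counts_beyond_denominator_rejected(self):
        with pytest.raises(ConfigError):
            relative_risk(101, 100, 5, 100)

    @given(a=st.integers(1, 400), n=st.integers(400, 5000))
    @settings(derandomize=True, max_examples=25)
    def test_symmetry_property(self, a, n):
        assert relative_risk(a, n, a, n) == 1.00


class TestBrier:
    def test_hand_worked_example(self):
        assert brier([0.2, 0.6, 0.9], [0, 1, 1]) == pytest.approx(0.07)

    def test_perfect_accuracy_and_inaccuracy(self):
        assert brier([0.0, 1.0], [0, 1]) == 0.0
        assert brier([1.0, 1.0], [0, 0]) == 1.0

    @given(st.lists(st.tuples(st.floats(0, 1), st.booleans()), min_size=1, max_size=40))
    @settings(derandomize=True, max_examples=30)
    def test_bounded_in_unit_interval(self, pairs):
        pred = [p for p, _ in pairs]
        obs = [float(o) for _, o in pairs]
        assert 0.0 <= brier(pred, obs) <= 1.0


def brute_force_concordance(risk, times, events):
    """Exhaustive pair enumeration with Harrell's comparability rule."""
    conc = comp = 0.0
    n = len(risk)
    for i, j in itertools.combinations(range(n), 2):
        if times[i] == times[j]:
            continue  # neither time is strictly shorter
        short, long_ = (i, j) if times[i] < times[j] else (j, i)
        if not events[short]:
            continue
        comp += 1
        if risk[short] > risk[long_]:
            conc += 1
        elif risk[short] == risk[long_]:
            conc += 0.5
    return conc / comp


class TestHarrellC:
    def test_perfect_discrimination(self):
        times = [1, 2, 3, 4, 5]
        risk = [5, 4, 3, 2, 1]
        assert harrell_c(risk, times, [True] * 5) == 1.0

    def test_random_risks_near_half(self):
        rng = np.random.default_rng(1)
        n = 4000
        times = rng.exponential(1, n)
        risk = rng.random(n)
        c = harrell_c(risk, times, np.ones(n, bool))
        assert abs(c - 0.5) < 0.03

    def test_censored_example_matches_pair_enumeration(self):
        times = [2.0, 4.0, 6.0, 5.0, 3.0]
        events = [True, False, True, True, True]
        risk = [0.9, 0.7, 0.1, 0.4, 0.8]
        assert harrell_c(risk, times, events) == pytest.approx(
            brute_force_concordance(risk, times, events), abs=1e-12
        )

    def test_risk_ties_count_half(self):
        times = [1.0, 2.0]
        events = [True, True]
        assert harrell_c([0.5, 0.5], times, events) == 0.5

    @given(st.integers(0, 1000))
    @settings(derandomize=True, max_examples=20)
    def test_negating_risk_maps_c_to_its_complement(self, seed):
        rng = np.random.default_rng(seed)
        n = 25
        times = rng.exponential(1, n)
        events = rng.random(n) < 0.7
        if not events.any():
            events[0] = True
        risk = rng.random(n)
        c = harrell_c(risk, times, events)
        assert harrell_c(-risk, times, events) == pytest.approx(1 - c, abs=1e-12)


class TestCumulativeIncidence:
    def test_no_censoring_reduces_to_ecdf(self):
        times = [1.0, 2.0, 2.0, 3.0, 5.0]
        obs = outcomes(times, [1] * 5, ["active"] * 5)
        ci = cumulative_incidence(obs)
        lookup = dict(zip(ci["time"], ci["cuminc"]))
        for t in set(times):
            assert lookup[t] == pytest.approx(np.mean([x <= t for x in times]))

    def test_all_censored_is_identically_zero(self):
        obs = outcomes([1.0, 2.0, 3.0], [0, 0, 0], ["active"] * 3)
        assert cumulative_incidence(obs)["cuminc"].max() == 0.0

    def test_eight_subject_product_limit_table(self):
        # hand-computed Kaplan-Meier: censored subjects leave the risk set
        # after the deaths at their own time
        times = [1, 2, 2, 3, 4, 5, 6, 7]
        events = [1, 1, 0, 1, 0, 1, 0, 1]
        obs = outcomes(times, events, ["active"] * 8)
        ci = cumulative_incidence(obs)
        lookup = dict(zip(ci["time"], ci["cuminc"]))
        expected = {1: 0.125, 2: 0.25, 3: 0.4, 5: 0.6, 7: 1.0}
        for t, v in expected.items():
            assert lookup[t] == pytest.approx(v, abs=1e-12)

    def test_nondecreasing_and_bounded(self):
        rng = np.random.default_rng(3)
        obs = outcomes(rng.exponential(2, 200), rng.random(200) < 0.6, ["active"] * 200)
        ci = cumulative_incidence(obs)
        assert (np.diff(ci["cuminc"]) >= -1e-12).all()
        assert ci["cuminc"].between(0, 1).all()

    def test_negative_times_rejected(self):
        with pytest.raises(ConfigError):
            cumulative_incidence(pd.DataFrame({"id": ["a"], "arm": ["active"], "endpoint": ["e"], "event": [True], "time": [-1.0]}))


def efron_free_partial_loglik(beta, times, events, treated):
    """Cox partial log-likelihood for distinct event times (no ties)."""
    ll = 0.0
    for i in range(len(times)):
        if not events[i]:
            continue
        at_risk = [j for j in range(len(times)) if times[j] >= times[i]]
        ll += beta * treated[i] - math.log(sum(math.exp(beta * treated[j]) for j in at_risk))
    return ll


class TestCoxHR:
    def test_identical_arms_give_unit_hazard_ratio(self):
        times = [1.0, 2.0, 3.0, 4.0]
        obs = outcomes(times + times, [1] * 8, ["active"] * 4 + ["placebo"] * 4)
        fit = cox_hr(obs)
        assert fit.hr == pytest.approx(1.0, abs=1e-6)

    def test_six_subject_example_matches_grid_search_oracle(self):
        times = [2.0, 5.0, 9.0, 1.0, 4.0, 8.0]
        treated = [1, 1, 1, 0, 0, 0]
        arms = ["active"] * 3 + ["placebo"] * 3
        obs = outcomes(times, [1] * 6, arms)
        oracle = minimize_scalar(
            lambda b: -efron_free_partial_loglik(b, times, [1] * 6, treated),
            bounds=(-4, 4),
            method="bounded",
            options={"xatol": 1e-10},
        )
        fit = cox_hr(obs)
        assert fit.hr == pytest.approx(math.exp(oracle.x), abs=1e-4)

    def test_recovers_simulated_hazard_ratio(self):
        rng = np.random.default_rng(8)
        n = 5000
        h0 = 0.2
        t_pl = rng.exponential(1 / h0, n)
        t_ac = rng.exponential(1 / (h0 * 0.8), n)
        times = np.concatenate([np.minimum(t_ac, 3.0), np.minimum(t_pl, 3.0)])
        events = np.concatenate([t_ac <= 3.0, t_pl <= 3.0])
        arms = ["active"] * n + ["placebo"] * n
        fit = cox_hr(outcomes(times, events, arms))
        assert abs(fit.log_hr - math.log(0.8)) < 3 * fit.se

    def test_no_events_rejected(self):
        obs = outcomes([1.0, 2.0], [0, 0], ["active", "placebo"])
        with pytest.raises(ConfigError):
            cox_hr(obs)

    def test_single_arm_rejected(self):
        obs = outcomes([1.0, 2.0], [1, 1], ["active", "active"])
        with pytest.raises(ConfigError):
            cox_hr(obs)


def logistic_loglik(params, x, y):
    a, b = params
    lp = a + b * x
    return float(np.sum(y * lp - np.logaddexp(0, lp)))


class TestCalibration:
    def test_self_consistency_slope_one_intercept_zero(self):
        rng = np.random.default_rng(10)
        n = 50_000
        pred = rng.beta(2, 12, n)
        obs = rng.random(n) < pred
        cal = calibration(pred, obs.astype(float))
        assert abs(cal.slope - 1.0) < 3 * cal.slope_se
        assert abs(cal.intercept) < 3 * cal.intercept_se

    def test_doubled_odds_gives_negative_log2_intercept(self):
        # predictions uniformly shifted by +log 2 on the logit scale while
        # outcomes follow the original risks: overestimation, intercept ~ -log 2
        rng = np.random.default_rng(11)
        n = 50_000
        p0 = rng.beta(2, 10, n)
        logit = np.log(p0 / (1 - p0)) + math.log(2)
        pred = 1 / (1 + np.exp(-logit))
        obs = (rng.random(n) < p0).astype(float)
        cal = calibration(pred, obs)
        assert abs(cal.intercept + math.log(2)) < 3 * cal.intercept_se

    def test_twenty_point_example_matches_likelihood_oracle(self):
        pred = np.array([0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5,
                         0.55, 0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9, 0.93, 0.97])
        obs = np.array([0, 0, 0, 1, 0, 0, 1, 0, 1, 1, 0, 1, 1, 1, 0, 1, 1, 1, 1, 1], dtype=float)
        x = np.log(pred / (1 - pred))
        oracle = minimize(
            lambda p: -logistic_loglik(p, x, obs), x0=[0.0, 1.0], method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000},
        )
        cal = calibration(pred, obs)
        assert cal.slope == pytest.approx(oracle.x[1], abs=1e-3)
        # offset-method intercept oracle: 1-parameter likelihood with slope 1
        off = minimize_scalar(
            lambda a: -logistic_loglik((a, 1.0), x, obs), bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        )
        assert cal.intercept == pytest.approx(off.x, abs=1e-3)

    def test_decile_table_partitions_cohort(self):
        rng = np.random.default_rng(12)
        pred = rng.random(1000)
        obs = (rng.random(1000) < pred).astype(float)
        cal = calibration(pred, obs)
        assert cal.table["n"].sum() == 1000
        assert len(cal.table) == 10
        assert cal.table["observed"].between(0, 1).all()

    def test_constant_predictions_flag_undefined_slope(self):
        cal = calibration([0.3] * 50, [0.0, 1.0] * 25)
        assert "slope_undefined" in cal.flags
        assert math.isnan(cal.slope)


class TestValidationReport:
    def _setup(self, n=150, seed=5):
        eqs = constant_hazard_set(0.08, name="mi", kind="event")
        cohort = [
            make_participant(f"p{i}", arm="active" if i % 2 else "placebo",
                             age=50.0 + (i % 30), sex="male" if i % 3 else "female")
            for i in range(n)
        ]
        sim = simulate_cohort(cohort, eqs, 3.0, replications=40, seed=seed)
        rng = np.random.default_rng(seed)
        t = rng.exponential(1 / 0.08, n)
        obs = [
            ObservedOutcome(id=p.id, arm=p.arm, endpoint="mi", event=bool(t[i] <= 3.0),
                            time=float(min(t[i], 3.0)))
            for i, p in enumerate(cohort)
        ]
        return obs, sim

    def test_whole_cohort_subgroup_equals_overall(self):
        obs, sim = self._setup()
        rep = build_validation_report(obs, sim, endpoints=["mi"], subgroups=("age_lt65", "age_ge65"))
        whole = rep.endpoints["mi"]
        lt, ge = rep.subgroups["age_lt65"]["mi"], rep.subgroups["age_ge65"]["mi"]
        assert lt.observed_active + ge.observed_active == whole.observed_active
        assert lt.n_active + ge.n_active == whole.n_active
        assert lt.simulated_active + ge.simulated_active == pytest.approx(whole.simulated_active)

    def test_id_mismatch_rejected(self):
        obs, sim = self._setup()
        obs.append(ObservedOutcome(id="ghost", arm="active", endpoint="mi", event=False, time=3.0))
        with pytest.raises(ConfigError, match="ghost"):
            build_validation_report(obs, sim, endpoints=["mi"], subgroups=None)

    def test_report_frame_is_tidy(self):
        obs, sim = self._setup()
        rep = build_validation_report(obs, sim, endpoints=["mi"], subgroups=("male", "female"))
        frame = rep.to_frame()
        assert set(frame["scope"]) == {"overall", "male", "female"}
        assert (frame["rr"].dropna() >= 0).all()


def test_observed_frame_normalizes_and_validates():
    obs = outcomes([1.0], [1], ["active"])
    df = observed_frame(obs)
    assert list(df.columns) == ["id", "arm", "endpoint", "event", "time"]
    with pytest.raises(ConfigError):
        observed_frame(pd.DataFrame({"id": ["a"], "arm": ["active"]}))
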