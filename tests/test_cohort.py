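"""Cohort ingestion and the mean-substitution / stratified imputation policies."""

import numpy as np
import pytest

from t2dsim.cohort import (
    CONTINUOUS_FACTORS,
    DEFAULT_LIMITS,
    FACTORS,
    FactorLimits,
    RiskFactorVector,
    age_band,
    count_missing,
    fill_followup,
    impute_mean_substitution,
    impute_stratified,
    load_cohort,
    save_cohort,
)
from t2dsim.equations import CoefficientSet, EquationSpec
from t2dsim.errors import ConfigError, SchemaError

from conftest import make_participant


def identity_progression() -> CoefficientSet:
    return CoefficientSet(
        "identity",
        [
            EquationSpec(name=f, kind="progression", coefficients={"current": 1.0})
            for f in CONTINUOUS_FACTORS
        ],
    )


def drift_progression(factor="hba1c", drift=0.1) -> CoefficientSet:
    eqs = []
    for f in CONTINUOUS_FACTORS:
        intercept = drift if f == factor else 0.0
        eqs.append(
            EquationSpec(name=f, kind="progression", intercept=intercept, coefficients={"current": 1.0})
        )
    return CoefficientSet("drift", eqs)


class TestLoadCohort:
    def test_roundtrip_preserves_values_and_missingness(self, tmp_path):
        cohort = [
            make_participant("a1", arm="active", prior=("mi", "heart_failure")),
            make_participant("a2", arm="placebo", sex="female", hba1c=None, hdl=None),
        ]
        cohort[0].followup[1] = RiskFactorVector(hba1c=7.5, smoking=True)
        path = tmp_path / "cohort.csv"
        save_cohort(cohort, path)
        back = load_cohort(path)
        assert [p.id for p in back] == ["a1", "a2"]
        assert back[0].prior.has("mi") and back[0].prior.has("heart_failure")
        assert back[0].prior.events["mi"] == 1.0  # default: 1 year before baseline
        assert back[0].followup[1].hba1c == 7.5
        assert back[0].followup[1].smoking is True
        assert back[0].followup[1].sbp is None
        assert back[1].baseline.hba1c is None and back[1].baseline.hdl is None
        assert back[1].baseline.ldl == 2.3

    def test_header_only_file_gives_empty_cohort(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("id,arm,age,sex\n")
        assert load_cohort(path) == []

    def test_unknown_arm_label_named_in_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,arm,age,sex\np1,crossover,60,male\n")
        with pytest.raises(SchemaError, match="crossover"):
            load_cohort(path)

    def test_missing_required_column_named_in_error(self, tmp_path):
        path = tmp_path / "noarm.csv"
        path.write_text("id,age,sex\np1,60,male\n")
        with pytest.raises(SchemaError, match="arm"):
            load_cohort(path)

    def test_unparseable_numeric_reports_id_and_field(self, tmp_path):
        path = tmp_path / "badnum.csv"
        path.write_text("id,arm,age,sex,hba1c\np7,active,60,male,seven\n")
        with pytest.raises(SchemaError, match="p7") as err:
            load_cohort(path)
        assert "hba1c" in str(err.value)

    def test_arm_labels_mapped_through_schema(self, tmp_path):
        path = tmp_path / "trial.csv"
        path.write_text("id,arm,age,sex\np1,sitagliptin,60,male\np2,placebo,61,female\n")
        cohort = load_cohort(path, schema={"arm_labels": {"sitagliptin": "active"}})
        assert [p.arm for p in cohort] == ["active", "placebo"]


class TestMeanSubstitution:
    def test_complete_cohort_unchanged(self):
        cohort = [make_participant(f"p{i}") for i in range(5)]
        out = impute_mean_substitution(cohort)
        for before, after in zip(cohort, out):
            assert before.baseline.as_dict() == after.baseline.as_dict()
            assert not after.imputed

    def test_stratum_mean_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        cohort = []
        for i in range(120):
            sex = "male" if rng.random() < 0.5 else "female"
            age = float(rng.uniform(45, 85))
            hba1c = float(rng.uniform(5.5, 11.0))
            cohort.append(make_participant(f"p{i}", sex=sex, age=age, hba1c=hba1c))
        target = make_participant("probe", sex="male", age=60.0, hba1c=None)
        cohort.append(target)

        out = impute_mean_substitution(cohort)
        # independent group-by oracle: in-range males in the 55-64 band
        band = age_band(60.0)
        pool = [
            p.baseline.hba1c
            for p in cohort
            if p.baseline.hba1c is not None
            and p.sex == "male"
            and age_band(p.age) == band
            and DEFAULT_LIMITS.in_range("hba1c", p.baseline.hba1c)
        ]
        assert out[-1].baseline.hba1c == pytest.approx(np.mean(pool), abs=1e-12)
        assert (0, "hba1c") in out[-1].imputed

    def test_out_of_range_value_treated_as_missing(self):
        cohort = [make_participant(f"p{i}", hba1c=7.0 + 0.1 * i) for i in range(10)]
        cohort.append(make_participant("hi", hba1c=25.0))  # above the 15% model max
        out = impute_mean_substitution(cohort)
        pool = [7.0 + 0.1 * i for i in range(10)]
        assert out[-1].baseline.hba1c == pytest.approx(np.mean(pool))

    def test_whole_study_missing_uses_population_average(self):
        cohort = [make_participant(f"p{i}", egfr=None) for i in range(4)]
        out = impute_mean_substitution(cohort, population_averages={"egfr": 80.0})
        assert all(p.baseline.egfr == 80.0 for p in out)

    def test_unknown_factor_limits_is_config_error(self):
        cohort = [make_participant("p1")]
        with pytest.raises(ConfigError):
            impute_mean_substitution(cohort, limits=FactorLimits({"hba1c": (4, 15)}), factors=("sbp",))


class TestStratifiedImputation:
    def _cohort_with_missing(self, n=400, missing_rate=0.397, seed=3):
        rng = np.random.default_rng(seed)
        cohort = []
        for i in range(n):
            hb = float(rng.normal(13.8, 1.5))
            cohort.append(
                make_participant(
                    f"p{i}",
                    sex="male" if rng.random() < 0.6 else "female",
                    age=float(rng.uniform(45, 85)),
                    prior=("mi",) if rng.random() < 0.5 else (),
                    haemoglobin=None if rng.random() < missing_rate else hb,
                )
            )
        return cohort

    def test_fills_all_and_flags_match_missing_fraction(self):
        cohort = self._cohort_with_missing()
        n_missing = count_missing(cohort, "haemoglobin")
        out = impute_stratified(cohort, seed=7)
        assert count_missing(out, "haemoglobin") == 0
        flagged = sum((0, "haemoglobin") in p.imputed for p in out)
        assert flagged == n_missing

    def test_imputed_values_drawn_from_observed_pool(self):
        cohort = self._cohort_with_missing(n=200)
        observed = {
            p.baseline.haemoglobin for p in cohort if p.baseline.haemoglobin is not None
        }
        out = impute_stratified(cohort, seed=7)
        for p in out:
            if (0, "haemoglobin") in p.imputed:
                assert p.baseline.haemoglobin in observed

    def test_no_missing_is_identity(self):
        cohort = [make_participant(f"p{i}") for i in range(5)]
        out = impute_stratified(cohort, seed=1)
        assert all(not p.imputed for p in out)

    def test_same_seed_cell_identical(self):
        cohort = self._cohort_with_missing()
        a = impute_stratified(cohort, seed=11)
        b = impute_stratified(cohort, seed=11)
        assert all(
            pa.baseline.as_dict() == pb.baseline.as_dict() for pa, pb in zip(a, b)
        )

    def test_mean_method_matches_groupby_oracle(self):
        cohort = self._cohort_with_missing(n=150)
        out = impute_stratified(cohort, seed=5, method="mean")
        for raw, p in zip(cohort, out):
            if (0, "haemoglobin") not in p.imputed:
                continue
            band, cv = age_band(raw.age), raw.prior.prior_cv
            pool = [
                q.baseline.haemoglobin
                for q in cohort
                if q.baseline.haemoglobin is not None
                and q.sex == raw.sex
                and age_band(q.age) == band
                and q.prior.prior_cv == cv
                and DEFAULT_LIMITS.in_range("haemoglobin", q.baseline.haemoglobin)
            ]
            if pool:
                assert p.baseline.haemoglobin == pytest.approx(np.mean(pool))


class TestFillFollowup:
    def test_complete_followup_unchanged(self):
        p = make_participant("p1")
        for y in (1, 2, 3):
            p.followup[y] = RiskFactorVector(**{f: getattr(p.baseline, f) for f in FACTORS})
        out = fill_followup([p], identity_progression(), 3.0)
        for y in (1, 2, 3):
            assert out[0].followup[y].as_dict() == p.followup[y].as_dict()

    def test_identity_progression_holds_baseline_fixed(self):
        p = make_participant("p1")
        out = fill_followup([p], identity_progression(), 3.0)
        for y in (1, 2, 3):
            for f in CONTINUOUS_FACTORS:
                assert getattr(out[0].followup[y], f) == getattr(p.baseline, f)

    def test_linear_drift_matches_direct_recursion(self):
        p = make_participant("p1", hba1c=7.0)
        out = fill_followup([p], drift_progression("hba1c", 0.1), 3.0)
        assert out[0].followup[3].hba1c == pytest.approx(7.3, abs=1e-12)

    def test_observed_midtrial_values_anchor_later_years(self):
        p = make_participant("p1", hba1c=7.0)
        p.followup[2] = RiskFactorVector(hba1c=9.0)
        out = fill_followup([p], drift_progression("hba1c", 0.1), 4.0)
        assert out[0].followup[2].hba1c == 9.0  # observed, never overwritten
        assert out[0].followup[3].hba1c == pytest.approx(9.1)
        assert out[0].followup[4].hba1c == pytest.approx(9.2)

    def test_generated_values_are_clamped_to_limits(self):
        p = make_participant("p1", hba1c=14.8)
        out = fill_followup([p], drift_progression("hba1c", 0.5), 3.0)
        assert out[0].followup[3].hba1c == 15.0  # model max

    def test_incomplete_baseline_rejected(self):
        p = make_participant("p1", hba1c=None)
        with pytest.raises(ConfigError, match="hba1c"):
            fill_followup([p], identity_progression(), 3.0)

    def test_missing_progression_equation_rejected(self):
        partial = CoefficientSet(
            "partial",
            [EquationSpec(name="hba1c", kind="progression", coefficients={"current": 1.0})],
        )
        with pytest.raises(ConfigError):
            fill_followup([make_participant("p1")], partial, 2.0)


def test_post_imputation_completeness_and_range_invariant():
    """After the full imputation policy, every covered cell is present and in range."""
    rng = np.random.default_rng(99)
    cohort = []
    for i in range(150):
        over = {}
        for f in CONTINUOUS_FACTORS:
            r = rng.random()
            if r < 0.25:
                over[f] = None
            elif r < 0.30:
                over[f] = 1e6  # absurd out-of-range value
        cohort.append(
            make_participant(
                f"p{i}",
                sex="male" if rng.random() < 0.5 else "female",
                age=float(rng.uniform(40, 90)),
                **over,
            )
        )
    out = impute_mean_substitution(cohort, factors=tuple(CONTINUOUS_FACTORS))
    out = fill_followup(out, identity_progression(), 3.0)
    for p in out:
        for f in CONTINUOUS_FACTORS:
            v = p.baseline.as_dict()[f]
            assert v is not None and DEFAULT_LIMITS.in_range(f, v)
            for y in (1, 2, 3):
                assert getattr(p.followup[y], f) is not None
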