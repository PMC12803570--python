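"""Participant-level cohort ingestion, validation and imputation.

A cohort is a list of :class:`Participant` records, each carrying a baseline
:class:`RiskFactorVector`, a :class:`PriorEventHistory` and optional
annualized follow-up measurements.  The imputation policy mirrors common
practice when feeding trial data into a diabetes outcomes simulation model:

* factors with low missingness (HbA1c, systolic BP, weight, heart rate, eGFR)
  are replaced by the age- and sex-adjusted cohort mean;
* factors missing not at random (HDL, LDL, haemoglobin) are filled by
  stratified imputation (sex x age band x prior-CV-event status, with a
  fallback chain);
* values outside prespecified model limits are treated as missing and
  re-imputed;
* missing annual follow-up values are generated forward from the last
  observed value with the risk-factor progression equations.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError, StratumError

CONTINUOUS_FACTORS = (
    "weight",
    "hdl",
    "ldl",
    "sbp",
    "hba1c",
    "heart_rate",
    "wbc",
    "haemoglobin",
    "egfr",
)
BOOLEAN_FACTORS = ("smoking", "af", "pad", "albuminuria")
FACTORS = CONTINUOUS_FACTORS + BOOLEAN_FACTORS

#: factors imputed by age- and sex-adjusted mean substitution (low missingness)
MEAN_SUBSTITUTION_FACTORS = ("hba1c", "sbp", "weight", "heart_rate", "egfr")
#: factors imputed by stratified imputation (missing not at random)
STRATIFIED_FACTORS = ("hdl", "ldl", "haemoglobin")

PRIOR_EVENTS = (
    "ihd",
    "heart_failure",
    "amputation",
    "blindness",
    "kidney_failure",
    "mi",
    "stroke",
    "ulcer",
)

ARMS = ("active", "placebo")

#: default age-band edges for "age- and sex-adjusted" strata:
#: <55, 55-64, 65-74, >=75
DEFAULT_AGE_BANDS = (55.0, 65.0, 75.0)


@dataclass
class RiskFactorVector:
    """One participant's clinical state at a given year; ``None`` = missing."""

    weight: float | None = None
    hdl: float | None = None
    ldl: float | None = None
    sbp: float | None = None
    hba1c: float | None = None
    heart_rate: float | None = None
    wbc: float | None = None
    haemoglobin: float | None = None
    egfr: float | None = None
    smoking: bool | None = None
    af: bool | None = None
    pad: bool | None = None
    albuminuria: bool | None = None

    def as_dict(self) -> dict[str, float | bool | None]:
        return {f: getattr(self, f) for f in FACTORS}

    def missing_fields(self) -> list[str]:
        return [f for f in FACTORS if getattr(self, f) is None]

    def is_complete(self) -> bool:
        return not self.missing_fields()

    def copy(self) -> "RiskFactorVector":
        return copy.copy(self)


@dataclass
class PriorEventHistory:
    """Prior clinical events with years elapsed since each.

    ``events`` maps a flagged event name to years-since-event; an event is
    absent from the mapping iff it did not occur.  Event dates were typically
    not recorded in the source trials, so the conventional default is that
    every known historical event occurred exactly 1 year before baseline.
    """

    events: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, years in self.events.items():
            if name not in PRIOR_EVENTS:
                raise ConfigError(f"unknown prior event category: {name!r}")
            if years < 0:
                raise ConfigError(f"years_since_event < 0 for {name!r}")

    @classmethod
    def from_flags(cls, flags: Iterable[str], years_since: float = 1.0) -> "PriorEventHistory":
        return cls({name: years_since for name in flags})

    def has(self, name: str) -> bool:
        return name in self.events

    @property
    def prior_cv(self) -> bool:
        """Any prior atherosclerotic/cardiac event (IHD, MI or stroke)."""
        return any(self.has(e) for e in ("ihd", "mi", "stroke"))

    def copy(self) -> "PriorEventHistory":
        return PriorEventHistory(dict(self.events))


@dataclass
class Participant:
    id: str
    arm: str
    age: float
    sex: str
    race: str = "white"
    diabetes_duration: float = 10.0
    height: float = 170.0
    baseline: RiskFactorVector = field(default_factory=RiskFactorVector)
    prior: PriorEventHistory = field(default_factory=PriorEventHistory)
    #: year index (>=1) -> annualized follow-up measurements
    followup: dict[int, RiskFactorVector] = field(default_factory=dict)
    #: (year, factor) cells whose value was imputed rather than observed
    imputed: set = field(default_factory=set)
    #: optional per-participant censoring time (years), used by generators
    followup_years: float | None = None

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise SchemaError(
                f"participant {self.id!r}: arm must be one of {ARMS}, got {self.arm!r}"
            )
        if not self.age > 0:
            raise SchemaError(f"participant {self.id!r}: age must be > 0")
        if self.diabetes_duration < 0:
            raise SchemaError(f"participant {self.id!r}: diabetes_duration must be >= 0")
        if self.sex not in ("male", "female"):
            raise SchemaError(f"participant {self.id!r}: sex must be male/female")
        years = sorted(self.followup)
        if any(y < 1 for y in years):
            raise SchemaError(f"participant {self.id!r}: follow-up year index must be >= 1")

    def copy(self) -> "Participant":
        return Participant(
            id=self.id,
            arm=self.arm,
            age=self.age,
            sex=self.sex,
            race=self.race,
            diabetes_duration=self.diabetes_duration,
            height=self.height,
            baseline=self.baseline.copy(),
            prior=self.prior.copy(),
            followup={y: v.copy() for y, v in self.followup.items()},
            imputed=set(self.imputed),
            followup_years=self.followup_years,
        )


class FactorLimits:
    """Model-admissible [min, max] range per continuous risk factor."""

    def __init__(self, limits: Mapping[str, tuple[float, float]]):
        for factor, (lo, hi) in limits.items():
            if not lo < hi:
                raise ConfigError(f"factor limits for {factor!r}: min must be < max")
        self._limits = {f: (float(lo), float(hi)) for f, (lo, hi) in limits.items()}

    def __contains__(self, factor: str) -> bool:
        return factor in self._limits

    def range(self, factor: str) -> tuple[float, float]:
        try:
            return self._limits[factor]
        except KeyError:
            raise ConfigError(f"no model limits configured for factor {factor!r}") from None

    def in_range(self, factor: str, value: float) -> bool:
        lo, hi = self.range(factor)
        return lo <= value <= hi

    def clamp(self, factor: str, value: float) -> float:
        lo, hi = self.range(factor)
        return min(max(value, lo), hi)

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return dict(self._limits)


# Prespecified admissible ranges (units as in RiskFactorVector).  These are a
# package default; the real model's limits can be supplied via JSON config.
DEFAULT_LIMITS = FactorLimits(
    {
        "weight": (30.0, 200.0),
        "hdl": (0.2, 3.5),
        "ldl": (0.3, 8.0),
        "sbp": (70.0, 220.0),
        "hba1c": (4.0, 15.0),
        "heart_rate": (30.0, 200.0),
        "wbc": (2.0, 20.0),
        "haemoglobin": (5.0, 20.0),
        "egfr": (5.0, 200.0),
    }
)

#: applied when a factor is missing for the whole study
DEFAULT_POPULATION_AVERAGES = {
    "weight": 86.0,
    "hdl": 1.1,
    "ldl": 2.3,
    "sbp": 135.0,
    "hba1c": 7.3,
    "heart_rate": 72.0,
    "wbc": 7.5,
    "haemoglobin": 13.8,
    "egfr": 75.0,
}


def age_band(age: float, edges: Sequence[float] = DEFAULT_AGE_BANDS) -> int:
    """Index of the age band containing ``age`` (0 = youngest)."""
    return int(np.searchsorted(np.asarray(edges, dtype=float), age, side="right"))


# ---------------------------------------------------------------------------
# CSV ingestion
# ---------------------------------------------------------------------------

DEMOGRAPHIC_COLUMNS = ("id", "arm", "age", "sex", "race", "diabetes_duration", "height")
PRIOR_COLUMNS = tuple(f"prior_{e}" for e in PRIOR_EVENTS)
REQUIRED_COLUMNS = ("id", "arm", "age", "sex")
ALL_COLUMNS = DEMOGRAPHIC_COLUMNS + ("year",) + FACTORS + PRIOR_COLUMNS

_NUMERIC_FIELDS = ("age", "diabetes_duration", "height") + CONTINUOUS_FACTORS
_BOOL_FIELDS = BOOLEAN_FACTORS + PRIOR_COLUMNS


def _parse_float(raw: str, pid: str, column: str) -> float | None:
    if raw == "" or raw.lower() == "nan":
        return None
    try:
        return float(raw)
    except ValueError:
        raise SchemaError(
            f"participant {pid!r}: unparseable numeric value {raw!r} in column {column!r}"
        ) from None


def _parse_bool(raw: str, pid: str, column: str) -> bool | None:
    if raw == "" or raw.lower() == "nan":
        return None
    if raw in ("0", "1", "0.0", "1.0"):
        return raw in ("1", "1.0")
    raise SchemaError(
        f"participant {pid!r}: boolean column {column!r} must be 0/1, got {raw!r}"
    )


def load_cohort(path, schema: Mapping | None = None) -> list[Participant]:
    """Read a participant-year CSV into a cohort.

    One row per participant-year with ``year`` 0 = baseline; booleans coded
    0/1 and missing values as empty cells.  ``schema`` may supply
    ``{"columns": {canonical: actual}}`` to map column names and
    ``{"arm_labels": {...}}`` / ``{"sex_labels": {...}}`` to map trial labels
    onto the canonical ``active``/``placebo`` and ``male``/``female``.
    """
    schema = dict(schema or {})
    colmap = dict(schema.get("columns", {}))
    arm_labels = {str(k).lower(): v for k, v in schema.get("arm_labels", {}).items()}
    sex_labels = {str(k).lower(): v for k, v in schema.get("sex_labels", {}).items()}
    sex_labels.setdefault("m", "male")
    sex_labels.setdefault("f", "female")

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = {actual: canonical for canonical, actual in colmap.items()}
    df = df.rename(columns=rename)

    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")
    if "year" not in df.columns:
        df["year"] = "0"

    participants: list[Participant] = []
    for pid, rows in df.groupby("id", sort=False):
        rows = rows.copy()
        rows["_year"] = [int(_parse_float(y, pid, "year") or 0) for y in rows["year"]]
        rows = rows.sort_values("_year")
        if rows["_year"].duplicated().any():
            raise SchemaError(f"participant {pid!r}: duplicate year rows")
        base_rows = rows[rows["_year"] == 0]
        if len(base_rows) != 1:
            raise SchemaError(f"participant {pid!r}: expected exactly one baseline (year 0) row")
        base = base_rows.iloc[0]

        arm_raw = str(base["arm"]).strip().lower()
        arm = arm_labels.get(arm_raw, arm_raw)
        if arm not in ARMS:
            raise SchemaError(
                f"participant {pid!r}: unrecognized arm label {base['arm']!r}"
            )
        sex_raw = str(base["sex"]).strip().lower()
        sex = sex_labels.get(sex_raw, sex_raw)

        def get(row, col):
            return str(row[col]).strip() if col in row.index else ""

        def rfv(row) -> RiskFactorVector:
            kwargs = {}
            for f in CONTINUOUS_FACTORS:
                kwargs[f] = _parse_float(get(row, f), pid, f)
            for f in BOOLEAN_FACTORS:
                kwargs[f] = _parse_bool(get(row, f), pid, f)
            return RiskFactorVector(**kwargs)

        prior_flags = []
        for event, col in zip(PRIOR_EVENTS, PRIOR_COLUMNS):
            if _parse_bool(get(base, col), pid, col):
                prior_flags.append(event)

        followup = {int(r["_year"]): rfv(r) for _, r in rows[rows["_year"] > 0].iterrows()}
        participants.append(
            Participant(
                id=str(pid),
                arm=arm,
                age=_parse_float(get(base, "age"), pid, "age"),
                sex=sex,
                race=get(base, "race") or "white",
                diabetes_duration=_parse_float(get(base, "diabetes_duration"), pid, "diabetes_duration")
                or 0.0,
                height=_parse_float(get(base, "height"), pid, "height") or 170.0,
                baseline=rfv(base),
                prior=PriorEventHistory.from_flags(prior_flags),
                followup=followup,
            )
        )
    return participants


def save_cohort(cohort: Sequence[Participant], path) -> None:
    """Write a cohort in the participant-year CSV dialect read by load_cohort."""

    def fmt(value):
        if value is None:
            return ""
        if isinstance(value, bool):
            return int(value)
        return value

    records = []
    for p in cohort:
        base = {
            "id": p.id,
            "arm": p.arm,
            "age": p.age,
            "sex": p.sex,
            "race": p.race,
            "diabetes_duration": p.diabetes_duration,
            "height": p.height,
            "year": 0,
        }
        base.update({f: fmt(v) for f, v in p.baseline.as_dict().items()})
        base.update(
            {f"prior_{e}": int(p.prior.has(e)) for e in PRIOR_EVENTS}
        )
        records.append(base)
        for year in sorted(p.followup):
            row = {"id": p.id, "arm": p.arm, "age": p.age, "sex": p.sex, "year": year}
            row.update({f: fmt(v) for f, v in p.followup[year].as_dict().items()})
            records.append(row)
    pd.DataFrame.from_records(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------


def _baseline_value(p: Participant, factor: str) -> float | None:
    return getattr(p.baseline, factor)


def impute_mean_substitution(
    cohort: Sequence[Participant],
    limits: FactorLimits = DEFAULT_LIMITS,
    age_bands: Sequence[float] = DEFAULT_AGE_BANDS,
    factors: Sequence[str] = MEAN_SUBSTITUTION_FACTORS,
    population_averages: Mapping[str, float] | None = None,
) -> list[Participant]:
    """Replace missing/out-of-range baseline values by the sex- and age-band mean.

    Falls back to the whole-study mean when a stratum has no valid values, and
    to the configured population average when the whole study lacks the factor.
    Observed in-range values are never altered.
    """
    if not cohort:
        raise ConfigError("cohort is empty")
    pop_avg = dict(DEFAULT_POPULATION_AVERAGES)
    pop_avg.update(population_averages or {})

    out = [p.copy() for p in cohort]
    for factor in factors:
        lo, hi = limits.range(factor)  # raises ConfigError if absent
        # stratum -> mean of valid values
        groups: dict[tuple[str, int], list[float]] = {}
        for p in out:
            v = _baseline_value(p, factor)
            if v is not None and lo <= v <= hi:
                groups.setdefault((p.sex, age_band(p.age, age_bands)), []).append(v)
        stratum_means = {k: float(np.mean(v)) for k, v in groups.items()}
        all_valid = [v for vals in groups.values() for v in vals]
        study_mean = float(np.mean(all_valid)) if all_valid else None

        for p in out:
            v = _baseline_value(p, factor)
            if v is not None and lo <= v <= hi:
                continue
            key = (p.sex, age_band(p.age, age_bands))
            if key in stratum_means:
                fill = stratum_means[key]
            elif study_mean is not None:
                fill = study_mean
            else:
                fill = pop_avg.get(factor)
                if fill is None:
                    raise ConfigError(
                        f"factor {factor!r} missing for the whole study and no "
                        "population average configured"
                    )
            setattr(p.baseline, factor, fill)
            p.imputed.add((0, factor))
    return out


def _stratum_chain(p: Participant, age_bands: Sequence[float]):
    band = age_band(p.age, age_bands)
    cv = p.prior.prior_cv
    yield (p.sex, band, cv)
    yield (p.sex, band)
    yield (p.sex,)
    yield ()


def impute_stratified(
    cohort: Sequence[Participant],
    factors: Sequence[str] = STRATIFIED_FACTORS,
    age_bands: Sequence[float] = DEFAULT_AGE_BANDS,
    limits: FactorLimits = DEFAULT_LIMITS,
    seed: int = 0,
    method: str = "sample",
    population_averages: Mapping[str, float] | None = None,
) -> list[Participant]:
    """Stratified imputation for factors missing not at random.

    Strata are sex x age band x prior-CV-event status; missing values are
    drawn from the empirical distribution (``method="sample"``) or mean
    (``method="mean"``) of observed in-range values in the same stratum, with
    a fallback chain dropping prior-CV status, then age band, then sex.
    Deterministic given ``seed``; every imputed cell is flagged.
    """
    if method not in ("sample", "mean"):
        raise ConfigError(f"unknown imputation method {method!r}")
    if not cohort:
        raise ConfigError("cohort is empty")
    pop_avg = dict(DEFAULT_POPULATION_AVERAGES)
    pop_avg.update(population_averages or {})
    rng = np.random.default_rng(seed)

    out = [p.copy() for p in cohort]
    for factor in factors:
        lo, hi = limits.range(factor)
        pools: dict[tuple, list[float]] = {}
        for p in out:
            v = _baseline_value(p, factor)
            if v is not None and lo <= v <= hi:
                band = age_band(p.age, age_bands)
                cv = p.prior.prior_cv
                for key in ((p.sex, band, cv), (p.sex, band), (p.sex,), ()):
                    pools.setdefault(key, []).append(v)
        pool_arrays = {k: np.asarray(v, dtype=float) for k, v in pools.items()}

        for p in out:
            v = _baseline_value(p, factor)
            if v is not None and lo <= v <= hi:
                continue
            fill = None
            for key in _stratum_chain(p, age_bands):
                arr = pool_arrays.get(key)
                if arr is not None and arr.size:
                    if method == "sample":
                        fill = float(arr[rng.integers(arr.size)])
                    else:
                        fill = float(arr.mean())
                    break
            if fill is None:
                fill = pop_avg.get(factor)
                if fill is None:
                    raise StratumError(
                        f"no observed values of {factor!r} in any stratum for "
                        f"participant {p.id!r} and no population average configured"
                    )
            setattr(p.baseline, factor, fill)
            p.imputed.add((0, factor))
    return out


def fill_followup(
    cohort: Sequence[Participant],
    progression: "CoefficientSet",
    horizon: float,
    limits: FactorLimits = DEFAULT_LIMITS,
) -> list[Participant]:
    """Populate every (participant, year, factor) cell up to ``horizon``.

    Observed in-range values are kept; gaps are filled forward from the last
    observed value with the progression equations (continuous factors) or by
    carrying the last observation forward (boolean factors), clamped to the
    model limits.  Requires a fully imputed baseline.
    """
    from .equations import progress_risk_factor  # local import to avoid cycle

    n_years = int(math.floor(horizon))
    out = [p.copy() for p in cohort]
    # fail fast if a continuous factor lacks a progression equation
    for factor in CONTINUOUS_FACTORS:
        if progression.progression_for(factor) is None:
            raise ConfigError(f"no progression equation for factor {factor!r}")

    for p in out:
        missing = p.baseline.missing_fields()
        if missing:
            raise ConfigError(
                f"participant {p.id!r}: baseline incomplete before follow-up fill "
                f"(missing {missing})"
            )
        current = p.baseline.as_dict()
        for year in range(1, n_years + 1):
            observed = p.followup.get(year, RiskFactorVector())
            state = dict(current)
            state["age"] = p.age + (year - 1)
            state["diabetes_duration"] = p.diabetes_duration + (year - 1)
            state["male"] = 1.0 if p.sex == "male" else 0.0
            state["height"] = p.height
            new = {}
            for factor in CONTINUOUS_FACTORS:
                obs = getattr(observed, factor)
                if obs is not None and limits.in_range(factor, obs):
                    new[factor] = obs
                else:
                    eq = progression.progression_for(factor)
                    st = dict(state)
                    st["current"] = current[factor]
                    new[factor] = limits.clamp(factor, progress_risk_factor(eq, st))
                    p.imputed.add((year, factor))
            for factor in BOOLEAN_FACTORS:
                obs = getattr(observed, factor)
                if obs is not None:
                    new[factor] = obs
                else:
                    new[factor] = current[factor]
                    p.imputed.add((year, factor))
            p.followup[year] = RiskFactorVector(**new)
            current = new
    return out


def count_missing(cohort: Sequence[Participant], factor: str) -> int:
    """Number of participants with a missing baseline value for ``factor``."""
    return sum(1 for p in cohort if _baseline_value(p, factor) is None)
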