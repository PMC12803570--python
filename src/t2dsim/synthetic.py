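"""Synthetic trial-cohort generator with known ground truth.

No participant-level data from the source cardiovascular outcome trials are
publicly available, so every pipeline stage is exercised on generated
cohorts that emulate their published shape: arm sizes, baseline risk-factor
marginals (correlated through a Gaussian copula), prior-event prevalences
(e.g. the fraction with established atherosclerotic cardiovascular disease),
per-factor missingness rates — including a missing-not-at-random mechanism
for HDL, LDL and haemoglobin — annual risk-factor trajectories with noise and
observation gaps, and arm-specific censored event times drawn from
configurable parametric hazards.

The built-in profiles are deliberately labelled *illustrative*: the trials'
true baseline distributions are not published at the level of detail needed
to copy them, and nothing downstream depends on their specific values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import (
    BOOLEAN_FACTORS,
    CONTINUOUS_FACTORS,
    DEFAULT_LIMITS,
    FactorLimits,
    Participant,
    PriorEventHistory,
    RiskFactorVector,
)
from .engine import simulate_cohort
from .equations import CoefficientSet, EquationSpec, linear_predictor
from .errors import ConfigError
from .metrics import ObservedOutcome

#: marginal distributions: name -> ("normal"|"lognormal", param1, param2)
Marginal = tuple[str, float, float]


@dataclass
class CohortProfile:
    """Shape of a synthetic trial cohort."""

    name: str
    n_active: int
    n_placebo: int
    #: continuous factor marginals
    factors: Mapping[str, Marginal]
    #: boolean factor prevalences
    boolean_prevalence: Mapping[str, float] = field(default_factory=dict)
    #: per-factor missingness rates in [0, 1]
    missingness: Mapping[str, float] = field(default_factory=dict)
    #: factors whose missingness depends on their own value (logistic link)
    mnar_factors: tuple[str, ...] = ()
    mnar_slope: float = -0.7
    #: fraction with prior atherosclerotic CV disease (IHD/MI/stroke)
    ascvd_prevalence: float = 0.0
    #: P(specific event | ASCVD); at least one is forced
    ascvd_mix: Mapping[str, float] = field(
        default_factory=lambda: {"ihd": 0.65, "mi": 0.45, "stroke": 0.20}
    )
    #: independent prevalences for the remaining prior-event categories
    other_prior_prevalence: Mapping[str, float] = field(default_factory=dict)
    age: Marginal = ("normal", 65.0, 8.0)
    diabetes_duration: Marginal = ("lognormal", math.log(10.0), 0.6)
    height: Marginal = ("normal", 170.0, 10.0)
    male_fraction: float = 0.62
    #: follow-up (censoring) drawn uniformly over the trial's IQR
    followup_iqr: tuple[float, float] = (2.3, 3.8)
    median_followup: float = 3.0
    #: Gaussian-copula correlation between continuous factors (pairs)
    correlations: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("weight", "sbp"): 0.2,
            ("weight", "hba1c"): 0.15,
            ("hdl", "ldl"): -0.15,
            ("hdl", "weight"): -0.2,
            ("sbp", "egfr"): -0.1,
        }
    )

    def __post_init__(self):
        if self.n_active <= 0 or self.n_placebo <= 0:
            raise ConfigError("arm sizes must be positive")
        for f, r in self.missingness.items():
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"missingness rate for {f!r} outside [0,1]")
        if not 0.0 <= self.ascvd_prevalence <= 1.0:
            raise ConfigError("ascvd_prevalence outside [0,1]")
        for f in self.factors:
            if f not in CONTINUOUS_FACTORS:
                raise ConfigError(f"unknown continuous factor {f!r}")


def tecos_profile(n_active: int = 7332, n_placebo: int = 7339) -> CohortProfile:
    """A sitagliptin-CV-safety-trial-like cohort: all participants have ASCVD,
    median follow-up 3.0 years (IQR 2.3-3.8)."""
    return CohortProfile(
        name="tecos",
        n_active=n_active,
        n_placebo=n_placebo,
        factors=_DEFAULT_MARGINALS,
        boolean_prevalence={"smoking": 0.12, "af": 0.05, "pad": 0.10, "albuminuria": 0.15},
        missingness={
            "hba1c": 0.02,
            "sbp": 0.01,
            "weight": 0.01,
            "heart_rate": 0.03,
            "egfr": 0.04,
            "hdl": 0.198,
            "ldl": 0.256,
            "haemoglobin": 0.397,
        },
        mnar_factors=("hdl", "ldl", "haemoglobin"),
        ascvd_prevalence=1.0,
        other_prior_prevalence={
            "heart_failure": 0.18,
            "amputation": 0.01,
            "blindness": 0.01,
            "kidney_failure": 0.02,
            "ulcer": 0.02,
        },
        age=("normal", 65.5, 8.0),
        diabetes_duration=("lognormal", math.log(10.0), 0.6),
        male_fraction=0.71,
        followup_iqr=(2.3, 3.8),
        median_followup=3.0,
    )


def exscel_profile(n_active: int = 7356, n_placebo: int = 7396) -> CohortProfile:
    """An exenatide-CV-outcome-trial-like cohort: 73.1% with prior ASCVD,
    median follow-up 3.2 years (IQR 2.2-4.4)."""
    p = tecos_profile(n_active, n_placebo)
    return CohortProfile(
        name="exscel",
        n_active=n_active,
        n_placebo=n_placebo,
        factors=p.factors,
        boolean_prevalence=p.boolean_prevalence,
        missingness=p.missingness,
        mnar_factors=p.mnar_factors,
        ascvd_prevalence=0.731,
        other_prior_prevalence={
            "heart_failure": 0.16,
            "amputation": 0.01,
            "blindness": 0.01,
            "kidney_failure": 0.02,
            "ulcer": 0.02,
        },
        age=("normal", 62.0, 8.5),
        diabetes_duration=("lognormal", math.log(11.0), 0.6),
        male_fraction=0.62,
        followup_iqr=(2.2, 4.4),
        median_followup=3.2,
    )


_DEFAULT_MARGINALS: dict[str, Marginal] = {
    "weight": ("normal", 86.0, 17.0),
    "hdl": ("lognormal", math.log(1.1), 0.22),
    "ldl": ("lognormal", math.log(2.3), 0.35),
    "sbp": ("normal", 135.0, 16.0),
    "hba1c": ("lognormal", math.log(7.3), 0.11),
    "heart_rate": ("normal", 72.0, 11.0),
    "wbc": ("normal", 7.5, 1.9),
    "haemoglobin": ("normal", 13.8, 1.6),
    "egfr": ("normal", 76.0, 20.0),
}

PROFILES = {"tecos": tecos_profile, "exscel": exscel_profile}


def load_profile(source) -> CohortProfile:
    """Resolve a built-in profile name or a JSON profile file."""
    if isinstance(source, CohortProfile):
        return source
    if str(source) in PROFILES:
        return PROFILES[str(source)]()
    with open(source) as fh:
        payload = json.load(fh)
    payload["factors"] = {k: tuple(v) for k, v in payload.get("factors", {}).items()}
    payload["mnar_factors"] = tuple(payload.get("mnar_factors", ()))
    payload["followup_iqr"] = tuple(payload.get("followup_iqr", (2.3, 3.8)))
    for key in ("age", "diabetes_duration", "height"):
        if key in payload:
            payload[key] = tuple(payload[key])
    if "correlations" in payload:
        payload["correlations"] = {tuple(k.split("~")): v for k, v in payload["correlations"].items()}
    return CohortProfile(**payload)


def _marginal_ppf(spec: Marginal, u: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    family, a, b = spec
    z = norm.ppf(u)
    if family == "normal":
        return a + b * z
    if family == "lognormal":
        return np.exp(a + b * z)
    raise ConfigError(f"unknown marginal family {family!r}")


def _copula_correlation(profile: CohortProfile, names: Sequence[str]) -> np.ndarray:
    k = len(names)
    corr = np.eye(k)
    idx = {n: i for i, n in enumerate(names)}
    for (a, b), rho in profile.correlations.items():
        if a in idx and b in idx:
            corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho
    # guard against an indefinite user-supplied matrix
    eigmin = np.linalg.eigvalsh(corr).min()
    if eigmin <= 1e-8:
        corr += np.eye(k) * (1e-8 - eigmin)
        corr /= np.sqrt(np.outer(np.diag(corr), np.diag(corr)))
    return corr


def _mnar_mask(values: np.ndarray, rate: float, slope: float, rng) -> np.ndarray:
    """Missingness mask whose probability follows a logistic link on the
    standardized value, with the intercept solved so the marginal rate is
    ``rate``."""
    if rate <= 0:
        return np.zeros(values.size, dtype=bool)
    if rate >= 1:
        return np.ones(values.size, dtype=bool)
    sd = values.std()
    z = (values - values.mean()) / (sd if sd > 0 else 1.0)

    def gap(a):
        return expit(a + slope * z).mean() - rate

    a = brentq(gap, -30.0, 30.0)
    return rng.random(values.size) < expit(a + slope * z)


def generate_cohort(profile: CohortProfile | str, seed: int = 0) -> list[Participant]:
    """Draw a synthetic baseline cohort from ``profile``.

    Missingness masks are applied at the configured per-factor rates; factors
    listed in ``mnar_factors`` use the missing-not-at-random logistic link.
    Deterministic given ``seed``.
    """
    profile = load_profile(profile)
    rng = np.random.default_rng([seed, 0x5EED])
    from scipy.stats import norm

    n = profile.n_active + profile.n_placebo
    names = list(profile.factors)
    corr = _copula_correlation(profile, names)
    z = rng.multivariate_normal(np.zeros(len(names)), corr, size=n, method="cholesky")
    u = norm.cdf(z)
    values = {f: _marginal_ppf(profile.factors[f], u[:, i]) for i, f in enumerate(names)}

    age = np.clip(_marginal_ppf(profile.age, rng.random(n)), 30.0, 95.0)
    duration = np.clip(_marginal_ppf(profile.diabetes_duration, rng.random(n)), 0.5, 50.0)
    height = _marginal_ppf(profile.height, rng.random(n))
    male = rng.random(n) < profile.male_fraction
    followup = rng.uniform(*profile.followup_iqr, size=n)

    booleans = {
        f: rng.random(n) < profile.boolean_prevalence.get(f, 0.0) for f in BOOLEAN_FACTORS
    }
    missing = {}
    for f in names:
        rate = profile.missingness.get(f, 0.0)
        if f in profile.mnar_factors:
            missing[f] = _mnar_mask(values[f], rate, profile.mnar_slope, rng)
        else:
            missing[f] = rng.random(n) < rate

    ascvd = rng.random(n) < profile.ascvd_prevalence
    mix_draws = {e: rng.random(n) < q for e, q in profile.ascvd_mix.items()}
    other = {e: rng.random(n) < q for e, q in profile.other_prior_prevalence.items()}

    width = len(str(n))
    cohort = []
    for i in range(n):
        flags = []
        if ascvd[i]:
            flags = [e for e, d in mix_draws.items() if d[i]]
            if not flags:
                flags = ["ihd"]
        flags += [e for e, d in other.items() if d[i]]
        kwargs = {}
        for f in names:
            kwargs[f] = None if missing[f][i] else float(values[f][i])
        for f in BOOLEAN_FACTORS:
            kwargs[f] = bool(booleans[f][i])
        cohort.append(
            Participant(
                id=f"{profile.name}-{i + 1:0{width}d}",
                arm="active" if i < profile.n_active else "placebo",
                age=float(age[i]),
                sex="male" if male[i] else "female",
                diabetes_duration=float(duration[i]),
                height=float(height[i]),
                baseline=RiskFactorVector(**kwargs),
                prior=PriorEventHistory.from_flags(flags),
                followup_years=float(followup[i]),
            )
        )
    return cohort


@dataclass
class GroundTruth:
    """True hazard specification used to generate observed outcomes."""

    coefficients: CoefficientSet
    #: multiplicative arm effect (hazard ratio, active vs placebo) per endpoint;
    #: a plain float applies to all endpoints
    hazard_ratio: Mapping[str, float] | float = 1.0

    def hr_for(self, endpoint: str) -> float:
        if isinstance(self.hazard_ratio, Mapping):
            return float(self.hazard_ratio.get(endpoint, 1.0))
        return float(self.hazard_ratio)


def _inverse_cdf_time(eq: EquationSpec, lp: float, t0: float, e: float) -> float:
    """Solve the cumulative hazard H(t) = e for the event time (years from
    baseline) on the diabetes-duration timescale."""
    scale = math.exp(lp)
    if eq.baseline_form == "exponential":
        return e / scale
    g = eq.shape
    if eq.baseline_form == "weibull":
        return (e / scale + t0**g) ** (1.0 / g) - t0
    if eq.baseline_form == "gompertz":
        inner = g * e / scale + math.exp(g * t0)
        return (math.log(inner)) / g - t0
    raise ConfigError(f"unsupported hazard family {eq.baseline_form!r} for outcome generation")


def generate_outcomes(
    cohort: Sequence[Participant],
    truth: GroundTruth,
    horizon: float,
    seed: int = 0,
    endpoints: Sequence[str] | None = None,
    use_followup_censoring: bool = True,
) -> list[ObservedOutcome]:
    """Draw censored event times from parametric true hazards, per endpoint.

    Each endpoint is drawn independently by inverse-CDF from its equation's
    hazard evaluated at the participant's baseline state; the arm hazard
    ratio multiplies the active arm's hazard.  Censoring is at
    ``min(followup_years, horizon)`` (or ``horizon`` when the cohort carries
    no follow-up draw or ``use_followup_censoring`` is off).
    """
    hazards = {eq.name: eq for eq in truth.coefficients.hazard_equations}
    endpoints = list(endpoints) if endpoints else list(hazards)
    missing = [ep for ep in endpoints if ep not in hazards]
    if missing:
        raise ConfigError(f"ground truth does not cover endpoints: {missing}")
    rng = np.random.default_rng([seed, 0x0B5])
    out: list[ObservedOutcome] = []
    for p in cohort:
        state = {
            "age": p.age,
            "diabetes_duration": p.diabetes_duration,
            "male": 1.0 if p.sex == "male" else 0.0,
            "height": p.height,
        }
        for f, v in p.baseline.as_dict().items():
            state[f] = float(v) if v is not None else float("nan")
        for e in ("ihd", "heart_failure", "amputation", "blindness", "kidney_failure", "mi", "stroke", "ulcer"):
            state[f"hist_{e}"] = 1.0 if p.prior.has(e) else 0.0
        censor = horizon
        if use_followup_censoring and p.followup_years is not None:
            censor = min(censor, p.followup_years)
        for ep in endpoints:
            eq = hazards[ep]
            lp = linear_predictor(eq, state)
            if math.isnan(lp):
                raise ConfigError(
                    f"participant {p.id!r}: baseline incomplete for outcome generation"
                )
            if p.arm == "active":
                lp += math.log(truth.hr_for(ep))
            t = _inverse_cdf_time(eq, lp, p.diabetes_duration, rng.exponential())
            out.append(
                ObservedOutcome(
                    id=p.id,
                    arm=p.arm,
                    endpoint=ep,
                    event=bool(t <= censor),
                    time=float(min(t, censor)),
                )
            )
    return out


def generate_outcomes_from_engine(
    cohort: Sequence[Participant],
    eqs: CoefficientSet,
    horizon: float,
    seed: int = 0,
    endpoints: Sequence[str] | None = None,
    use_followup_censoring: bool = False,
) -> list[ObservedOutcome]:
    """Generate observed outcomes by running the simulation engine itself at
    one replication — the generating model *is* the simulation model.

    Used for end-to-end self-validation: a correctly implemented pipeline
    should then show relative risk ~ 1, calibration slope ~ 1 and intercept
    ~ 0 up to Monte-Carlo error.
    """
    sim = simulate_cohort(cohort, eqs, horizon, replications=1, seed=seed)
    endpoints = list(endpoints) if endpoints else sim.endpoints
    out: list[ObservedOutcome] = []
    ids = sim.participants["id"].to_numpy()
    arms = sim.participants["arm"].to_numpy()
    for ep in endpoints:
        times = sim.event_times(ep)[:, 0]
        eligible = sim.eligible_mask(ep)
        for i in range(len(ids)):
            if not eligible[i]:
                continue
            censor = horizon
            if use_followup_censoring and cohort[i].followup_years is not None:
                censor = min(censor, cohort[i].followup_years)
            t = times[i]
            event = bool(not np.isnan(t) and t <= censor + 1e-9)
            out.append(
                ObservedOutcome(
                    id=str(ids[i]),
                    arm=str(arms[i]),
                    endpoint=ep,
                    event=event,
                    time=float(min(t, censor) if event else censor),
                )
            )
    return out


def generate_followup_trajectories(
    cohort: Sequence[Participant],
    progression: CoefficientSet,
    noise_sd: Mapping[str, float] | float = 0.0,
    seed: int = 0,
    years: int = 3,
    gap_rate: float = 0.0,
    limits: FactorLimits = DEFAULT_LIMITS,
) -> list[Participant]:
    """Attach annual follow-up records: progression recurrence + Gaussian
    noise, clamped to the model limits, with optional observation gaps
    (cells blanked at ``gap_rate``) to exercise the follow-up fill-in."""
    from .equations import progress_risk_factor

    rng = np.random.default_rng([seed, 0xF011])
    if not isinstance(noise_sd, Mapping):
        noise_sd = {f: float(noise_sd) for f in CONTINUOUS_FACTORS}
    out = [p.copy() for p in cohort]
    for p in out:
        current = p.baseline.as_dict()
        if any(v is None for v in current.values()):
            raise ConfigError(f"participant {p.id!r}: baseline incomplete")
        for year in range(1, years + 1):
            state = dict(current)
            state["age"] = p.age + (year - 1)
            state["diabetes_duration"] = p.diabetes_duration + (year - 1)
            state["male"] = 1.0 if p.sex == "male" else 0.0
            state["height"] = p.height
            new = {}
            for f in CONTINUOUS_FACTORS:
                eq = progression.progression_for(f)
                if eq is None:
                    raise ConfigError(f"no progression equation for factor {f!r}")
                st = dict(state)
                st["current"] = current[f]
                val = progress_risk_factor(eq, st) + rng.normal(0.0, noise_sd.get(f, 0.0))
                new[f] = limits.clamp(f, val)
            for f in BOOLEAN_FACTORS:
                new[f] = current[f]
            record = dict(new)
            if gap_rate > 0:
                for f in CONTINUOUS_FACTORS:
                    if rng.random() < gap_rate:
                        record[f] = None
            p.followup[year] = RiskFactorVector(**record)
            current = new
    return out
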