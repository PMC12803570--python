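"""External-validation metrics for simulated vs observed trial outcomes.

Implements the validation battery used to assess an outcomes model against a
cardiovascular outcome trial: accuracy (observed vs simulated counts and the
between-arm relative risk against the trial hazard ratio), calibration
(risk-decile table plus logistic recalibration intercept and slope), the
Brier score, and Harrell's C for discrimination under censoring.

Conventions
-----------
* Relative risk = ratio of cumulative event proportions, active arm over
  placebo, rounded half-up (as in published trial tables).
* Calibration slope is the coefficient of logit(predicted risk) in a logistic
  regression of the outcome; the intercept is refitted with the slope fixed
  at 1 (offset method).  Slope 1 / intercept 0 = perfect calibration;
  a negative intercept indicates overestimation.
* Brier score and calibration are computed at the fixed horizon on
  participants who either had the event by the horizon or were followed to
  it; participants censored earlier are excluded.
* Harrell's C uses censoring-comparable pairs; risk ties count 1/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.utils import concordance_index

from .engine import RESTRICTED_ENDPOINTS, SimulatedOutcomes, first_event_summary
from .errors import ConfigError

_TIME_EPS = 1e-9


@dataclass(frozen=True)
class ObservedOutcome:
    """One participant's observed status for one endpoint."""

    id: str
    arm: str
    endpoint: str
    event: bool
    time: float  # years to event or censoring

    def __post_init__(self):
        if self.time < 0:
            raise ConfigError(f"participant {self.id!r}: negative follow-up time")


def observed_frame(observed: Iterable[ObservedOutcome] | pd.DataFrame) -> pd.DataFrame:
    """Normalize observed outcomes to a DataFrame (id, arm, endpoint, event, time)."""
    if isinstance(observed, pd.DataFrame):
        df = observed.copy()
    else:
        df = pd.DataFrame(
            [
                {"id": o.id, "arm": o.arm, "endpoint": o.endpoint, "event": o.event, "time": o.time}
                for o in observed
            ]
        )
    required = {"id", "arm", "endpoint", "event", "time"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"observed outcomes missing columns {sorted(missing)}")
    if (df["time"] < 0).any():
        raise ConfigError("observed outcomes contain negative times")
    df["event"] = df["event"].astype(bool)
    df["id"] = df["id"].astype(str)
    return df


# ---------------------------------------------------------------------------
# Elementary metrics
# ---------------------------------------------------------------------------


def round_half_up(value: float, digits: int) -> float:
    """Decimal round-half-up (the rounding used in trial report tables)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def proportion_pct(events: float, n: int, digits: int = 1) -> float:
    """Percentage ``events / n``, rounded half-up to ``digits`` decimals."""
    if n <= 0:
        raise ConfigError("denominator must be positive")
    return round_half_up(100.0 * events / n, digits)


def relative_risk(
    events_a: float, n_a: int, events_b: float, n_b: int, digits: int = 2
) -> float | None:
    """Cumulative-incidence ratio, active (a) over placebo (b), half-up rounded.

    Returns ``None`` when the placebo arm has no events (undefined ratio).
    """
    if n_a <= 0 or n_b <= 0:
        raise ConfigError("arm sizes must be positive")
    if events_a > n_a or events_b > n_b:
        raise ConfigError("event counts cannot exceed arm sizes")
    if events_b == 0:
        return None
    rr = (events_a / n_a) / (events_b / n_b)
    return round_half_up(rr, digits)


def brier(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Mean squared difference between predicted risk and binary outcome.

    0 = perfect accuracy, 1 = perfect inaccuracy; < 0.25 is conventionally
    considered informative.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size == 0:
        raise ConfigError("pred and obs must be nonempty and aligned")
    return float(np.mean((pred - obs) ** 2))


def harrell_c(risk: Sequence[float], times: Sequence[float], events: Sequence[bool]) -> float:
    """Harrell's concordance for a risk score under right censoring.

    Probability that, of a censoring-comparable pair, the participant with the
    event is assigned the higher risk; ties in risk count 1/2.  Returns NaN
    (with a warning) when no comparable pair exists.
    """
    risk = np.asarray(risk, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if not (risk.shape == times.shape == events.shape):
        raise ConfigError("risk, times and events must be aligned")
    if not events.any():
        warnings.warn("no events: concordance undefined", stacklevel=2)
        return float("nan")
    try:
        # lifelines scores concordance of predicted survival; negate the risk
        return float(concordance_index(times, -risk, events))
    except ZeroDivisionError:
        warnings.warn("no comparable pairs: concordance undefined", stacklevel=2)
        return float("nan")


def cumulative_incidence(observed: Iterable[ObservedOutcome] | pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier cumulative incidence (1 - S) as a right-continuous step table."""
    df = observed if isinstance(observed, pd.DataFrame) else observed_frame(observed)
    if df.empty:
        raise ConfigError("no observations")
    if (df["time"] < 0).any():
        raise ConfigError("negative times")
    km = KaplanMeierFitter()
    km.fit(df["time"], event_observed=df["event"])
    sf = km.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(dtype=float), "cuminc": 1.0 - sf.iloc[:, 0].to_numpy()}
    ).reset_index(drop=True)


@dataclass
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    log_hr: float
    se: float
    flags: list = field(default_factory=list)


def cox_hr(observed: Iterable[ObservedOutcome] | pd.DataFrame) -> CoxResult:
    """Unadjusted proportional-hazards arm effect (active vs placebo).

    Partial likelihood with Efron tie handling; Wald 95% CI.  Convergence
    failure (e.g. separation) is flagged rather than raised.
    """
    df = observed if isinstance(observed, pd.DataFrame) else observed_frame(observed)
    arms = set(df["arm"])
    if arms != {"active", "placebo"}:
        raise ConfigError(f"both arms required for a hazard ratio, got {sorted(arms)}")
    if not df["event"].any():
        raise ConfigError("no events: hazard ratio undefined")
    fit_df = pd.DataFrame(
        {
            "T": np.maximum(df["time"].to_numpy(dtype=float), _TIME_EPS),
            "E": df["event"].to_numpy(dtype=bool),
            "active": (df["arm"] == "active").astype(float).to_numpy(),
        }
    )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(fit_df, duration_col="T", event_col="E")
    except ConvergenceError:
        return CoxResult(float("nan"), float("nan"), float("nan"), float("nan"), float("nan"), ["separation"])
    beta = float(cph.params_["active"])
    se = float(cph.standard_errors_["active"])
    return CoxResult(
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959964 * se)),
        ci_high=float(np.exp(beta + 1.959964 * se)),
        log_hr=beta,
        se=se,
    )


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


@dataclass
class CalibrationResult:
    """Decile calibration table plus logistic recalibration parameters."""

    table: pd.DataFrame  # columns: bin, mean_pred, observed, n
    intercept: float
    intercept_se: float
    slope: float
    slope_se: float
    flags: list = field(default_factory=list)


_CLIP = 1e-6


def calibration(
    pred: Sequence[float], obs: Sequence[float], bins: int = 10
) -> CalibrationResult:
    """Calibration-in-the-large and calibration slope.

    ``slope`` is the coefficient of logit(pred) in a logistic regression of
    the binary outcome; ``intercept`` is refitted with logit(pred) as a fixed
    offset.  The decile table reports mean predicted risk and observed
    proportion per risk decile.
    """
    import statsmodels.api as sm

    pred = np.clip(np.asarray(pred, dtype=float), _CLIP, 1.0 - _CLIP)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size == 0:
        raise ConfigError("pred and obs must be nonempty and aligned")

    order = np.argsort(pred, kind="stable")
    bin_id = np.empty(pred.size, dtype=int)
    bin_id[order] = np.minimum((np.arange(pred.size) * bins) // pred.size, bins - 1)
    table = (
        pd.DataFrame({"bin": bin_id, "pred": pred, "obs": obs})
        .groupby("bin")
        .agg(mean_pred=("pred", "mean"), observed=("obs", "mean"), n=("obs", "size"))
        .reset_index()
    )

    logit_pred = np.log(pred / (1.0 - pred))
    flags: list[str] = []
    if np.ptp(logit_pred) < 1e-12:
        flags.append("slope_undefined")
        slope = slope_se = float("nan")
    else:
        x = sm.add_constant(logit_pred)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(obs, x, family=sm.families.Binomial()).fit()
        slope, slope_se = float(fit.params[1]), float(fit.bse[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        off = sm.GLM(
            obs, np.ones((obs.size, 1)), family=sm.families.Binomial(), offset=logit_pred
        ).fit()
    return CalibrationResult(
        table=table,
        intercept=float(off.params[0]),
        intercept_se=float(off.bse[0]),
        slope=slope,
        slope_se=slope_se,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Full validation report
# ---------------------------------------------------------------------------


@dataclass
class EndpointReport:
    endpoint: str
    n_active: int
    n_placebo: int
    observed_active: int
    observed_placebo: int
    simulated_active: float
    simulated_placebo: float
    hr: CoxResult | None
    rr: float | None
    brier: float
    c_statistic: float
    calibration: CalibrationResult | None
    restricted: bool
    flags: list = field(default_factory=list)

    @property
    def observed_pct_active(self) -> float:
        return proportion_pct(self.observed_active, self.n_active) if self.n_active else float("nan")

    @property
    def observed_pct_placebo(self) -> float:
        return proportion_pct(self.observed_placebo, self.n_placebo) if self.n_placebo else float("nan")

    @property
    def simulated_pct_active(self) -> float:
        return proportion_pct(self.simulated_active, self.n_active) if self.n_active else float("nan")

    @property
    def simulated_pct_placebo(self) -> float:
        return proportion_pct(self.simulated_placebo, self.n_placebo) if self.n_placebo else float("nan")


@dataclass
class ValidationReport:
    endpoints: dict[str, EndpointReport]
    subgroups: dict[str, dict[str, EndpointReport]] = field(default_factory=dict)
    horizon: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for scope, reports in [("overall", self.endpoints)] + [
            (name, eps) for name, eps in self.subgroups.items()
        ]:
            for ep, r in reports.items():
                hr = r.hr
                rows.append(
                    {
                        "scope": scope,
                        "endpoint": ep,
                        "n_active": r.n_active,
                        "n_placebo": r.n_placebo,
                        "observed_active": r.observed_active,
                        "observed_placebo": r.observed_placebo,
                        "simulated_active": r.simulated_active,
                        "simulated_placebo": r.simulated_placebo,
                        "observed_pct_active": r.observed_pct_active,
                        "observed_pct_placebo": r.observed_pct_placebo,
                        "simulated_pct_active": r.simulated_pct_active,
                        "simulated_pct_placebo": r.simulated_pct_placebo,
                        "hr": None if hr is None else hr.hr,
                        "hr_ci_low": None if hr is None else hr.ci_low,
                        "hr_ci_high": None if hr is None else hr.ci_high,
                        "rr": r.rr,
                        "brier": r.brier,
                        "c_statistic": r.c_statistic,
                        "calibration_intercept": None
                        if r.calibration is None
                        else r.calibration.intercept,
                        "calibration_slope": None
                        if r.calibration is None
                        else r.calibration.slope,
                        "restricted": r.restricted,
                        "flags": ";".join(r.flags),
                    }
                )
        return pd.DataFrame(rows)


DEFAULT_SUBGROUPS = ("age_lt65", "age_ge65", "male", "female", "prior_cv", "no_prior_cv")


def _subgroup_masks(participants: pd.DataFrame, names: Sequence[str]) -> dict[str, np.ndarray]:
    defs = {
        "age_lt65": participants["age"].to_numpy() < 65,
        "age_ge65": participants["age"].to_numpy() >= 65,
        "male": (participants["sex"] == "male").to_numpy(),
        "female": (participants["sex"] == "female").to_numpy(),
        "prior_cv": participants["prior_cv"].to_numpy(dtype=bool),
        "no_prior_cv": ~participants["prior_cv"].to_numpy(dtype=bool),
    }
    unknown = [n for n in names if n not in defs]
    if unknown:
        raise ConfigError(f"unknown subgroup definitions: {unknown}")
    return {n: defs[n] for n in names}


def _endpoint_report(
    ep: str,
    obs_ep: pd.DataFrame,
    simulated: SimulatedOutcomes,
    mask: np.ndarray,
    horizon: float,
    min_events_for_hr: int = 1,
) -> EndpointReport:
    parts = simulated.participants
    eligible = simulated.eligible_mask(ep) & mask
    ids = parts.loc[eligible, "id"]
    obs_ep = obs_ep[obs_ep["id"].isin(set(ids))]
    flags: list[str] = []

    ind = simulated.event_indicator(ep)
    arm_active = (parts["arm"] == "active").to_numpy()
    n_a = int((eligible & arm_active).sum())
    n_p = int((eligible & ~arm_active).sum())
    sim_a = float(ind[eligible & arm_active].sum(axis=0).mean()) if n_a else 0.0
    sim_p = float(ind[eligible & ~arm_active].sum(axis=0).mean()) if n_p else 0.0

    ev_by_h = obs_ep["event"] & (obs_ep["time"] <= horizon + _TIME_EPS)
    obs_a = int((ev_by_h & (obs_ep["arm"] == "active")).sum())
    obs_p = int((ev_by_h & (obs_ep["arm"] == "placebo")).sum())

    hr = None
    if obs_ep["event"].sum() >= min_events_for_hr and {"active", "placebo"} <= set(obs_ep["arm"]):
        hr = cox_hr(obs_ep)
    else:
        flags.append("hr_undefined")
    rr = relative_risk(sim_a, n_a, sim_p, n_p) if n_a and n_p else None
    if rr is None:
        flags.append("rr_undefined")

    # per-participant predicted risk = replication event frequency
    pred_all = pd.Series(simulated.predicted_risk(ep), index=parts["id"].to_numpy())
    merged = obs_ep.merge(
        pred_all.rename("pred"), left_on="id", right_index=True, how="left"
    )
    if merged["pred"].isna().any():
        raise ConfigError(
            "observed outcomes reference ids missing from the simulation: "
            f"{sorted(merged.loc[merged['pred'].isna(), 'id'])[:5]} ..."
        )
    # fixed-horizon subset for Brier/calibration
    at_h = merged[(merged["event"] & (merged["time"] <= horizon + _TIME_EPS)) | (merged["time"] >= horizon - _TIME_EPS)]
    y = (at_h["event"] & (at_h["time"] <= horizon + _TIME_EPS)).to_numpy(dtype=float)
    b = brier(at_h["pred"].to_numpy(), y) if len(at_h) else float("nan")
    cal = None
    if len(at_h) >= 20 and 0 < y.sum() < len(at_h):
        cal = calibration(at_h["pred"].to_numpy(), y)
    else:
        flags.append("calibration_undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        c = harrell_c(merged["pred"], merged["time"], merged["event"]) if len(merged) else float("nan")

    return EndpointReport(
        endpoint=ep,
        n_active=n_a,
        n_placebo=n_p,
        observed_active=obs_a,
        observed_placebo=obs_p,
        simulated_active=sim_a,
        simulated_placebo=sim_p,
        hr=hr,
        rr=rr,
        brier=b,
        c_statistic=c,
        calibration=cal,
        restricted=ep in RESTRICTED_ENDPOINTS,
        flags=flags,
    )


def build_validation_report(
    observed: Iterable[ObservedOutcome] | pd.DataFrame,
    simulated: SimulatedOutcomes,
    endpoints: Sequence[str] | None = None,
    subgroups: Sequence[str] | None = DEFAULT_SUBGROUPS,
) -> ValidationReport:
    """Assemble the full observed-vs-simulated validation report.

    ``observed`` must cover the same participant ids as the simulation; any
    mismatch is an error.  Subgroup reports repeat the per-endpoint battery
    within age (<65 / >=65), sex and prior-CV-event strata.
    """
    obs = observed_frame(observed)
    parts = simulated.participants
    sim_ids = set(parts["id"])
    stray = set(obs["id"]) - sim_ids
    if stray:
        raise ConfigError(f"observed ids absent from simulation: {sorted(stray)[:5]} ...")

    endpoints = list(endpoints) if endpoints else [
        ep for ep in simulated.endpoints if ep in set(obs["endpoint"])
    ]
    horizon = simulated.horizon
    all_mask = np.ones(len(parts), dtype=bool)
    overall = {}
    for ep in endpoints:
        if ep not in simulated.event_cycles:
            raise ConfigError(f"endpoint {ep!r} was not simulated")
        overall[ep] = _endpoint_report(ep, obs[obs["endpoint"] == ep], simulated, all_mask, horizon)

    sub_reports: dict[str, dict[str, EndpointReport]] = {}
    for name, mask in _subgroup_masks(parts, subgroups or ()).items():
        sub_reports[name] = {
            ep: _endpoint_report(ep, obs[obs["endpoint"] == ep], simulated, mask, horizon)
            for ep in endpoints
        }
    return ValidationReport(endpoints=overall, subgroups=sub_reports, horizon=horizon)


__all__ = [
    "ObservedOutcome",
    "observed_frame",
    "round_half_up",
    "proportion_pct",
    "relative_risk",
    "brier",
    "harrell_c",
    "cumulative_incidence",
    "CoxResult",
    "cox_hr",
    "CalibrationResult",
    "calibration",
    "EndpointReport",
    "ValidationReport",
    "build_validation_report",
    "first_event_summary",
]
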