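"""Parametric annual event/death equations and risk-factor progression.

The simulation engine is coefficient-driven: each endpoint has an
:class:`EquationSpec` with a proportional-hazards baseline (exponential,
Weibull or Gompertz, integrated over the annual cycle on the
diabetes-duration timescale) or a logistic form, and each annualized risk
factor has a linear autoregressive progression equation.  The published
coefficient values of the real model are supplied by the user as JSON; the
package ships a clearly labelled illustrative (synthetic) set for testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .cohort import BOOLEAN_FACTORS, CONTINUOUS_FACTORS, PRIOR_EVENTS
from .errors import ConfigError, EvaluationError

BASELINE_FORMS = ("exponential", "weibull", "gompertz", "logistic")
KINDS = ("event", "death", "progression")

DEMOGRAPHIC_COVARIATES = ("age", "male", "diabetes_duration", "height")
HISTORY_COVARIATES = tuple(f"hist_{e}" for e in PRIOR_EVENTS)
#: names resolvable in an event/death equation
EVENT_COVARIATES = frozenset(
    CONTINUOUS_FACTORS + BOOLEAN_FACTORS + DEMOGRAPHIC_COVARIATES + HISTORY_COVARIATES
)
#: progression equations may additionally reference the factor's current value
PROGRESSION_COVARIATES = EVENT_COVARIATES | {"current"}


@dataclass(frozen=True)
class EquationSpec:
    """One parametric annual equation with named coefficients.

    For ``kind`` in {event, death} the linear predictor scales a baseline
    hazard (``baseline_form``); ``shape`` is the Weibull/Gompertz shape
    parameter.  ``requires_no_history`` lists history flags that make the
    equation inapplicable (first-event-only endpoints).  ``case_fatality`` is
    the probability that a fired event is fatal (MI/stroke).
    """

    name: str
    kind: str
    coefficients: Mapping[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    baseline_form: str = "exponential"
    shape: float | None = None
    requires_no_history: tuple[str, ...] = ()
    case_fatality: float | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ConfigError(f"equation {self.name!r}: unknown kind {self.kind!r}")
        if self.kind != "progression":
            if self.baseline_form not in BASELINE_FORMS:
                raise ConfigError(
                    f"equation {self.name!r}: unknown baseline_form {self.baseline_form!r}"
                )
            if self.baseline_form in ("weibull", "gompertz"):
                if self.shape is None or not self.shape > 0:
                    raise ConfigError(
                        f"equation {self.name!r}: {self.baseline_form} requires shape > 0"
                    )
        vocabulary = (
            PROGRESSION_COVARIATES if self.kind == "progression" else EVENT_COVARIATES
        )
        for cov in self.coefficients:
            if cov not in vocabulary:
                raise ConfigError(
                    f"equation {self.name!r}: unresolvable covariate {cov!r}"
                )
        for flag in self.requires_no_history:
            if flag not in PRIOR_EVENTS:
                raise ConfigError(
                    f"equation {self.name!r}: unknown history flag {flag!r}"
                )
        if self.case_fatality is not None and not 0.0 <= self.case_fatality <= 1.0:
            raise ConfigError(f"equation {self.name!r}: case_fatality outside [0,1]")


def linear_predictor(eq: EquationSpec, state: Mapping[str, float]) -> float:
    """``intercept + sum(coefficient * covariate)`` over the equation's terms."""
    total = eq.intercept
    for cov, coef in eq.coefficients.items():
        try:
            total += coef * float(state[cov])
        except KeyError:
            raise EvaluationError(
                f"equation {eq.name!r}: covariate {cov!r} missing from state"
            ) from None
    return total


def _integrated_hazard(eq: EquationSpec, lp, t0, cycle_length):
    """Cumulative hazard over [t0, t0 + cycle_length] on the duration timescale."""
    if eq.baseline_form == "exponential":
        return np.exp(lp) * cycle_length
    t1 = t0 + cycle_length
    g = eq.shape
    if eq.baseline_form == "weibull":
        return np.exp(lp) * (np.power(t1, g) - np.power(t0, g))
    if eq.baseline_form == "gompertz":
        return np.exp(lp) * (np.exp(g * t1) - np.exp(g * t0)) / g
    raise ConfigError(f"equation {eq.name!r}: not a hazard form")


def annual_event_probability(
    eq: EquationSpec, state: Mapping[str, float], cycle_length: float = 1.0
) -> float:
    """Probability the event fires during one cycle of length ``cycle_length``.

    Hazard forms use ``p = 1 - exp(-H)`` with the baseline cumulative hazard
    integrated exactly over the cycle and scaled by ``exp(linear predictor)``;
    the logistic form scales its annual probability by
    ``1 - (1 - p)**cycle_length``.
    """
    if eq.kind not in ("event", "death"):
        raise ConfigError(f"equation {eq.name!r}: kind {eq.kind!r} has no event probability")
    if not 0.0 < cycle_length <= 1.0:
        raise ConfigError(f"cycle_length must be in (0, 1], got {cycle_length}")
    lp = linear_predictor(eq, state)
    if eq.baseline_form == "logistic":
        p1 = 1.0 / (1.0 + np.exp(-lp))
        return float(-np.expm1(cycle_length * np.log1p(-p1))) if p1 < 1.0 else 1.0
    t0 = state.get("diabetes_duration", 0.0)
    if eq.baseline_form in ("weibull", "gompertz") and "diabetes_duration" not in state:
        raise EvaluationError(
            f"equation {eq.name!r}: {eq.baseline_form} baseline needs diabetes_duration"
        )
    h = _integrated_hazard(eq, lp, float(t0), cycle_length)
    return float(-np.expm1(-h))


def progress_risk_factor(eq: EquationSpec, state: Mapping[str, float]) -> float:
    """Next-cycle factor value from the linear autoregressive recurrence."""
    if eq.kind != "progression":
        raise ConfigError(f"equation {eq.name!r} is not a progression equation")
    return linear_predictor(eq, state)


class CoefficientSet:
    """A versioned collection of event/death and progression equations."""

    def __init__(
        self,
        version: str,
        equations: Sequence[EquationSpec],
        ua_proxy_share: float = 0.0,
    ):
        names = [eq.name for eq in equations]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ConfigError(f"duplicate equation names: {sorted(dupes)}")
        if not 0.0 <= ua_proxy_share <= 1.0:
            raise ConfigError("ua_proxy_share outside [0,1]")
        self.version = version
        self.equations = list(equations)
        self.ua_proxy_share = float(ua_proxy_share)
        self._by_name = {eq.name: eq for eq in equations}

    def __getitem__(self, name: str) -> EquationSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise ConfigError(f"no equation named {name!r} in coefficient set") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def hazard_equations(self) -> list[EquationSpec]:
        """Event and death equations, in file order."""
        return [eq for eq in self.equations if eq.kind in ("event", "death")]

    @property
    def progression_equations(self) -> list[EquationSpec]:
        return [eq for eq in self.equations if eq.kind == "progression"]

    def progression_for(self, factor: str) -> EquationSpec | None:
        eq = self._by_name.get(factor)
        return eq if eq is not None and eq.kind == "progression" else None

    def assert_covers(self, endpoints: Sequence[str]) -> None:
        missing = [
            e for e in endpoints if e not in self._by_name or self._by_name[e].kind == "progression"
        ]
        if missing:
            raise ConfigError(f"coefficient set does not cover endpoints: {missing}")

    def to_json_dict(self) -> dict:
        eqs = []
        for eq in self.equations:
            d = {
                "name": eq.name,
                "kind": eq.kind,
                "intercept": eq.intercept,
                "coefficients": dict(eq.coefficients),
            }
            if eq.kind != "progression":
                d["baseline_form"] = eq.baseline_form
                if eq.shape is not None:
                    d["shape"] = eq.shape
            if eq.requires_no_history:
                d["requires_no_history"] = list(eq.requires_no_history)
            if eq.case_fatality is not None:
                d["case_fatality"] = eq.case_fatality
            eqs.append(d)
        return {
            "version": self.version,
            "ua_proxy_share": self.ua_proxy_share,
            "equations": eqs,
        }


def _spec_from_dict(d: Mapping) -> EquationSpec:
    unknown = set(d) - {
        "name",
        "kind",
        "intercept",
        "coefficients",
        "baseline_form",
        "shape",
        "requires_no_history",
        "case_fatality",
    }
    if unknown:
        raise ConfigError(f"unknown equation fields: {sorted(unknown)}")
    for key in ("name", "kind"):
        if key not in d:
            raise ConfigError(f"equation entry missing required field {key!r}")
    return EquationSpec(
        name=str(d["name"]),
        kind=str(d["kind"]),
        intercept=float(d.get("intercept", 0.0)),
        coefficients={str(k): float(v) for k, v in dict(d.get("coefficients", {})).items()},
        baseline_form=str(d.get("baseline_form", "exponential")),
        shape=None if d.get("shape") is None else float(d["shape"]),
        requires_no_history=tuple(d.get("requires_no_history", ())),
        case_fatality=None if d.get("case_fatality") is None else float(d["case_fatality"]),
    )


def coefficients_from_dict(payload: Mapping) -> CoefficientSet:
    if "equations" not in payload:
        raise ConfigError("coefficient file missing 'equations'")
    return CoefficientSet(
        version=str(payload.get("version", "unversioned")),
        equations=[_spec_from_dict(d) for d in payload["equations"]],
        ua_proxy_share=float(payload.get("ua_proxy_share", 0.0)),
    )


def load_coefficients(path) -> CoefficientSet:
    """Load and validate a coefficient set from a JSON file."""
    with open(path) as fh:
        payload = json.load(fh)
    return coefficients_from_dict(payload)


def save_coefficients(cset: CoefficientSet, path) -> None:
    with open(path, "w") as fh:
        json.dump(cset.to_json_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def illustrative_coefficients() -> CoefficientSet:
    """The shipped synthetic coefficient set (NOT the published model values)."""
    payload = json.loads(
        resources.files("t2dsim.data").joinpath("illustrative_coefficients.json").read_text()
    )
    return coefficients_from_dict(payload)
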