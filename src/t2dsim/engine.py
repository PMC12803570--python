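"""Probabilistic discrete-time illness-death microsimulation.

Each participant is advanced in annual cycles over the trial horizon.  Within
a cycle, every applicable event/death equation is evaluated in a uniformly
random order and fires with its annual probability via an independent uniform
draw.  A death (a death equation, or a fatal MI/stroke resolved by the
equation's case-fatality term) truncates the cycle: events positioned after
it in the random order do not occur.  Fired events update the participant's
event history, which enters the covariate state from the next cycle onward.
Risk factors advance each cycle from observed annualized follow-up data when
available, otherwise via the progression equations.

A non-integer horizon (e.g. the 3.2-year median follow-up of an
exenatide-outcome-trial-like cohort) is simulated as full annual cycles plus
one partial cycle whose hazards are integrated over the remaining fraction of
a year.

Replication streams are keyed by (seed, participant id), so results do not
depend on cohort ordering.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    BOOLEAN_FACTORS,
    CONTINUOUS_FACTORS,
    DEFAULT_LIMITS,
    FACTORS,
    FactorLimits,
    PRIOR_EVENTS,
    Participant,
    RiskFactorVector,
)
from .equations import (
    CoefficientSet,
    EquationSpec,
    annual_event_probability,
    linear_predictor,
    progress_risk_factor,
)
from .errors import ConfigError, EvaluationError

#: endpoints whose equations only model first events; participants with the
#: corresponding prior event are excluded from numerator and denominator
RESTRICTED_ENDPOINTS = {"ihd": "ihd", "heart_failure": "heart_failure"}


def _id_stream_key(pid: str) -> int:
    """Stable 32-bit key for a participant id (order-independent substreams)."""
    return zlib.crc32(str(pid).encode())


def cycle_lengths(horizon: float) -> list[float]:
    """Full annual cycles plus one partial cycle for a fractional horizon."""
    if not horizon > 0:
        raise ConfigError(f"horizon must be > 0, got {horizon}")
    full = int(math.floor(horizon))
    frac = horizon - full
    lengths = [1.0] * full
    if frac > 1e-9:
        lengths.append(frac)
    return lengths


# ---------------------------------------------------------------------------
# Scalar single-participant state (reference semantics, used in unit tests)
# ---------------------------------------------------------------------------


@dataclass
class SimState:
    """One participant's state within a single simulated replication."""

    participant: Participant
    cycle: int = 0
    time: float = 0.0
    alive: bool = True
    factors: RiskFactorVector = None
    history: dict = field(default_factory=dict)
    event_flags: dict = field(default_factory=dict)
    event_cycle: dict = field(default_factory=dict)
    excluded_endpoints: frozenset = frozenset()

    @classmethod
    def initial(cls, participant: Participant) -> "SimState":
        history = {e: participant.prior.has(e) for e in PRIOR_EVENTS}
        excluded = frozenset(
            ep for ep, flag in RESTRICTED_ENDPOINTS.items() if history.get(flag)
        )
        return cls(
            participant=participant,
            factors=participant.baseline.copy(),
            history=history,
            excluded_endpoints=excluded,
        )


def _covariate_state(p: Participant, factors: RiskFactorVector, time: float) -> dict:
    state = {
        "age": p.age + time,
        "diabetes_duration": p.diabetes_duration + time,
        "male": 1.0 if p.sex == "male" else 0.0,
        "height": p.height,
    }
    for f, v in factors.as_dict().items():
        if v is None:
            raise EvaluationError(
                f"participant {p.id!r}: risk factor {f!r} missing at simulation time "
                f"{time} (cohort not fully imputed)"
            )
        state[f] = float(v)
    return state


def run_cycle(
    state: SimState,
    eqs: CoefficientSet,
    cycle_length: float = 1.0,
    rng: np.random.Generator | None = None,
    limits: FactorLimits = DEFAULT_LIMITS,
) -> SimState:
    """Advance one participant-replication by a single cycle.

    Returns a new :class:`SimState`; the input state is not modified.
    """
    if not state.alive:
        raise ConfigError("run_cycle requires a live state")
    rng = rng if rng is not None else np.random.default_rng()
    p = state.participant
    hazards = eqs.hazard_equations
    k = len(hazards)

    cov = _covariate_state(p, state.factors, state.time)
    for e in PRIOR_EVENTS:
        cov[f"hist_{e}"] = 1.0 if state.history.get(e) else 0.0

    # one uniform per equation gives the random evaluation order; one per
    # equation gives the firing draw; fixed extra draws keep the stream
    # layout identical across cycles
    positions = rng.random(k)
    fire_u = rng.random(k)
    fatal_u = rng.random(k)
    ua_u = rng.random()

    new = SimState(
        participant=p,
        cycle=state.cycle + 1,
        time=state.time + cycle_length,
        alive=True,
        factors=state.factors.copy(),
        history=dict(state.history),
        event_flags=dict(state.event_flags),
        event_cycle=dict(state.event_cycle),
        excluded_endpoints=state.excluded_endpoints,
    )

    died = False
    death_is_cv = False
    fired_names: list[str] = []
    for j in np.argsort(positions):
        eq = hazards[j]
        if any(state.history.get(f) or new.history.get(f) for f in eq.requires_no_history):
            continue
        prob = annual_event_probability(eq, cov, cycle_length)
        if not fire_u[j] < prob:
            continue
        fatal = eq.kind == "death" or (
            eq.case_fatality is not None and fatal_u[j] < eq.case_fatality
        )
        if eq.kind != "death":
            fired_names.append(eq.name)
            if eq.case_fatality is not None and fatal:
                fired_names.append(f"fatal_{eq.name}")
            if eq.name == "ihd" and eqs.ua_proxy_share > 0 and ua_u < eqs.ua_proxy_share:
                fired_names.append("ua")
        if fatal:
            died = True
            death_is_cv = eq.name == "cv_death" or eq.kind != "death"
            break

    cv_event = any(n in fired_names for n in ("mi", "stroke")) or (died and death_is_cv)
    if died and death_is_cv:
        fired_names.append("cv_death")
    if died:
        fired_names.append("all_cause_death")
    if cv_event:
        fired_names.append("mace3")
    if cv_event or "ua" in fired_names:
        fired_names.append("mace4")

    for name in fired_names:
        if name in new.excluded_endpoints:
            continue
        if not new.event_flags.get(name):
            new.event_flags[name] = True
            new.event_cycle[name] = state.cycle
        if name in PRIOR_EVENTS:
            new.history[name] = True

    new.alive = not died
    if new.alive:
        next_year = state.cycle + 1
        observed = p.followup.get(next_year, RiskFactorVector())
        prog_state = dict(cov)
        for f in CONTINUOUS_FACTORS:
            obs = getattr(observed, f)
            if obs is not None and limits.in_range(f, obs):
                setattr(new.factors, f, obs)
            else:
                eq = eqs.progression_for(f)
                if eq is not None:
                    st = dict(prog_state)
                    st["current"] = prog_state[f]
                    setattr(new.factors, f, limits.clamp(f, progress_risk_factor(eq, st)))
                # else: carry forward
        for f in BOOLEAN_FACTORS:
            obs = getattr(observed, f)
            if obs is not None:
                setattr(new.factors, f, obs)
    return new


# ---------------------------------------------------------------------------
# Cohort-level vectorized simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedOutcomes:
    """Per-participant, per-replication simulated event histories."""

    participants: pd.DataFrame
    #: endpoint -> (n_participants, replications) first-event cycle, -1 = none
    event_cycles: dict[str, np.ndarray]
    horizon: float
    replications: int
    seed: int
    coefficients_version: str

    @property
    def endpoints(self) -> list[str]:
        return list(self.event_cycles)

    @property
    def cycle_ends(self) -> np.ndarray:
        return np.cumsum(cycle_lengths(self.horizon))

    def event_indicator(self, endpoint: str) -> np.ndarray:
        if endpoint not in self.event_cycles:
            raise ConfigError(f"unknown endpoint {endpoint!r}")
        return self.event_cycles[endpoint] >= 0

    def event_times(self, endpoint: str) -> np.ndarray:
        """End-of-cycle event time (years); NaN where no event."""
        cyc = self.event_cycles[endpoint]
        ends = self.cycle_ends
        t = np.full(cyc.shape, np.nan)
        mask = cyc >= 0
        t[mask] = ends[cyc[mask]]
        return t

    def eligible_mask(self, endpoint: str) -> np.ndarray:
        """Participants in the endpoint's denominator (first-event restriction)."""
        flag = RESTRICTED_ENDPOINTS.get(endpoint)
        if flag is None:
            return np.ones(len(self.participants), dtype=bool)
        return ~self.participants[f"prior_{flag}"].to_numpy(dtype=bool)

    def predicted_risk(self, endpoint: str) -> np.ndarray:
        """Per-participant event frequency across replications."""
        return self.event_indicator(endpoint).mean(axis=1)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(outdir / "participants.csv", index=False)
        rows = []
        for ep, cyc in self.event_cycles.items():
            idx, rep = np.nonzero(cyc >= 0)
            rows.append(
                pd.DataFrame(
                    {
                        "participant": self.participants["id"].to_numpy()[idx],
                        "replication": rep,
                        "endpoint": ep,
                        "cycle": cyc[idx, rep],
                    }
                )
            )
        events = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
            columns=["participant", "replication", "endpoint", "cycle"]
        )
        events.to_csv(outdir / "events.csv", index=False)
        meta = {
            "horizon": self.horizon,
            "replications": self.replications,
            "seed": self.seed,
            "coefficients_version": self.coefficients_version,
            "endpoints": self.endpoints,
        }
        with open(outdir / "meta.json", "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, outdir) -> "SimulatedOutcomes":
        outdir = Path(outdir)
        with open(outdir / "meta.json") as fh:
            meta = json.load(fh)
        participants = pd.read_csv(outdir / "participants.csv", dtype={"id": str})
        events = pd.read_csv(outdir / "events.csv", dtype={"participant": str})
        n, r = len(participants), meta["replications"]
        pos = {pid: i for i, pid in enumerate(participants["id"])}
        cycles = {ep: np.full((n, r), -1, dtype=np.int16) for ep in meta["endpoints"]}
        for ep, grp in events.groupby("endpoint"):
            arr = cycles[ep]
            arr[
                [pos[pid] for pid in grp["participant"]],
                grp["replication"].to_numpy(),
            ] = grp["cycle"].to_numpy()
        return cls(
            participants=participants,
            event_cycles=cycles,
            horizon=meta["horizon"],
            replications=r,
            seed=meta["seed"],
            coefficients_version=meta["coefficients_version"],
        )


def _precompute_participant(
    p: Participant,
    eqs: CoefficientSet,
    lengths: Sequence[float],
    limits: FactorLimits,
):
    """Per-cycle base linear predictors (with integrated-baseline offsets) and
    history-coefficient vectors; everything that does not vary by replication."""
    hazards = eqs.hazard_equations
    n_cycles = len(lengths)

    # deterministic risk-factor trajectory
    states = []
    factors = {f: getattr(p.baseline, f) for f in FACTORS}
    for c in range(n_cycles):
        missing = [f for f, v in factors.items() if v is None]
        if missing:
            raise EvaluationError(
                f"participant {p.id!r}: risk factors {missing} missing at year {c} "
                "(cohort not fully imputed)"
            )
        state = dict(factors)
        state["age"] = p.age + c
        state["diabetes_duration"] = p.diabetes_duration + c
        state["male"] = 1.0 if p.sex == "male" else 0.0
        state["height"] = p.height
        states.append(state)
        if c + 1 < n_cycles:
            observed = p.followup.get(c + 1, RiskFactorVector())
            nxt = {}
            for f in CONTINUOUS_FACTORS:
                obs = getattr(observed, f)
                if obs is not None and limits.in_range(f, obs):
                    nxt[f] = obs
                else:
                    eq = eqs.progression_for(f)
                    if eq is not None:
                        st = dict(state)
                        st["current"] = state[f]
                        nxt[f] = limits.clamp(f, progress_risk_factor(eq, st))
                    else:
                        nxt[f] = factors[f]
            for f in BOOLEAN_FACTORS:
                obs = getattr(observed, f)
                nxt[f] = obs if obs is not None else factors[f]
            factors = nxt

    k = len(hazards)
    base_lp = np.zeros((n_cycles, k))
    hist_w = np.zeros((k, len(PRIOR_EVENTS)))
    is_logistic = np.array([eq.baseline_form == "logistic" for eq in hazards])
    for j, eq in enumerate(hazards):
        state_coefs = {}
        for cov, coef in eq.coefficients.items():
            if cov.startswith("hist_"):
                hist_w[j, PRIOR_EVENTS.index(cov[5:])] = coef
            else:
                state_coefs[cov] = coef
        partial = EquationSpec(
            name=eq.name, kind=eq.kind, coefficients=state_coefs, intercept=eq.intercept,
            baseline_form=eq.baseline_form, shape=eq.shape,
        )
        for c, cl in enumerate(lengths):
            lp = linear_predictor(partial, states[c])
            if eq.baseline_form == "logistic":
                base_lp[c, j] = lp  # logistic keeps the raw linear predictor
            else:
                from .equations import _integrated_hazard

                h1 = _integrated_hazard(eq, 0.0, states[c]["diabetes_duration"], cl)
                base_lp[c, j] = lp + math.log(h1)
    return base_lp, hist_w, is_logistic


def _simulate_participant_reps(
    base_lp: np.ndarray,
    hist_w: np.ndarray,
    is_logistic: np.ndarray,
    hazards: Sequence[EquationSpec],
    prior_flags: np.ndarray,
    lengths: Sequence[float],
    replications: int,
    rng: np.random.Generator,
    ua_share: float,
    endpoint_index: Mapping[str, int],
    out: np.ndarray,
    row: int,
) -> None:
    """Vectorized over replications; fills ``out[:, row, :]`` with first-event
    cycles (-1 = none).  Draw layout matches :func:`run_cycle`."""
    k = len(hazards)
    R = replications
    req = np.zeros((k, len(PRIOR_EVENTS)), dtype=bool)
    cf = np.full(k, np.nan)
    is_death_eq = np.zeros(k, dtype=bool)
    for j, eq in enumerate(hazards):
        for f in eq.requires_no_history:
            req[j, PRIOR_EVENTS.index(f)] = True
        if eq.case_fatality is not None:
            cf[j] = eq.case_fatality
        is_death_eq[j] = eq.kind == "death"
    try:
        idx_cv_death = [eq.name for eq in hazards].index("cv_death")
    except ValueError:
        idx_cv_death = -1
    names = [eq.name for eq in hazards]
    hist_updatable = [(j, PRIOR_EVENTS.index(n)) for j, n in enumerate(names) if n in PRIOR_EVENTS]
    idx_ihd = names.index("ihd") if "ihd" in names else -1

    H = np.tile(prior_flags.astype(float), (R, 1))
    alive = np.ones(R, dtype=bool)
    excluded = np.zeros((R, k), dtype=bool)  # prior-event first-event exclusion
    for j in range(k):
        if req[j].any() and (prior_flags[req[j]]).any():
            excluded[:, j] = True

    def record(name: str, mask: np.ndarray, cycle: int) -> None:
        col = out[endpoint_index[name], row]
        np.copyto(col, cycle, where=mask & (col < 0))

    for c, cl in enumerate(lengths):
        if not alive.any():
            break
        positions = rng.random((R, k))
        fire_u = rng.random((R, k))
        fatal_u = rng.random((R, k))
        ua_u = rng.random(R)

        lp = base_lp[c][None, :] + H @ hist_w.T
        if is_logistic.any():
            P = np.empty((R, k))
            lg = is_logistic
            p1 = 1.0 / (1.0 + np.exp(-lp[:, lg]))
            P[:, lg] = -np.expm1(cl * np.log1p(-np.minimum(p1, 1 - 1e-15)))
            P[:, ~lg] = -np.expm1(-np.exp(lp[:, ~lg]))
        else:
            P = -np.expm1(-np.exp(lp))

        applicable = alive[:, None] & ~excluded[:, : k] & ~(H @ req.T.astype(float) > 0)
        fired = (fire_u < P) & applicable

        fatal = fired & (is_death_eq[None, :] | (fatal_u < cf[None, :]))
        pos_masked = np.where(fatal, positions, np.inf)
        death_pos = pos_masked.min(axis=1)
        died = np.isfinite(death_pos)
        counted = fired & (positions <= death_pos[:, None])

        cause = np.where(died, pos_masked.argmin(axis=1), -1)
        cv_death_now = died & (
            (cause == idx_cv_death) | (~is_death_eq[np.maximum(cause, 0)] & died)
        )

        cv_component = np.zeros(R, dtype=bool)
        for j, eq in enumerate(hazards):
            if eq.kind == "death":
                continue
            col = counted[:, j]
            record(eq.name, col, c)
            if eq.case_fatality is not None:
                record(f"fatal_{eq.name}", col & fatal[:, j], c)
            if eq.name in ("mi", "stroke"):
                cv_component |= col
        if idx_ihd >= 0 and ua_share > 0:
            ua_now = counted[:, idx_ihd] & (ua_u < ua_share)
            record("ua", ua_now, c)
        else:
            ua_now = np.zeros(R, dtype=bool)

        record("cv_death", cv_death_now, c)
        record("all_cause_death", died, c)
        mace3_now = cv_component | cv_death_now
        record("mace3", mace3_now, c)
        record("mace4", mace3_now | ua_now, c)

        for j, flag_idx in hist_updatable:
            H[counted[:, j], flag_idx] = 1.0
        alive &= ~died


def derived_endpoints(eqs: CoefficientSet) -> list[str]:
    names = [eq.name for eq in eqs.hazard_equations]
    eps = [n for n in names if eqs[n].kind != "death"]
    eps += [f"fatal_{n}" for n in names if eqs[n].kind != "death" and eqs[n].case_fatality is not None]
    if eqs.ua_proxy_share > 0 and "ihd" in names:
        eps.append("ua")
    eps += ["cv_death", "all_cause_death", "mace3", "mace4"]
    return eps


def simulate_cohort(
    cohort: Sequence[Participant],
    eqs: CoefficientSet,
    horizon: float,
    replications: int = 200,
    seed: int = 0,
    limits: FactorLimits = DEFAULT_LIMITS,
) -> SimulatedOutcomes:
    """Simulate every participant for ``horizon`` years x ``replications``.

    Returns first-event cycles per endpoint; expectation over replications is
    the model's estimate of each participant's event risk by the horizon.
    """
    if replications < 1:
        raise ConfigError("replications must be >= 1")
    lengths = cycle_lengths(horizon)
    hazards = eqs.hazard_equations
    if not hazards:
        raise ConfigError("coefficient set contains no event/death equations")
    endpoints = derived_endpoints(eqs)
    endpoint_index = {ep: i for i, ep in enumerate(endpoints)}

    n = len(cohort)
    out = np.full((len(endpoints), n, replications), -1, dtype=np.int16)
    for row, p in enumerate(cohort):
        base_lp, hist_w, is_logistic = _precompute_participant(p, eqs, lengths, limits)
        prior = np.array([p.prior.has(e) for e in PRIOR_EVENTS])
        rng = np.random.default_rng([seed, _id_stream_key(p.id)])
        _simulate_participant_reps(
            base_lp,
            hist_w,
            is_logistic,
            hazards,
            prior,
            lengths,
            replications,
            rng,
            eqs.ua_proxy_share,
            endpoint_index,
            out,
            row,
        )

    participants = pd.DataFrame(
        {
            "id": [p.id for p in cohort],
            "arm": [p.arm for p in cohort],
            "age": [p.age for p in cohort],
            "sex": [p.sex for p in cohort],
            "prior_ihd": [p.prior.has("ihd") for p in cohort],
            "prior_heart_failure": [p.prior.has("heart_failure") for p in cohort],
            "prior_cv": [p.prior.prior_cv for p in cohort],
        }
    )
    return SimulatedOutcomes(
        participants=participants,
        event_cycles={ep: out[i] for ep, i in endpoint_index.items()},
        horizon=horizon,
        replications=replications,
        seed=seed,
        coefficients_version=eqs.version,
    )


def first_event_summary(out: SimulatedOutcomes, endpoint: str) -> pd.DataFrame:
    """Per-arm expected first-event counts and proportions.

    The denominator excludes participants with the corresponding prior event
    for first-event-restricted endpoints (IHD, heart failure).
    """
    ind = out.event_indicator(endpoint)
    eligible = out.eligible_mask(endpoint)
    rows = []
    for arm in ("active", "placebo"):
        mask = (out.participants["arm"] == arm).to_numpy() & eligible
        denom = int(mask.sum())
        expected = float(ind[mask].sum(axis=0).mean()) if denom else 0.0
        rows.append(
            {
                "arm": arm,
                "expected_events": expected,
                "denominator": denom,
                "proportion": expected / denom if denom else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("arm")
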