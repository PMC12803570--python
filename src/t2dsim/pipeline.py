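"""End-to-end orchestration: ingest -> impute -> simulate -> validate -> report.

`run_pipeline` is deterministic given its :class:`RunConfig`: rerunning with
an equal config produces byte-identical report tables.  All randomness flows
from ``config.seed``; stage-specific substreams are derived from it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .cohort import (
    fill_followup,
    impute_mean_substitution,
    impute_stratified,
    load_cohort,
    save_cohort,
)
from .engine import cycle_lengths, simulate_cohort
from .equations import illustrative_coefficients, load_coefficients
from .errors import ConfigError
from .metrics import (
    ValidationReport,
    build_validation_report,
    cumulative_incidence,
    observed_frame,
    round_half_up,
)
from .synthetic import (
    generate_cohort,
    generate_followup_trajectories,
    generate_outcomes_from_engine,
    load_profile,
)

log = logging.getLogger("t2dsim")

RESTRICTION_NOTES = {
    "heart_failure": "In those without prior heart failure.",
    "ihd": "In those without prior ischemic heart disease.",
}


@dataclass
class RunConfig:
    outdir: str
    horizon: float = 3.0
    replications: int = 200
    seed: int = 0
    #: path to a participant-year cohort CSV; mutually exclusive with profile
    cohort: str | None = None
    #: built-in profile name ("tecos"/"exscel") or profile JSON path
    profile: str | None = None
    #: coefficient JSON path; None uses the shipped illustrative set
    coefficients: str | None = None
    #: observed-outcome CSV; None generates self-validation outcomes by
    #: running the engine itself at one replication
    observed: str | None = None
    endpoints: tuple[str, ...] | None = None
    subgroups: tuple[str, ...] | None = ("age_lt65", "age_ge65", "male", "female", "prior_cv", "no_prior_cv")
    #: synthetic trajectory options
    trajectory_noise_sd: float = 0.0
    trajectory_gap_rate: float = 0.3

    def validate(self) -> None:
        if not self.horizon > 0:
            raise ConfigError("horizon must be > 0")
        if self.replications < 1:
            raise ConfigError("replications must be >= 1")
        if (self.cohort is None) == (self.profile is None):
            raise ConfigError("exactly one of 'cohort' and 'profile' must be set")
        for name in ("cohort", "coefficients", "observed"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{name} file not found: {path}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            if path.suffix in (".yaml", ".yml"):
                import yaml

                payload = yaml.safe_load(fh)
            else:
                payload = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("endpoints", "subgroups"):
            if payload.get(key) is not None:
                payload[key] = tuple(payload[key])
        return cls(**payload)


def _load_coefficient_set(config: RunConfig):
    if config.coefficients is None:
        return illustrative_coefficients()
    return load_coefficients(config.coefficients)


def format_outcome_table(report: ValidationReport) -> pd.DataFrame:
    """Render a trial-style outcome table: per endpoint, observed and
    simulated counts with percentages, the observed HR (95% CI), the
    simulated RR and the C-statistic."""

    def cell(count: float, pct: float) -> str:
        return f"{round_half_up(count, 0):.0f} ({pct:.1f}%)"

    rows = []
    for ep, r in report.endpoints.items():
        hr = r.hr
        rows.append(
            {
                "outcome": ep,
                "active_observed": cell(r.observed_active, r.observed_pct_active),
                "active_simulated": cell(r.simulated_active, r.simulated_pct_active),
                "placebo_observed": cell(r.observed_placebo, r.observed_pct_placebo),
                "placebo_simulated": cell(r.simulated_placebo, r.simulated_pct_placebo),
                "observed_hr_95ci": "--"
                if hr is None or hr.hr != hr.hr
                else f"{round_half_up(hr.hr, 2):.2f} ({round_half_up(hr.ci_low, 2):.2f}-{round_half_up(hr.ci_high, 2):.2f})",
                "simulated_rr": "--" if r.rr is None else f"{r.rr:.2f}",
                "c_statistic": "--" if r.c_statistic != r.c_statistic else f"{round_half_up(r.c_statistic, 2):.2f}",
                "note": RESTRICTION_NOTES.get(ep, "") if r.restricted else "",
            }
        )
    return pd.DataFrame(rows)


def _write_plot_data(report, observed, simulated, outdir: Path) -> None:
    """Tidy CSVs backing calibration and cumulative-incidence plots."""
    cal_rows = []
    for ep, r in report.endpoints.items():
        if r.calibration is None:
            continue
        t = r.calibration.table.copy()
        t.insert(0, "endpoint", ep)
        cal_rows.append(t)
    if cal_rows:
        pd.concat(cal_rows, ignore_index=True).to_csv(outdir / "calibration.csv", index=False)

    obs = observed_frame(observed)
    ci_rows = []
    ends = simulated.cycle_ends
    for ep in report.endpoints:
        for arm in ("active", "placebo"):
            sub = obs[(obs["endpoint"] == ep) & (obs["arm"] == arm)]
            if len(sub) and sub["event"].any():
                km = cumulative_incidence(sub)
                km.insert(0, "source", "observed")
                km.insert(0, "arm", arm)
                km.insert(0, "endpoint", ep)
                ci_rows.append(km)
            ind = simulated.event_cycles[ep]
            mask = (simulated.participants["arm"] == arm).to_numpy() & simulated.eligible_mask(ep)
            denom = mask.sum()
            if denom:
                sim_ci = [
                    float(((ind[mask] >= 0) & (ind[mask] <= c)).sum(axis=0).mean() / denom)
                    for c in range(len(ends))
                ]
                ci_rows.append(
                    pd.DataFrame(
                        {
                            "endpoint": ep,
                            "arm": arm,
                            "source": "simulated",
                            "time": ends,
                            "cuminc": sim_ci,
                        }
                    )
                )
    if ci_rows:
        pd.concat(ci_rows, ignore_index=True).to_csv(outdir / "cumulative_incidence.csv", index=False)


def run_pipeline(config: RunConfig) -> ValidationReport:
    """Run the full validation pipeline and write its artifacts to
    ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t_start = time.perf_counter()
    try:
        eqs = _load_coefficient_set(config)

        t0 = time.perf_counter()
        if config.cohort is not None:
            cohort = load_cohort(config.cohort)
        else:
            cohort = generate_cohort(load_profile(config.profile), seed=config.seed)
        log.info("stage=cohort n=%d elapsed=%.2fs", len(cohort), time.perf_counter() - t0)

        t0 = time.perf_counter()
        cohort = impute_mean_substitution(cohort)
        cohort = impute_stratified(cohort, seed=config.seed + 2)
        if config.profile is not None:
            # synthetic annual measurements, built on the imputed baseline
            cohort = generate_followup_trajectories(
                cohort,
                eqs,
                noise_sd=config.trajectory_noise_sd,
                seed=config.seed + 1,
                years=max(1, int(config.horizon)),
                gap_rate=config.trajectory_gap_rate,
            )
        cohort = fill_followup(cohort, eqs, config.horizon)
        n_imputed = sum(len(p.imputed) for p in cohort)
        log.info("stage=impute imputed_cells=%d elapsed=%.2fs", n_imputed, time.perf_counter() - t0)

        t0 = time.perf_counter()
        if config.observed is not None:
            observed = observed_frame(pd.read_csv(config.observed, dtype={"id": str}))
        else:
            observed = observed_frame(
                generate_outcomes_from_engine(cohort, eqs, config.horizon, seed=config.seed + 3)
            )
        log.info("stage=observed records=%d elapsed=%.2fs", len(observed), time.perf_counter() - t0)

        t0 = time.perf_counter()
        simulated = simulate_cohort(
            cohort, eqs, config.horizon, replications=config.replications, seed=config.seed + 4
        )
        log.info(
            "stage=simulate cycles=%d reps=%d elapsed=%.2fs",
            len(cycle_lengths(config.horizon)),
            config.replications,
            time.perf_counter() - t0,
        )

        t0 = time.perf_counter()
        report = build_validation_report(
            observed, simulated, endpoints=config.endpoints, subgroups=config.subgroups
        )
        for ep, r in report.endpoints.items():
            for flag in r.flags:
                log.warning("endpoint=%s flag=%s", ep, flag)
        log.info("stage=validate endpoints=%d elapsed=%.2fs", len(report.endpoints), time.perf_counter() - t0)

        report.to_frame().to_csv(outdir / "report.csv", index=False)
        format_outcome_table(report).to_csv(outdir / "outcome_table.csv", index=False)
        simulated.write(outdir / "simulated")
        observed.to_csv(outdir / "observed.csv", index=False)
        save_cohort(cohort, outdir / "cohort_imputed.csv")
        _write_plot_data(report, observed, simulated, outdir)
        meta = {
            "package_version": __version__,
            "coefficients_version": eqs.version,
            "config": dataclasses.asdict(config),
        }
        with open(outdir / "metadata.json", "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True, default=list)
            fh.write("\n")
        log.info("pipeline complete elapsed=%.2fs", time.perf_counter() - t_start)
        return report
    finally:
        log.removeHandler(handler)
        handler.close()
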