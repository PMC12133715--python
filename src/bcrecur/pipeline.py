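"""End-to-end orchestration: simulate -> cohort -> ascertain -> estimate -> tabulate.

The pipeline reads three linked tables (registry, HDD, OPS) — or generates
them synthetically — applies the eligibility cascade, resolves each woman's
first event from claims and registry dates, estimates cumulative incidences
in the competing-risks framework overall and by stratum, and tabulates the
six-state 10-year follow-up status.  Outputs are deterministic RFC-4180 CSV
files plus a human-readable summary; identical config and seed give
byte-identical output directories.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import ascertain as asc
from . import cohort as coh
from . import competing as cr
from . import tabulate as tab
from .synthetic import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

STRATA = ("period", "age_group", "subtype", "stage")
REPORT_HORIZONS_YEARS = (5.0, 10.0)


@dataclass
class RunConfig:
    """One pipeline run: either synthetic mode or three real input tables."""

    outdir: Path
    admin_cutoff: date = date(2021, 12, 31)
    seed: int = 0
    simulation: Optional[SimulationConfig] = None
    registry_path: Optional[Path] = None
    hdd_path: Optional[Path] = None
    ops_path: Optional[Path] = None
    codeset_path: Optional[Path] = None
    sensitivity_12m: bool = False
    left_truncation: bool = False
    age_bands: str = "five"
    verbosity: str = "INFO"

    def validate(self) -> None:
        real = all(p is not None for p in (self.registry_path, self.hdd_path, self.ops_path))
        some_real = any(p is not None for p in (self.registry_path, self.hdd_path, self.ops_path))
        if self.simulation is not None and some_real:
            raise ValueError("give either a simulation config or real input paths, not both")
        if self.simulation is None and not real:
            raise ValueError("need either a simulation config or all three input paths")
        if self.age_bands not in ("five", "four"):
            raise ValueError("age_bands must be 'five' or 'four'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            sim = raw["simulation"]
            raw["simulation"] = (
                SimulationConfig.from_yaml(sim) if isinstance(sim, str) else _sim_from_dict(sim)
            )
        for key in ("outdir", "registry_path", "hdd_path", "ops_path", "codeset_path"):
            if raw.get(key):
                raw[key] = Path(raw[key])
        if isinstance(raw.get("admin_cutoff"), str):
            raw["admin_cutoff"] = date.fromisoformat(raw["admin_cutoff"])
        return cls(**raw)

    def hash(self) -> str:
        payload = {
            "admin_cutoff": self.admin_cutoff.isoformat(),
            "seed": self.seed,
            "simulation": self.simulation.to_dict() if self.simulation else None,
            "inputs": [str(p) for p in (self.registry_path, self.hdd_path, self.ops_path) if p],
            "codeset": str(self.codeset_path) if self.codeset_path else None,
            "sensitivity_12m": self.sensitivity_12m,
            "left_truncation": self.left_truncation,
            "age_bands": self.age_bands,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _sim_from_dict(raw: dict) -> SimulationConfig:
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".yaml", delete=False) as fh:
        yaml.safe_dump(raw, fh)
        name = fh.name
    try:
        return SimulationConfig.from_yaml(name)
    finally:
        Path(name).unlink(missing_ok=True)


def configure_logging(verbosity: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("bcrecur")
    root.handlers[:] = [handler]
    root.setLevel(getattr(logging, verbosity.upper(), logging.INFO))


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def _read_table(path: Path, name: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise FileNotFoundError(f"missing input file for {name}: {path}")
    except pd.errors.ParserError as exc:
        raise ValueError(f"garbled input file {path}: {exc}") from exc


def _cif_frame(estimate: cr.CIFEstimate, stratum: str) -> pd.DataFrame:
    rows = []
    for k in cr.CAUSES:
        for j, t in enumerate(estimate.times):
            rows.append(
                {
                    "stratum": stratum,
                    "time_days": int(t),
                    "cause": k,
                    "cif": estimate.cif[k][j],
                    "var": estimate.var[k][j],
                    "ci_low": estimate.ci_low[k][j],
                    "ci_high": estimate.ci_high[k][j],
                    "n_risk": int(estimate.n_risk[j]),
                }
            )
    return pd.DataFrame(rows, columns=["stratum", "time_days", "cause", "cif", "var", "ci_low", "ci_high", "n_risk"])


def _fmt_cif(point: cr.CIFPoint) -> str:
    return (
        f"{tab.round1(100 * point.point):.1f} % "
        f"({tab.round1(100 * point.ci_low):.1f} %-{tab.round1(100 * point.ci_high):.1f} %)"
    )


def stage_seed(seed: int, stage_index: int) -> int:
    """Per-stage substream seed fanned out from the single global seed."""
    return int(
        np.random.SeedSequence(seed).spawn(stage_index + 1)[stage_index].generate_state(1)[0]
        % 2**31
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and write every output table; returns the run report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- inputs -----------------------------------------------------------
    if config.simulation is not None:
        sim = config.simulation
        sim.seed = stage_seed(config.seed, 0)
        registry, hdd, ops, truth = simulate_cohort(sim)
        _write_csv(registry, outdir / "registry.csv")
        _write_csv(hdd, outdir / "hdd.csv")
        _write_csv(ops, outdir / "ops.csv")
        _write_csv(truth, outdir / "truth.csv")
        logger.info("simulated %d patients", len(registry))
    else:
        registry = _read_table(config.registry_path, "registry")
        hdd = _read_table(config.hdd_path, "hdd")
        ops = _read_table(config.ops_path, "ops")

    code_set = (
        asc.CodeSet.from_yaml(config.codeset_path) if config.codeset_path else asc.CodeSet()
    )

    # --- cohort -----------------------------------------------------------
    eligible, log = coh.apply_eligibility(registry, reference_end=config.admin_cutoff)
    cohort = coh.derive_strata(eligible, bands=config.age_bands)
    _write_csv(log.to_frame(), outdir / "exclusions.csv")
    _write_csv(cohort, outdir / "cohort.csv")
    logger.info("cohort: %d of %d eligible", log.final, log.initial)

    # --- ascertainment ----------------------------------------------------
    outcomes = asc.ascertain_cohort(
        cohort, hdd, ops, code_set, config.admin_cutoff, config.sensitivity_12m
    )
    _write_csv(outcomes, outdir / "outcomes.csv")

    # --- competing-risks estimation --------------------------------------
    timelines = cr.build_timelines(
        outcomes, cohort, config.left_truncation, config.sensitivity_12m
    )
    overall = cr.aalen_johansen(timelines["time_days"], timelines["cause"], timelines["entry_days"])
    _write_csv(_cif_frame(overall, "all"), outdir / "cif_overall.csv")
    by_stratum: dict[str, dict[str, cr.CIFEstimate]] = {}
    for stratum in STRATA:
        estimates = cr.stratified_cif(timelines, stratum)
        by_stratum[stratum] = estimates
        frame = pd.concat(
            [_cif_frame(est, label) for label, est in estimates.items()],
            ignore_index=True,
        )
        _write_csv(frame, outdir / f"cif_{stratum}.csv")

    # --- crude rates ------------------------------------------------------
    rate_rows = []

    def _rate_row(var: str, level: str, subset: pd.DataFrame) -> None:
        events = int((subset["cause"] == "recurrence").sum())
        py = float(subset["time_days"].sum()) / cr.DAYS_PER_YEAR
        rate_rows.append(
            {
                "stratum_var": var,
                "stratum": level,
                "n_recurrences": events,
                "person_years": round(py, 1),
                "rate_per_1000py": round(cr.crude_rate(events, py), 1) if py > 0 else "",
            }
        )

    _rate_row("all", "all", timelines)
    for stratum in STRATA:
        for level in sorted(x for x in timelines[stratum].dropna().unique() if x not in ("", "not_available")):
            _rate_row(stratum, str(level), timelines[timelines[stratum] == level])
    rates = pd.DataFrame(rate_rows)
    _write_csv(rates, outdir / "rates.csv")

    # --- 10-year status ---------------------------------------------------
    death_days = pd.Series(
        [
            (pd.Timestamp(d).date() - pd.Timestamp(g).date()).days if str(d) not in ("", "nan", "NaT") else np.nan
            for d, g in zip(cohort["death_date"], cohort["diagnosis_date"])
        ],
        index=outcomes.index,
    )
    statuses = tab.classify_cohort(outcomes, death_days)
    status_table = tab.tabulate_status(cohort, statuses)
    _write_csv(status_table, outdir / "status10y.csv")

    conditional = {
        f"alive_with_recurrence_{int(t1)}y_given_{int(t0)}y": tab.conditional_alive_with_recurrence(
            outcomes, death_days, t0, t1
        )
        for t0, t1 in ((2.0, 7.0), (2.0, 10.0), (5.0, 7.0), (5.0, 10.0))
    }

    # --- report -----------------------------------------------------------
    report = {
        "config_hash": config.hash(),
        "initial_n": log.initial,
        "cohort_size": log.final,
        "exclusions": dict(log.steps),
        "n_recurrences": int((outcomes["event"] == "recurrence").sum()),
        "person_years": round(cr.person_years(outcomes), 1),
        "cif_recurrence": {
            f"{int(t)}y": cr.cif_at(overall, "recurrence", t) for t in REPORT_HORIZONS_YEARS
        },
        "cif_by_stratum": {
            stratum: {
                label: {f"{int(t)}y": cr.cif_at(est, "recurrence", t) for t in REPORT_HORIZONS_YEARS}
                for label, est in by_stratum[stratum].items()
            }
            for stratum in STRATA
        },
        "status_at_10y": {
            state: int((statuses == state).sum()) for state in tab.STATES
        },
        "conditional_alive_with_recurrence": conditional,
    }

    summary = _format_summary(report)
    (outdir / "summary.txt").write_text(summary)
    return report


def _format_summary(report: dict) -> str:
    lines = [
        f"run config hash: {report['config_hash']}",
        f"cohort: {report['cohort_size']} of {report['initial_n']} eligible",
        "exclusions: " + ", ".join(f"{k}={v}" for k, v in report["exclusions"].items()),
        f"recurrences: {report['n_recurrences']} over {report['person_years']} person-years",
        "",
        "cumulative incidence of recurrence (95 % CI):",
    ]
    for horizon, point in report["cif_recurrence"].items():
        lines.append(f"  all cohort, {horizon}: {_fmt_cif(point)}")
    for stratum, groups in report["cif_by_stratum"].items():
        lines.append(f"  by {stratum}:")
        for label, horizons in groups.items():
            per_h = "; ".join(f"{h}: {_fmt_cif(p)}" for h, p in horizons.items())
            lines.append(f"    {label}: {per_h}")
    lines.append("")
    lines.append("follow-up status at 10 years:")
    total = sum(report["status_at_10y"].values())
    for state, count in report["status_at_10y"].items():
        pct = tab.share(count, total) if total else 0.0
        lines.append(f"  {state}: {count} ({pct:.1f} %)")
    lines.append("")
    lines.append("probability of remaining alive with recurrence:")
    for key, value in report["conditional_alive_with_recurrence"].items():
        shown = "undefined" if value != value else f"{value:.3f}"
        lines.append(f"  {key}: {shown}")
    return "\n".join(lines) + "\n"
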