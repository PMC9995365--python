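"""Structured study configuration and pipeline runners.

A study config is one YAML or JSON document naming the study kind, the
calendar window, the input tables and the stage parameters.  ``run_study``
validates it up front, executes the matching pipeline, and writes a
per-patient table plus a machine-readable JSON report (attrition counters
included) atomically — a temp file in the output directory renamed into
place, so a crashed run never leaves a half-written report.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Any

import yaml

from . import io as cio
from .equivalence import DoseEquivalenceTable
from .records import Route, StudyWindow
from .simulate import (
    SsaSimConfig,
    UtilizationSimConfig,
    simulate_exposure_outcome,
    simulate_prescriptions,
    triptan_dose_table,
)
from .ssa import SequenceSymmetry
from .utilization import CumulativeDoseStudy, DurationStudy, OveruseStudy

log = logging.getLogger("claimslab")

STUDY_KINDS = ("overuse", "cumulative_dose", "duration_cohorts", "ssa", "simulate")

_REQUIRED_INPUTS = {
    "overuse": ("prescriptions", "dose_table"),
    "cumulative_dose": ("prescriptions",),
    "duration_cohorts": ("prescriptions",),
    "ssa": ("exposures", "events"),
    "simulate": (),
}


class ConfigError(ValueError):
    """The study configuration fails schema validation."""


@dataclass
class StudyConfig:
    study: str
    window: StudyWindow
    inputs: dict[str, str]
    params: dict[str, Any]

    @classmethod
    def from_mapping(cls, doc: dict[str, Any], base_dir: Path | None = None) -> "StudyConfig":
        if not isinstance(doc, dict):
            raise ConfigError("config document must be a mapping")
        study = doc.get("study")
        if study not in STUDY_KINDS:
            raise ConfigError(f"study must be one of {STUDY_KINDS}, got {study!r}")
        wdoc = doc.get("window")
        if not isinstance(wdoc, dict):
            raise ConfigError("config requires a 'window' mapping")
        try:
            window = StudyWindow(
                **{k: _as_date(wdoc[k]) for k in ("data_start", "run_in_end", "analysis_start", "analysis_end")}
            )
        except KeyError as exc:
            raise ConfigError(f"window missing field {exc}") from None
        except ValueError as exc:
            raise ConfigError(str(exc)) from None
        inputs = dict(doc.get("inputs") or {})
        if base_dir is not None:
            inputs = {k: str((base_dir / v)) if not os.path.isabs(v) else v for k, v in inputs.items()}
        missing = [k for k in _REQUIRED_INPUTS[study] if k not in inputs]
        if missing:
            raise ConfigError(f"study {study!r} requires input path(s) {missing}")
        params = dict(doc.get("params") or {})
        return cls(study=study, window=window, inputs=inputs, params=params)

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        with open(path) as fh:
            doc = yaml.safe_load(fh)  # YAML is a JSON superset; one loader covers both
        return cls.from_mapping(doc, base_dir=path.parent)


def _as_date(v: Any) -> date:
    if isinstance(v, date):
        return v
    return date.fromisoformat(str(v))


def _atomic_write_text(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _write_report(out_dir: Path, name: str, payload: dict[str, Any]) -> Path:
    path = out_dir / name
    _atomic_write_text(path, json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def _write_table(out_dir: Path, name: str, frame) -> Path:
    path = out_dir / name
    _atomic_write_text(path, frame.to_csv(sep="\t", index=False))
    return path


def run_study(cfg: StudyConfig, out_dir: str | Path, seed: int | None = None) -> dict[str, Path]:
    """Execute the configured pipeline; returns the written file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    runner = {
        "overuse": _run_overuse,
        "cumulative_dose": _run_cumdose,
        "duration_cohorts": _run_duration,
        "ssa": _run_ssa,
        "simulate": _run_simulate,
    }[cfg.study]
    log.info("running study kind %s", cfg.study)
    return runner(cfg, out_dir, seed)


def _echo(cfg: StudyConfig, seed: int | None) -> dict[str, Any]:
    w = cfg.window
    return {
        "study": cfg.study,
        "window": {
            "data_start": w.data_start.isoformat(),
            "run_in_end": w.run_in_end.isoformat(),
            "analysis_start": w.analysis_start.isoformat(),
            "analysis_end": w.analysis_end.isoformat(),
        },
        "inputs": cfg.inputs,
        "params": {k: v for k, v in sorted(cfg.params.items())},
        "seed": seed,
    }


def _run_overuse(cfg: StudyConfig, out_dir: Path, seed) -> dict[str, Path]:
    rx = cio.read_prescriptions(cfg.inputs["prescriptions"])
    table = DoseEquivalenceTable.from_csv(cfg.inputs["dose_table"])
    basis = cfg.params.get("basis", "single_dose")
    res = OveruseStudy(rx, table).fit(basis=basis)
    log.info("overuse: %d patients, %d flagged", res.n_patients, res.n_flagged)
    paths = {
        "table": _write_table(out_dir, "overuse_patients.tsv", res.to_frame()),
        "report": _write_report(
            out_dir,
            "overuse_report.json",
            {
                "config": _echo(cfg, seed),
                "n_patients": res.n_patients,
                "n_flagged": res.n_flagged,
                "prevalence": res.prevalence,
                "basis": basis,
            },
        ),
    }
    return paths


def _run_cumdose(cfg: StudyConfig, out_dir: Path, seed) -> dict[str, Path]:
    rx = cio.read_prescriptions(cfg.inputs["prescriptions"])
    bin_width = float(cfg.params.get("bin_width", 10_000.0))
    res = CumulativeDoseStudy(rx).fit(bin_width=bin_width)
    payload = {
        "config": _echo(cfg, seed),
        "stats": res.stats.as_dict() if res.stats else None,
        "histogram": [
            {"lower": b.lower, "upper": b.upper, "count": b.count} for b in res.histogram
        ],
    }
    return {
        "table": _write_table(out_dir, "cumulative_dose_patients.tsv", res.to_frame()),
        "report": _write_report(out_dir, "cumulative_dose_report.json", payload),
    }


def _run_duration(cfg: StudyConfig, out_dir: Path, seed) -> dict[str, Path]:
    rx = cio.read_prescriptions(cfg.inputs["prescriptions"])
    res = DurationStudy(rx, cfg.window).fit()
    payload = {
        "config": _echo(cfg, seed),
        "n_patients": len(res.summaries),
        "n_excluded_run_in": res.n_excluded,
        "cohorts": {
            str(c): {
                "cumulative_days": s.as_dict(),
                "daily_dose": res.cohort_stats("daily_dose_per_patient")[c].as_dict(),
            }
            for c, s in res.cohort_stats("cumulative_days").items()
        },
    }
    log.info(
        "duration: %d patients, %d run-in excluded, %d cohorts",
        len(res.summaries),
        res.n_excluded,
        len(res.cohorts()),
    )
    return {
        "table": _write_table(out_dir, "duration_patients.tsv", res.to_frame()),
        "report": _write_report(out_dir, "duration_report.json", payload),
    }


def _run_ssa(cfg: StudyConfig, out_dir: Path, seed) -> dict[str, Path]:
    exposures = cio.read_prescriptions(cfg.inputs["exposures"])
    events = cio.read_clinical_events(cfg.inputs["events"])
    routes = cfg.params.get("routes")
    route_set = {Route(r) for r in routes} if routes else None
    model = SequenceSymmetry(
        exposures,
        events,
        cfg.window,
        route=route_set,
        max_gap=int(cfg.params.get("max_gap", 90)),
    )
    res = model.fit(
        alpha=float(cfg.params.get("alpha", 0.05)),
        restricted_nesr=bool(cfg.params.get("restricted_nesr", True)),
        ci_method=cfg.params.get("ci_method", "clopper_pearson"),
    )
    r = res.result
    for k, v in r.attrition.items():
        log.info("ssa attrition %s = %d", k, v)
    import pandas as pd

    table = pd.DataFrame(
        [
            {
                "total_patients": r.attrition["analyzed"],
                "n_exposure_first": r.n_exposure_first,
                "n_outcome_first": r.n_outcome_first,
                "csr": r.csr,
                "nesr": r.nesr,
                "asr": r.asr,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
            }
        ]
    )
    payload = {
        "config": _echo(cfg, seed),
        "attrition": r.attrition,
        "n_exposure_first": r.n_exposure_first,
        "n_outcome_first": r.n_outcome_first,
        "csr": _jsonable(r.csr),
        "nesr": _jsonable(r.nesr),
        "asr": _jsonable(r.asr),
        "ci_low": _jsonable(r.ci_low),
        "ci_high": _jsonable(r.ci_high),
        "alpha": r.alpha,
    }
    return {
        "table": _write_table(out_dir, "ssa_result.tsv", table),
        "report": _write_report(out_dir, "ssa_report.json", payload),
    }


def _jsonable(x):
    if x is None:
        return None
    x = float(x)
    if x != x:
        return "nan"
    if x in (float("inf"), float("-inf")):
        return "inf" if x > 0 else "-inf"
    return x


def _run_simulate(cfg: StudyConfig, out_dir: Path, seed) -> dict[str, Path]:
    mode = cfg.params.get("mode", "utilization")
    rng_seed = int(seed if seed is not None else cfg.params.get("seed", 0))
    paths: dict[str, Path] = {}
    if mode == "utilization":
        sim = UtilizationSimConfig(
            n_patients=int(cfg.params.get("n_patients", 1000)),
            window=cfg.window,
            rx_rate_per_month=float(cfg.params.get("rx_rate_per_month", 0.6)),
            overuse_fraction=float(cfg.params.get("overuse_fraction", 0.05)),
            overuse_intensity=float(cfg.params.get("overuse_intensity", 5.0)),
            rng_seed=rng_seed,
        )
        records = simulate_prescriptions(sim)
        prx = out_dir / "prescriptions.csv"
        _atomic_write_text(prx, cio.prescriptions_to_frame(records).to_csv(index=False))
        dt = out_dir / "dose_table.csv"
        triptan_dose_table().to_csv(dt)
        paths.update(prescriptions=prx, dose_table=dt)
        log.info("simulated %d prescriptions for %d patients", len(records), sim.n_patients)
    elif mode == "ssa":
        sim = SsaSimConfig(
            n_patients=int(cfg.params.get("n_patients", 2000)),
            window=cfg.window,
            exposure_p_start=float(cfg.params.get("exposure_p_start", 0.001)),
            exposure_p_end=float(cfg.params.get("exposure_p_end", 0.001)),
            outcome_daily_p=float(cfg.params.get("outcome_daily_p", 0.0025)),
            effect=float(cfg.params.get("effect", 1.0)),
            risk_window_days=int(cfg.params.get("risk_window_days", 30)),
            rng_seed=rng_seed,
        )
        exposures, events = simulate_exposure_outcome(sim)
        pex = out_dir / "exposures.csv"
        pev = out_dir / "events.csv"
        _atomic_write_text(pex, cio.prescriptions_to_frame(exposures).to_csv(index=False))
        _atomic_write_text(pev, cio.events_to_frame(events).to_csv(index=False))
        paths.update(exposures=pex, events=pev)
        log.info("simulated %d exposures / %d events", len(exposures), len(events))
    else:
        raise ConfigError(f"simulate mode must be 'utilization' or 'ssa', got {mode!r}")
    paths["report"] = _write_report(
        out_dir, "simulate_config.json", {"config": _echo(cfg, rng_seed), "mode": mode}
    )
    return paths
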