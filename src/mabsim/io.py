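"""YAML configuration loading/validation and CSV readers/writers.

A run configuration has sections ``physiology``, ``drug``, ``tmdd``,
``disease``, ``regimen``, ``population``, ``solver`` plus the scalar
``weight_kg``.  Absent optional keys take package defaults; unknown keys
are rejected by name (typo safety).  ``resolve_config`` returns the
fully-resolved dictionary so a config echo written next to outputs
round-trips to an identical configuration.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError, InvalidArgumentError
from .estimation import ObservedSeries
from .parameters import (REFERENCE_WEIGHT_KG, DiseaseParameters, DoseEvent,
                         DrugParameters, PhysiologyParameters, TMDDParameters)
from .population import DEFAULT_VARIABILITY, TrialDesign, VariabilitySpec
from .synthetic import make_regimen

# YAML key -> dataclass field for the tmdd section (units in the key names)
_TMDD_KEYS = {"km_uM": "km", "kint_per_h": "kint", "kdeg_per_h": "kdeg",
              "rmax_uM": "rmax", "ksyn_uM_per_h": "ksyn",
              "target_compartment": "target_compartment"}
_DISEASE_KEYS = {"y0": "y0", "yss": "yss", "tp_h": "tp_h",
                 "drive_mode": "drive_mode"}
_DOSE_KEYS = {"start_time": "start_time", "dose": "dose", "per_kg": "per_kg",
              "route": "route", "infusion_duration": "infusion_duration",
              "ka": "ka", "f": "f"}

_SOLVER_DEFAULTS = {"t_end": 2000.0, "output_step": 1.0,
                    "rtol": 1e-8, "atol": 1e-12, "method": "LSODA"}


@dataclass
class RunConfig:
    """Validated, fully-resolved view of one run configuration."""

    phys: PhysiologyParameters
    drug: DrugParameters
    tmdd: TMDDParameters | None
    disease: DiseaseParameters | None
    doses: list[DoseEvent]
    design: TrialDesign
    variability: tuple[VariabilitySpec, ...]
    weight_cv_percent: float
    report_metric: str
    weight_kg: float
    t_end: float
    output_step: float
    rtol: float
    atol: float
    method: str


def _check_keys(section: str, given: dict, allowed) -> None:
    unknown = set(given) - set(allowed)
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in section {section!r}; "
            f"allowed: {sorted(allowed)}")


def _build(section: str, cls, given: dict, keymap: dict | None = None):
    keymap = keymap or {f.name: f.name for f in dataclasses.fields(cls)}
    _check_keys(section, given, keymap)
    kwargs = {keymap[k]: v for k, v in given.items()}
    try:
        return cls(**kwargs)
    except (InvalidArgumentError, ConfigurationError) as exc:
        raise ConfigurationError(f"section {section!r}: {exc}") from exc


def resolve_config(raw: dict) -> RunConfig:
    """Validate a raw config mapping and fill in all defaults."""
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    _check_keys("<root>", raw, {"physiology", "drug", "tmdd", "disease",
                                "regimen", "population", "solver",
                                "weight_kg"})

    phys = _build("physiology", PhysiologyParameters,
                  raw.get("physiology") or {})
    drug = _build("drug", DrugParameters, raw.get("drug") or {})

    tmdd_raw = dict(raw.get("tmdd") or {})
    report_metric = tmdd_raw.pop("report_metric", "total")
    if report_metric not in ("total", "free"):
        raise ConfigurationError(
            f"tmdd.report_metric must be 'total' or 'free', got {report_metric!r}")
    tmdd_enabled = tmdd_raw.pop("enabled", True)
    tmdd = (_build("tmdd", TMDDParameters, tmdd_raw, _TMDD_KEYS)
            if tmdd_enabled else None)

    dis_raw = dict(raw.get("disease") or {})
    dis_enabled = dis_raw.pop("enabled", True)
    disease = (_build("disease", DiseaseParameters, dis_raw, _DISEASE_KEYS)
               if dis_enabled else None)

    reg = dict(raw.get("regimen") or {})
    _check_keys("regimen", reg, {"name", "n_weeks", "infusion_duration",
                                 "events"})
    if "events" in reg and "name" in reg:
        raise ConfigurationError("regimen: give either 'name' or 'events'")
    if "events" in reg:
        doses = [_build(f"regimen.events[{i}]", DoseEvent, e, _DOSE_KEYS)
                 for i, e in enumerate(reg["events"])]
    else:
        name = reg.get("name", "single_1")
        doses = make_regimen(name, n_weeks=int(reg.get("n_weeks", 4)),
                             infusion_duration=float(
                                 reg.get("infusion_duration", 1.0)))

    pop = dict(raw.get("population") or {})
    _check_keys("population", pop, {"n_trials", "n_subjects", "seed",
                                    "weight_cv_percent", "variability",
                                    "age_range", "proportion_female"})
    var_raw = pop.get("variability")
    if var_raw is None:
        variability = DEFAULT_VARIABILITY
    else:
        variability = tuple(
            _build(f"population.variability[{i}]", VariabilitySpec, v)
            for i, v in enumerate(var_raw))
    design = TrialDesign(
        n_trials=int(pop.get("n_trials", 5)),
        n_subjects_per_trial=int(pop.get("n_subjects", 100)),
        age_range=tuple(pop.get("age_range", (25.0, 50.0))),
        proportion_female=float(pop.get("proportion_female", 0.5)),
        seed=int(pop.get("seed", 0)))

    solver = dict(raw.get("solver") or {})
    _check_keys("solver", solver, _SOLVER_DEFAULTS)
    sv = {**_SOLVER_DEFAULTS, **solver}

    for d in doses:
        if d.start_time > sv["t_end"]:
            raise ConfigurationError(
                f"dose at t={d.start_time} h lies beyond solver.t_end="
                f"{sv['t_end']} h")

    return RunConfig(
        phys=phys, drug=drug, tmdd=tmdd, disease=disease, doses=doses,
        design=design, variability=variability,
        weight_cv_percent=float(pop.get("weight_cv_percent", 0.0)),
        report_metric=report_metric,
        weight_kg=float(raw.get("weight_kg", REFERENCE_WEIGHT_KG)),
        t_end=float(sv["t_end"]), output_step=float(sv["output_step"]),
        rtol=float(sv["rtol"]), atol=float(sv["atol"]),
        method=str(sv["method"]))


def config_to_dict(cfg: RunConfig) -> dict:
    """Fully-resolved mapping that reloads to an identical RunConfig."""
    inv_tmdd = {v: k for k, v in _TMDD_KEYS.items()}
    out = {
        "physiology": dataclasses.asdict(cfg.phys),
        "drug": dataclasses.asdict(cfg.drug),
        "weight_kg": cfg.weight_kg,
        "regimen": {"events": [dataclasses.asdict(d) for d in cfg.doses]},
        "population": {
            "n_trials": cfg.design.n_trials,
            "n_subjects": cfg.design.n_subjects_per_trial,
            "age_range": list(cfg.design.age_range),
            "proportion_female": cfg.design.proportion_female,
            "seed": cfg.design.seed,
            "weight_cv_percent": cfg.weight_cv_percent,
            "variability": [dataclasses.asdict(v) for v in cfg.variability],
        },
        "solver": {"t_end": cfg.t_end, "output_step": cfg.output_step,
                   "rtol": cfg.rtol, "atol": cfg.atol, "method": cfg.method},
    }
    if cfg.tmdd is None:
        out["tmdd"] = {"enabled": False}
    else:
        t = {inv_tmdd[k]: v for k, v in dataclasses.asdict(cfg.tmdd).items()}
        t["report_metric"] = cfg.report_metric
        out["tmdd"] = t
    if cfg.disease is None:
        out["disease"] = {"enabled": False}
    else:
        out["disease"] = dataclasses.asdict(cfg.disease)
    return out


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    return resolve_config(raw or {})


def write_config_echo(cfg: RunConfig, path) -> None:
    """Write the fully-resolved config next to the outputs."""
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)


def write_results(result, path) -> None:
    """Write a SimulationResult as the fixed-dialect CSV (>=15 sig digits)."""
    result.to_dataframe().to_csv(path, index=False, float_format="%.15g")


def read_results(path):
    """Read back a results CSV written by :func:`write_results`."""
    import pandas as pd
    return pd.read_csv(path)


def read_observed(path, kind: str = "pasi") -> ObservedSeries:
    """Read an observed series CSV (time_h, value[, weight]).

    Malformed rows raise with their line number; times must be strictly
    increasing and the data section non-empty.
    """
    path = Path(path)
    times, values, weights = [], [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise InvalidArgumentError(f"{path}: file is empty") from None
        header = [h.strip() for h in header]
        if not header or header[0] != "time_h" or len(header) < 2:
            raise InvalidArgumentError(
                f"{path}: header must start with 'time_h,value', got {header}")
        has_weight = len(header) >= 3 and header[2] == "weight"
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                times.append(float(row[0]))
                values.append(float(row[1]))
                if has_weight:
                    weights.append(float(row[2]))
            except (ValueError, IndexError) as exc:
                raise InvalidArgumentError(
                    f"{path}: malformed row at line {lineno}: {row}") from exc
    if not times:
        raise InvalidArgumentError(f"{path}: data section is empty")
    try:
        return ObservedSeries(
            times=np.asarray(times), values=np.asarray(values), kind=kind,
            weights=np.asarray(weights) if has_weight else None)
    except InvalidArgumentError as exc:
        raise InvalidArgumentError(f"{path}: {exc}") from exc


def write_observed(series: ObservedSeries, path) -> None:
    """Write an observed series in the dialect read_observed expects."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        if series.weights is not None:
            w.writerow(["time_h", "value", "weight"])
            for t, v, wt in zip(series.times, series.values, series.weights):
                w.writerow([f"{t:.15g}", f"{v:.15g}", f"{wt:.15g}"])
        else:
            w.writerow(["time_h", "value"])
            for t, v in zip(series.times, series.values):
                w.writerow([f"{t:.15g}", f"{v:.15g}"])
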