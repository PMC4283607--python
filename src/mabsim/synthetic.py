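"""Study-shaped synthetic inputs: dosing regimens and noisy observations.

The named regimens reproduce the published efalizumab trial schedules
(single IV doses of 1, 3 and 10 mg/kg; the escalating multiple-dose arm
0.3/0.4/0.6 mg/kg in weeks 1-3 then 1 mg/kg weekly for four weeks; flat
1 mg/kg weekly).  All doses are 1-h IV infusions unless overridden.

Observation generators interpolate a simulated truth and add a
configurable noise model, standing in for digitized clinical mean
series so that the estimation pipeline can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InvalidArgumentError
from .estimation import ObservedSeries
from .parameters import DoseEvent
from .pbpk import SimulationResult

WEEK_H = 168.0

REGIMEN_NAMES = ("single_1", "single_3", "single_10",
                 "gottlieb_escalating", "weekly_1")

#: default dense post-dose PK sampling offsets (h) within a dosing interval
PK_SAMPLE_OFFSETS_H = (0.5, 1.0, 2.0, 4.0, 8.0, 24.0, 48.0, 96.0, 168.0)


@dataclass(frozen=True)
class NoiseModel:
    """Observation-noise description.

    ``proportional`` applies a mean-1 lognormal multiplier with the given
    CV; ``additive`` adds zero-mean gaussian noise of standard deviation
    ``sd`` (truncated at zero); ``combined`` applies both.
    """

    kind: str = "proportional"
    cv: float = 0.05
    sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("proportional", "additive", "combined"):
            raise ConfigurationError(
                f"unknown noise kind {self.kind!r}")
        if self.cv < 0 or self.sd < 0:
            raise InvalidArgumentError("cv and sd must be >= 0")


def make_regimen(name: str, n_weeks: int = 4,
                 infusion_duration: float = 1.0) -> list[DoseEvent]:
    """Return the dose-event list for a named published regimen.

    ``n_weeks`` applies to ``weekly_1`` only.  All events are per-kg 1-h
    IV infusions (duration configurable).
    """
    def ev(t: float, mg_kg: float) -> DoseEvent:
        return DoseEvent(start_time=t, dose=mg_kg, per_kg=True,
                         route="iv_infusion",
                         infusion_duration=infusion_duration)

    if name == "single_1":
        return [ev(0.0, 1.0)]
    if name == "single_3":
        return [ev(0.0, 3.0)]
    if name == "single_10":
        return [ev(0.0, 10.0)]
    if name == "gottlieb_escalating":
        weekly = [0.3, 0.4, 0.6, 1.0, 1.0, 1.0, 1.0]
        return [ev(i * WEEK_H, d) for i, d in enumerate(weekly)]
    if name == "weekly_1":
        if n_weeks < 1:
            raise InvalidArgumentError("n_weeks must be >= 1")
        return [ev(i * WEEK_H, 1.0) for i in range(n_weeks)]
    raise ConfigurationError(
        f"unknown regimen {name!r}; expected one of {REGIMEN_NAMES}")


def weekly_sample_times(n_weeks: int, include_zero: bool = True) -> np.ndarray:
    """Weekly assessment grid in hours (PASI scores are scored weekly)."""
    start = 0 if include_zero else 1
    return np.arange(start, n_weeks + 1) * WEEK_H


def generate_observations(truth: SimulationResult, sample_times,
                          noise: NoiseModel, n_replicates: int = 1,
                          series: str = "pasi") -> list[ObservedSeries]:
    """Sample noisy replicate observation series from a simulated truth.

    The requested ``series`` (``pasi`` or ``plasma_conc``, the latter in
    µg/mL) is interpolated at ``sample_times`` and perturbed per the
    noise model; values never go negative (additive noise is truncated
    at zero and the truncation rate is recorded on each series'
    ``truncated_fraction``).  Reproducible for a fixed ``noise.seed``.
    """
    sample_times = np.asarray(sample_times, dtype=float)
    if sample_times.size == 0:
        raise InvalidArgumentError("sample_times must be non-empty")
    if np.any(sample_times < truth.time_h[0]) or \
            np.any(sample_times > truth.time_h[-1]):
        raise InvalidArgumentError(
            "sample_times must lie within the simulated time range")
    if n_replicates < 1:
        raise InvalidArgumentError("n_replicates must be >= 1")
    if series == "pasi":
        base = np.interp(sample_times, truth.time_h, truth.pasi)
        kind = "pasi"
    elif series == "plasma_conc":
        base = np.interp(sample_times, truth.time_h, truth.cp_ex_ug_per_ml)
        kind = "plasma_conc"
    else:
        raise ConfigurationError(
            f"unknown series {series!r}; expected 'pasi' or 'plasma_conc'")

    rng = np.random.default_rng(noise.seed)
    out = []
    for _ in range(n_replicates):
        values = base.copy()
        if noise.kind in ("proportional", "combined") and noise.cv > 0:
            sigma = np.sqrt(np.log1p(noise.cv ** 2))
            values = values * rng.lognormal(-0.5 * sigma ** 2, sigma,
                                            size=values.shape)
        n_trunc = 0
        if noise.kind in ("additive", "combined") and noise.sd > 0:
            values = values + rng.normal(0.0, noise.sd, size=values.shape)
            n_trunc = int(np.sum(values < 0))
            values = np.maximum(values, 0.0)
        s = ObservedSeries(times=sample_times.copy(), values=values,
                           kind=kind)
        s.truncated_fraction = n_trunc / values.size
        out.append(s)
    return out
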