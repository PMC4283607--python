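"""Asymptotic disease-progression model for PASI scores.

Untreated patients sit at the baseline score Y0.  Treatment engages the
target; the engagement drive E in [0, 1] pulls the attractor of a
first-order tracking ODE from Y0 toward the treated asymptote Yss:

    dY/dt = (ln 2 / Tp) * (Ytarget(E) - Y),   Ytarget = Y0 - (Y0 - Yss)*E

Under constant full drive (E = 1) the solution is exactly the asymptotic
progression curve Y(t) = Yss + (Y0 - Yss)*2^(-t/Tp); with no drug (E = 0)
the score stays at baseline.  Tp is the half-life of progression.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import ConfigurationError, InvalidArgumentError
from .parameters import DiseaseParameters

LN2 = math.log(2.0)


def pasi_closed_form(t, p: DiseaseParameters):
    """PASI score at time ``t`` (h) under constant full engagement.

    Y(t) = Yss + (Y0 - Yss) * 2^(-t/Tp).  Accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidArgumentError("t must be >= 0")
    out = p.yss + (p.y0 - p.yss) * np.exp2(-t / p.tp_h)
    return float(out) if out.ndim == 0 else out


def occupancy_drive(rfree: float, rbound: float, rtot: float, rmax: float,
                    mode: str = "free_suppression") -> float:
    """Map target engagement to the progression drive E in [0, 1].

    ``free_suppression``: E = 1 - Rfree/Rmax, clamped to [0, 1] — how far
    the free target has been pushed below its baseline.  ``bound_fraction``:
    E = Rbound/Rtot, the occupied fraction of the current pool (0 when the
    pool is empty).
    """
    for name, v in (("rfree", rfree), ("rbound", rbound), ("rtot", rtot)):
        if not math.isfinite(v) or v < 0:
            raise InvalidArgumentError(f"{name} must be finite and >= 0, got {v!r}")
    if rmax <= 0:
        raise InvalidArgumentError(f"rmax must be > 0, got {rmax!r}")
    if mode == "free_suppression":
        return min(max(1.0 - rfree / rmax, 0.0), 1.0)
    if mode == "bound_fraction":
        return rbound / rtot if rtot > 0 else 0.0
    raise ConfigurationError(
        f"unknown drive mode {mode!r}; expected 'free_suppression' or 'bound_fraction'")


def pasi_rate(y: float, e: float, p: DiseaseParameters) -> float:
    """dY/dt for the tracking ODE at score ``y`` and drive ``e``."""
    if not math.isfinite(y) or y < 0:
        raise InvalidArgumentError(f"y must be finite and >= 0, got {y!r}")
    if not 0.0 <= e <= 1.0:
        raise InvalidArgumentError(f"e must be in [0, 1], got {e!r}")
    y_target = p.y0 - (p.y0 - p.yss) * e
    return LN2 / p.tp_h * (y_target - y)
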