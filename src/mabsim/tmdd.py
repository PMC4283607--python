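"""Michaelis-Menten approximation of target-mediated drug disposition.

The full kinetic TMDD scheme (kon/koff binding, complex internalization
at kint) is reduced to a quasi-steady-state form governed by the constant
Km: drug is eliminated through the target at rate kint*Rtot*C/(Km+C) and
the total target pool turns over by zero-order synthesis (ksyn) and
first-order degradation (kdeg), with the drug-occupied fraction turning
over at kint instead of kdeg.  Under sustained saturating drug the total
target settles at ksyn/kint, i.e. 100*kdeg/kint percent of baseline.
"""

from __future__ import annotations

import math

from .errors import InvalidArgumentError
from .parameters import TMDDParameters


def _check_nonneg(**kw: float) -> None:
    for name, v in kw.items():
        if not math.isfinite(v) or v < 0:
            raise InvalidArgumentError(f"{name} must be finite and >= 0, got {v!r}")


def mm_elimination_rate(c: float, rtot: float, p: TMDDParameters) -> float:
    """Drug elimination rate through the target (µM/h).

    ``c`` is the free drug concentration in the target compartment and
    ``rtot`` the current total target concentration (both µM).
    """
    _check_nonneg(c=c, rtot=rtot)
    return p.kint * rtot * c / (p.km + c)


def target_turnover_rate(c: float, rtot: float, p: TMDDParameters) -> float:
    """d(Rtot)/dt (µM/h): synthesis, degradation and complex internalization.

    The bound fraction c/(Km+c) of the target pool is removed at kint
    rather than kdeg, so the net rate is
    ksyn - kdeg*Rtot - (kint - kdeg)*Rtot*c/(Km + c).
    """
    _check_nonneg(c=c, rtot=rtot)
    return p.ksyn - p.kdeg * rtot - (p.kint - p.kdeg) * rtot * c / (p.km + c)


def partition_target(c: float, rtot: float, km: float) -> tuple[float, float]:
    """Split total target into (free, drug-bound) at quasi-steady state.

    Rbound = Rtot*c/(Km+c); Rfree is the remainder, so the two always sum
    to Rtot exactly.
    """
    _check_nonneg(c=c, rtot=rtot)
    if km <= 0:
        raise InvalidArgumentError(f"km must be > 0, got {km!r}")
    rbound = rtot * c / (km + c)
    return rtot - rbound, rbound


def suppression_percent(rx: float, rmax: float) -> float:
    """Express a target concentration as percent of its drug-free baseline."""
    if not math.isfinite(rmax) or rmax <= 0:
        raise InvalidArgumentError(f"rmax must be finite and > 0, got {rmax!r}")
    _check_nonneg(rx=rx)
    return 100.0 * rx / rmax


def saturating_plateau_percent(p: TMDDParameters) -> float:
    """Analytic steady-state total target under saturating drug, % of baseline.

    With c >> Km the turnover equation has the fixed point ksyn/kint; as a
    percent of the baseline rmax (= ksyn/kdeg when ksyn is derived) this
    is 100*ksyn/(kint*rmax) = 100*kdeg/kint for the derived default.
    """
    return 100.0 * p.ksyn / (p.kint * p.rmax)
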