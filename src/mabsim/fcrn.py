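"""Competitive FcRn binding equilibrium in the endosome.

Exogenous mAb and endogenous IgG compete for a fixed pool of FcRn under
rapid equilibrium.  Given total endosomal concentrations of the two IgG
species, the free-receptor concentration F solves

    F + Ct_ex*F/(KD_ex + F) + Ct_en*F/(KD_en + F) = FcRn_total

and each bound species is Ct_x*F/(KD_x + F).  With equal dissociation
constants (the default: no printed evidence distinguishes them) the
problem collapses to a quadratic solved in closed form; otherwise the
cubic is solved and Newton-polished.  Conservation of receptor and of
each IgG species holds to ~1e-15 relative.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np

from .errors import InvalidArgumentError, NumericalError


class FcRnEquilibrium(NamedTuple):
    free_ex: float
    bound_ex: float
    free_en: float
    bound_en: float
    free_fcrn: float


def _free_receptor(ct_ex: float, ct_en: float, r_tot: float,
                   kd_ex: float, kd_en: float) -> float:
    """Free FcRn concentration at equilibrium (µM)."""
    if r_tot == 0.0:
        return 0.0
    if kd_ex == kd_en or ct_ex == 0.0 or ct_en == 0.0:
        # single effective ligand pool -> quadratic
        if ct_ex == 0.0 and ct_en > 0.0:
            kd, ct = kd_en, ct_en
        else:
            kd, ct = kd_ex, ct_ex + ct_en
        if ct == 0.0:
            return r_tot
        # F^2 + b F - kd r_tot = 0, b = kd + ct - r_tot; stable form
        b = kd + ct - r_tot
        disc = math.sqrt(b * b + 4.0 * kd * r_tot)
        free = (disc - b) / 2.0 if b <= 0 else 2.0 * kd * r_tot / (disc + b)
    else:
        # distinct KDs -> monic cubic in F
        a2 = kd_ex + kd_en + ct_ex + ct_en - r_tot
        a1 = (kd_ex * kd_en + ct_ex * kd_en + ct_en * kd_ex
              - r_tot * (kd_ex + kd_en))
        a0 = -r_tot * kd_ex * kd_en
        roots = np.roots([1.0, a2, a1, a0])
        cands = [r.real for r in roots
                 if abs(r.imag) < 1e-9 * max(1.0, abs(r.real))
                 and -1e-12 * r_tot <= r.real <= r_tot * (1 + 1e-12)]
        if not cands:
            raise NumericalError(
                "no physical root for the FcRn equilibrium "
                f"(inputs: {ct_ex}, {ct_en}, {r_tot}, {kd_ex}, {kd_en})")
        free = min(max(min(cands, key=lambda f: abs(
            f + ct_ex * f / (kd_ex + f) + ct_en * f / (kd_en + f) - r_tot)),
            0.0), r_tot)
    # Newton polish on g(F) = F + sum Ct F/(KD+F) - r_tot (monotone)
    for _ in range(4):
        gex = ct_ex * free / (kd_ex + free)
        gen = ct_en * free / (kd_en + free)
        g = free + gex + gen - r_tot
        dg = (1.0 + ct_ex * kd_ex / (kd_ex + free) ** 2
              + ct_en * kd_en / (kd_en + free) ** 2)
        step = g / dg
        new = free - step
        if new < 0.0:
            new = free / 2.0
        free = new
        if abs(step) <= 1e-15 * max(free, 1e-300):
            break
    return free


def solve_fcrn_equilibrium(ce_tot_ex: float, ce_tot_en: float,
                           fcrn_total: float, kd_ex: float,
                           kd_en: float) -> FcRnEquilibrium:
    """Partition endosomal IgG species over free/FcRn-bound states.

    Parameters are total endosomal concentrations (µM) of the exogenous
    mAb and endogenous IgG, the total FcRn concentration and the two
    dissociation constants.  Returns free/bound concentrations of each
    species plus free receptor; each species and the receptor pool are
    conserved to near machine precision.
    """
    for name, v in (("ce_tot_ex", ce_tot_ex), ("ce_tot_en", ce_tot_en),
                    ("fcrn_total", fcrn_total)):
        if not math.isfinite(v) or v < 0:
            raise InvalidArgumentError(f"{name} must be finite and >= 0, got {v!r}")
    for name, v in (("kd_ex", kd_ex), ("kd_en", kd_en)):
        if not math.isfinite(v) or v <= 0:
            raise InvalidArgumentError(f"{name} must be finite and > 0, got {v!r}")

    free = _free_receptor(ce_tot_ex, ce_tot_en, fcrn_total, kd_ex, kd_en)
    bound_ex = ce_tot_ex * free / (kd_ex + free)
    bound_en = ce_tot_en * free / (kd_en + free)
    return FcRnEquilibrium(
        free_ex=ce_tot_ex - bound_ex,
        bound_ex=bound_ex,
        free_en=ce_tot_en - bound_en,
        bound_en=bound_en,
        free_fcrn=free,
    )
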