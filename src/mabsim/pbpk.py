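"""Lumped-tissue FcRn PBPK model: ODE system, simulation driver and NCA.

The model tracks exogenous mAb and endogenous IgG through three spaces of
a single lumped tissue — plasma (vascular), endosomal and interstitial.
Drug extravasates by convection through vascular pores (reflection
coefficient sigma_v) and returns with lymph (sigma_i).  Endothelial
pinocytosis takes both species into the endosome from the luminal and
abluminal sides (split by delta); there they compete for FcRn at rapid
equilibrium.  FcRn-bound IgG is recycled (fraction FR to plasma, the
rest transcytosed to interstitium) at rate krc, while unbound IgG is
catabolized with intrinsic clearance cl_cat.  Optionally the exogenous
mAb is also cleared through its pharmacological target (Michaelis-Menten
TMDD) and the resulting target engagement drives a PASI progression ODE.

State vector (concentrations in µM, amounts in µmol):

    0 cp_ex   plasma mAb            5 ce_en   endosomal total IgG
    1 ci_ex   interstitial mAb      6 rtot    total target
    2 ce_ex   endosomal total mAb   7 a_depot sc depot amount
    3 cp_en   plasma IgG            8 y       PASI score
    4 ci_en   interstitial IgG      9 a_cat   cumulative mAb catabolized
                                   10 a_tmdd  cumulative mAb via target
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import disease as _disease
from . import tmdd as _tmdd
from .errors import (CalibrationError, ConfigurationError, ExtrapolationError,
                     InvalidArgumentError, NumericalError)
from .fcrn import solve_fcrn_equilibrium
from .parameters import (REFERENCE_WEIGHT_KG, DiseaseParameters, DoseEvent,
                         DrugParameters, PhysiologyParameters, TMDDParameters)

N_STATES = 11
(I_CP_EX, I_CI_EX, I_CE_EX, I_CP_EN, I_CI_EN, I_CE_EN,
 I_RTOT, I_DEPOT, I_Y, I_ACAT, I_ATMDD) = range(N_STATES)


@dataclass
class SimulationResult:
    """Time grid plus state and derived trajectories of one simulation.

    Concentration series are in µM unless the name says otherwise; the
    mass-balance residual is |administered - (in system + eliminated)|
    relative to the administered amount (0 where nothing was dosed yet).
    """

    time_h: np.ndarray
    states: np.ndarray                 # (n_times, N_STATES)
    weight_kg: float
    administered_umol: np.ndarray
    rfree_uM: np.ndarray
    rbound_uM: np.ndarray
    rtot_pct_baseline: np.ndarray
    rfree_pct_baseline: np.ndarray
    occupancy_drive: np.ndarray
    cp_ex_ug_per_ml: np.ndarray
    massbal_residual: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time_h) <= 0):
            raise InvalidArgumentError("time grid must be strictly increasing")

    @property
    def cp_ex_uM(self) -> np.ndarray:
        return self.states[:, I_CP_EX]

    @property
    def pasi(self) -> np.ndarray:
        return self.states[:, I_Y]

    def to_dataframe(self) -> pd.DataFrame:
        s = self.states
        return pd.DataFrame({
            "time_h": self.time_h,
            "cp_ex_uM": s[:, I_CP_EX],
            "cp_ex_ug_per_ml": self.cp_ex_ug_per_ml,
            "ci_ex_uM": s[:, I_CI_EX],
            "ce_tot_ex_uM": s[:, I_CE_EX],
            "rtot_uM": s[:, I_RTOT],
            "rfree_uM": self.rfree_uM,
            "rtot_pct_baseline": self.rtot_pct_baseline,
            "rfree_pct_baseline": self.rfree_pct_baseline,
            "occupancy_drive": self.occupancy_drive,
            "pasi": s[:, I_Y],
            "massbal_residual": self.massbal_residual,
        })


def rhs(t: float, y: Sequence[float], phys: PhysiologyParameters,
        drug: DrugParameters, tmdd: TMDDParameters | None,
        dis: DiseaseParameters | None, in_en_umol_h: float,
        infusion_rate_umol_h: float = 0.0, ka: float = 0.0) -> np.ndarray:
    """Right-hand side of the coupled PBPK/TMDD/PD system.

    ``in_en_umol_h`` is the zero-order endogenous IgG synthesis rate and
    ``infusion_rate_umol_h`` the current IV infusion rate, constant
    within an integration segment (bolus additions and infusion on/off
    switching are segment boundaries in :func:`simulate`).  ``ka`` is the
    first-order release constant of the subcutaneous depot state.
    """
    cp_ex = max(y[I_CP_EX], 0.0)
    ci_ex = max(y[I_CI_EX], 0.0)
    ce_ex = max(y[I_CE_EX], 0.0)
    cp_en = max(y[I_CP_EN], 0.0)
    ci_en = max(y[I_CI_EN], 0.0)
    ce_en = max(y[I_CE_EN], 0.0)
    rtot = max(y[I_RTOT], 0.0)
    a_depot = max(y[I_DEPOT], 0.0)
    ysc = y[I_Y]

    a_lum = phys.delta / (1.0 + phys.delta)
    b_ablum = 1.0 / (1.0 + phys.delta)
    kup_ve = phys.kup * phys.ve
    l_out = phys.l_lymph * (1.0 - phys.sigma_v)
    l_ret = phys.l_lymph * (1.0 - phys.sigma_i)
    krc_ve = phys.krc * phys.ve

    eq = solve_fcrn_equilibrium(ce_ex, ce_en, phys.fcrn_total,
                                drug.kd_ex, drug.kd_en)

    dy = np.zeros(N_STATES)

    # exogenous mAb input: infusion plus sc depot release
    release = ka * a_depot
    dy[I_DEPOT] = -release
    in_ex = infusion_rate_umol_h + release

    dy[I_CP_EX] = (in_ex - l_out * cp_ex - kup_ve * a_lum * cp_ex
                   + phys.fr * krc_ve * eq.bound_ex + l_ret * ci_ex) / phys.vp
    dy[I_CE_EX] = (kup_ve * (a_lum * cp_ex + b_ablum * ci_ex)
                   - phys.cl_cat * eq.free_ex
                   - krc_ve * eq.bound_ex) / phys.ve
    dy[I_CI_EX] = (l_out * cp_ex - l_ret * ci_ex - kup_ve * b_ablum * ci_ex
                   + (1.0 - phys.fr) * krc_ve * eq.bound_ex) / phys.vi

    # endogenous IgG: zero-order synthesis into plasma, no TMDD
    dy[I_CP_EN] = (in_en_umol_h - l_out * cp_en - kup_ve * a_lum * cp_en
                   + phys.fr * krc_ve * eq.bound_en + l_ret * ci_en) / phys.vp
    dy[I_CE_EN] = (kup_ve * (a_lum * cp_en + b_ablum * ci_en)
                   - phys.cl_cat * eq.free_en
                   - krc_ve * eq.bound_en) / phys.ve
    dy[I_CI_EN] = (l_out * cp_en - l_ret * ci_en - kup_ve * b_ablum * ci_en
                   + (1.0 - phys.fr) * krc_ve * eq.bound_en) / phys.vi

    dy[I_ACAT] = phys.cl_cat * eq.free_ex

    # TMDD acts on the exogenous mAb only (the target binds the drug)
    if tmdd is not None:
        c_tgt = cp_ex if tmdd.target_compartment == "plasma" else ci_ex
        occ = c_tgt / (tmdd.km + c_tgt)
        mm_rate = tmdd.kint * rtot * occ
        dy[I_RTOT] = (tmdd.ksyn - tmdd.kdeg * rtot
                      - (tmdd.kint - tmdd.kdeg) * rtot * occ)
        if tmdd.target_compartment == "plasma":
            dy[I_CP_EX] -= mm_rate
            dy[I_ATMDD] = mm_rate * phys.vp
        else:
            dy[I_CI_EX] -= mm_rate
            dy[I_ATMDD] = mm_rate * phys.vi
        # disease progression driven by target engagement
        if dis is not None:
            rfree = rtot * (1.0 - occ)
            rbound = rtot * occ
            e = _disease.occupancy_drive(rfree, rbound, rtot, tmdd.rmax,
                                         dis.drive_mode)
            dy[I_Y] = (_disease.LN2 / dis.tp_h
                       * (dis.y0 - (dis.y0 - dis.yss) * e - ysc))
    return dy


def initialize_endogenous_steady_state(
        phys: PhysiologyParameters,
        drug: DrugParameters) -> tuple[float, np.ndarray]:
    """Endogenous synthesis rate and drug-free steady initial state.

    Solves for the zero-order plasma synthesis rate of endogenous IgG and
    the endosomal/interstitial steady levels such that the drug-free
    system holds plasma IgG at ``phys.igg_en_baseline``.  Returns
    ``(in_en_umol_h, y0)``.
    """
    if phys.igg_en_baseline <= 0:
        raise ConfigurationError("igg_en_baseline must be > 0")
    cp = phys.igg_en_baseline
    a_lum = phys.delta / (1.0 + phys.delta)
    b_ablum = 1.0 / (1.0 + phys.delta)
    kup_ve = phys.kup * phys.ve
    l_out = phys.l_lymph * (1.0 - phys.sigma_v)
    l_ret = phys.l_lymph * (1.0 - phys.sigma_i)
    krc_ve = phys.krc * phys.ve
    denom_i = l_ret + kup_ve * b_ablum

    def bound(ce: float) -> float:
        return solve_fcrn_equilibrium(0.0, ce, phys.fcrn_total,
                                      drug.kd_ex, drug.kd_en).bound_en

    def ci_of(ce: float) -> float:
        return (l_out * cp + (1.0 - phys.fr) * krc_ve * bound(ce)) / denom_i

    def g(ce: float) -> float:
        # endosomal balance: uptake - catabolism - recycling
        b = bound(ce)
        return (kup_ve * (a_lum * cp + b_ablum * ci_of(ce))
                - phys.cl_cat * (ce - b) - krc_ve * b)

    hi = 1.0
    while g(hi) > 0:
        hi *= 2.0
        if hi > 1e9:
            raise ConfigurationError(
                "no physical endogenous steady state (endosomal balance "
                "never closes); check cl_cat/krc/kup")
    ce = brentq(g, 0.0, hi, xtol=1e-14, rtol=8.9e-16)
    ci = ci_of(ce)
    in_en = (l_out * cp + kup_ve * a_lum * cp
             - phys.fr * krc_ve * bound(ce) - l_ret * ci)
    y0 = np.zeros(N_STATES)
    y0[I_CP_EN] = cp
    y0[I_CI_EN] = ci
    y0[I_CE_EN] = ce
    return in_en, y0


def administered_input(doses: Sequence[DoseEvent], weight_kg: float,
                       mw: float, t) -> np.ndarray:
    """Cumulative administered amount (µmol) at the times ``t``.

    For sc doses only the bioavailable fraction F*dose counts as input,
    since the non-absorbed remainder never enters the modelled system.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    total = np.zeros_like(t)
    for d in doses:
        amt = d.amount_umol(weight_kg, mw)
        if d.route == "iv_bolus":
            total += np.where(t >= d.start_time, amt, 0.0)
        elif d.route == "iv_infusion":
            frac = np.clip((t - d.start_time) / d.infusion_duration, 0.0, 1.0)
            total += amt * frac
        else:
            total += np.where(t >= d.start_time, amt * d.f, 0.0)
    return total


def simulate(phys: PhysiologyParameters, drug: DrugParameters,
             tmdd: TMDDParameters | None, dis: DiseaseParameters | None,
             doses: Sequence[DoseEvent], t_end: float,
             output_step: float = 1.0,
             weight_kg: float = REFERENCE_WEIGHT_KG,
             rtol: float = 1e-8, atol: float = 1e-12,
             method: str = "LSODA") -> SimulationResult:
    """Integrate the full system and return all trajectories.

    Dose starts and infusion stops are integration breakpoints; within a
    segment the infusion input is constant so the stiff solver sees a
    smooth right-hand side.  Instantaneous inputs (boluses, sc depot
    loads) are applied at the start of the segment they open, so output
    points at a dose time show the post-dose state.
    """
    if t_end <= 0:
        raise InvalidArgumentError(f"t_end must be > 0, got {t_end}")
    if output_step <= 0:
        raise InvalidArgumentError(f"output_step must be > 0, got {output_step}")
    for d in doses:
        if d.start_time > t_end:
            raise InvalidArgumentError(
                f"dose at t={d.start_time} h lies beyond t_end={t_end} h")

    in_en, y0 = initialize_endogenous_steady_state(phys, drug)
    if tmdd is not None:
        y0[I_RTOT] = tmdd.rmax
    if dis is not None:
        y0[I_Y] = dis.y0

    boluses, infusions, sc = [], [], []
    for d in doses:
        amt = d.amount_umol(weight_kg, drug.mw)
        if d.route == "iv_bolus":
            boluses.append((d.start_time, amt))
        elif d.route == "iv_infusion":
            infusions.append((d.start_time,
                              min(d.start_time + d.infusion_duration, t_end),
                              amt / d.infusion_duration))
        else:
            sc.append((d.start_time, amt * d.f, d.ka))
    if sc and len({s[2] for s in sc}) > 1:
        raise ConfigurationError("all sc doses in one regimen must share ka")
    ka = sc[0][2] if sc else 0.0

    breaks = {0.0, float(t_end)}
    breaks.update(tb for tb, _ in boluses if tb < t_end)
    breaks.update(ts for ts, _, _ in sc if ts < t_end)
    for t0, t1, _ in infusions:
        breaks.add(t0)
        breaks.add(t1)
    seg_edges = sorted(b for b in breaks if 0.0 <= b <= t_end)

    grid = np.arange(0.0, t_end + 0.5 * output_step, output_step)
    if grid[-1] > t_end:
        grid = grid[:-1]

    def apply_instant(yv: np.ndarray, tt: float) -> None:
        for tb, amt in boluses:
            if abs(tb - tt) < 1e-9:
                yv[I_CP_EX] += amt / phys.vp
        for ts, amt_f, _ in sc:
            if abs(ts - tt) < 1e-9:
                yv[I_DEPOT] += amt_f

    y = y0.copy()
    apply_instant(y, 0.0)
    times = [0.0]
    states = [y.copy()]

    for t0, t1 in zip(seg_edges[:-1], seg_edges[1:]):
        inf_rate = sum(r for (s, e, r) in infusions
                       if s <= t0 + 1e-12 and t1 <= e + 1e-12)
        interior = grid[(grid > t0 + 1e-9) & (grid < t1 - 1e-9)]
        t_eval = np.concatenate([interior, [t1]])
        sol = solve_ivp(rhs, (t0, t1), y, method=method, t_eval=t_eval,
                        rtol=rtol, atol=atol,
                        args=(phys, drug, tmdd, dis, in_en, inf_rate, ka))
        if not sol.success:
            raise NumericalError(
                f"ODE solver failed on [{t0}, {t1}] h: {sol.message}")
        y = sol.y[:, -1].copy()
        if t1 < t_end:
            apply_instant(y, t1)
        times.extend(sol.t[:-1])
        states.extend(sol.y.T[:-1])
        # the boundary point carries the post-dose state of the next segment
        times.append(t1)
        states.append(y.copy())

    time = np.asarray(times)
    st = np.maximum(np.vstack(states), 0.0)
    return _build_result(time, st, phys, drug, tmdd, doses, weight_kg)


def _build_result(time, states, phys, drug, tmdd, doses, weight_kg):
    n = len(time)
    cp_ex = states[:, I_CP_EX]
    ci_ex = states[:, I_CI_EX]
    rtot = states[:, I_RTOT]
    if tmdd is not None:
        c_tgt = cp_ex if tmdd.target_compartment == "plasma" else ci_ex
        rbound = rtot * c_tgt / (tmdd.km + c_tgt)
        rfree = rtot - rbound
        rtot_pct = 100.0 * rtot / tmdd.rmax
        rfree_pct = 100.0 * rfree / tmdd.rmax
        drive = np.clip(1.0 - rfree / tmdd.rmax, 0.0, 1.0)
    else:
        rbound = np.zeros(n)
        rfree = np.zeros(n)
        rtot_pct = np.zeros(n)
        rfree_pct = np.zeros(n)
        drive = np.zeros(n)

    administered = administered_input(doses, weight_kg, drug.mw, time)
    in_system = (phys.vp * cp_ex + phys.vi * ci_ex
                 + phys.ve * states[:, I_CE_EX] + states[:, I_DEPOT])
    eliminated = states[:, I_ACAT] + states[:, I_ATMDD]
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = np.where(administered > 0,
                         np.abs(administered - in_system - eliminated)
                         / administered, 0.0)

    return SimulationResult(
        time_h=time, states=states, weight_kg=weight_kg,
        administered_umol=administered,
        rfree_uM=rfree, rbound_uM=rbound,
        rtot_pct_baseline=rtot_pct, rfree_pct_baseline=rfree_pct,
        occupancy_drive=drive,
        cp_ex_ug_per_ml=cp_ex * drug.mw / 1000.0,
        massbal_residual=resid,
    )


def nca_clearance(result: SimulationResult, dose_umol: float,
                  weight_kg: float | None = None,
                  n_terminal: int = 10) -> dict:
    """Non-compartmental clearance: dose / AUC(0-inf).

    AUC to the last point is trapezoidal; the tail is extrapolated as
    Clast/lambda_z with lambda_z from a log-linear fit to the last
    ``n_terminal`` positive points.  Returns a dict with clearance in
    L/h and mL/day/kg, the AUC, lambda_z, terminal half-life and the
    extrapolated fraction.
    """
    if weight_kg is None:
        weight_kg = result.weight_kg
    t = result.time_h
    c = result.cp_ex_uM
    # points below ~1e-6 of Cmax sit at the solver noise floor and would
    # corrupt the log-linear terminal fit
    pos = c > max(c.max(), 0.0) * 1e-6
    if pos.sum() < max(3, n_terminal):
        raise ExtrapolationError("too few positive concentrations for NCA")
    t_pos, c_pos = t[pos], c[pos]
    auc_last = float(np.trapezoid(c, t))

    tail_t = t_pos[-n_terminal:]
    tail_c = c_pos[-n_terminal:]
    slope = np.polyfit(tail_t, np.log(tail_c), 1)[0]
    lam_z = -slope
    if lam_z <= 0:
        raise ExtrapolationError(
            "terminal phase is not decaying; extend the simulation")
    auc_extra = float(c_pos[-1] / lam_z)
    auc_inf = auc_last + auc_extra
    cl = dose_umol / auc_inf
    return {
        "cl_L_per_h": cl,
        "cl_ml_per_day_per_kg": cl * 1000.0 * 24.0 / weight_kg,
        "auc_inf_uM_h": auc_inf,
        "lambda_z_per_h": lam_z,
        "terminal_half_life_h": math.log(2.0) / lam_z,
        "fraction_extrapolated": auc_extra / auc_inf,
    }


def calibrate_clcat(phys: PhysiologyParameters, drug: DrugParameters,
                    reference_dose_mg_kg: float = 1.0,
                    weight_kg: float = REFERENCE_WEIGHT_KG,
                    t_end: float = 6000.0, output_step: float = 4.0,
                    tol: float = 0.002) -> float:
    """Calibrate the intrinsic catabolic clearance against ``drug.cl_ref``.

    Bisection on log(cl_cat): for each candidate the drug-free endogenous
    steady state is re-solved, a single 1-h IV infusion of the reference
    dose is simulated with TMDD disabled, and the realized NCA clearance
    is compared with the reference linear clearance, to relative
    tolerance ``tol``.  Raises :class:`CalibrationError` with the
    achievable range when the target lies outside the search bracket.
    """
    doses = [DoseEvent(0.0, reference_dose_mg_kg, route="iv_infusion",
                       infusion_duration=1.0)]
    amt = doses[0].amount_umol(weight_kg, drug.mw)

    def realized(clcat: float) -> float:
        p = phys.replace(cl_cat=clcat)
        res = simulate(p, drug, None, None, doses, t_end,
                       output_step=output_step, weight_kg=weight_kg)
        return nca_clearance(res, amt, weight_kg)["cl_L_per_h"]

    lo, hi = 1e-3, 1e3
    cl_lo, cl_hi = realized(lo), realized(hi)
    if not (cl_lo <= drug.cl_ref <= cl_hi):
        raise CalibrationError(
            f"reference clearance {drug.cl_ref} L/h outside achievable "
            f"range [{cl_lo:.3g}, {cl_hi:.3g}] L/h")

    llo, lhi = math.log(lo), math.log(hi)
    for _ in range(80):
        mid = 0.5 * (llo + lhi)
        cl_mid = realized(math.exp(mid))
        if abs(cl_mid - drug.cl_ref) / drug.cl_ref < tol:
            return math.exp(mid)
        if cl_mid < drug.cl_ref:
            llo = mid
        else:
            lhi = mid
    raise CalibrationError("calibration did not converge in 80 bisections")
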