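"""Parameter containers for the lumped-tissue FcRn PBPK / TMDD / disease model.

All parameter classes are frozen dataclasses validated at construction.
Units follow the package conventions: time in hours, volumes in litres,
concentrations in micromolar (µM), amounts in micromoles (µmol).

The drug-specific defaults describe efalizumab, a humanized anti-CD11a
IgG1 used here as the built-in worked case.  Physiological defaults
describe a 70-kg adult reference subject with a single lumped tissue
(vascular / endosomal / interstitial spaces) and are fully configurable.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

from .errors import ConfigurationError, InvalidArgumentError

REFERENCE_WEIGHT_KG = 70.0

ROUTES = ("iv_bolus", "iv_infusion", "sc_first_order")


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidArgumentError(msg)


def _finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise InvalidArgumentError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class PhysiologyParameters:
    """Volumes, flows and FcRn-pathway constants of the lumped tissue.

    Attributes
    ----------
    vp, ve, vi : float
        Plasma, endosomal and interstitial volumes (L).
    l_lymph : float
        Lymph flow (L/h); convective drug transport scales with it.
    kup : float
        Endothelial pinocytotic uptake rate constant (1/h), applied to the
        endosomal volume: total uptake clearance is ``kup * ve`` L/h.
    delta : float
        Ratio of luminal (plasma-facing) to abluminal (interstitium-facing)
        uptake rates; the uptake clearance splits delta/(1+delta) from
        plasma and 1/(1+delta) from interstitium.
    fr : float
        Fraction of FcRn-bound IgG recycled to plasma; the remainder is
        transcytosed to the interstitium.
    krc : float
        Recycling rate constant of FcRn-bound IgG (1/h).
    sigma_v, sigma_i : float
        Vascular and lymphatic reflection coefficients (0-1).
    fcrn_total : float
        Total endosomal FcRn concentration (µM).
    igg_en_baseline : float
        Endogenous plasma IgG concentration (µM); ~10 g/L at 150 kDa.
    cl_cat : float
        Intrinsic catabolic clearance of FcRn-unbound endosomal IgG (L/h).
        The default is calibrated with :func:`mabsim.pbpk.calibrate_clcat`
        so that the no-TMDD systemic clearance of the reference mAb matches
        its observed linear clearance; recalibrate after changing any other
        physiological constant.
    """

    vp: float = 2.6
    ve: float = 0.1
    vi: float = 6.3
    l_lymph: float = 0.12
    kup: float = 1.0
    delta: float = 1.0
    fr: float = 0.715
    krc: float = 1.0
    sigma_v: float = 0.95
    sigma_i: float = 0.2
    fcrn_total: float = 45.0
    igg_en_baseline: float = 67.0
    cl_cat: float = 0.25425730390229434

    def __post_init__(self) -> None:
        for name in ("vp", "ve", "vi", "l_lymph", "kup", "krc",
                     "igg_en_baseline"):
            v = getattr(self, name)
            _finite(name, v)
            _require(v > 0, f"{name} must be strictly positive, got {v}")
        _finite("fcrn_total", self.fcrn_total)
        # zero receptor is the unprotected (linear) limit and is legal
        _require(self.fcrn_total >= 0,
                 f"fcrn_total must be >= 0, got {self.fcrn_total}")
        _require(self.delta > 0, f"delta must be > 0, got {self.delta}")
        for name in ("fr", "sigma_v", "sigma_i"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, f"{name} must be in [0, 1], got {v}")
        _finite("cl_cat", self.cl_cat)
        _require(self.cl_cat >= 0, f"cl_cat must be >= 0, got {self.cl_cat}")

    def replace(self, **kw) -> "PhysiologyParameters":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class DrugParameters:
    """Molecular and FcRn-binding properties of the mAb.

    ``kd_ex`` is the mAb-FcRn equilibrium dissociation constant in the
    acidified endosome.  Efalizumab's value was derived from its observed
    (short) half-life, i.e. it binds FcRn more weakly than bulk endogenous
    IgG; ``kd_en`` therefore defaults to a typical pH-6 IgG-FcRn affinity
    of 0.5 µM, which reproduces a normal endogenous IgG terminal
    half-life (~2-3 weeks) alongside the drug's faster clearance.
    ``cl_ref`` is the observed linear (no-TMDD) systemic clearance used
    as the calibration anchor for the catabolic clearance.
    """

    mw: float = 148841.0           # g/mol, efalizumab
    kd_ex: float = 2.96423         # µM
    kd_en: float = 0.5             # µM
    cl_ref: float = 0.0227         # L/h

    def __post_init__(self) -> None:
        _require(self.mw > 0, f"mw must be > 0, got {self.mw}")
        _require(self.kd_ex > 0, f"kd_ex must be > 0, got {self.kd_ex}")
        _require(self.kd_en > 0, f"kd_en must be > 0, got {self.kd_en}")
        _require(self.cl_ref > 0, f"cl_ref must be > 0, got {self.cl_ref}")

    def replace(self, **kw) -> "DrugParameters":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class TMDDParameters:
    """Michaelis-Menten TMDD constants for the CD11a target.

    ``ksyn`` defaults to ``rmax * kdeg`` so that the drug-free target level
    is a fixed point of the turnover equation; pass an explicit value to
    override.
    """

    km: float = 0.000573           # µM
    kint: float = 0.1              # 1/h
    kdeg: float = 0.0185           # 1/h
    rmax: float = 0.01             # µM
    ksyn: float | None = None      # µM/h; derived as rmax*kdeg if None
    target_compartment: str = "plasma"

    def __post_init__(self) -> None:
        for name in ("km", "kint", "kdeg", "rmax"):
            v = getattr(self, name)
            _require(v > 0, f"{name} must be > 0, got {v}")
        if self.ksyn is None:
            object.__setattr__(self, "ksyn", self.rmax * self.kdeg)
        _require(self.ksyn > 0, f"ksyn must be > 0, got {self.ksyn}")
        if self.target_compartment not in ("plasma", "interstitial"):
            raise ConfigurationError(
                "target_compartment must be 'plasma' or 'interstitial', "
                f"got {self.target_compartment!r}")

    def replace(self, **kw) -> "TMDDParameters":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class DiseaseParameters:
    """Asymptotic PASI disease-progression parameters.

    Under full, constant target engagement the score relaxes from the
    baseline ``y0`` toward the treated asymptote ``yss`` with half-life
    ``tp_h``.  ``drive_mode`` selects how target engagement is mapped to
    the drive E in [0, 1]: ``free_suppression`` uses 1 - Rfree/Rmax,
    ``bound_fraction`` uses Rbound/Rtot.
    """

    y0: float = 24.8
    yss: float = 14.8
    tp_h: float = 397.0
    drive_mode: str = "free_suppression"

    def __post_init__(self) -> None:
        _require(self.y0 > 0, f"y0 must be > 0, got {self.y0}")
        _require(0.0 <= self.yss <= self.y0,
                 f"yss must lie in [0, y0], got yss={self.yss}, y0={self.y0}")
        _require(self.tp_h > 0, f"tp_h must be > 0, got {self.tp_h}")
        if self.drive_mode not in ("free_suppression", "bound_fraction"):
            raise ConfigurationError(
                "drive_mode must be 'free_suppression' or 'bound_fraction', "
                f"got {self.drive_mode!r}")

    def replace(self, **kw) -> "DiseaseParameters":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class DoseEvent:
    """A single administration.

    ``dose`` is in mg/kg when ``per_kg`` is true (the usual clinical
    spec), otherwise an absolute mg amount.  Routes: ``iv_bolus``,
    ``iv_infusion`` (constant-rate over ``infusion_duration`` h) and
    ``sc_first_order`` (bioavailable fraction ``f`` enters a depot
    absorbed at rate ``ka``).
    """

    start_time: float              # h
    dose: float                    # mg/kg (per_kg) or mg
    per_kg: bool = True
    route: str = "iv_infusion"
    infusion_duration: float = 1.0  # h
    ka: float = 0.01               # 1/h, sc only
    f: float = 0.5                 # bioavailability, sc only

    def __post_init__(self) -> None:
        _require(self.start_time >= 0,
                 f"start_time must be >= 0, got {self.start_time}")
        _require(self.dose >= 0, f"dose must be >= 0, got {self.dose}")
        if self.route not in ROUTES:
            raise ConfigurationError(
                f"unknown route {self.route!r}; expected one of {ROUTES}")
        if self.route == "iv_infusion":
            _require(self.infusion_duration > 0,
                     "infusion_duration must be > 0 for iv_infusion")
        if self.route == "sc_first_order":
            _require(self.ka > 0, "ka must be > 0 for sc_first_order")
            _require(0 < self.f <= 1, "f must be in (0, 1] for sc_first_order")

    def amount_umol(self, weight_kg: float, mw: float) -> float:
        """Administered amount in µmol for a subject of ``weight_kg``."""
        mg = self.dose * weight_kg if self.per_kg else self.dose
        return mg / mw * 1000.0
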