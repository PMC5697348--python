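"""Kinetic core of the ppGpp / growth / fatty-acid / biosensor model.

The model tracks nine dynamic quantities in a batch culture of *E. coli*:

==========  ======================================================  =========
variable    meaning                                                 units
==========  ======================================================  =========
AcylACP     long-chain acyl-ACP, end product of fatty-acid          uM
            synthesis (FAS) and substrate of phospholipid
            synthesis (PLS) and thioesterase (Tes)
FA          free fatty acid accumulated by the whole culture        mg/l
N           cell number                                             OD600
nutr        growth-supporting nutrient (relative amount)            --
lim         exponential-phase-limiting nutrient (relative amount)   --
ppGpp       alarmone guanosine tetraphosphate                       uM
rib         relative ribosomal activity                             --
I           relative amount of the transcriptional inhibitor        --
            expressed from the ppGpp-inhibited rRNA P1/P2 promoter
GFP         relative fluorescence of the reporter repressed by I    --
==========  ======================================================  =========

Time is measured in minutes throughout.

The wiring: depletion of ``lim`` at the end of exponential growth slows
ppGpp hydrolysis, so ppGpp rises; ppGpp inhibits the tandem rRNA promoter
P1/P2 (Hill coefficient ``m_hill``), which lowers ribosomal activity and
hence growth, FAS and PLS; ppGpp also inhibits PlsB (the committed PLS
enzyme) directly.  Thioesterase drains acyl-ACP into free fatty acid;
excessive drain depletes acyl-ACP, which blocks SpoT-mediated ppGpp
hydrolysis and raises ppGpp even in mid-exponential phase.  The biosensor
is a double-negative relay: P1/P2 drives inhibitor I, I represses GFP
(Hill coefficient ``l_hill``), so high ppGpp reads out as high GFP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from enum import IntEnum

import numpy as np

__all__ = [
    "ModelParameters",
    "ModelState",
    "DerivedRates",
    "StateIndex",
    "STATE_NAMES",
    "DomainError",
    "IntegrationFailure",
    "v_fas",
    "v_pls",
    "v_fa",
    "p1p2_activity",
    "growth_rate",
    "derived_rates",
    "rhs",
    "make_rhs",
]


class DomainError(ValueError):
    """A rate law or type was evaluated outside its physical domain."""


class IntegrationFailure(RuntimeError):
    """The ODE solver failed; carries the last valid time and state."""

    def __init__(self, message: str, t: float | None = None, state=None):
        super().__init__(message)
        self.t = t
        self.state = state


class StateIndex(IntEnum):
    """Position of each dynamic variable in the state vector."""

    ACYL_ACP = 0
    FA = 1
    N = 2
    NUTR = 3
    LIM = 4
    PPGPP = 5
    RIB = 6
    I = 7
    GFP = 8


STATE_NAMES = ("AcylACP", "FA", "N", "nutr", "lim", "ppGpp", "rib", "I", "GFP")

# Parameters that admit zero (switching a process off is physical);
# everything else positive must be strictly positive.
_NONNEG_OK = frozenset({"V_tes", "K_gr", "k_nutr", "k_lim", "km_ppGpp"})
_HILL = ("n_hill", "m_hill", "l_hill")
_NON_NUMERIC = frozenset({"acp_coupling"})

#: documented unit for every parameter key (consumed by the config loader)
PARAMETER_UNITS = {
    "Vm_FAS": "uM/min",
    "Km_ACP": "uM",
    "Km_AcCoA": "uM",
    "Ki_AcylACP": "uM",
    "ACP_const": "uM",
    "AcCoA_const": "uM",
    "Vm_PLS": "uM/min",
    "Km_AcylACP": "uM",
    "Ki_ppGpp": "uM",
    "n_hill": "dimensionless",
    "V_tes": "mg/l/OD/min",
    "Km_tes": "uM",
    "k_fa": "uM per mg/l/OD",
    "K_gr": "1/min",
    "V0": "uM/min",
    "k_nutr": "1/(OD*min)",
    "k_lim": "1/(OD*min)",
    "kp_ppGpp": "uM/min",
    "km_ppGpp": "1/min",
    "k0m_ppGpp": "1/min",
    "Km_Ac_pp": "uM",
    "kp_rib": "1/min",
    "km_rib": "1/min",
    "Ki_P1P2_ppGpp": "uM",
    "m_hill": "dimensionless",
    "k_I": "1/min",
    "k_GFP": "1/min",
    "Ki_I": "dimensionless",
    "l_hill": "dimensionless",
    "depletion_floor": "dimensionless",
    "acp_coupling": "mode",
}


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set of the model.

    Defaults are the shipped reference set: printed constants (Hill
    coefficients m=2 and l=4, k_GFP=0.1/min, the nutrient-depletion floor
    0.001, the control-line Tes activity 0.08 mg/l/OD/min) plus the
    calibrated values produced by
    :func:`ppgppsim.experiments.calibrate_reference_set`.
    """

    # -- fatty-acid synthesis (FAS) lump -----------------------------------
    Vm_FAS: float = 60.0          # max FAS rate, uM/min
    Km_ACP: float = 1.0           # Michaelis constant for free ACP, uM
    Km_AcCoA: float = 10.0        # Michaelis constant for acetyl-CoA, uM
    Ki_AcylACP: float = 1.0       # product feedback inhibition, uM
    ACP_const: float = 50.0       # effective free-ACP pool, uM (saturating)
    AcCoA_const: float = 500.0    # effective acetyl-CoA pool, uM (saturating)
    # -- phospholipid synthesis (PLS, PlsB) --------------------------------
    Vm_PLS: float = 60.0          # max PLS rate, uM/min
    Km_AcylACP: float = 1.0       # PlsB Michaelis constant, uM
    Ki_ppGpp: float = 560.0       # PlsB inhibition by ppGpp, uM
    n_hill: float = 2.0           # Hill coefficient of PLS inhibition
    # -- thioesterase (Tes) ------------------------------------------------
    V_tes: float = 0.08           # Tes activity, mg/l/OD/min (control line)
    Km_tes: float = 1.0           # Tes Michaelis constant, uM
    k_fa: float = 2.0             # volume factor mg/l/OD -> uM intracellular
    # -- growth ------------------------------------------------------------
    K_gr: float = 0.025           # max specific growth rate, 1/min
    V0: float = 2.0               # minimal PLS rate sustaining growth, uM/min
    k_nutr: float = 0.004         # nutr depletion, 1/(OD*min)
    k_lim: float = 0.02           # lim depletion, 1/(OD*min)
    # -- ppGpp balance -----------------------------------------------------
    kp_ppGpp: float = 360.0       # synthesis per unit rib, uM/min
    km_ppGpp: float = 3.9         # lim-dependent hydrolysis, 1/min
    k0m_ppGpp: float = 0.3        # background hydrolysis, 1/min
    Km_Ac_pp: float = 0.5         # acyl-ACP half-saturation of hydrolysis, uM
    # -- ribosomal activity and P1/P2 promoter -----------------------------
    kp_rib: float = 0.2           # rib synthesis, 1/min
    km_rib: float = 0.1           # rib decay, 1/min
    Ki_P1P2_ppGpp: float = 144.0  # P1/P2 inhibition by ppGpp, uM
    m_hill: float = 2.0           # Hill coefficient of P1/P2 inhibition
    # -- biosensor cascade -------------------------------------------------
    k_I: float = 0.15             # inhibitor I turnover, 1/min (fast-degraded)
    k_GFP: float = 0.1            # GFP turnover, 1/min
    Ki_I: float = 0.1             # GFP repression by I, dimensionless
    l_hill: float = 4.0           # Hill coefficient of GFP repression
    # -- numerics / structure ----------------------------------------------
    depletion_floor: float = 0.001
    acp_coupling: str = "constant"   # "constant" | "conserved"

    def __post_init__(self):
        for f in fields(self):
            if f.name in _NON_NUMERIC:
                continue
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise DomainError(f"parameter {f.name} must be a finite number, got {v!r}")
            object.__setattr__(self, f.name, float(v))
            v = float(v)
            if f.name in _HILL:
                if v < 1.0:
                    raise DomainError(f"Hill coefficient {f.name} must be >= 1, got {v}")
            elif f.name in _NONNEG_OK:
                if v < 0.0:
                    raise DomainError(f"parameter {f.name} must be >= 0, got {v}")
            elif v <= 0.0:
                raise DomainError(f"parameter {f.name} must be > 0, got {v}")
        if self.acp_coupling not in ("constant", "conserved"):
            raise DomainError(
                f"acp_coupling must be 'constant' or 'conserved', got {self.acp_coupling!r}"
            )

    def with_updates(self, **kwargs) -> "ModelParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class ModelState:
    """One point in state space (see module docstring for units)."""

    AcylACP: float
    FA: float
    N: float
    nutr: float
    lim: float
    ppGpp: float
    rib: float
    I: float
    GFP: float

    def __post_init__(self):
        for name in STATE_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise DomainError(f"state component {name} is not finite: {v}")
            if v < 0.0:
                raise DomainError(f"state component {name} must be >= 0, got {v}")
        for name in ("I", "GFP"):
            if getattr(self, name) > 1.0 + 1e-9:
                raise DomainError(f"state component {name} must be <= 1")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y) -> "ModelState":
        y = np.asarray(y, dtype=float)
        if y.shape != (9,):
            raise DomainError(f"state vector must have 9 components, got shape {y.shape}")
        return cls(*y)

    def replace(self, **kwargs) -> "ModelState":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DerivedRates:
    """Algebraic quantities evaluated along a trajectory."""

    V_FAS: float   # uM/min
    V_PLS: float   # uM/min
    V_FA: float    # mg/l/min/OD
    P1P2: float    # dimensionless in [0, 1]
    v_g: float     # 1/min


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------

def _free_acp(acyl_acp: float, p: ModelParameters) -> float:
    if p.acp_coupling == "conserved":
        return max(p.ACP_const - acyl_acp, 0.0)
    return p.ACP_const


def _v_fas(acyl_acp: float, rib: float, p: ModelParameters) -> float:
    acp = _free_acp(acyl_acp, p)
    return (
        p.Vm_FAS
        * rib
        * acp / (acp + p.Km_ACP)
        * p.AcCoA_const / (p.AcCoA_const + p.Km_AcCoA)
        / (1.0 + acyl_acp / p.Ki_AcylACP)
    )


def _v_pls(acyl_acp: float, ppgpp: float, rib: float, p: ModelParameters) -> float:
    return (
        p.Vm_PLS
        * rib
        * acyl_acp / (acyl_acp + p.Km_AcylACP)
        / (1.0 + (ppgpp / p.Ki_ppGpp) ** p.n_hill)
    )


def _v_fa(acyl_acp: float, p: ModelParameters) -> float:
    return p.V_tes * acyl_acp / (acyl_acp + p.Km_tes)


def _p1p2(ppgpp: float, p: ModelParameters) -> float:
    return 1.0 / (1.0 + (ppgpp / p.Ki_P1P2_ppGpp) ** p.m_hill)


def _growth_rate(v_pls_val: float, nutr: float, rib: float, p: ModelParameters) -> float:
    return p.K_gr * nutr * rib * v_pls_val / (v_pls_val + p.V0)


def v_fas(state: ModelState, p: ModelParameters) -> float:
    """Fatty-acid synthesis flux (uM/min).

    Michaelis-Menten in free ACP and acetyl-CoA, proportional to ribosomal
    activity, with linear product feedback inhibition by acyl-ACP.
    """
    return _v_fas(state.AcylACP, state.rib, p)


def v_pls(state: ModelState, p: ModelParameters) -> float:
    """Phospholipid synthesis flux (uM/min).

    Michaelis-Menten in acyl-ACP and Hill-inhibited by ppGpp (PlsB is the
    committed, ppGpp-inhibited step).
    """
    return _v_pls(state.AcylACP, state.ppGpp, state.rib, p)


def v_fa(acyl_acp: float, p: ModelParameters) -> float:
    """Per-cell free fatty-acid release by thioesterase (mg/l/min/OD)."""
    if not math.isfinite(acyl_acp) or acyl_acp < 0.0:
        raise DomainError(f"AcylACP must be >= 0 and finite, got {acyl_acp}")
    return _v_fa(acyl_acp, p)


def p1p2_activity(ppgpp: float, p: ModelParameters) -> float:
    """Relative activity of the tandem rRNA P1/P2 promoter in (0, 1]."""
    if not math.isfinite(ppgpp) or ppgpp < 0.0:
        raise DomainError(f"ppGpp must be >= 0 and finite, got {ppgpp}")
    return _p1p2(ppgpp, p)


def growth_rate(state: ModelState, p: ModelParameters) -> float:
    """Specific growth rate v_g (1/min).

    Proportional to nutrient availability and ribosomal activity, and
    saturating in the PLS flux: a minimal rate of membrane phospholipid
    synthesis V0 is needed to sustain division.
    """
    return _growth_rate(v_pls(state, p), state.nutr, state.rib, p)


def derived_rates(state: ModelState, p: ModelParameters) -> DerivedRates:
    """All algebraic rates at one state."""
    vf = v_fas(state, p)
    vp = v_pls(state, p)
    return DerivedRates(
        V_FAS=vf,
        V_PLS=vp,
        V_FA=v_fa(state.AcylACP, p),
        P1P2=p1p2_activity(state.ppGpp, p),
        v_g=_growth_rate(vp, state.nutr, state.rib, p),
    )


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

def _rhs_array(t: float, y, p: ModelParameters, out=None) -> np.ndarray:
    """d(state)/dt for a raw 9-vector.

    Tolerates the tiny negative excursions a stiff solver can produce by
    clipping to zero before evaluating the rate laws; on valid states this
    is the identity, so the algebraic flux-balance identity is exact.
    """
    acyl = y[0] if y[0] > 0.0 else 0.0
    n = y[2] if y[2] > 0.0 else 0.0
    nutr = y[3] if y[3] > 0.0 else 0.0
    lim = y[4] if y[4] > 0.0 else 0.0
    ppgpp = y[5] if y[5] > 0.0 else 0.0
    rib = y[6] if y[6] > 0.0 else 0.0
    inh = y[7] if y[7] > 0.0 else 0.0
    gfp = y[8] if y[8] > 0.0 else 0.0

    vfas = _v_fas(acyl, rib, p)
    vpls = _v_pls(acyl, ppgpp, rib, p)
    vfa = _v_fa(acyl, p)
    p1p2 = _p1p2(ppgpp, p)
    vg = _growth_rate(vpls, nutr, rib, p)
    floor = p.depletion_floor

    if out is None:
        out = np.empty(9)
    out[0] = vfas - vpls - p.k_fa * vfa
    out[1] = n * vfa
    out[2] = vg * n
    out[3] = -p.k_nutr * n * nutr / (nutr + floor)
    out[4] = -p.k_lim * n * lim / (lim + floor)
    out[5] = p.kp_ppGpp * rib - ppgpp * (p.km_ppGpp * lim + p.k0m_ppGpp) * acyl / (
        acyl + p.Km_Ac_pp
    )
    out[6] = p.kp_rib * p1p2 - p.km_rib * rib
    out[7] = p.k_I * (p1p2 - inh)
    out[8] = p.k_GFP * (1.0 / (1.0 + (inh / p.Ki_I) ** p.l_hill) - gfp)
    return out


def rhs(t: float, state: ModelState, p: ModelParameters) -> np.ndarray:
    """Time derivative of the full 9-dimensional state.

    Raises :class:`IntegrationFailure` on non-finite input (the signal a
    failed solver step propagates).
    """
    y = state.to_array()
    if not np.all(np.isfinite(y)):
        raise IntegrationFailure("non-finite state passed to rhs", t=t, state=y)
    return _rhs_array(t, y, p)


def make_rhs(p: ModelParameters, clamp_ppGpp: float | None = None):
    """Return ``f(t, y)`` suitable for :func:`scipy.integrate.solve_ivp`.

    With ``clamp_ppGpp`` set, ppGpp is held at that value (its derivative
    is zeroed and the clamped value is used in every rate law), which is
    how steady-state dose-response points are computed.
    """
    if clamp_ppGpp is None:
        def f(t, y):
            return _rhs_array(t, y, p)
    else:
        cval = float(clamp_ppGpp)
        if cval < 0.0:
            raise DomainError("clamped ppGpp must be >= 0")

        def f(t, y):
            yc = np.array(y, dtype=float)
            yc[StateIndex.PPGPP] = cval
            out = _rhs_array(t, yc, p)
            out[StateIndex.PPGPP] = 0.0
            return out

    return f
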