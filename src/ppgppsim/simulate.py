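"""Scenario definition, stiff ODE integration, events and phase detection.

A :class:`Scenario` bundles a parameter set, an initial state (or a
pre-equilibration directive), a horizon, an output grid and an event
schedule.  Events are instantaneous state resets (nutrient upshift,
ppGpp clamping) applied mid-run; integration restarts at the event time,
so trajectories are exact piecewise solutions of the ODE system.

The system is stiff — acyl-ACP turns over in seconds at high thioesterase
activity while the culture evolves over a day — so integration uses a
variable-order BDF method with tight tolerances (rtol 1e-8, atol 1e-10
by default).

The biosensor relay (I, GFP) is strictly downstream of the rest of the
model: neither variable appears in any growth, nutrient, ppGpp or flux
equation.  Integration honours that structure exactly — the 7-dimensional
core system is solved first, then the 2-dimensional sensor cascade is
driven by the dense core solution.  Perturbing sensor parameters
therefore leaves the core trajectory bit-identical, which is the
behaviour the model structure dictates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.integrate import solve_ivp

from .core import (
    DomainError,
    IntegrationFailure,
    ModelParameters,
    ModelState,
    StateIndex,
    STATE_NAMES,
    _p1p2,
    _rhs_array,
)

__all__ = [
    "Event",
    "Scenario",
    "Trajectory",
    "PhaseBoundaries",
    "PhaseNotReached",
    "TriggerNotReached",
    "DEFAULT_RTOL",
    "DEFAULT_ATOL",
    "DEFAULT_OUTPUT_DT",
    "DEFAULT_UPSHIFT_DELAY",
    "PHASE_THRESHOLD",
    "equilibrate_exponential",
    "initial_state",
    "simulate",
    "detect_phases",
    "apply_upshift",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
#: output grid spacing (min) of the reference batch scenarios
DEFAULT_OUTPUT_DT = 10.0
#: operational nutrient-depletion threshold defining phase boundaries
PHASE_THRESHOLD = 0.01

_CORE = slice(0, 7)          # AcylACP, FA, N, nutr, lim, ppGpp, rib
_CORE_NAMES = STATE_NAMES[:7]
_ACTIONS = ("set_lim", "set_nutr", "clamp_ppGpp", "release_clamp")
_ACTION_INDEX = {"set_lim": StateIndex.LIM, "set_nutr": StateIndex.NUTR}


class PhaseNotReached(RuntimeError):
    """The requested nutrient never crossed the depletion threshold."""


class TriggerNotReached(RuntimeError):
    """A state-triggered event never fired within the horizon."""


@dataclass(frozen=True)
class Event:
    """An instantaneous intervention.

    Exactly one of ``time`` (minutes) or ``trigger`` must be given;
    ``trigger`` is ``(state_name, threshold)`` and fires at the first
    downward crossing of that (core) state component through the
    threshold.  A triggered event with ``delay`` > 0 is applied that many
    minutes after the crossing (e.g. a nutrient upshift a fixed interval
    after nutrient exhaustion is detected).
    """

    action: str
    value: Optional[float] = None
    time: Optional[float] = None
    trigger: Optional[tuple[str, float]] = None
    delay: float = 0.0

    def __post_init__(self):
        if self.delay < 0.0:
            raise DomainError("event delay must be >= 0")
        if self.delay > 0.0 and self.trigger is None:
            raise DomainError("event delay requires a trigger")
        if self.action not in _ACTIONS:
            raise DomainError(f"unknown event action {self.action!r}; expected one of {_ACTIONS}")
        if (self.time is None) == (self.trigger is None):
            raise DomainError("event needs exactly one of 'time' or 'trigger'")
        if self.action != "release_clamp":
            if self.value is None or self.value < 0.0:
                raise DomainError(f"event action {self.action!r} needs a value >= 0")
        if self.trigger is not None:
            name, thr = self.trigger
            if name not in _CORE_NAMES:
                raise DomainError(f"trigger variable must be one of {_CORE_NAMES}, got {name!r}")
            if thr <= 0.0:
                raise DomainError("trigger threshold must be > 0")
        if self.time is not None and self.time < 0.0:
            raise DomainError("event time must be >= 0")


@dataclass(frozen=True)
class Scenario:
    """A complete, reproducible simulation request."""

    params: ModelParameters
    init: Optional[ModelState] = None      # None -> pre-equilibrate
    t_end: float = 1440.0                  # min (24 h)
    output_dt: float = DEFAULT_OUTPUT_DT   # min
    events: tuple[Event, ...] = ()
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL

    def __post_init__(self):
        if self.t_end <= 0.0:
            raise DomainError("t_end must be > 0")
        if self.output_dt <= 0.0:
            raise DomainError("output_dt must be > 0")
        if self.rtol <= 0.0 or self.atol <= 0.0:
            raise DomainError("integration tolerances must be > 0")
        object.__setattr__(self, "events", tuple(self.events))
        for ev in self.events:
            if ev.time is not None and not (0.0 <= ev.time <= self.t_end):
                raise DomainError(f"event time {ev.time} outside [0, {self.t_end}]")

    def with_updates(self, **kwargs) -> "Scenario":
        from dataclasses import replace

        return replace(self, **kwargs)


@dataclass
class Trajectory:
    """Integrated solution on the output grid plus derived fluxes.

    ``states`` is (n_times, 9) ordered as :data:`ppgppsim.core.STATE_NAMES`;
    ``derived`` is (n_times, 5) ordered (V_FAS, V_PLS, V_FA, P1P2, v_g).
    """

    t: np.ndarray
    states: np.ndarray
    derived: np.ndarray
    events_applied: list = field(default_factory=list)
    params: Optional[ModelParameters] = None

    DERIVED_NAMES = ("V_FAS", "V_PLS", "V_FA", "P1P2", "v_g")

    def __getitem__(self, name: str) -> np.ndarray:
        if name in STATE_NAMES:
            return self.states[:, STATE_NAMES.index(name)]
        if name in self.DERIVED_NAMES:
            return self.derived[:, self.DERIVED_NAMES.index(name)]
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.t)

    def state_at(self, index: int) -> ModelState:
        y = np.clip(self.states[index], 0.0, None)
        y[StateIndex.I] = min(y[StateIndex.I], 1.0)
        y[StateIndex.GFP] = min(y[StateIndex.GFP], 1.0)
        return ModelState.from_array(y)

    def value_at(self, t: float, name: str) -> float:
        """Linear interpolation of one column at time ``t``."""
        return float(np.interp(t, self.t, self[name]))

    def final(self, name: str) -> float:
        return float(self[name][-1])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_min": self.t,
                "acyl_acp_uM": self["AcylACP"],
                "fa_mg_per_l": self["FA"],
                "n_od": self["N"],
                "nutr": self["nutr"],
                "lim": self["lim"],
                "ppgpp_uM": self["ppGpp"],
                "rib": self["rib"],
                "i": self["I"],
                "gfp": self["GFP"],
                "v_fas": self["V_FAS"],
                "v_pls": self["V_PLS"],
                "v_fa": self["V_FA"],
                "p1p2": self["P1P2"],
                "v_g": self["v_g"],
            }
        )


@dataclass(frozen=True)
class PhaseBoundaries:
    """Times (min) at which the two nutrients cross the depletion threshold."""

    t_phase1_end: float   # lim crossing: exponential -> transition phase
    t_phase2_end: float   # nutr crossing: transition -> stationary phase


# ---------------------------------------------------------------------------
# initial conditions
# ---------------------------------------------------------------------------

def _core_rhs(p: ModelParameters, clamp: Optional[float], frozen: tuple = ()):
    """Right-hand side of the 7-dimensional core subsystem."""
    scratch = np.zeros(9)
    out9 = np.empty(9)

    def f(t, y):
        scratch[_CORE] = y
        if clamp is not None:
            scratch[StateIndex.PPGPP] = clamp
        _rhs_array(t, scratch, p, out=out9)
        if clamp is not None:
            out9[StateIndex.PPGPP] = 0.0
        for i in frozen:
            out9[i] = 0.0
        return out9[_CORE].copy()

    return f


def equilibrate_exponential(
    p: ModelParameters, t_eq: float = 4000.0, rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL
) -> np.ndarray:
    """Quasi-steady intracellular core state for established exponential growth.

    Integrates the core subsystem (acyl-ACP, ppGpp, rib) with both
    nutrients clamped at 1 and the culture variables (N, FA) frozen, long
    enough for transients to die out.  Returns the 7-vector of core
    variables.  The result does not depend on the sensor parameters.
    """
    y0 = np.array([1.0, 0.0, 0.0, 1.0, 1.0, p.kp_ppGpp / (p.km_ppGpp + p.k0m_ppGpp), 1.0])
    frozen = (StateIndex.FA, StateIndex.N, StateIndex.NUTR, StateIndex.LIM)
    f = _core_rhs(p, clamp=None, frozen=frozen)
    sol = solve_ivp(f, (0.0, t_eq), y0, method="BDF", rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationFailure(f"pre-equilibration failed: {sol.message}", t=sol.t[-1])
    return sol.y[:, -1]


def initial_state(p: ModelParameters, N0: float = 0.01) -> ModelState:
    """Default initial condition: culture inoculated from exponential growth.

    The culture starts at ``N0`` OD in fresh medium (nutr = lim = 1) with
    no accumulated fatty acid; acyl-ACP, ppGpp and ribosomal activity take
    their exponential-growth quasi-steady values (pre-equilibration run);
    the inhibitor starts fully expressed (I = 1) with GFP at the matching
    repressed steady level 1/(1+(1/Ki_I)^l).
    """
    y = np.empty(9)
    y[_CORE] = equilibrate_exponential(p)
    y[StateIndex.FA] = 0.0
    y[StateIndex.N] = N0
    y[StateIndex.NUTR] = 1.0
    y[StateIndex.LIM] = 1.0
    y[StateIndex.I] = 1.0
    y[StateIndex.GFP] = 1.0 / (1.0 + (1.0 / p.Ki_I) ** p.l_hill)
    y[:7] = np.clip(y[:7], 0.0, None)
    return ModelState.from_array(y)


# ---------------------------------------------------------------------------
# integration with events
# ---------------------------------------------------------------------------

def _make_trigger(ev: Event) -> Callable:
    idx = _CORE_NAMES.index(ev.trigger[0])
    thr = ev.trigger[1]

    def g(t, y):
        return y[idx] - thr

    g.terminal = True
    g.direction = -1.0
    return g


def _integrate_sensor(p, t0, t1, z0, ppgpp_of_t, t_eval, rtol, atol):
    """Integrate the (I, GFP) relay driven by the core ppGpp path."""

    def f(t, z):
        inh = z[0] if z[0] > 0.0 else 0.0
        gfp = z[1] if z[1] > 0.0 else 0.0
        p1p2 = _p1p2(max(ppgpp_of_t(t), 0.0), p)
        return [
            p.k_I * (p1p2 - inh),
            p.k_GFP * (1.0 / (1.0 + (inh / p.Ki_I) ** p.l_hill) - gfp),
        ]

    sol = solve_ivp(
        f,
        (t0, t1),
        z0,
        method="BDF",
        rtol=rtol,
        atol=atol,
        t_eval=t_eval if len(t_eval) else None,
        dense_output=True,
    )
    if not sol.success:
        raise IntegrationFailure(f"sensor integration failed: {sol.message}", t=t0)
    return sol


def simulate(scenario: Scenario) -> Trajectory:
    """Integrate a scenario and return its trajectory on the output grid.

    Events are applied as discontinuous state resets with integration
    restarted at the event time; the event log records the time, action
    and value of every event actually applied.  Raises
    :class:`~ppgppsim.core.IntegrationFailure` with the last valid time
    and state if the solver cannot complete a segment.
    """
    p = scenario.params
    init = scenario.init if scenario.init is not None else initial_state(p)
    y = init.to_array()
    t_end = scenario.t_end

    n_out = int(round(t_end / scenario.output_dt))
    t_out = np.linspace(0.0, n_out * scenario.output_dt, n_out + 1)
    t_out = t_out[t_out <= t_end + 1e-9]
    if t_out[-1] < t_end - 1e-9:
        t_out = np.append(t_out, t_end)

    timed = sorted([ev for ev in scenario.events if ev.time is not None], key=lambda e: e.time)
    triggered = [ev for ev in scenario.events if ev.trigger is not None]

    ts: list[float] = []
    ys: list[np.ndarray] = []
    log: list[dict] = []
    clamp: Optional[float] = None
    t_cur = 0.0

    def apply(ev: Event, t_ev: float, y_ev: np.ndarray) -> np.ndarray:
        nonlocal clamp
        y_new = y_ev.copy()
        if ev.action in _ACTION_INDEX:
            y_new[_ACTION_INDEX[ev.action]] = ev.value
        elif ev.action == "clamp_ppGpp":
            clamp = float(ev.value)
            y_new[StateIndex.PPGPP] = clamp
        elif ev.action == "release_clamp":
            clamp = None
        log.append({"time": float(t_ev), "action": ev.action, "value": ev.value})
        return y_new

    def schedule(ev: Event, t_fire: float):
        import bisect

        timed_ev = Event(action=ev.action, value=ev.value, time=t_fire)
        bisect.insort(timed, timed_ev, key=lambda e: e.time)

    # events whose trigger already holds at t = 0 fire immediately
    for ev in list(triggered):
        if y[_CORE_NAMES.index(ev.trigger[0])] < ev.trigger[1]:
            if ev.delay > 0.0:
                schedule(ev, ev.delay)
            else:
                y = apply(ev, 0.0, y)
            triggered.remove(ev)
    while timed and timed[0].time <= 0.0:
        y = apply(timed.pop(0), 0.0, y)

    ts.append(0.0)
    ys.append(y.copy())

    while t_cur < t_end - 1e-9:
        t_stop = min(timed[0].time if timed else t_end, t_end)
        f_core = _core_rhs(p, clamp)
        trig_funcs = [_make_trigger(ev) for ev in triggered]
        seg_eval = t_out[(t_out > t_cur + 1e-9) & (t_out <= t_stop + 1e-9)]
        sol = solve_ivp(
            f_core,
            (t_cur, t_stop),
            y[_CORE],
            method="BDF",
            rtol=scenario.rtol,
            atol=scenario.atol,
            t_eval=seg_eval if len(seg_eval) else None,
            events=trig_funcs if trig_funcs else None,
            dense_output=True,
        )
        if not sol.success and sol.status != 1:
            t_fail = float(sol.t[-1]) if len(sol.t) else t_cur
            raise IntegrationFailure(
                f"integration failed at t={t_fail:.3f} min: {sol.message}",
                t=t_fail,
                state=sol.y[:, -1] if sol.y.size else y[_CORE],
            )

        if sol.status == 1:  # a trigger fired; it terminates this segment
            fired_i = next(i for i, te in enumerate(sol.t_events) if len(te))
            t_seg_end = float(sol.t_events[fired_i][0])
            core_end = sol.y_events[fired_i][0].copy()
            fired = triggered.pop(fired_i)
        else:
            t_seg_end = t_stop
            core_end = sol.y[:, -1].copy() if sol.y.size else y[_CORE].copy()
            fired = None

        if clamp is not None:
            def ppgpp_of_t(t, _c=clamp):
                return _c
        else:
            dense = sol.sol

            def ppgpp_of_t(t, _d=dense):
                return float(_d(t)[StateIndex.PPGPP])

        keep = seg_eval[seg_eval <= t_seg_end + 1e-12] if len(seg_eval) else seg_eval
        sens = _integrate_sensor(
            p, t_cur, t_seg_end, y[7:], ppgpp_of_t, keep, scenario.rtol, scenario.atol
        )
        if len(keep):
            core_kept = sol.y[:, : len(keep)] if sol.status == 1 else sol.y
            for j, tj in enumerate(keep):
                row = np.empty(9)
                row[_CORE] = core_kept[:, j]
                row[7:] = sens.sol(tj) if sens.t.size else y[7:]
                ts.append(float(tj))
                ys.append(row)

        y_new = np.empty(9)
        y_new[_CORE] = core_end
        y_new[7:] = sens.sol(t_seg_end)
        y = y_new
        t_cur = t_seg_end
        if fired is not None:
            if fired.delay > 0.0:
                schedule(fired, t_cur + fired.delay)
            else:
                y = apply(fired, t_cur, y)
        else:
            while timed and timed[0].time <= t_cur + 1e-9:
                y = apply(timed.pop(0), t_cur, y)

    t_arr = np.array(ts)
    y_arr = np.clip(np.array(ys), 0.0, None)
    # re-sample onto the requested output grid (event restarts may drop the
    # grid point nearest an event); state columns are continuous across
    # events except the reset one, and grid points never coincide with an
    # event interior interval, so linear interpolation is exact-grade here
    if len(t_arr) != len(t_out) or not np.allclose(t_arr, t_out, atol=1e-6):
        y_grid = np.empty((len(t_out), 9))
        for j in range(9):
            y_grid[:, j] = np.interp(t_out, t_arr, y_arr[:, j])
        t_arr, y_arr = t_out, y_grid

    return Trajectory(
        t=t_arr,
        states=y_arr,
        derived=_derived_matrix(t_arr, y_arr, p),
        events_applied=log,
        params=p,
    )


def _derived_matrix(t: np.ndarray, y: np.ndarray, p: ModelParameters) -> np.ndarray:
    acyl = y[:, StateIndex.ACYL_ACP]
    nutr = y[:, StateIndex.NUTR]
    ppgpp = y[:, StateIndex.PPGPP]
    rib = y[:, StateIndex.RIB]
    if p.acp_coupling == "conserved":
        acp = np.clip(p.ACP_const - acyl, 0.0, None)
    else:
        acp = np.full_like(acyl, p.ACP_const)
    vfas = (
        p.Vm_FAS
        * rib
        * acp / (acp + p.Km_ACP)
        * p.AcCoA_const / (p.AcCoA_const + p.Km_AcCoA)
        / (1.0 + acyl / p.Ki_AcylACP)
    )
    vpls = (
        p.Vm_PLS
        * rib
        * acyl / (acyl + p.Km_AcylACP)
        / (1.0 + (ppgpp / p.Ki_ppGpp) ** p.n_hill)
    )
    vfa = p.V_tes * acyl / (acyl + p.Km_tes)
    p1p2 = 1.0 / (1.0 + (ppgpp / p.Ki_P1P2_ppGpp) ** p.m_hill)
    vg = p.K_gr * nutr * rib * vpls / (vpls + p.V0)
    return np.column_stack([vfas, vpls, vfa, p1p2, vg])


# ---------------------------------------------------------------------------
# phase detection and upshift
# ---------------------------------------------------------------------------

def _first_downward_crossing(t: np.ndarray, x: np.ndarray, threshold: float) -> float:
    above = x > threshold
    for i in range(len(t) - 1):
        if above[i] and not above[i + 1]:
            frac = (x[i] - threshold) / (x[i] - x[i + 1])
            return float(t[i] + frac * (t[i + 1] - t[i]))
    raise PhaseNotReached(
        f"no downward crossing through {threshold} within [{t[0]}, {t[-1]}] min"
    )


def detect_phases(traj: Trajectory, threshold: float = PHASE_THRESHOLD) -> PhaseBoundaries:
    """Growth-phase boundaries from nutrient depletion.

    Phase 1 (exponential growth) ends when ``lim`` first crosses the
    threshold downward; phase 2 (the exponential-to-stationary
    transition) ends when ``nutr`` does.  Crossing times are linearly
    interpolated between output points.  Raises :class:`PhaseNotReached`
    if a crossing is absent.
    """
    t1 = _first_downward_crossing(traj.t, traj["lim"], threshold)
    t2 = _first_downward_crossing(traj.t, traj["nutr"], threshold)
    return PhaseBoundaries(t_phase1_end=t1, t_phase2_end=t2)


#: default interval (min) between lim exhaustion and the reference
#: nutrient upshift — long enough for the stringent spike to establish,
#: so the upshift relaxes an elevated ppGpp/GFP state
DEFAULT_UPSHIFT_DELAY = 12.0


def apply_upshift(
    scenario: Scenario,
    threshold: float = PHASE_THRESHOLD,
    value: float = 1.0,
    delay: float = DEFAULT_UPSHIFT_DELAY,
) -> tuple[Trajectory, float]:
    """Run a scenario with a nutrient upshift at the end of phase 1.

    The upshift resets ``lim`` to ``value`` (an instantaneous medium
    change) ``delay`` minutes after the first downward crossing of
    ``lim`` through ``threshold``; all other state components are
    continuous.  The delay lets the stringent response establish before
    the medium change, matching the protocol of upshifting a culture
    whose sensor already reports starvation.  Returns the trajectory and
    the event time.  Raises :class:`TriggerNotReached` if the upshift is
    never applied within the horizon.
    """
    ev = Event(action="set_lim", value=value, trigger=("lim", threshold), delay=delay)
    traj = simulate(scenario.with_updates(events=scenario.events + (ev,)))
    for rec in traj.events_applied:
        if rec["action"] == "set_lim":
            return traj, rec["time"]
    raise TriggerNotReached(f"lim never crossed {threshold} within {scenario.t_end} min")
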