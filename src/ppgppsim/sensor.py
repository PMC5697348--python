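"""Biosensor characteristics: dose-response, response time, peak fluorescence.

The sensor is a double-negative relay: ppGpp inhibits the P1/P2 promoter,
P1/P2 drives the repressor I, and I represses GFP.  Composing the two
inhibitions makes steady-state GFP a monotone increasing function of
ppGpp, so GFP fluorescence reports intracellular ppGpp — and hence
nutrient limitation — over the physiologically observable range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DomainError, ModelParameters, ModelState, p1p2_activity
from .simulate import (
    Event,
    Scenario,
    Trajectory,
    TriggerNotReached,
    apply_upshift,
    simulate,
)

__all__ = [
    "SensorMetrics",
    "sensor_steady_state",
    "dose_response_curve",
    "clamped_sensor_simulation",
    "response_time",
    "half_decay_time",
    "peak_gfp",
    "peak_value",
    "SENSOR_PRESETS",
]

#: named sensor presets: the reference response-time sensor uses a weak
#: repressor coupling (Ki_I = 0.3); the diagnostics sensor uses the
#: optimal Ki_I = 0.1; the high-sensitivity variant uses Ki_I = 0.02.
SENSOR_PRESETS = {
    "response_time_reference": {"k_GFP": 0.1, "Ki_I": 0.3},
    "diagnostics_optimal": {"k_GFP": 0.1, "Ki_I": 0.1},
    "diagnostics_steep": {"k_GFP": 0.1, "Ki_I": 0.02},
}


@dataclass(frozen=True)
class SensorMetrics:
    """Summary of one sensor characterisation run."""

    T05_GFP: float | None = None            # min
    GFP_peak: float | None = None           # dimensionless in [0, 1]
    t_GFP_peak: float | None = None         # min
    dose_response: tuple = field(default_factory=tuple)  # ((ppGpp uM, GFP*), ...)

    def to_json_dict(self) -> dict:
        return {
            "T05_GFP_min": self.T05_GFP,
            "GFP_peak": self.GFP_peak,
            "t_GFP_peak_min": self.t_GFP_peak,
            "dose_response": [list(pair) for pair in self.dose_response],
        }


def sensor_steady_state(ppgpp_clamped: float, p: ModelParameters) -> tuple[float, float]:
    """Steady state (I*, GFP*) of the relay at clamped ppGpp.

    Closed form: I* equals the P1/P2 activity (synthesis and degradation
    of I share the rate constant k_I), and GFP* = 1/(1+(I*/Ki_I)^l).
    """
    i_star = p1p2_activity(ppgpp_clamped, p)
    gfp_star = 1.0 / (1.0 + (i_star / p.Ki_I) ** p.l_hill)
    return i_star, gfp_star


def dose_response_curve(ppgpp_grid, p: ModelParameters) -> tuple[tuple[float, float], ...]:
    """Steady-state GFP* over a grid of clamped ppGpp concentrations.

    The grid must be non-negative and strictly increasing; the returned
    curve is monotone non-decreasing (double-negative composition).
    """
    grid = np.asarray(ppgpp_grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0:
        raise DomainError("ppGpp grid must be a non-empty 1-D sequence")
    if np.any(grid < 0.0):
        raise DomainError("ppGpp grid must be non-negative")
    if np.any(np.diff(grid) <= 0.0) and len(grid) > 1:
        raise DomainError("ppGpp grid must be strictly increasing")
    return tuple((float(c), sensor_steady_state(float(c), p)[1]) for c in grid)


def clamped_sensor_simulation(
    ppgpp_clamped: float, p: ModelParameters, t_end: float = 2500.0
) -> tuple[float, float]:
    """(I, GFP) after a long simulation with ppGpp clamped — the ODE oracle
    for :func:`sensor_steady_state`.

    Uses a cell-free configuration (N = 0, nutrients untouched) so the
    clamped relay relaxes undisturbed to its steady state.
    """
    init = ModelState(
        AcylACP=1.0, FA=0.0, N=0.0, nutr=1.0, lim=1.0,
        ppGpp=ppgpp_clamped, rib=1.0, I=1.0, GFP=0.0,
    )
    scen = Scenario(
        params=p,
        init=init,
        t_end=t_end,
        output_dt=t_end / 10.0,
        events=(Event(action="clamp_ppGpp", value=ppgpp_clamped, time=0.0),),
    )
    traj = simulate(scen)
    return traj.final("I"), traj.final("GFP")


def half_decay_time(traj: Trajectory, t_ref: float, name: str = "GFP") -> float:
    """First time after ``t_ref`` at which ``name`` falls to half its value
    at ``t_ref`` (linearly interpolated); raises :class:`TriggerNotReached`
    if the half level is never reached within the trajectory horizon."""
    ref = traj.value_at(t_ref, name)
    if ref <= 0.0:
        raise DomainError(f"{name} at reference time is not positive")
    target = 0.5 * ref
    t, x = traj.t, traj[name]
    mask = t >= t_ref
    t, x = t[mask], x[mask]
    below = x <= target
    if not below.any():
        raise TriggerNotReached(
            f"{name} never fell to half its reference value within {traj.t[-1]} min"
        )
    i = int(np.argmax(below))
    if i == 0:
        return float(t[0] - t_ref)
    frac = (x[i - 1] - target) / (x[i - 1] - x[i])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]) - t_ref)


def response_time(p: ModelParameters, upshift_scenario: Scenario) -> float:
    """Biosensor response time T0.5,GFP (min).

    Runs the scenario with a nutrient upshift triggered at the end of
    phase 1 (lim crossing the depletion threshold) and returns the time
    needed for a 2-fold decrease of GFP fluorescence after the upshift.
    """
    traj, t_ev = apply_upshift(upshift_scenario.with_updates(params=p))
    return half_decay_time(traj, t_ev, "GFP")


def peak_value(t: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Global maximum of a sampled curve with quadratic refinement.

    Fits a parabola through the three points bracketing the discrete
    maximum, making the peak estimate insensitive to the output grid; at
    the grid boundary the boundary sample is returned.
    """
    i = int(np.argmax(x))
    if i == 0 or i == len(x) - 1:
        return float(x[i]), float(t[i])
    t0, t1, t2 = t[i - 1], t[i], t[i + 1]
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    denom = (t0 - t1) * (t0 - t2) * (t1 - t2)
    a = (t2 * (x1 - x0) + t1 * (x0 - x2) + t0 * (x2 - x1)) / denom
    b = (t2 * t2 * (x0 - x1) + t1 * t1 * (x2 - x0) + t0 * t0 * (x1 - x2)) / denom
    if a >= 0.0:  # degenerate (flat or non-concave) bracket
        return float(x1), float(t1)
    t_pk = -b / (2.0 * a)
    if not (t0 <= t_pk <= t2):
        return float(x1), float(t1)
    c = x1 - a * t1 * t1 - b * t1
    return float(a * t_pk * t_pk + b * t_pk + c), float(t_pk)


def peak_gfp(traj: Trajectory) -> tuple[float, float]:
    """(GFP_peak, t_GFP_peak) over a trajectory, grid-refined."""
    if len(traj) == 0:
        raise DomainError("empty trajectory")
    return peak_value(traj.t, traj["GFP"])
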