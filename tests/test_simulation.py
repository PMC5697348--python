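"""Integration, events, phase detection and trajectory invariants."""

import numpy as np
import pytest

from ppgppsim import (
    Event,
    ModelParameters,
    ModelState,
    PhaseNotReached,
    Scenario,
    detect_phases,
    initial_state,
    simulate,
)
from ppgppsim.core import StateIndex, rhs
from ppgppsim.simulate import TriggerNotReached, apply_upshift, equilibrate_exponential


class TestInitialState:
    def test_fresh_medium_and_inoculum(self, ref_params):
        s = initial_state(ref_params)
        assert s.nutr == 1.0 and s.lim == 1.0
        assert s.N == pytest.approx(0.01)
        assert s.FA == 0.0
        assert s.I == 1.0
        assert s.GFP == pytest.approx(
            1.0 / (1.0 + (1.0 / ref_params.Ki_I) ** ref_params.l_hill)
        )

    def test_core_variables_pre_equilibrated(self, ref_params):
        # with nutrients clamped at 1 the intracellular derivatives vanish
        y = equilibrate_exponential(ref_params)
        s = ModelState.from_array(np.concatenate([np.clip(y, 0, None), [1.0, 0.0]]))
        d = rhs(0.0, s.replace(nutr=1.0, lim=1.0), ref_params)
        for idx in (StateIndex.ACYL_ACP, StateIndex.PPGPP, StateIndex.RIB):
            scale = max(abs(getattr(s, "AcylACP")), 1.0)
            assert abs(d[idx]) < 1e-4 * max(abs(y[idx]), 1.0)


class TestEquilibriumPreservation:
    def test_fixed_point_stays_fixed(self, ref_params):
        # a dormant culture (N = 0, growth switched off) at the intracellular
        # quasi-steady state is a fixed point of the full system
        p = ref_params.with_updates(K_gr=0.0)
        y = np.clip(equilibrate_exponential(p, t_eq=8000.0), 0.0, None)
        y[StateIndex.N] = 0.0
        i0 = 1.0 / (1.0 + (y[StateIndex.PPGPP] / p.Ki_P1P2_ppGpp) ** p.m_hill)
        init = ModelState.from_array(
            np.concatenate([y, [i0, 1.0 / (1.0 + (i0 / p.Ki_I) ** p.l_hill)]])
        )
        traj = simulate(Scenario(params=p, init=init, t_end=500.0, output_dt=50.0))
        for name in ("AcylACP", "ppGpp", "rib", "I", "GFP", "N", "nutr", "lim", "FA"):
            col = traj[name]
            assert col == pytest.approx(col[0], rel=1e-4, abs=1e-9), name


class TestTrajectoryInvariants:
    @pytest.mark.parametrize("run", ["line0_run", "line3_run"])
    def test_non_negativity_and_bounds(self, run, request):
        traj, _ = request.getfixturevalue(run)
        assert np.all(traj.states >= 0.0)
        assert np.all(traj["I"] <= 1.0 + 1e-9)
        assert np.all(traj["GFP"] <= 1.0 + 1e-9)
        assert np.all(traj["nutr"] <= 1.0 + 1e-9)
        assert np.all(traj["lim"] <= 1.0 + 1e-9)

    @pytest.mark.parametrize("run", ["line0_run", "line3_run"])
    def test_nutrients_monotone_non_increasing(self, run, request):
        traj, _ = request.getfixturevalue(run)
        assert np.all(np.diff(traj["nutr"]) <= 1e-12)
        assert np.all(np.diff(traj["lim"]) <= 1e-12)

    def test_no_tes_no_fatty_acid(self, ref_params):
        traj = simulate(
            Scenario(params=ref_params.with_updates(V_tes=0.0), t_end=600.0)
        )
        assert np.all(traj["FA"] == 0.0)

    def test_output_grid_does_not_alter_dynamics(self, ref_params):
        scen = Scenario(params=ref_params, t_end=400.0, output_dt=20.0)
        coarse = simulate(scen)
        fine = simulate(scen.with_updates(output_dt=10.0))
        shared = np.isin(fine.t, coarse.t)
        np.testing.assert_allclose(
            fine.states[shared], coarse.states, rtol=1e-6, atol=1e-10
        )


class TestDetectPhases:
    def test_phase_ordering_on_control_line(self, line0_run):
        traj, _ = line0_run
        ph = detect_phases(traj)
        assert 0.0 < ph.t_phase1_end < ph.t_phase2_end

    def test_constant_nutrient_signals_phase_not_reached(self, ref_params):
        # a dormant culture depletes nothing
        init = initial_state(ref_params).replace(N=0.0)
        traj = simulate(Scenario(params=ref_params, init=init, t_end=200.0))
        with pytest.raises(PhaseNotReached):
            detect_phases(traj)

    def test_higher_threshold_crossed_earlier(self, line0_run):
        traj, _ = line0_run
        early = detect_phases(traj, threshold=0.5)
        late = detect_phases(traj, threshold=0.01)
        assert early.t_phase1_end < late.t_phase1_end
        assert early.t_phase2_end < late.t_phase2_end


class TestEvents:
    def test_noop_reset_leaves_trajectory_unchanged(self, ref_params):
        scen = Scenario(params=ref_params, t_end=300.0, output_dt=10.0)
        ref = simulate(scen)
        lim_at_100 = ref.value_at(100.0, "lim")
        ev = Event(action="set_lim", value=lim_at_100, time=100.0)
        with_ev = simulate(scen.with_updates(events=(ev,)))
        # agreement at the integration-tolerance class: the solver restart
        # shifts the steep lim crash by O(1e-6) min, which dominates the
        # relative difference there
        np.testing.assert_allclose(with_ev.states, ref.states, rtol=1e-3, atol=1e-8)

    def test_state_continuous_across_event_except_reset_component(self, ref_params):
        ev = Event(action="set_nutr", value=1.0, time=150.0)
        scen = Scenario(params=ref_params, t_end=300.0, output_dt=1.0, events=(ev,))
        traj = simulate(scen)
        i = int(np.searchsorted(traj.t, 150.0))
        for name in ("AcylACP", "N", "lim", "ppGpp", "rib", "I", "GFP", "FA"):
            before, after = traj[name][i - 1], traj[name][i + 1]
            assert after == pytest.approx(before, rel=0.05, abs=1e-6), name
        assert traj.value_at(151.0, "nutr") > traj.value_at(149.0, "nutr")

    def test_clamp_holds_ppgpp_constant(self, ref_params):
        evs = (Event(action="clamp_ppGpp", value=300.0, time=0.0),)
        traj = simulate(
            Scenario(params=ref_params, t_end=200.0, output_dt=10.0, events=evs)
        )
        assert np.all(traj["ppGpp"] == 300.0)

    def test_event_log_records_application(self, ref_params):
        evs = (Event(action="set_lim", value=1.0, time=50.0),)
        traj = simulate(Scenario(params=ref_params, t_end=100.0, events=evs))
        assert traj.events_applied == [{"time": 50.0, "action": "set_lim", "value": 1.0}]

    def test_invalid_events_rejected(self):
        from ppgppsim.core import DomainError

        with pytest.raises(DomainError):
            Event(action="set_lim", value=1.0)  # neither time nor trigger
        with pytest.raises(DomainError):
            Event(action="set_lim", value=1.0, time=10.0, trigger=("lim", 0.01))
        with pytest.raises(DomainError):
            Event(action="warp", value=1.0, time=10.0)
        with pytest.raises(DomainError):
            Event(action="set_lim", value=-1.0, time=10.0)


class TestUpshift:
    def test_ppgpp_decreases_after_upshift(self, upshift_run):
        # restored hydrolysis collapses ppGpp within minutes; it stays
        # below the elevated event level while ribosome activity recovers
        traj, t_ev = upshift_run
        pp_ev = traj.value_at(t_ev, "ppGpp")
        assert traj.value_at(t_ev + 2.0, "ppGpp") < 0.5 * pp_ev
        after = (traj.t > t_ev) & (traj.t <= t_ev + 30.0)
        assert np.all(traj["ppGpp"][after] < pp_ev)

    def test_gfp_falls_below_half_event_value(self, upshift_run):
        traj, t_ev = upshift_run
        g_ev = traj.value_at(t_ev, "GFP")
        after = traj["GFP"][traj.t > t_ev]
        assert after.min() < 0.5 * g_ev

    def test_trigger_never_reached_signalled(self, ref_params):
        # a dormant culture never depletes lim
        init = initial_state(ref_params).replace(N=0.0)
        scen = Scenario(params=ref_params, init=init, t_end=200.0)
        with pytest.raises(TriggerNotReached):
            apply_upshift(scen)
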