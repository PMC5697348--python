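"""Unit tests of the algebraic rate laws and the ODE right-hand side."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppgppsim.core import (
    DomainError,
    ModelParameters,
    ModelState,
    derived_rates,
    growth_rate,
    p1p2_activity,
    rhs,
    v_fa,
    v_fas,
    v_pls,
)


def state(**kw) -> ModelState:
    base = dict(AcylACP=1.0, FA=0.0, N=0.1, nutr=1.0, lim=1.0,
                ppGpp=50.0, rib=1.0, I=0.5, GFP=0.1)
    base.update(kw)
    return ModelState(**base)


@pytest.fixture(scope="module")
def p():
    # saturating substrate pools so the two Michaelis factors are ~1
    return ModelParameters(ACP_const=1e6, AcCoA_const=1e6)


class TestFasRate:
    def test_no_ribosome_activity_no_flux(self, p):
        assert v_fas(state(rib=0.0), p) == 0.0

    def test_saturating_substrates_no_feedback(self, p):
        val = v_fas(state(AcylACP=0.0, rib=1.0), p)
        assert val == pytest.approx(p.Vm_FAS, rel=1e-4)

    def test_half_inhibition_at_ki(self, p):
        val = v_fas(state(AcylACP=p.Ki_AcylACP, rib=1.0), p)
        assert val == pytest.approx(p.Vm_FAS / 2, rel=1e-4)

    def test_strictly_decreasing_in_acyl_acp(self, p):
        vals = [v_fas(state(AcylACP=a), p) for a in np.linspace(0, 20, 40)]
        assert np.all(np.diff(vals) < 0)

    def test_conserved_acp_mode_depletes_free_pool(self):
        pc = ModelParameters(acp_coupling="conserved", ACP_const=10.0)
        # free ACP = total - AcylACP; at AcylACP = total the FAS flux dies
        assert v_fas(state(AcylACP=10.0), pc) == 0.0
        assert v_fas(state(AcylACP=1.0), pc) > 0.0


class TestPlsRate:
    def test_no_substrate_no_flux(self, p):
        assert v_pls(state(AcylACP=0.0), p) == 0.0

    def test_half_inhibition_at_ki_ppgpp(self, p):
        val = v_pls(state(AcylACP=1e6, ppGpp=p.Ki_ppGpp, rib=1.0), p)
        assert val == pytest.approx(p.Vm_PLS / 2, rel=1e-4)

    def test_full_inhibition_limit(self, p):
        assert v_pls(state(ppGpp=1e12), p) == pytest.approx(0.0, abs=1e-12)

    def test_strictly_decreasing_in_ppgpp(self, p):
        vals = [v_pls(state(ppGpp=c), p) for c in np.linspace(0, 2000, 50)]
        assert np.all(np.diff(vals) < 0)


class TestTesRate:
    def test_no_substrate(self, p):
        assert v_fa(0.0, p) == 0.0

    def test_half_saturation(self, p):
        assert v_fa(p.Km_tes, p) == pytest.approx(p.V_tes / 2)

    @pytest.mark.parametrize("v_tes", [0.08, 1.6, 19.0, 110.0])
    def test_linear_in_tes_activity(self, p, v_tes):
        # at fixed Acyl-ACP the rate scales linearly with enzyme activity
        base = v_fa(2.0, p.with_updates(V_tes=1.0))
        assert v_fa(2.0, p.with_updates(V_tes=v_tes)) == pytest.approx(v_tes * base)

    def test_negative_input_rejected(self, p):
        with pytest.raises(DomainError):
            v_fa(-1.0, p)


class TestP1P2:
    def test_uninhibited_promoter(self, p):
        assert p1p2_activity(0.0, p) == 1.0

    def test_half_inhibition(self, p):
        assert p1p2_activity(p.Ki_P1P2_ppGpp, p) == pytest.approx(0.5)

    def test_three_ki_with_m2_gives_tenth(self, p):
        # 1/(1 + 3^2) with the squared Hill form
        assert p1p2_activity(3 * p.Ki_P1P2_ppGpp, p) == pytest.approx(0.1)

    def test_strictly_decreasing(self, p):
        vals = [p1p2_activity(c, p) for c in np.linspace(0, 3000, 60)]
        assert np.all(np.diff(vals) < 0)


class TestGrowthRate:
    def test_stationary_phase_no_growth(self, p):
        assert growth_rate(state(nutr=0.0), p) == 0.0

    def test_half_saturation_in_pls(self):
        # engineer V_PLS == V0 exactly: saturating substrate, no inhibition
        p = ModelParameters(ACP_const=1e6, AcCoA_const=1e6, Km_AcylACP=1e-9,
                            Ki_ppGpp=1e9, V0=60.0)
        s = state(AcylACP=1e6, ppGpp=0.0, rib=1.0, nutr=1.0)
        assert growth_rate(s, p) == pytest.approx(p.K_gr / 2, rel=1e-4)

    def test_pls_unlimited_growth(self, p):
        pv = p.with_updates(V0=1e-9)
        assert growth_rate(state(rib=1.0), pv) == pytest.approx(p.K_gr, rel=1e-4)


class TestParameterValidation:
    @pytest.mark.parametrize("field,value", [
        ("Km_tes", -1.0), ("Km_tes", 0.0), ("Vm_FAS", -5.0),
        ("Ki_I", 0.0), ("m_hill", 0.5), ("l_hill", 0.0),
    ])
    def test_invalid_parameters_rejected(self, field, value):
        with pytest.raises(DomainError, match=field):
            ModelParameters(**{field: value})

    def test_switch_off_values_allowed(self):
        ModelParameters(V_tes=0.0, K_gr=0.0, k_nutr=0.0)

    def test_unknown_acp_coupling_rejected(self):
        with pytest.raises(DomainError):
            ModelParameters(acp_coupling="linked")


class TestStateValidation:
    def test_negative_component_rejected(self):
        with pytest.raises(DomainError, match="ppGpp"):
            state(ppGpp=-1.0)

    def test_bounded_components_rejected_above_one(self):
        with pytest.raises(DomainError):
            state(GFP=1.5)

    def test_non_finite_rejected(self):
        with pytest.raises(DomainError):
            state(AcylACP=math.nan)


class TestRhs:
    def test_flux_balance_identity_exact(self, p):
        s = state()
        d = rhs(0.0, s, p)
        expect = v_fas(s, p) - v_pls(s, p) - p.k_fa * v_fa(s.AcylACP, p)
        assert d[0] == expect  # exact algebraic identity, no tolerance

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        acyl=st.floats(0, 1e3), ppgpp=st.floats(0, 1e4),
        rib=st.floats(0, 5), n=st.floats(0, 10),
        nutr=st.floats(0, 1), lim=st.floats(0, 1),
    )
    def test_flux_balance_identity_property(self, acyl, ppgpp, rib, n, nutr, lim):
        p = ModelParameters()
        s = state(AcylACP=acyl, ppGpp=ppgpp, rib=rib, N=n, nutr=nutr, lim=lim)
        d = rhs(0.0, s, p)
        expect = v_fas(s, p) - v_pls(s, p) - p.k_fa * v_fa(s.AcylACP, p)
        assert d[0] == expect

    def test_cascade_equilibrium_when_i_matches_promoter(self, p):
        s = state(I=p1p2_activity(50.0, p), ppGpp=50.0)
        assert rhs(0.0, s, p)[7] == pytest.approx(0.0, abs=1e-15)

    def test_fas_equals_pls_without_tes_at_quasi_steady_state(self):
        # with no thioesterase, d(AcylACP)/dt = 0 forces V_FAS = V_PLS
        from scipy.optimize import brentq

        p = ModelParameters(V_tes=0.0)

        def d_acyl(a):
            return rhs(0.0, state(AcylACP=a), p)[0]

        a_star = brentq(d_acyl, 1e-6, 100.0)
        s = state(AcylACP=a_star)
        assert v_fas(s, p) == pytest.approx(v_pls(s, p), rel=1e-10)

    def test_loss_terms_vanish_at_zero(self, p):
        # every component's loss term vanishes at 0, so derivatives there
        # are non-negative wherever the state is at the boundary
        s = state(AcylACP=0.0, FA=0.0, N=0.0, nutr=0.0, lim=0.0,
                  ppGpp=0.0, rib=0.0, I=0.0, GFP=0.0)
        assert np.all(rhs(0.0, s, ModelParameters()) >= 0.0)

    def test_derived_rates_bounds(self, p):
        d = derived_rates(state(), p)
        assert 0.0 < d.P1P2 <= 1.0
        assert d.V_FAS >= 0 and d.V_PLS >= 0 and d.V_FA >= 0 and d.v_g >= 0
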