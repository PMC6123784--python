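"""Promoter function, topology construction, and right-hand-side contracts."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from luxlink.circuit import (
    ModelParams,
    PopulationState,
    SystemState,
    build_configuration,
    model_rhs,
    observable,
    promoter_activity,
    rhs_array,
    sensed_ahl,
)
from luxlink.errors import ConfigurationError, InputDomainError, NumericalStateError


@pytest.fixture
def hill_params():
    return ModelParams(delta=0.02, alpha=1.0, C0=30.0, n_hill=2.0)


def _state(rho=0.5, I=0.0, A=0.0, G=0.0, H=0.0, rho_r=None, I_r=0.0,
           A_r=0.0, G_r=0.0, H_r=0.0, t=0.0):
    s = PopulationState(rho, I, A, G, H)
    r = PopulationState(rho if rho_r is None else rho_r, I_r, A_r, G_r, H_r)
    return SystemState(s, r, t)


class TestPromoterActivity:
    def test_basal_limit(self, hill_params):
        assert promoter_activity(0.0, hill_params) == pytest.approx(0.02)

    def test_half_activation(self, hill_params):
        assert promoter_activity(30.0, hill_params) == pytest.approx(0.52)

    def test_saturation(self, hill_params):
        assert promoter_activity(1e6, hill_params) == pytest.approx(1.02, abs=1e-6)

    def test_negative_input_rejected(self, hill_params):
        with pytest.raises(InputDomainError):
            promoter_activity(-1.0, hill_params)

    @settings(max_examples=50, deadline=None)
    @given(H=st.floats(min_value=0.0, max_value=1e9))
    def test_bounded_and_monotone(self, H):
        p = ModelParams()
        v = promoter_activity(H, p)
        assert p.delta <= v <= p.delta + p.alpha + 1e-12
        assert promoter_activity(H * 1.5 + 1e-9, p) >= v - 1e-12


class TestSensedAhl:
    def test_no_lactonase_tracks_compartment(self):
        p = ModelParams()
        for H in (0.0, 5.0, 50.0, 500.0):
            assert sensed_ahl(H, 0.0, p) == pytest.approx(H, rel=1e-12, abs=1e-12)

    def test_lactonase_depletes_cytoplasm(self):
        p = ModelParams()
        assert sensed_ahl(100.0, 200.0, p) < 100.0

    def test_monotone_decreasing_in_aiiA(self):
        p = ModelParams()
        vals = [sensed_ahl(50.0, A, p) for A in (0.0, 10.0, 100.0, 1000.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestBuildConfiguration:
    def test_osc_a_receiver_lacks_luxI(self):
        cfg = build_configuration("OSC_A")
        assert cfg.receiver.has_luxI is False
        assert cfg.receiver.has_aiiA is True

    def test_ind_induction_time(self):
        cfg = build_configuration("IND")
        assert cfg.sender.induction_time == 180.0
        assert cfg.sender.driver == "arabinose"

    def test_blocked_differs_only_in_coupling(self):
        ind = build_configuration("IND")
        blk = build_configuration("IND_BLOCKED")
        assert blk.coupling_enabled is False
        assert blk.sender == ind.sender
        assert blk.receiver == ind.receiver

    def test_osc_b_and_c_are_deletions_of_a(self):
        a = build_configuration("OSC_A")
        b = build_configuration("OSC_B")
        c = build_configuration("OSC_C")
        assert b.sender == a.sender
        assert b.receiver == dataclasses.replace(a.receiver, has_aiiA=False)
        assert c.receiver == a.receiver
        assert c.sender == dataclasses.replace(a.sender, has_aiiA=False)

    def test_unknown_name_lists_valid(self):
        with pytest.raises(ConfigurationError) as err:
            build_configuration("OSC_X")
        assert "OSC_A" in str(err.value)


class TestModelRhs:
    def test_pure_exchange_antisymmetry(self):
        # no production, no decay: exchange moves AHL conservatively
        p = ModelParams(mu_H=0.0, k_cat=0.0, k_x=1.0, kappa_I=0.0,
                        kappa_A=0.0, kappa_G=0.0, kappa_G_receiver=0.0, b=0.0)
        cfg = build_configuration("OSC_A")
        st_ = _state(H=100.0, H_r=0.0)
        d = model_rhs(st_, (0.0, 0.0), cfg, p)
        assert d.sender.H == pytest.approx(-100.0)
        assert d.receiver.H == pytest.approx(100.0)

    def test_logistic_growth_at_half_capacity(self):
        p = ModelParams(r_growth=0.0244)
        d = model_rhs(_state(rho=0.5), (0.0, 0.0),
                      build_configuration("OSC_A"), p)
        assert d.sender.rho == pytest.approx(0.0244 * 0.25)

    def test_washout_only(self):
        p = ModelParams(mu_H=0.1, k_x=0.0, b=0.0)
        d = model_rhs(_state(H=10.0, H_r=10.0), (0.0, 0.0),
                      build_configuration("OSC_A"), p)
        assert d.sender.H == pytest.approx(-1.0)

    def test_nan_state_identifies_field(self):
        with pytest.raises(NumericalStateError, match="receiver.G"):
            bad = _state()
            bad.receiver.G = float("nan")
            model_rhs(bad, (0.0, 0.0), build_configuration("OSC_A"),
                      ModelParams())

    @pytest.mark.parametrize("topology", ["IND", "IND_BLOCKED", "OSC_A",
                                          "OSC_B", "OSC_C"])
    def test_production_terms_match_topology_flags(self, topology):
        """Unit-impulse probe: a gene produces iff the topology carries it."""
        cfg = build_configuration(topology)
        p = ModelParams()
        y = np.zeros(10)
        y[0] = y[5] = 1.0
        # saturating sensed AHL and past-induction time: all drives ~ max
        dy = rhs_array(1000.0, y, (1e9, 1e9), cfg, p)
        for ip, circ in enumerate((cfg.sender, cfg.receiver)):
            o = 5 * ip
            assert (dy[o + 1] > 0) == circ.has_luxI
            assert (dy[o + 2] > 0) == circ.has_aiiA
            assert (dy[o + 3] > 0) == circ.has_reporter

    def test_blocked_coupling_zeroes_exchange(self):
        p = ModelParams(mu_H=0.0, b=0.0, k_cat=0.0)
        blk = build_configuration("IND_BLOCKED")
        d = model_rhs(_state(H=50.0, H_r=0.0, t=0.0), (0.0, 0.0), blk, p)
        assert d.sender.H == 0.0
        assert d.receiver.H == 0.0


class TestObservable:
    @pytest.mark.parametrize(("rho", "G", "expected"),
                             [(1.0, 40.0, 40.0), (0.5, 40.0, 20.0),
                              (0.9, 0.0, 0.0)])
    def test_values(self, rho, G, expected):
        st_ = _state(rho=rho, G=G, rho_r=rho, G_r=G)
        assert observable(st_, "sender") == pytest.approx(expected)
        assert observable(st_, "receiver") == pytest.approx(expected)

    def test_unknown_population(self):
        with pytest.raises(ConfigurationError):
            observable(_state(), "middle")


class TestValidation:
    def test_population_state_rejects_negative(self):
        with pytest.raises(InputDomainError):
            PopulationState(0.5, -1.0, 0.0, 0.0, 0.0)

    def test_density_capped_at_one(self):
        with pytest.raises(InputDomainError):
            PopulationState(1.5, 0.0, 0.0, 0.0, 0.0)

    def test_params_reject_negative_rates(self):
        with pytest.raises(ConfigurationError, match="k_x"):
            ModelParams(k_x=-1.0)

    def test_hill_coefficient_at_least_one(self):
        with pytest.raises(ConfigurationError):
            ModelParams(n_hill=0.5)
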