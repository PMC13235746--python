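"""Instantaneous model: Liebig growth, uptake slaving, excretion, budgets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from nitrocrm import (
    CommunityState,
    SupplySpec,
    compute_fluxes,
    nitrogen_budget_residual,
    potential_growth,
    realized_growth,
    rhs,
)
from nitrocrm.model import excretion_fluxes
from nitrocrm.traits import HETEROTROPHS, resource_index, type_index


def state_with(R, B=None):
    return CommunityState(np.zeros(7) if B is None else B, R)


class TestPotentialGrowth:
    def test_half_saturation(self, traits):
        # at R = K the Monod factor is 1/2, so growth = y*Vm/2
        st_ = state_with([0.1, 0, 0, 0, 0])
        assert potential_growth(traits, st_, "B1", "OM") == pytest.approx(
            0.15 * 1.377 / 2
        )

    def test_zero_resource_gives_zero(self, traits):
        st_ = state_with(np.zeros(5))
        for tp, res in traits.used_pairs():
            assert potential_growth(traits, st_, tp, res) == 0.0

    def test_saturation_limit(self, traits):
        st_ = state_with([1e9, 0, 0, 0, 0])
        assert potential_growth(traits, st_, "B1", "OM") == pytest.approx(
            0.20655, rel=1e-4
        )

    def test_unused_pair_raises(self, traits):
        with pytest.raises(ValueError, match="does not use"):
            potential_growth(traits, state_with(np.ones(5)), "B5", "OM")

    @settings(max_examples=50, deadline=None)
    @given(r1=st.floats(0, 100), r2=st.floats(0, 100))
    def test_monotone_in_resource(self, traits, r1, r2):
        lo, hi = sorted([r1, r2])
        g = lambda r: potential_growth(traits, state_with([r, 0, 0, 0, 0]), "B1", "OM")
        assert g(lo) <= g(hi)


class TestRealizedGrowth:
    def test_limited_by_acceptor_at_its_rstar(self, traits):
        from nitrocrm.theory import subsistence_concentration

        rstar = subsistence_concentration(traits, "B1", "NO3")
        st_ = state_with([1e9, rstar, 0, 0, 0])
        rate, limiting, colim = realized_growth(traits, st_, "B1")
        assert rate == pytest.approx(traits.dilution, rel=1e-9)
        assert limiting == "NO3"
        assert not colim

    def test_essential_resources_not_substitutable(self, traits):
        # anammox with NH4+ plentiful but no NO2- cannot grow at all
        st_ = state_with([0, 0, 0, 0, 100.0])
        rate, _, _ = realized_growth(traits, st_, "B5")
        assert rate == 0.0

    def test_colimitation_flagged_at_double_rstar(self, traits):
        from nitrocrm.theory import subsistence_concentration

        r_om = subsistence_concentration(traits, "B1", "OM")
        r_no3 = subsistence_concentration(traits, "B1", "NO3")
        rate, limiting, colim = realized_growth(
            traits, state_with([r_om, r_no3, 0, 0, 0]), "B1"
        )
        assert rate == pytest.approx(traits.dilution, rel=1e-9)
        assert limiting == "OM"  # tie reports the lowest resource index
        assert colim


class TestExcretion:
    def test_b1_routes_all_reduced_nitrate_to_nitrite(self, traits):
        st_ = state_with([1e9, 1e9, 0, 0, 0], B=np.eye(7)[0])
        fr = compute_fluxes(traits, st_)
        mu1 = fr.mu[0]
        e = excretion_fluxes(traits, fr, "B1")
        assert e[resource_index("NO2")] == pytest.approx(mu1 / 0.011)
        # NH4+ release closes the OM nitrogen balance: e = mu (1/y_OM - 1)
        assert e[resource_index("NH4")] == pytest.approx(mu1 * (1 / 0.15 - 1))
        assert e[resource_index("OM")] == 0 and e[resource_index("NO3")] == 0

    def test_excretion_at_dilution_rate_reference_numbers(self, traits):
        # a B1 cell growing at a = 0.04/d excretes NO2- at 3.636/d and
        # NH4+ at 0.2267/d per unit biomass
        from nitrocrm.theory import subsistence_concentration

        r_no3 = subsistence_concentration(traits, "B1", "NO3")
        st_ = state_with([1e9, r_no3, 0, 0, 0], B=np.eye(7)[0])
        fr = compute_fluxes(traits, st_)
        e = excretion_fluxes(traits, fr, "B1")
        assert e[resource_index("NO2")] == pytest.approx(3.636, rel=1e-3)
        assert e[resource_index("NH4")] == pytest.approx(0.2267, rel=1e-3)

    def test_anammox_excretes_nothing(self, traits):
        st_ = state_with(np.full(5, 10.0), B=np.eye(7)[4])
        fr = compute_fluxes(traits, st_)
        assert np.all(excretion_fluxes(traits, fr, "B5") == 0.0)

    def test_heterotroph_nitrogen_closure(self, traits):
        """OM-N uptake = growth + NH4+ excretion for every heterotroph."""
        st_ = state_with(np.full(5, 5.0), B=np.full(7, 0.1))
        fr = compute_fluxes(traits, st_)
        jom, jnh4 = resource_index("OM"), resource_index("NH4")
        for tp in HETEROTROPHS:
            i = type_index(tp)
            assert fr.Vr[i, jom] == pytest.approx(fr.mu[i] + fr.E[i, jnh4], rel=1e-12)


class TestRHS:
    def test_washout_is_fixed_point(self, traits, supply_b1):
        dB, dR, _ = rhs(traits, supply_b1.washout_state(), supply_b1)
        assert np.all(dB == 0)
        np.testing.assert_allclose(dR, 0, atol=1e-15)

    def test_single_species_equilibrium_is_stationary(self, traits, supply_b1):
        from nitrocrm import single_species_closed_form

        st_ = single_species_closed_form(traits, "B1", supply_b1)
        dB, dR, _ = rhs(traits, st_, supply_b1)
        assert np.max(np.abs(np.concatenate([dB, dR]))) < 1e-10

    def test_negative_state_rejected(self, traits, supply_b1):
        bad = CommunityState(np.full(7, -1e-6), supply_b1.s.copy())
        with pytest.raises(ValueError, match="negative"):
            rhs(traits, bad, supply_b1)

    def test_liebig_uptake_slaving(self, traits):
        """Vr_ij * y_ij equals mu_i on every used resource (uptake is slaved
        to the limiting resource, never independent)."""
        st_ = state_with(np.array([0.5, 2.0, 0.3, 0.1, 0.7]), B=np.full(7, 0.2))
        fr = compute_fluxes(traits, st_)
        prod = fr.Vr * np.nan_to_num(traits.y)
        for i in range(7):
            used = traits.usage[i]
            np.testing.assert_allclose(prod[i, used], fr.mu[i], rtol=1e-12)

    @settings(max_examples=80, deadline=None)
    @given(
        x=arrays(np.float64, 12, elements=st.floats(0, 50)),
        s=arrays(np.float64, 5, elements=st.floats(0, 50)),
    )
    def test_nitrogen_budget_closes_everywhere(self, traits, x, s):
        """a·Σs − a·(ΣR + ΣB) − d/dt(ΣR + ΣB) − N2 ≡ 0 at any state."""
        state = CommunityState(x[:7], x[7:])
        resid = nitrogen_budget_residual(traits, state, SupplySpec(s))
        assert abs(resid) < 1e-10


class TestGasFluxes:
    def test_all_zero_without_biomass(self, traits):
        fr = compute_fluxes(traits, state_with(np.full(5, 10.0)))
        assert fr.gas_n2 == fr.gas_n2o_prod == fr.gas_n2o_cons == 0.0

    def test_b2_produces_n2o_without_consumption(self, traits):
        st_ = state_with(np.full(5, 10.0), B=np.array([0.1, 0.1, 0, 0, 0, 0, 0.0]))
        fr = compute_fluxes(traits, st_)
        assert fr.gas_n2 == 0.0
        assert fr.gas_n2o_prod > 0.0
        assert fr.gas_n2o_cons == 0.0

    def test_anammox_n2_contribution(self, traits):
        """At mu5 = a the anammox N2 rate is (a/y_NO2 + a/y_NH4 − a)·B5."""
        from nitrocrm.theory import subsistence_concentration

        r_no2 = subsistence_concentration(traits, "B5", "NO2")
        st_ = state_with([0, 0, r_no2, 0, 100.0], B=np.eye(7)[4] * 0.5)
        fr = compute_fluxes(traits, st_)
        a = traits.dilution
        expected = (a / 0.011 + a / 0.013 - a) * 0.5
        assert fr.gas_n2 == pytest.approx(expected, rel=1e-9)
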