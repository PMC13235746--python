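"""Resource-ratio theory: R*, consumption vectors, feeder thresholds, ZNGIs."""

import numpy as np
import pytest

from nitrocrm import (
    CommunityState,
    SupplySpec,
    anammox_supply_zngi,
    consortium_consumption_vector,
    consumption_vector,
    feeder_threshold_biomass,
    find_equilibrium,
    rstar_table,
    subsistence_concentration,
    zngi,
)
from nitrocrm.theory import NonPersistenceError
from nitrocrm.traits import resource_index, type_index


class TestSubsistence:
    @pytest.mark.parametrize(
        "tp,res,expected",
        [
            ("B1", "OM", 0.0240),
            ("B4", "OM", 0.0108),
            ("B6", "NO2", 0.2066),
            ("B7", "NO3", 0.124),
        ],
    )
    def test_reference_values(self, traits, tp, res, expected):
        assert subsistence_concentration(traits, tp, res) == pytest.approx(
            expected, rel=0.01
        )

    def test_zero_dilution_gives_zero(self, traits):
        t0 = traits.with_dilution(0.0)
        assert subsistence_concentration(t0, "B1", "OM") == 0.0

    def test_unsustainable_dilution_raises(self, traits):
        t = traits.with_dilution(0.25)  # > y*Vm = 0.207 for (B1, OM)
        with pytest.raises(NonPersistenceError):
            subsistence_concentration(t, "B1", "OM")

    def test_table_covers_all_pairs(self, traits):
        assert len(rstar_table(traits)) == 14

    def test_om_ordering_across_pathway(self, traits):
        """Downstream modules are better OM competitors: R*3,OM < R*1,OM <
        R*2,OM; anammox beats B3 on NO2-."""
        r = lambda tp, res: subsistence_concentration(traits, tp, res)
        assert r("B3", "OM") < r("B1", "OM") < r("B2", "OM")
        assert r("B5", "NO2") < r("B3", "NO2")


class TestConsumptionVectors:
    def test_individual_values(self, traits):
        assert consumption_vector(traits, "B1").value == pytest.approx(13.64, abs=0.01)
        assert consumption_vector(traits, "B3").value == pytest.approx(8.208, abs=0.01)
        assert consumption_vector(traits, "B2").value == pytest.approx(6.435, abs=0.01)

    def test_anammox_has_no_consumption_vector(self, traits):
        with pytest.raises(ValueError, match="OM"):
            consumption_vector(traits, "B5")

    def test_consortium_values(self, traits):
        c13 = consortium_consumption_vector(traits, "B1", "B3")
        c24 = consortium_consumption_vector(traits, "B2", "B4")
        assert c13.value == pytest.approx(5.124, abs=0.005)
        assert c24.value == pytest.approx(5.024, abs=0.005)

    def test_consortium_below_feeder(self, traits):
        """A recipient always tilts the pair toward relatively more OM use."""
        for feeder, recipient in (("B1", "B3"), ("B2", "B4")):
            pair = consortium_consumption_vector(traits, feeder, recipient)
            assert pair.value < consumption_vector(traits, feeder).value

    def test_nondependent_pair_rejected(self, traits):
        with pytest.raises(ValueError, match="not a feeder-recipient pair"):
            consortium_consumption_vector(traits, "B1", "B4")

    def test_consortium_limit_strong_recipient(self, traits):
        """As the recipient's own vector grows, the pair tends to the feeder's."""
        import dataclasses

        y = traits.y.copy()
        y[type_index("B3"), resource_index("NO2")] = 1e-9  # c3 -> infinity
        t2 = dataclasses.replace(traits, y=y)
        c1 = consumption_vector(t2, "B1").value
        c13 = consortium_consumption_vector(t2, "B1", "B3").value
        assert c13 == pytest.approx(c1, rel=1e-6)

    def test_community_uptake_matches_c13_at_pair_equilibrium(self, traits):
        """At a simulated {B1,B3} equilibrium with B3 NO2-limited, the
        community NO3:OM uptake ratio equals the composite vector."""
        sup = SupplySpec.om_no3(3.0, 30.0)
        B = np.zeros(7)
        B[[0, 2]] = 1e-3
        eq = find_equilibrium(traits, CommunityState(B, sup.s.copy()), sup)
        assert eq.persistent_set == {"B1", "B3"}
        assert eq.limiting["B3"] == "NO2"
        up = eq.fluxes.Vr * eq.state.B[:, None]
        ratio = up[:, 1].sum() / up[:, 0].sum()  # NO3-N per OM-N consumed
        c13 = consortium_consumption_vector(traits, "B1", "B3").value
        assert ratio == pytest.approx(c13, rel=0.01)


class TestFeederThreshold:
    def test_reference_value(self, traits):
        # a·y(B1,NO3)/mu with mu = a gives exactly the feeder yield 0.011
        assert feeder_threshold_biomass(traits, "B1", "B5", 0.04) == pytest.approx(0.011)
        assert feeder_threshold_biomass(traits, "B1", "B3", 0.04) == pytest.approx(0.011)

    def test_inverse_proportionality(self, traits):
        t1 = feeder_threshold_biomass(traits, "B1", "B5", 0.04)
        t2 = feeder_threshold_biomass(traits, "B1", "B5", 0.08)
        assert t2 == pytest.approx(t1 / 2)

    def test_rejects_nonpositive_growth(self, traits):
        with pytest.raises(ValueError, match="positive"):
            feeder_threshold_biomass(traits, "B1", "B5", 0.0)

    def test_rejects_non_recipient(self, traits):
        with pytest.raises(ValueError, match="does not consume"):
            feeder_threshold_biomass(traits, "B1", "B4", 0.04)


class TestZNGI:
    def test_b1_corner(self, traits):
        poly = zngi(traits, "B1", ("OM", "NO3"))
        corner = poly.vertices[1]
        assert corner[0] == pytest.approx(0.024, rel=0.01)
        assert corner[1] == pytest.approx(0.295, rel=0.05)

    def test_b3_corner(self, traits):
        poly = zngi(traits, "B3", ("OM", "NO2"))
        corner = poly.vertices[1]
        assert corner[0] == pytest.approx(0.0172, rel=0.01)
        assert corner[1] == pytest.approx(0.138, rel=0.02)

    def test_inapplicable_axes_raise(self, traits):
        with pytest.raises(ValueError, match="does not use"):
            zngi(traits, "B1", ("OM", "NO2"))

    def test_anammox_boundary_above_b1_boundary(self, traits):
        """At fixed NO3- supply, anammox needs strictly more OM supply than
        B1 itself: the feeder must be dense enough, not merely present."""
        curve = anammox_supply_zngi(traits, np.array([30.0]))
        s1_b5 = curve.vertices[0, 0]
        s1_b1 = subsistence_concentration(traits, "B1", "OM")
        assert s1_b5 > s1_b1
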