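"""Producer rules, remineralisation pathways and the oxidant loops."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxybox.ecosystem import (
    EcosystemParams,
    diazotroph_production,
    make_compensating_ecosystem,
    ordinary_production,
    remineralize,
)
from oxybox.stoichiometry import StoichiometryParams

STOICH = StoichiometryParams()


@pytest.fixture(scope="module")
def eco():
    return EcosystemParams()


class TestProduction:
    def test_nitrate_limitation(self, eco):
        assert ordinary_production(0.0, 1.0, 20.0, eco) == 0.0

    def test_phosphate_limitation(self, eco):
        assert ordinary_production(10.0, 0.0, 20.0, eco) == 0.0
        assert diazotroph_production(0.0, 20.0, eco) == 0.0

    def test_saturation_limit(self, eco):
        rate = ordinary_production(1e4, 1e4, 20.0, eco)
        assert rate == pytest.approx(
            eco.mu_max_phy * eco.biomass_proxy, rel=1e-3
        )

    def test_diazotrophs_dead_just_below_cutoff(self, eco):
        """Zero growth at temperatures below 15 degC: a hard step."""
        assert diazotroph_production(1.0, 14.9, eco) == 0.0
        assert diazotroph_production(1.0, 15.0, eco) > 0.0

    def test_diazotroph_rate_below_half_ordinary(self, eco):
        warm, rich = 20.0, 1e4
        d = diazotroph_production(rich, warm, eco)
        o = ordinary_production(rich, rich, warm, eco)
        assert d <= 0.5 * o

    def test_diazotrophs_ignore_nitrate(self, eco):
        """Fixation proceeds in nitrate-free water."""
        assert diazotroph_production(1.0, 20.0, eco) > 0.0

    def test_growth_rate_bound_enforced(self):
        with pytest.raises(ValueError):
            EcosystemParams(mu_max_phy=2.0, mu_max_diaz=1.0)

    def test_partition_must_normalise(self):
        with pytest.raises(ValueError):
            EcosystemParams(partition={"LowLatSurface": {"Deep": 0.5}})

    def test_compensating_variant_leaves_producers_untouched(self, eco):
        comp = make_compensating_ecosystem({"Deep": -10.0}, eco)
        assert comp.mu_max_diaz == eco.mu_max_phy * 0 + eco.mu_max_diaz
        assert comp.compensating_restore_rate > 0.0
        assert comp.compensation_reference_nstar == {"Deep": -10.0}


class TestRemineralize:
    def test_aerobic_pathway_consumes_10_6_per_orgN(self):
        """1 mol organic N (1/16 mol P) costs 10.6 mol O2 aerobically."""
        flux_p = 1.0 / 16.0
        res = remineralize(flux_p, o2=100.0, no3=30.0, stoich=STOICH)
        assert -res.d_o2 == pytest.approx(10.6, abs=1e-12)
        assert res.d_no3 == pytest.approx(1.0, abs=1e-12)  # org N returned
        assert res.denitrified_fraction == 0.0
        assert res.remainder_p == 0.0

    def test_suboxic_pathway_removes_7_48_per_orgN(self):
        """Below the threshold with ample NO3: 7.48 mol NO3 drawn down
        gross per mol organic N, no O2 consumed."""
        flux_p = 1.0 / 16.0
        res = remineralize(flux_p, o2=2.0, no3=30.0, stoich=STOICH)
        assert res.d_o2 == 0.0
        # net change: gross draw 7.48 minus the 1.0 organic N returned
        assert res.d_no3 == pytest.approx(-(7.48 - 1.0), abs=1e-12)
        assert res.denitrified_fraction == 1.0

    def test_remineralisation_stops_without_nitrate(self):
        res = remineralize(1.0, o2=2.0, no3=0.0, stoich=STOICH)
        assert res.aerobic_p == 0.0 and res.denitrified_p == 0.0
        assert res.remainder_p == 1.0
        assert res.d_o2 == 0.0 and res.d_no3 == 0.0 and res.d_po4 == 0.0

    def test_tie_breaks_aerobic_at_threshold(self):
        res = remineralize(1e-9, o2=STOICH.o2_threshold, no3=30.0,
                           stoich=STOICH)
        assert res.denitrified_p == 0.0
        assert res.aerobic_p > 0.0

    def test_negative_flux_rejected(self):
        with pytest.raises(ValueError):
            remineralize(-1.0, 100.0, 30.0, STOICH)

    def test_capacity_split_resolves_subbox_suboxia(self):
        """With a finite O2 capacity the excess demand denitrifies."""
        res = remineralize(
            1.0, o2=10.0, no3=30.0, stoich=STOICH,
            o2_capacity=0.5 * STOICH.r_o2p,
        )
        assert res.aerobic_p == pytest.approx(0.5)
        assert res.denitrified_p == pytest.approx(0.5)
        assert res.denitrified_fraction == pytest.approx(0.5)

    @given(
        flux=st.floats(0.0, 10.0, allow_nan=False),
        o2=st.floats(0.0, 300.0, allow_nan=False),
        no3=st.floats(0.0, 40.0, allow_nan=False),
        o2_cap=st.floats(0.0, 2000.0, allow_nan=False),
        no3_cap=st.floats(0.0, 2000.0, allow_nan=False),
    )
    @settings(deadline=None, max_examples=200)
    def test_bookkeeping_properties(self, flux, o2, no3, o2_cap, no3_cap):
        res = remineralize(
            flux, o2, no3, STOICH, o2_capacity=o2_cap, no3_capacity=no3_cap
        )
        # pathway split is a partition of the flux
        assert res.aerobic_p >= 0 and res.denitrified_p >= 0
        assert res.remainder_p >= -1e-12
        assert res.aerobic_p + res.denitrified_p + res.remainder_p == (
            pytest.approx(flux, rel=1e-12, abs=1e-12)
        )
        assert 0.0 <= res.denitrified_fraction <= 1.0
        # no O2 drawn below the threshold; none at all when suboxic
        if o2 < STOICH.o2_threshold:
            assert res.aerobic_p == 0.0
        # oxidant accounting follows the split exactly
        assert res.d_o2 == pytest.approx(-STOICH.r_o2p * res.aerobic_p)
        assert res.d_po4 == pytest.approx(res.aerobic_p + res.denitrified_p)


class TestOxidantLoops:
    """Closed production/remineralisation cycles, the heart of why a
    nitrate loss is an oxygen gain."""

    def test_fixation_export_aerobic_loop(self):
        """Fixing N, exporting it and remineralising it aerobically
        nets +1 NO3 per mol fixed N and costs the ocean exactly the
        nitrate-loss O2 equivalent (~1.417 mol O2 per mol N)."""
        p = 1.0  # mol P of diazotroph production
        d_o2 = STOICH.o2_yield_diazotroph_production() * p
        d_no3 = 0.0  # no uptake
        res = remineralize(p, o2=100.0, no3=30.0, stoich=STOICH)
        d_o2 += res.d_o2
        d_no3 += res.d_no3
        assert d_no3 == pytest.approx(STOICH.r_np * p)  # +1 per org N
        assert d_o2 == pytest.approx(
            -STOICH.r_np * STOICH.o2_per_no3_lost() * p, abs=1e-12
        )

    def test_ordinary_export_denitrification_loop(self):
        """Nitrate-fuelled production later denitrified: zero direct O2
        use, net NO3 loss 119.68 per mol P across the loop."""
        p = 1.0
        d_o2 = STOICH.o2_yield_ordinary_production() * p
        d_no3 = -STOICH.r_np * p  # uptake
        res = remineralize(p, o2=2.0, no3=1000.0, stoich=STOICH)
        d_no3 += res.d_no3
        assert res.d_o2 == 0.0
        assert d_no3 == pytest.approx(-STOICH.r_no3p * p, abs=1e-12)
        # the O2 credited at production is exactly the budget identity's
        # per-loop source: 1.417 per NO3 lost
        assert d_o2 == pytest.approx(
            -d_no3 * STOICH.o2_per_no3_lost() * (STOICH.r_no3p /
                                                 STOICH.r_no3p), abs=1e-9
        )

    def test_ordinary_closed_aerobic_loop_is_neutral(self):
        """Production followed by aerobic remineralisation returns every
        molecule: no net O2 or NO3 change."""
        p = 1.0
        d_o2 = STOICH.o2_yield_ordinary_production() * p
        d_no3 = -STOICH.r_np * p
        res = remineralize(p, o2=100.0, no3=30.0, stoich=STOICH)
        assert d_o2 + res.d_o2 == pytest.approx(0.0, abs=1e-12)
        assert d_no3 + res.d_no3 == pytest.approx(0.0, abs=1e-12)
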