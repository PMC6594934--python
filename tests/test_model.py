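"""Integrator contracts: conservation, ledgers, analytic steady states."""

import numpy as np
import pytest

import oxybox as ox
from oxybox.model import initial_state
from oxybox.scenario import ScenarioParams


def short_warming(geom, peak=2100.0, end=2400.0):
    labels = geom.labels
    return ox.make_warming_scenario(
        ScenarioParams(
            peak_year=peak, end_year=end,
            onset_years={lab: 1900.0 for lab in labels},
            warming_pattern={lab: 1.0 for lab in labels},
        ),
        geom,
    )


@pytest.fixture(scope="module")
def short_run():
    """50 model years of the default configuration from the first-guess
    state (identities hold from any state, spun or not)."""
    cfg = ox.ModelConfig()
    forcing = ox.make_control_scenario(years=50.0, geom=cfg.geometry)
    return ox.run(cfg, initial_state(cfg), forcing)


class TestConservation:
    def test_phosphorus_strictly_conserved(self, short_run):
        p = short_run.frame["po4_inventory_pmol"].to_numpy()
        assert np.max(np.abs(p - p[0])) / p[0] < 1e-12

    def test_fixed_nitrogen_ledger(self, short_run):
        """NO3 inventory change equals cumulative fixation minus
        denitrification, step-accumulated."""
        f = short_run.frame
        d_no3 = f["no3_inventory_pmol"] - f["no3_inventory_pmol"].iloc[0]
        ledger = f["cum_fixation_n_pmol"] - f["cum_denitrification_n_pmol"]
        scale = f["no3_inventory_pmol"].iloc[0]
        assert np.max(np.abs(d_no3 - ledger)) / scale < 1e-10

    def test_oxygen_budget_identity_from_any_state(self, short_run):
        f = short_run.frame
        s = ox.StoichiometryParams()
        b = ox.decompose_budget(
            f, f["time_yr"].iloc[0], f["time_yr"].iloc[-1], s
        )
        assert abs(b.residual_primary) < 1e-9


class TestDeterminismAndStepping:
    def test_identical_runs_are_identical(self):
        cfg = ox.ModelConfig()
        forcing = ox.make_control_scenario(years=10.0, geom=cfg.geometry)
        a = ox.run(cfg, initial_state(cfg), forcing)
        b = ox.run(cfg, initial_state(cfg), forcing)
        assert a.frame.equals(b.frame)

    def test_halving_dt_preserves_trajectories(self):
        """dt is a numerical knob: halving it perturbs inventories only
        slightly over a multi-decade window."""
        out = {}
        for dt in (0.05, 0.025):
            cfg = ox.ModelConfig(dt=dt)
            forcing = ox.make_control_scenario(years=25.0, geom=cfg.geometry)
            out[dt] = ox.run(cfg, initial_state(cfg), forcing).frame
        for col in ("o2_inventory_pmol", "no3_inventory_pmol"):
            a = out[0.05][col].iloc[-1]
            b = out[0.025][col].iloc[-1]
            assert a == pytest.approx(b, rel=2e-3)

    def test_oversized_dt_rejected(self):
        with pytest.raises(ValueError):
            ox.ModelConfig(dt=0.2)


class TestIdealAge:
    def test_two_box_steady_state_matches_v_over_psi(self, two_box_config):
        """Analytic oracle: with overturning psi and no mixing, the deep
        box's ideal age equilibrates at V_deep / psi."""
        cfg = two_box_config
        psi = cfg.circulation.overturning[("Surface", "Deep")]
        v_deep = float(cfg.geometry.volumes[1])
        analytic = v_deep / psi
        forcing = ox.make_control_scenario(
            years=20.0 * analytic, geom=cfg.geometry
        )
        res = ox.run(cfg, initial_state(cfg), forcing)
        assert res.final_state.age[1] == pytest.approx(analytic, rel=1e-4)
        assert res.final_state.age[0] == 0.0

    def test_zero_transport_interior_ages_linearly(self):
        geom = ox.two_box_geometry(v_surface=5e15, v_deep=2e16, area=5e13)
        cfg = ox.ModelConfig(
            geometry=geom,
            circulation=ox.CirculationScheme(overturning={}, mixing={}),
            base_temperature={"Surface": 10.0, "Deep": 10.0},
            downstream={},
            biology_enabled=False,
        )
        forcing = ox.make_control_scenario(years=50.0, geom=geom)
        res = ox.run(cfg, initial_state(cfg), forcing)
        assert res.final_state.age[1] == pytest.approx(50.0, rel=1e-9)

    def test_fast_overturning_limit_young_interior(self, two_box_config):
        """psi -> large drives the interior age towards zero."""
        from dataclasses import replace

        cfg = two_box_config
        big = ox.CirculationScheme(
            overturning={k: 50.0 * v for k, v in
                         cfg.circulation.overturning.items()},
            mixing={},
        )
        cfg_big = replace(cfg, circulation=big)
        forcing = ox.make_control_scenario(years=100.0, geom=cfg.geometry)
        age_small = ox.run(
            cfg, initial_state(cfg), forcing
        ).final_state.age[1]
        age_big = ox.run(
            cfg_big, initial_state(cfg_big), forcing
        ).final_state.age[1]
        assert age_big < age_small / 10.0


class TestSpinup:
    def test_two_box_spinup_converges(self, two_box_config):
        state, report = ox.spinup(two_box_config)
        assert report["converged"]
        assert np.all(state.o2 > 0.0)
        # surface abiotic O2 sits at saturation, and the interior holds
        # the saturation of its ventilating surface box
        sat = ox.o2_saturation(10.0, two_box_config.gas_exchange.salinity)
        np.testing.assert_allclose(state.abiotic_o2, sat, rtol=1e-6)

    def test_spun_state_is_a_fixed_point(self, two_box_config):
        state, _ = ox.spinup(two_box_config)
        state2, report2 = ox.spinup(two_box_config, state=state)
        assert report2["converged"]
        assert report2["years"] <= two_box_config.spinup_check_interval
        np.testing.assert_allclose(state2.o2, state.o2, rtol=1e-9)

    def test_nonconvergence_raises_with_residual(self, two_box_config):
        from dataclasses import replace

        cfg = replace(two_box_config, spinup_max_years=5.0)
        with pytest.raises(ox.SpinupError) as exc:
            ox.spinup(cfg)
        assert exc.value.residual > cfg.spinup_tol


class TestAbioticTracer:
    def test_biology_off_o2_identical_to_abiotic(self):
        """With biology disabled the two oxygen tracers obey identical
        dynamics and stay equal to rounding."""
        from dataclasses import replace

        cfg = replace(ox.ModelConfig(), biology_enabled=False)
        state = initial_state(cfg)
        state.o2 = state.abiotic_o2.copy()
        forcing = short_warming(cfg.geometry)
        res = ox.run(cfg, state, forcing)
        f = res.frame
        for lab in cfg.geometry.labels:
            np.testing.assert_allclose(
                f[f"o2_{lab}"], f[f"abiotic_o2_{lab}"], atol=1e-12
            )
        # warming-only inventory decline equals the abiotic decline
        d_o2 = f["o2_inventory_pmol"].iloc[-1] - f["o2_inventory_pmol"].iloc[0]
        d_ab = (
            f["abiotic_o2_inventory_pmol"].iloc[-1]
            - f["abiotic_o2_inventory_pmol"].iloc[0]
        )
        assert d_o2 == pytest.approx(d_ab, abs=1e-12)
        assert d_ab < 0.0  # warming expels oxygen

    def test_denitrification_disabled_flux_balances_o2(self):
        """With the anaerobic pathway and diazotrophs off (and demand
        low enough that no box goes suboxic), the O2 inventory change
        is the cumulative air-sea flux alone and nitrate is conserved."""
        eco = ox.EcosystemParams(
            production_scale={
                "LowLatSurface": 0.3, "SouthernOceanSurface": 0.1,
                "NorthSurface": 0.2,
            }
        )
        cfg = ox.ModelConfig(
            ecosystem=eco,
            diazotrophs_enabled=False,
            denitrification_enabled=False,
        )
        forcing = short_warming(cfg.geometry)
        res = ox.run(cfg, initial_state(cfg), forcing)
        f = res.frame
        assert f["cum_remainder_p_pmol"].iloc[-1] == 0.0
        d_o2 = f["o2_inventory_pmol"].iloc[-1] - f["o2_inventory_pmol"].iloc[0]
        flux = f["cum_airsea_o2_pmol"].iloc[-1]
        assert d_o2 == pytest.approx(flux, abs=1e-9)
        d_no3 = (
            f["no3_inventory_pmol"].iloc[-1] - f["no3_inventory_pmol"].iloc[0]
        )
        assert abs(d_no3) < 1e-9
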