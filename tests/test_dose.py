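"""Dose metrics: scaling, averages, no-escape reference, aggregation."""

import math

import numpy as np
import pytest

from xtaldose.dose import (
    KEV_TO_J,
    DoseGrid,
    ader,
    adwc,
    aggregate_runs,
    consistency_warning,
    diffraction_efficiency,
    dose_fraction,
    expected_elastic_scatters,
    raddose_style_dose,
    scale_to_experiment,
)
from xtaldose.engine import TransportOptions
from xtaldose.geometry import BeamModel, Wedge, build_geometry, region_in_beam
from xtaldose.io import run_simulation
from xtaldose.materials import photon_cross_sections
from xtaldose.photons import mean_compton_recoil_energy
from xtaldose.scenarios import make_scenario


def _beam(flux=1e12, energy=12.0, size=(1.0, 1.0)):
    return BeamModel(profile="tophat", size_um=size, energy_keV=energy, flux_ph_s=flux)


def _wedge(t=1.0):
    return Wedge(angle_start_deg=0.0, angle_end_deg=0.0, exposure_time_s=t)


class TestScaleToExperiment:
    def test_unit_scale_dose_arithmetic(self, water_crystal):
        """1 keV in a (0.2 um)^3 voxel of unit-density material at scale 1
        gives 1.602e-16 J / 8e-21 m^3 / 1000 kg/m^3 ~ 20 Gy."""
        geo = build_geometry((1.0, 1.0, 1.0), 5.0, water_crystal)
        raw = np.zeros(geo.n_voxels)
        raw[2, 2, 2] = 1.0
        beam = _beam(flux=1e5)
        grid = scale_to_experiment(raw, 100_000, beam, _wedge(1.0), geo)
        expected = KEV_TO_J / (0.2e-6**3 * water_crystal.density * 1000.0)
        assert grid.dose_Gy[2, 2, 2] == pytest.approx(expected, rel=1e-6)
        assert expected == pytest.approx(20.0, rel=0.01)

    def test_doubling_flux_doubles_dose(self, water_crystal):
        geo = build_geometry((1.0, 1.0, 1.0), 5.0, water_crystal)
        raw = np.random.default_rng(0).uniform(size=geo.n_voxels)
        g1 = scale_to_experiment(raw, 1000, _beam(flux=1e12), _wedge(), geo)
        g2 = scale_to_experiment(raw, 1000, _beam(flux=2e12), _wedge(), geo)
        assert np.allclose(g2.dose_Gy, 2.0 * g1.dose_Gy, rtol=1e-12)

    def test_zero_photon_count_rejected(self, water_crystal):
        geo = build_geometry((1.0, 1.0, 1.0), 5.0, water_crystal)
        with pytest.raises(ValueError):
            scale_to_experiment(np.zeros(geo.n_voxels), 0, _beam(), _wedge(), geo)

    def test_dose_identity_energy_over_mass(self):
        """D_n = J_n / (V_n rho) holds exactly for every voxel."""
        grid = DoseGrid(
            energy_J=np.array([[[1.0e-12, 2.0e-12]]]),
            voxel_volume_m3=8e-21,
            density_kg_m3=1175.0,
        )
        manual = grid.energy_J / (8e-21 * 1175.0)
        assert np.array_equal(grid.dose_Gy, manual)


class TestAverages:
    def test_uniform_grid_adwc_equals_ader(self):
        g = DoseGrid(np.full((3, 3, 3), 5e6 * 8e-21 * 1175.0), 8e-21, 1175.0)
        mask = np.ones((3, 3, 3), dtype=bool)
        assert adwc(g) == pytest.approx(5.0)
        assert ader(g, mask) == pytest.approx(5.0)

    def test_checkerboard_mean(self):
        vals = np.indices((4, 4, 4)).sum(axis=0) % 2 * 10.0  # 0/10 MGy pattern
        g = DoseGrid(vals * 1e6 * 8e-21 * 1175.0, 8e-21, 1175.0)
        assert adwc(g) == pytest.approx(5.0)

    def test_empty_mask_raises_helpful_error(self):
        g = DoseGrid(np.ones((2, 2, 2)), 8e-21, 1175.0)
        with pytest.raises(ValueError, match="beam"):
            ader(g, np.zeros((2, 2, 2), dtype=bool))


class TestRaddoseStyleDose:
    def test_thin_target_closed_form(self, water_crystal):
        """For a thin crystal the no-escape ADER reduces to
        I * mu_pc * E_mean / rho (attenuation negligible)."""
        geo = build_geometry((1.0, 1.0, 0.2), 5.0, water_crystal)
        beam = _beam()
        grid = raddose_style_dose(geo, beam, _wedge())
        xs = photon_cross_sections(water_crystal, 12.0)
        mu_ph = 1.0 / xs.lambda_photo_mm * 1e-3  # 1/um
        mu_cp = 1.0 / xs.lambda_comp_mm * 1e-3
        e_mean_keV = mu_ph * 12.0 + mu_cp * mean_compton_recoil_energy(12.0)
        intensity = 1e12 / 1.0  # photons per um^2
        dose = (
            intensity
            * e_mean_keV
            * KEV_TO_J
            / (1e-18 * water_crystal.density * 1000.0)  # voxel mass per um^3, kg
        )
        assert adwc(grid) * 1e6 == pytest.approx(dose, rel=0.005)

    def test_zero_flux_impossible_but_linearity_holds(self, water_crystal):
        geo = build_geometry((1.0, 1.0, 1.0), 5.0, water_crystal)
        g1 = raddose_style_dose(geo, _beam(flux=1e12), _wedge())
        g2 = raddose_style_dose(geo, _beam(flux=3e12), _wedge())
        assert np.allclose(g2.dose_Gy, 3 * g1.dose_Gy, rtol=1e-12)

    def test_mc_variant_consistent_with_analytic(self):
        """The MC no-escape tally agrees with the analytic expectation within
        3 sigma of its run-to-run confidence interval."""
        sc = make_scenario(
            "fig5_size_energy", size_um=1.0, energy_keV=12.0, runs=4, simphotons=15000
        )
        res, _ = run_simulation(sc.config, seed=21)
        ci = res.aggregates["raddose_style_ader_mc"]["ci95"]
        sigma = ci / 2.776 * math.sqrt(4)  # back out the per-run sd
        assert abs(
            res.raddose_style_ader_mc_MGy - res.raddose_style_ader_MGy
        ) < 3 * max(sigma / math.sqrt(4), 1e-9)
        assert not res.warnings

    def test_forced_and_analog_transport_agree(self):
        """Forced-interaction importance sampling is expectation-identical to
        analog exponential transport."""
        sc = make_scenario(
            "fig5_size_energy", size_um=20.0, energy_keV=12.0, runs=3, simphotons=60000
        )
        res_a, _ = run_simulation(
            sc.config, seed=5, options=TransportOptions(forced=False)
        )
        res_f, _ = run_simulation(sc.config, seed=5)
        ci = math.hypot(
            res_a.aggregates["dose_fraction"]["ci95"],
            res_f.aggregates["dose_fraction"]["ci95"],
        )
        assert abs(res_a.dose_fraction - res_f.dose_fraction) < 1.5 * ci + 0.01


class TestRatios:
    def test_dose_fraction_ratio_and_guard(self):
        assert dose_fraction(1.0, 4.0) == 0.25
        with pytest.raises(ZeroDivisionError):
            dose_fraction(1.0, 0.0)

    def test_diffraction_efficiency_flux_invariant(self, water_crystal):
        geo = build_geometry((1.0, 1.0, 1.0), 5.0, water_crystal)
        w = _wedge()
        effs = []
        for flux in (1e12, 2e12):
            beam = _beam(flux=flux)
            elastic = expected_elastic_scatters(geo, beam, w)
            rd = raddose_style_dose(geo, beam, w)
            mask = region_in_beam(geo, beam, w)
            effs.append(diffraction_efficiency(elastic, ader(rd, mask)))
        assert effs[0] == pytest.approx(effs[1], rel=1e-12)

    def test_lower_dose_higher_efficiency(self):
        assert diffraction_efficiency(1e7, 10.0) > diffraction_efficiency(1e7, 20.0)


class TestAggregation:
    def test_identical_runs_zero_ci(self):
        runs = [{"ader": 5.0}] * 4
        agg = aggregate_runs(runs)
        assert agg["ader"]["mean"] == 5.0
        assert agg["ader"]["ci95"] == pytest.approx(0.0, abs=1e-12)

    def test_t_interval_n6(self):
        """Known sd -> CI = mean +- 2.571 sd/sqrt(6)."""
        vals = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        agg = aggregate_runs([{"x": v} for v in vals])
        sd = np.std(vals, ddof=1)
        assert agg["x"]["ci95"] == pytest.approx(2.5706 * sd / math.sqrt(6), rel=1e-3)

    def test_permutation_invariance(self):
        runs = [{"x": v} for v in (3.0, 1.0, 2.0)]
        a = aggregate_runs(runs)
        b = aggregate_runs(runs[::-1])
        assert a == b

    def test_single_run_warns_without_ci(self):
        with pytest.warns(UserWarning):
            agg = aggregate_runs([{"x": 1.0}])
        assert "ci95" not in agg["x"]


class TestConsistencyWarning:
    def test_identical_values_no_warning(self):
        assert consistency_warning(100.0, 100.0) is None

    def test_ten_percent_discrepancy_warns_with_advice(self):
        msg = consistency_warning(110.0, 100.0)
        assert msg is not None and "SIMPHOTONS" in msg

    def test_threshold_configurable(self):
        assert consistency_warning(104.0, 100.0, threshold=0.05) is None
        assert consistency_warning(104.0, 100.0, threshold=0.01) is not None
        # zero threshold tolerates only exact equality
        assert consistency_warning(100.0, 100.0, threshold=0.0) is None
        assert consistency_warning(100.0000001, 100.0, threshold=0.0) is not None
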