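"""Materials layer: cross sections, stopping power, ranges, relaxation."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xtaldose.materials import (
    AVOGADRO,
    ELEMENTS,
    ConfigurationError,
    build_crystal_material,
    build_surrounding_material,
    csda_range,
    electron_elastic_mfpl,
    elastic_element_weights,
    k_shell_relaxation,
    mean_excitation_energy_eV,
    photon_cross_sections,
    stopping_power,
)


class TestPhotonCrossSections:
    @pytest.mark.parametrize("energy", [1.5, 5.0, 10.0, 12.4, 30.0, 100.0, 250.0])
    def test_channel_combination_identity(self, water, protein_crystal, energy):
        """1/lambda_tot must equal 1/lambda_photo + 1/lambda_comp exactly."""
        for mat in (water, protein_crystal):
            xs = photon_cross_sections(mat, energy)
            lhs = 1.0 / xs.lambda_tot_mm
            rhs = 1.0 / xs.lambda_photo_mm + 1.0 / xs.lambda_comp_mm
            assert lhs == pytest.approx(rhs, rel=1e-12)
            assert sum(xs.per_element_photo_fractions.values()) == pytest.approx(
                1.0, rel=1e-12
            )

    def test_mfpl_scales_inversely_with_density(self, water):
        doubled = water.scaled(2.0)
        a = photon_cross_sections(water, 10.0)
        b = photon_cross_sections(doubled, 10.0)
        assert b.lambda_tot_mm == pytest.approx(a.lambda_tot_mm / 2.0, rel=1e-12)
        assert b.lambda_photo_mm == pytest.approx(a.lambda_photo_mm / 2.0, rel=1e-12)
        assert b.lambda_elastic_mm == pytest.approx(
            a.lambda_elastic_mm / 2.0, rel=1e-12
        )

    def test_mixture_linearity_in_number_density(self, water):
        """A 50/50 combination of two stoichiometries equals the sum of the
        macroscopic cross sections of the halves."""
        oil = build_surrounding_material(
            "density_based", elements={"C": 4.0, "H": 8.0}, density=0.92
        )
        half_w = water.scaled(0.5)
        half_o = oil.scaled(0.5)
        counts = dict(half_w.element_counts)
        for s, n in half_o.element_counts.items():
            counts[s] = counts.get(s, 0.0) + n
        from xtaldose.materials import Material

        mix = Material(
            element_counts=counts,
            reference_volume_A3=1000.0,
            density=half_w.density + half_o.density,
        )
        for e in (5.0, 12.4, 60.0):
            mu_mix = 1.0 / photon_cross_sections(mix, e).lambda_tot_mm
            mu_sum = (
                1.0 / photon_cross_sections(half_w, e).lambda_tot_mm
                + 1.0 / photon_cross_sections(half_o, e).lambda_tot_mm
            )
            assert mu_mix == pytest.approx(mu_sum, rel=1e-9)

    def test_energy_out_of_range_rejected(self, water):
        with pytest.raises(ValueError, match="range"):
            photon_cross_sections(water, 0.5)
        with pytest.raises(ValueError, match="range"):
            photon_cross_sections(water, 400.0)

    def test_photoelectric_monotone_above_edges(self):
        for rec in ELEMENTS.values():
            grid = rec.energy_grid
            xs = rec.photoelectric_xs
            above = grid > max(rec.k_binding, grid[0]) * (1 + 1e-9)
            assert np.all(np.diff(xs[above]) < 0)


class TestMaterialBuilders:
    def test_explicit_water_counts_match_surrounding_water(self, water, water_crystal):
        for e in (5.0, 10.0, 20.0):
            a = photon_cross_sections(water, e)
            b = photon_cross_sections(water_crystal, e)
            assert b.lambda_tot_mm == pytest.approx(
                a.lambda_tot_mm, rel=2e-4
            )  # counts rounded to 4 digits in the fixture
        assert stopping_power(water_crystal, 20.0) == pytest.approx(
            stopping_power(water, 20.0), rel=2e-4
        )

    def test_full_solvent_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            build_crystal_material(
                num_residues=10, unit_cell_volume_A3=1e4, solvent_fraction=1.0
            )

    def test_unknown_element_symbol_named_in_error(self):
        with pytest.raises(ConfigurationError, match="Xx"):
            build_crystal_material(
                explicit_atom_counts={"Xx": 1.0}, unit_cell_volume_A3=1e3
            )

    def test_residue_heuristic_density_matches_hand_recomputation(self):
        """Mass of (5 C, 8 H, 1.35 N, 1.5 O, 0.04 S) per residue plus solvent
        water, over the cell volume, reproduces the declared density."""
        vol = 2.0e5
        mat = build_crystal_material(
            num_residues=129.0, unit_cell_volume_A3=vol, solvent_fraction=0.4
        )
        res_mass = (
            5 * 12.011 + 8 * 1.008 + 1.35 * 14.007 + 1.5 * 15.999 + 0.04 * 32.06
        )
        water_g = 1.0 * 0.4 * vol * 1e-24
        hand = (129.0 * res_mass / AVOGADRO + water_g) / (vol * 1e-24)
        assert mat.density == pytest.approx(hand, rel=1e-2)

    def test_density_based_polyisobutylene(self):
        mat = build_surrounding_material(
            "density_based", elements={"C": 4.0, "H": 8.0}, density=0.92
        )
        assert mat.density == pytest.approx(0.92, rel=1e-12)
        assert mat.derived_density() == pytest.approx(0.92, rel=1e-9)
        assert mat.element_counts["H"] / mat.element_counts["C"] == pytest.approx(2.0)

    def test_default_water_is_unit_density_h2o(self, water):
        assert water.density == pytest.approx(1.00)
        assert water.element_counts["H"] / water.element_counts["O"] == pytest.approx(
            2.0
        )

    def test_zero_concentration_solutes_identical_to_ice(self, ice):
        spiked = build_surrounding_material(
            "solutes_mM_in_amorphous_ice", solutes_mM={"Na": 0.0}
        )
        for e in (5.0, 12.0):
            assert photon_cross_sections(spiked, e).lambda_tot_mm == pytest.approx(
                photon_cross_sections(ice, e).lambda_tot_mm, rel=1e-12
            )

    def test_negative_concentration_rejected(self):
        with pytest.raises(ConfigurationError):
            build_surrounding_material(
                "solutes_mM_in_amorphous_ice", solutes_mM={"As": -1.0}
            )


class TestStoppingPower:
    def test_monotone_decline_over_kev_range(self, water):
        s5, s50 = stopping_power(water, 5.0), stopping_power(water, 50.0)
        assert s5 > s50 > 0

    def test_independent_closed_form_evaluation(self, water):
        """Re-code the relativistic Bethe collision formula independently and
        compare at 20 keV (same mean excitation energy)."""
        e = 20.0
        i_eV = mean_excitation_energy_eV(water)
        tau = e / 511.0
        gamma = 1 + tau
        beta2 = 1 - 1 / gamma**2
        i_eff = i_eV / (1 + 0.85 * i_eV / 1000.0 / e) / 1000.0 / 511.0
        ln_term = math.log(tau * tau * (tau + 2) / (2 * i_eff**2))
        f = 1 - beta2 + (tau**2 / 8 - (2 * tau + 1) * math.log(2)) / gamma**2
        n_e = water.electrons_per_cm3()
        s = 2.54955e-25 * n_e / beta2 * (ln_term + f) * 1e3 / 1e4
        assert stopping_power(water, e) == pytest.approx(s, rel=0.05)

    def test_below_cutoff_rejected(self, water):
        with pytest.raises(ValueError):
            stopping_power(water, 0.01)

    def test_water_mean_excitation_near_75_eV(self, water):
        assert mean_excitation_energy_eV(water) == pytest.approx(75.0, rel=0.02)


class TestCsdaRange:
    def test_strictly_increasing_in_energy(self, ice):
        energies = [1.0, 3.0, 8.0, 15.0, 40.0]
        ranges = [csda_range(ice, e) for e in energies]
        assert all(b > a for a, b in zip(ranges, ranges[1:]))

    def test_quadrature_refinement_stable(self, ice):
        coarse = csda_range(ice, 11.457, n_grid=2048)
        fine = csda_range(ice, 11.457, n_grid=20480)
        assert fine == pytest.approx(coarse, rel=1e-3)

    def test_empty_integral_at_cutoff(self, ice):
        assert csda_range(ice, 0.05) == 0.0

    def test_constant_stopping_power_analytic_limit(self, water, monkeypatch):
        """With S forced to 1 keV/um the range is numerically E - 0.05 um."""
        import xtaldose.materials as m

        monkeypatch.setattr(m, "stopping_power", lambda mat, e: 1.0)
        assert m.csda_range(water, 10.0) == pytest.approx(10.0 - 0.05, rel=1e-6)


class TestElectronElastic:
    def test_density_proportionality(self, water):
        a = electron_elastic_mfpl(water, 10.0)
        b = electron_elastic_mfpl(water.scaled(2.0), 10.0)
        assert b == pytest.approx(a / 2.0, rel=1e-12)

    def test_mfpl_increases_with_energy(self, water):
        vals = [electron_elastic_mfpl(water, e) for e in (1.0, 5.0, 20.0, 100.0)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_mixture_matches_per_element_brute_force(self, water):
        """Direct summation of per-element screened-Rutherford cross sections
        over number densities reproduces the mixed MFPL."""
        e = 10.0
        inv = 0.0
        for sym, n in water.number_densities_cm3().items():
            z = ELEMENTS[sym].atomic_number
            alpha = 3.4e-3 * z ** (2.0 / 3.0) / e
            rel = ((e + 511.0) / (e + 1024.0)) ** 2
            sigma = 5.21e-21 * z * z / e**2 * 4 * math.pi / (alpha * (1 + alpha)) * rel
            inv += n * sigma
        assert electron_elastic_mfpl(water, e) == pytest.approx(1e4 / inv, rel=0.02)

    def test_element_weights_normalized(self, protein_crystal):
        w = elastic_element_weights(protein_crystal, 7.0)
        assert sum(w.values()) == pytest.approx(1.0, rel=1e-12)


class TestKShellRelaxation:
    def test_forced_yield_extremes(self, rng, monkeypatch):
        rec0 = dataclasses.replace(ELEMENTS["O"], k_fluorescence_yield=0.0)
        monkeypatch.setitem(ELEMENTS, "O", rec0)
        assert all(
            k_shell_relaxation("O", rng).branch == "auger" for _ in range(200)
        )
        rec1 = dataclasses.replace(ELEMENTS["O"], k_fluorescence_yield=1.0)
        monkeypatch.setitem(ELEMENTS, "O", rec1)
        assert all(
            k_shell_relaxation("O", rng).branch == "fluorescence" for _ in range(200)
        )

    def test_auger_energy_is_binding_minus_twice_l(self, rng):
        out = None
        while out is None or out.branch != "auger":
            out = k_shell_relaxation("O", rng)
        rec = ELEMENTS["O"]
        assert out.auger_electron_energy_keV == pytest.approx(
            rec.k_binding - 2 * rec.l_binding
        )

    def test_fluorescence_fraction_matches_yield_binomially(self, rng):
        n = 100_000
        hits = sum(
            1 for _ in range(n) if k_shell_relaxation("O", rng).branch == "fluorescence"
        )
        p = ELEMENTS["O"].k_fluorescence_yield
        sigma = math.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * sigma + 1e-12


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    energy=st.floats(min_value=1.5, max_value=290.0),
    scale=st.floats(min_value=0.1, max_value=10.0),
)
def test_density_scaling_property(energy, scale):
    water = build_surrounding_material("default_water")
    xs = photon_cross_sections(water, energy)
    xs2 = photon_cross_sections(water.scaled(scale), energy)
    assert xs2.lambda_tot_mm * scale == pytest.approx(xs.lambda_tot_mm, rel=1e-9)
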