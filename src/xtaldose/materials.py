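"""Element data and macroscopic photon/electron interaction quantities.

This module owns the bundled per-element physics tables (photoelectric,
incoherent and coherent photon cross sections on a 1-300 keV log grid, K-shell
relaxation data, atomic masses and mean excitation energies) and evaluates
macroscopic quantities for arbitrary compositions:

* photon mean free path lengths (MFPLs) from the number densities of a
  :class:`Material`, by summing atomic cross sections over the reference
  volume and inverting -- the photoelectric and Compton channels are combined
  as ``1/lambda_tot = 1/lambda_photo + 1/lambda_comp``;
* collision stopping power for electrons (relativistic Bethe formula with a
  Joy-Luo low-energy correction) and the CSDA range obtained by integrating
  its reciprocal;
* electron elastic-scattering MFPLs from a relativistic screened-Rutherford
  parametrization (a pluggable stand-in for tabulated partial-wave data);
* K-shell vacancy relaxation (Auger electron vs K-alpha fluorescence).

Units: photon and electron energies in keV, cross sections in cm^2/atom,
densities in g/cm^3, MFPLs in mm (photons) or um (electrons), stopping power
in keV/um, CSDA ranges in um.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "AVOGADRO",
    "ELEMENTS",
    "ElementRecord",
    "Material",
    "PhotonCrossSections",
    "RelaxationOutcome",
    "build_crystal_material",
    "build_surrounding_material",
    "photon_cross_sections",
    "stopping_power",
    "csda_range",
    "electron_elastic_mfpl",
    "k_shell_relaxation",
    "mean_excitation_energy_eV",
    "PROTEIN_RESIDUE_ATOMS",
    "WATER_DENSITY",
    "AMORPHOUS_ICE_DENSITY",
]

AVOGADRO = 6.02214076e23
WATER_DENSITY = 1.00  # g/cm^3, liquid water surroundings
AMORPHOUS_ICE_DENSITY = 0.94  # g/cm^3, vitrified solvent at ~100 K
ELECTRON_REST_KEV = 511.0

# Per amino-acid residue heuristic used when a crystal composition is given as
# a residue count (a stated convention of this package, matching the
# crystallographic "average protein" bookkeeping).
PROTEIN_RESIDUE_ATOMS = {"C": 5.0, "H": 8.0, "N": 1.35, "O": 1.5, "S": 0.04}

# Energy window of the electron-physics parametrizations, keV.
ELECTRON_E_MIN = 0.05
ELECTRON_E_MAX = 300.0


class ConfigurationError(ValueError):
    """Raised for invalid compositions or simulation configuration."""


@dataclass(frozen=True)
class ElementRecord:
    """Bundled physics data for one element."""

    symbol: str
    atomic_number: int
    atomic_mass: float  # g/mol
    energy_grid: np.ndarray  # keV
    photoelectric_xs: np.ndarray  # cm^2/atom
    incoherent_xs: np.ndarray
    coherent_xs: np.ndarray
    k_binding: float  # keV
    k_fluorescence_yield: float
    k_alpha_energy: float  # keV
    l_binding: float  # keV
    k_shell_fraction: float
    mean_excitation: float  # eV

    def _interp(self, table: np.ndarray, energy_keV: float | np.ndarray) -> np.ndarray:
        e = np.asarray(energy_keV, dtype=float)
        lo, hi = self.energy_grid[0], self.energy_grid[-1]
        if np.any(e < lo) or np.any(e > hi):
            raise ValueError(
                f"photon energy out of table range [{lo:g}, {hi:g}] keV for "
                f"element {self.symbol}"
            )
        out = np.exp(
            np.interp(np.log(e), np.log(self.energy_grid), np.log(table))
        )
        return out if out.ndim else float(out)

    def photoelectric(self, energy_keV):
        return self._interp(self.photoelectric_xs, energy_keV)

    def incoherent(self, energy_keV):
        return self._interp(self.incoherent_xs, energy_keV)

    def coherent(self, energy_keV):
        return self._interp(self.coherent_xs, energy_keV)


def _load_elements() -> dict[str, ElementRecord]:
    data = resources.files("xtaldose") / "data"
    meta_lines = (data / "elements_meta.txt").read_text().splitlines()
    records: dict[str, ElementRecord] = {}
    for line in meta_lines:
        if not line.strip() or line.startswith("#"):
            continue
        sym, z, mass, kb, fy, ka, lb, kf, iex = line.split()
        table = np.loadtxt(
            (data / "elements" / f"{sym}.txt").open("r"), comments="#"
        )
        records[sym] = ElementRecord(
            symbol=sym,
            atomic_number=int(z),
            atomic_mass=float(mass),
            energy_grid=table[:, 0],
            photoelectric_xs=table[:, 1],
            incoherent_xs=table[:, 2],
            coherent_xs=table[:, 3],
            k_binding=float(kb),
            k_fluorescence_yield=float(fy),
            k_alpha_energy=float(ka),
            l_binding=float(lb),
            k_shell_fraction=float(kf),
            mean_excitation=float(iex),
        )
    return records


ELEMENTS: dict[str, ElementRecord] = _load_elements()


def _check_elements(counts: dict[str, float]) -> None:
    for sym in counts:
        if sym not in ELEMENTS:
            raise ConfigurationError(
                f"unknown element symbol {sym!r}; bundled elements: "
                + ", ".join(sorted(ELEMENTS))
            )


@dataclass
class Material:
    """Elemental composition referenced to a volume.

    ``element_counts`` holds N_j, the number of atoms of element j in the
    reference volume V (for crystals the unit cell, for surroundings a nominal
    1 nm^3 cell). All macroscopic quantities derive from the number densities
    N_j / V.
    """

    element_counts: dict[str, float]
    reference_volume_A3: float
    density: float  # g/cm^3
    name: str = "material"

    def __post_init__(self):
        if not self.element_counts:
            raise ConfigurationError("material needs at least one element")
        _check_elements(self.element_counts)
        if self.density <= 0:
            raise ConfigurationError("material density must be positive")
        derived = self.derived_density()
        if abs(derived - self.density) > 0.01 * self.density:
            raise ConfigurationError(
                f"composition of {self.name!r} implies density {derived:.4f} "
                f"g/cm^3, inconsistent with declared {self.density:.4f}"
            )

    def derived_density(self) -> float:
        mass = sum(
            n * ELEMENTS[s].atomic_mass for s, n in self.element_counts.items()
        )
        return mass / AVOGADRO / (self.reference_volume_A3 * 1e-24)

    def number_densities_cm3(self) -> dict[str, float]:
        v_cm3 = self.reference_volume_A3 * 1e-24
        return {s: n / v_cm3 for s, n in self.element_counts.items()}

    def electrons_per_cm3(self) -> float:
        return sum(
            n * ELEMENTS[s].atomic_number
            for s, n in self.number_densities_cm3().items()
        )

    def scaled(self, factor: float, name: str | None = None) -> "Material":
        """Same stoichiometry at ``factor`` times the number density."""
        return Material(
            element_counts={s: n * factor for s, n in self.element_counts.items()},
            reference_volume_A3=self.reference_volume_A3,
            density=self.density * factor,
            name=name or self.name,
        )


@dataclass(frozen=True)
class PhotonCrossSections:
    """Macroscopic photon MFPLs (mm) at one energy.

    ``lambda_tot`` combines the two ionizing channels only (photoelectric and
    Compton); the elastic (coherent) MFPL is carried separately for the
    diffraction-efficiency accounting and does not attenuate the beam in the
    transport model.
    """

    energy_keV: float
    lambda_photo_mm: float
    lambda_comp_mm: float
    lambda_elastic_mm: float
    lambda_tot_mm: float
    per_element_photo_fractions: dict[str, float]


def photon_cross_sections(material: Material, energy_keV: float) -> PhotonCrossSections:
    """Evaluate MFPLs by summing atomic cross sections over the composition."""
    ndens = material.number_densities_cm3()
    mu_photo = mu_comp = mu_el = 0.0
    photo_by_elem: dict[str, float] = {}
    for sym, n in ndens.items():
        rec = ELEMENTS[sym]
        p = n * rec.photoelectric(energy_keV)
        mu_photo += p
        photo_by_elem[sym] = p
        mu_comp += n * rec.incoherent(energy_keV)
        mu_el += n * rec.coherent(energy_keV)
    if mu_photo <= 0 or mu_comp <= 0:
        raise ValueError("degenerate cross sections")
    lam_photo = 10.0 / mu_photo  # cm^-1 -> mm
    lam_comp = 10.0 / mu_comp
    lam_el = 10.0 / mu_el if mu_el > 0 else math.inf
    lam_tot = 1.0 / (1.0 / lam_photo + 1.0 / lam_comp)
    total_p = sum(photo_by_elem.values())
    return PhotonCrossSections(
        energy_keV=float(energy_keV),
        lambda_photo_mm=lam_photo,
        lambda_comp_mm=lam_comp,
        lambda_elastic_mm=lam_el,
        lambda_tot_mm=lam_tot,
        per_element_photo_fractions={s: p / total_p for s, p in photo_by_elem.items()},
    )


# ---------------------------------------------------------------------------
# material builders


def build_crystal_material(
    *,
    num_residues: float | None = None,
    explicit_atom_counts: dict[str, float] | None = None,
    unit_cell_volume_A3: float,
    solvent_fraction: float = 0.0,
    name: str = "crystal",
) -> Material:
    """Build a crystal material from a residue heuristic or explicit counts.

    With ``num_residues``, each residue contributes 5 C, 8 H, 1.35 N, 1.5 O
    and 0.04 S atoms (a stated convention of this package) and the solvent
    fraction of the unit cell is filled with liquid water. With
    ``explicit_atom_counts`` the counts are taken as-is per unit cell.
    """
    if not 0.0 <= solvent_fraction < 1.0:
        raise ConfigurationError("solvent_fraction must lie in [0, 1)")
    if unit_cell_volume_A3 <= 0:
        raise ConfigurationError("unit cell volume must be positive")
    counts: dict[str, float] = {}
    if explicit_atom_counts is not None:
        _check_elements(explicit_atom_counts)
        counts.update(explicit_atom_counts)
    elif num_residues is not None:
        for sym, per_res in PROTEIN_RESIDUE_ATOMS.items():
            counts[sym] = counts.get(sym, 0.0) + per_res * num_residues
    else:
        raise ConfigurationError(
            "crystal composition needs num_residues or explicit_atom_counts"
        )
    if solvent_fraction > 0.0:
        water_cm3 = solvent_fraction * unit_cell_volume_A3 * 1e-24
        n_water = WATER_DENSITY * water_cm3 / 18.015 * AVOGADRO
        counts["H"] = counts.get("H", 0.0) + 2.0 * n_water
        counts["O"] = counts.get("O", 0.0) + n_water
    mass = sum(n * ELEMENTS[s].atomic_mass for s, n in counts.items())
    density = mass / AVOGADRO / (unit_cell_volume_A3 * 1e-24)
    return Material(
        element_counts=counts,
        reference_volume_A3=unit_cell_volume_A3,
        density=density,
        name=name,
    )


def average_protein_crystal(
    solvent_fraction: float = 0.5,
    num_residues: float = 100.0,
    protein_density: float = 1.35,
) -> Material:
    """Average-protein crystal: residues at the heuristic stoichiometry packed
    at ``protein_density`` in (1 - solvent_fraction) of the cell, the rest
    liquid water."""
    res_mass = sum(
        per * ELEMENTS[s].atomic_mass for s, per in PROTEIN_RESIDUE_ATOMS.items()
    )
    protein_cm3 = num_residues * res_mass / AVOGADRO / protein_density
    volume = protein_cm3 / (1.0 - solvent_fraction) * 1e24
    return build_crystal_material(
        num_residues=num_residues,
        unit_cell_volume_A3=volume,
        solvent_fraction=solvent_fraction,
        name="average protein crystal",
    )


_NOMINAL_SURROUNDING_V = 1000.0  # A^3 == 1 nm^3


def _water_counts(density: float, volume_A3: float = _NOMINAL_SURROUNDING_V):
    n = density * volume_A3 * 1e-24 / 18.015 * AVOGADRO
    return {"H": 2.0 * n, "O": n}


def build_surrounding_material(
    mode: str = "default_water",
    *,
    solutes_mM: dict[str, float] | None = None,
    elements: dict[str, float] | None = None,
    density: float | None = None,
    name: str = "surrounding",
) -> Material:
    """Build the material surrounding the crystal.

    Modes:

    * ``default_water`` -- pure liquid water at 1.00 g/cm^3;
    * ``solutes_mM_in_amorphous_ice`` -- solute atoms at the given mM
      concentrations added to amorphous ice (0.94 g/cm^3 water);
    * ``density_based`` -- an elemental stoichiometry normalized to the given
      mass density (oils and other non-aqueous media).
    """
    if mode == "default_water":
        counts = _water_counts(WATER_DENSITY)
        rho = WATER_DENSITY
    elif mode == "solutes_mM_in_amorphous_ice":
        counts = _water_counts(AMORPHOUS_ICE_DENSITY)
        rho = AMORPHOUS_ICE_DENSITY
        for sym, conc in (solutes_mM or {}).items():
            if conc < 0:
                raise ConfigurationError(f"negative concentration for {sym}")
            _check_elements({sym: conc})
            # 1 mM == 6.022e-4 atoms per nm^3
            n = conc * 1e-3 * AVOGADRO * (_NOMINAL_SURROUNDING_V * 1e-27)
            counts[sym] = counts.get(sym, 0.0) + n
            rho += n * ELEMENTS[sym].atomic_mass / AVOGADRO / (
                _NOMINAL_SURROUNDING_V * 1e-24
            )
    elif mode == "density_based":
        if not elements:
            raise ConfigurationError("density_based surrounding needs elements")
        if density is None or density <= 0:
            raise ConfigurationError("density_based surrounding needs density > 0")
        _check_elements(elements)
        unit_mass = sum(n * ELEMENTS[s].atomic_mass for s, n in elements.items())
        scale = (
            density * (_NOMINAL_SURROUNDING_V * 1e-24) * AVOGADRO / unit_mass
        )
        counts = {s: n * scale for s, n in elements.items()}
        rho = density
    else:
        raise ConfigurationError(f"unknown surrounding mode {mode!r}")
    return Material(
        element_counts=counts,
        reference_volume_A3=_NOMINAL_SURROUNDING_V,
        density=rho,
        name=name,
    )


# ---------------------------------------------------------------------------
# electron physics


def mean_excitation_energy_eV(material: Material) -> float:
    """Bragg-additivity mean excitation energy, weighted by electron count."""
    num = den = 0.0
    for sym, n in material.element_counts.items():
        rec = ELEMENTS[sym]
        num += n * rec.atomic_number * math.log(rec.mean_excitation)
        den += n * rec.atomic_number
    return math.exp(num / den)


_JOY_LUO_K = 0.85


def stopping_power(material: Material, electron_energy_keV: float) -> float:
    """Collision stopping power in keV/um.

    Relativistic Bethe formula (Moller-corrected, density effect neglected at
    these energies) with the Joy-Luo substitution I -> I/(1 + k I/E) so the
    formula stays positive and physically plausible down to the 50 eV
    transport cutoff.
    """
    e = float(electron_energy_keV)
    if not (ELECTRON_E_MIN <= e <= ELECTRON_E_MAX):
        raise ValueError(
            f"electron energy {e:g} keV outside [{ELECTRON_E_MIN}, "
            f"{ELECTRON_E_MAX}] keV"
        )
    i_eV = mean_excitation_energy_eV(material)
    i_eff = i_eV / (1.0 + _JOY_LUO_K * (i_eV / 1000.0) / e)  # eV
    tau = e / ELECTRON_REST_KEV
    gamma = 1.0 + tau
    beta2 = 1.0 - 1.0 / gamma**2
    i_ratio = (i_eff / 1000.0) / ELECTRON_REST_KEV
    ln_term = math.log(tau * tau * (tau + 2.0) / (2.0 * i_ratio**2))
    f_term = (
        1.0
        - beta2
        + (tau**2 / 8.0 - (2.0 * tau + 1.0) * math.log(2.0)) / gamma**2
    )
    n_e = material.electrons_per_cm3()
    # 2 pi r_e^2 m c^2 = 2.54955e-25 MeV cm^2 per electron
    s_mev_cm = 2.54955e-25 * n_e / beta2 * (ln_term + f_term)
    return max(s_mev_cm, 1e-30) * 1e3 / 1e4  # MeV/cm -> keV/um


def csda_range(
    material: Material, electron_energy_keV: float, *, n_grid: int = 2048
) -> float:
    """CSDA range in um: integral of 1/stopping_power from 0.05 keV to E."""
    e = float(electron_energy_keV)
    if not (ELECTRON_E_MIN <= e <= ELECTRON_E_MAX):
        raise ValueError("electron energy outside stopping-power range")
    if e == ELECTRON_E_MIN:
        return 0.0
    grid = np.geomspace(ELECTRON_E_MIN, e, n_grid)
    inv_s = np.array([1.0 / stopping_power(material, ei) for ei in grid])
    return float(np.trapezoid(inv_s, grid))


# screened-Rutherford elastic scattering (relativistic, Nigam screening).
# The screening parameter alpha = 3.4e-3 Z^(2/3) / E(keV) and total cross
# section follow the standard electron-microscopy Monte Carlo parametrization.


def _elastic_sigma_cm2(z: int, energy_keV: float) -> float:
    alpha = 3.4e-3 * z ** (2.0 / 3.0) / energy_keV
    rel = ((energy_keV + 511.0) / (energy_keV + 1024.0)) ** 2
    return (
        5.21e-21 * z * z / energy_keV**2 * 4.0 * math.pi / (alpha * (1.0 + alpha)) * rel
    )


def elastic_screening_alpha(z: int, energy_keV: float) -> float:
    return 3.4e-3 * z ** (2.0 / 3.0) / energy_keV


def electron_elastic_mfpl(material: Material, electron_energy_keV: float) -> float:
    """Elastic-scattering MFPL in um, mixed over elements like the photon MFPLs."""
    e = float(electron_energy_keV)
    if not (ELECTRON_E_MIN <= e <= ELECTRON_E_MAX):
        raise ValueError("electron energy outside elastic-model range")
    inv = 0.0
    for sym, n in material.number_densities_cm3().items():
        inv += n * _elastic_sigma_cm2(ELEMENTS[sym].atomic_number, e)
    return 1e4 / inv  # cm -> um


def elastic_element_weights(material: Material, energy_keV: float) -> dict[str, float]:
    """Relative probability that an elastic event is on each element."""
    w = {
        sym: n * _elastic_sigma_cm2(ELEMENTS[sym].atomic_number, energy_keV)
        for sym, n in material.number_densities_cm3().items()
    }
    total = sum(w.values())
    return {s: v / total for s, v in w.items()}


# ---------------------------------------------------------------------------
# K-shell relaxation


@dataclass(frozen=True)
class RelaxationOutcome:
    branch: str  # "auger" | "fluorescence" | "none"
    auger_electron_energy_keV: float = 0.0
    fluorescent_photon_energy_keV: float = 0.0


def k_shell_relaxation(element: str, rng: np.random.Generator) -> RelaxationOutcome:
    """Relax a K vacancy: K-alpha fluorescence with the bundled yield,
    otherwise a KLL Auger electron at E_K - 2 E_L (clamped at zero)."""
    rec = ELEMENTS[element]
    if rec.k_alpha_energy <= 0 and rec.k_fluorescence_yield <= 0:
        return RelaxationOutcome(branch="none")
    if rng.random() < rec.k_fluorescence_yield:
        return RelaxationOutcome(
            branch="fluorescence",
            fluorescent_photon_energy_keV=rec.k_alpha_energy,
        )
    return RelaxationOutcome(
        branch="auger",
        auger_electron_energy_keV=max(rec.k_binding - 2.0 * rec.l_binding, 0.0),
    )
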