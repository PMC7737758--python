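"""Dose accumulation and the absorbed-dose metrics.

The Monte Carlo tally of energy per voxel (keV) is scaled to the experimental
photon count (flux x exposure time over photons simulated) and converted to
dose via D_n = J_n / (V_n rho): energy per voxel over voxel mass.

Metrics:

* ADWC -- average dose over all crystal voxels;
* ADER -- average dose over the voxels inside the beam footprint;
* "RADDOSE-3D style" dose -- the equivalent no-electron-escape dose, in two
  flavours: an analytic expectation (Beer-Lambert attenuated interaction
  density, all photoelectric and Compton energy deposited where the photon
  interacts) and a Monte Carlo variant tallied during transport; comparing
  the two is the built-in consistency check;
* dose fraction -- MC ADER over RADDOSE-style ADER; below one when electron
  escape wins, above one when the surrounding feeds electrons in;
* diffraction efficiency -- expected elastically scattered photons per MGy
  of MC ADER; flux and exposure cancel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from xtaldose.geometry import BeamModel, SampleGeometry, Wedge, orientation_transform
from xtaldose.materials import ELEMENTS, Material, photon_cross_sections
from xtaldose.photons import mean_compton_recoil_energy

__all__ = [
    "KEV_TO_J",
    "DoseGrid",
    "SimulationResult",
    "scale_to_experiment",
    "adwc",
    "ader",
    "raddose_style_dose",
    "expected_elastic_scatters",
    "dose_fraction",
    "diffraction_efficiency",
    "aggregate_runs",
    "consistency_warning",
]

KEV_TO_J = 1.602176634e-16


@dataclass
class DoseGrid:
    """Per-voxel deposited energy (J, scaled to the experiment) and dose."""

    energy_J: np.ndarray
    voxel_volume_m3: float
    density_kg_m3: float

    def __post_init__(self):
        if self.voxel_volume_m3 <= 0 or self.density_kg_m3 <= 0:
            raise ValueError("voxel volume and density must be positive")

    @property
    def dose_Gy(self) -> np.ndarray:
        return self.energy_J / (self.voxel_volume_m3 * self.density_kg_m3)

    @property
    def dose_MGy(self) -> np.ndarray:
        return self.dose_Gy * 1e-6


def scale_to_experiment(
    raw_grid_keV: np.ndarray,
    n_simulated: int,
    beam: BeamModel,
    wedge: Wedge,
    geometry: SampleGeometry,
) -> DoseGrid:
    """Scale a raw keV tally by (experimental photons / simulated photons)
    and convert to a DoseGrid."""
    if n_simulated <= 0:
        raise ValueError("n_simulated must be positive")
    n_exp = beam.flux_ph_s * wedge.exposure_time_s
    if n_exp <= 0:
        raise ValueError("flux x exposure time must be positive")
    scale = n_exp / n_simulated
    vol_m3 = float(np.prod(geometry.voxel_size_um)) * 1e-18
    rho = geometry.crystal_material.density * 1000.0  # g/cm^3 -> kg/m^3
    return DoseGrid(
        energy_J=np.asarray(raw_grid_keV, dtype=float) * scale * KEV_TO_J,
        voxel_volume_m3=vol_m3,
        density_kg_m3=rho,
    )


def adwc(grid: DoseGrid) -> float:
    """Average dose over the whole crystal, MGy."""
    return float(np.mean(grid.dose_MGy))


def ader(grid: DoseGrid, mask: np.ndarray) -> float:
    """Average dose over the exposed region, MGy."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError(
            "exposed-region mask is empty: enlarge the beam or refine the grid"
        )
    return float(np.mean(grid.dose_MGy[mask]))


def _upstream_attenuation(
    geometry: SampleGeometry,
    centers_sample: np.ndarray,
    d_sample: np.ndarray,
    mu_c: float,
    mu_s: float,
) -> np.ndarray:
    """exp(-tau) from the sample entry point to each voxel centre, with the
    (convex) crystal and surrounding path lengths found analytically."""

    def exit_distance(half):
        # distance along -d from each centre to the box boundary
        t = np.full(centers_sample.shape[0], np.inf)
        for ax in range(3):
            d = -d_sample[ax]
            if abs(d) < 1e-14:
                continue
            t1 = (-half[ax] - centers_sample[:, ax]) / d
            t2 = (half[ax] - centers_sample[:, ax]) / d
            t = np.minimum(t, np.maximum(t1, t2))
        return t

    l_c = exit_distance(geometry.half_dims_um)
    tau = mu_c * l_c
    if geometry.has_surrounding:
        l_o = exit_distance(geometry.outer_half_dims_um)
        tau = tau + mu_s * np.maximum(l_o - l_c, 0.0)
    return np.exp(-tau)


def _angle_nodes(wedge: Wedge, n_angle_nodes: int | None) -> np.ndarray:
    if n_angle_nodes is None:
        n_angle_nodes = max(1, min(72, int(math.ceil(wedge.span_deg / 5.0)) + 1))
    if wedge.span_deg == 0:
        return np.array([wedge.angle_start_deg])
    # midpoint nodes of the uniform-in-time rotation
    q = (np.arange(n_angle_nodes) + 0.5) / n_angle_nodes
    return wedge.angle_start_deg + q * wedge.span_deg


def _energy_nodes(beam: BeamModel, n_energy_nodes: int) -> np.ndarray:
    if beam.energy_fwhm_keV <= 0:
        return np.array([beam.energy_keV])
    from scipy.special import ndtri

    q = (np.arange(n_energy_nodes) + 0.5) / n_energy_nodes
    return np.clip(
        beam.energy_keV + beam.energy_sigma_keV * ndtri(q), 1.0, 300.0
    )


def _expected_grid(
    geometry: SampleGeometry,
    beam: BeamModel,
    wedge: Wedge,
    weight_kind: str,
    n_angle_nodes: int | None = None,
    n_energy_nodes: int = 16,
) -> np.ndarray:
    """Expected per-voxel quantity for one experimental photon-count unit
    (flux x exposure): deposited keV for ``weight_kind='energy'`` (all
    photoelectric + Compton energy local), elastic event count for
    ``weight_kind='elastic'``."""
    crystal = geometry.crystal_material
    surr = geometry.surrounding_material
    centers = geometry.voxel_centers().reshape(-1, 3)
    v_vox = float(np.prod(geometry.voxel_size_um))
    angles = _angle_nodes(wedge, n_angle_nodes)
    energies = _energy_nodes(beam, n_energy_nodes)
    total = np.zeros(centers.shape[0])
    for e in energies:
        xs_c = photon_cross_sections(crystal, e)
        mu_ph_c = 1.0 / xs_c.lambda_photo_mm / 1000.0  # 1/um
        mu_cp_c = 1.0 / xs_c.lambda_comp_mm / 1000.0
        mu_pc_c = mu_ph_c + mu_cp_c
        mu_el_c = 1.0 / xs_c.lambda_elastic_mm / 1000.0
        if surr is not None and geometry.has_surrounding:
            xs_s = photon_cross_sections(surr, e)
            mu_pc_s = (
                1.0 / xs_s.lambda_photo_mm + 1.0 / xs_s.lambda_comp_mm
            ) / 1000.0
        else:
            mu_pc_s = 0.0
        if weight_kind == "energy":
            e_mean = (
                mu_ph_c * e + mu_cp_c * mean_compton_recoil_energy(e)
            ) / mu_pc_c
            factor = mu_pc_c * e_mean
        elif weight_kind == "elastic":
            factor = mu_el_c
        else:
            raise ValueError(weight_kind)
        for a in angles:
            tr = orientation_transform(geometry, wedge, a)
            lab = tr.apply(centers)
            intensity = beam.intensity(lab[:, 0], lab[:, 1])  # 1/um^2
            d_sample = tr.inverse_apply_vector(np.array([0.0, 0.0, 1.0]))
            atten = _upstream_attenuation(
                geometry, centers, d_sample, mu_pc_c, mu_pc_s
            )
            total += intensity * atten * factor * v_vox
    total /= len(angles) * len(energies)
    return total.reshape(geometry.n_voxels)


def raddose_style_dose(
    geometry: SampleGeometry,
    beam: BeamModel,
    wedge: Wedge,
    n_angle_nodes: int | None = None,
    n_energy_nodes: int = 16,
) -> DoseGrid:
    """Analytic no-escape dose: expected interaction density per voxel with
    Beer-Lambert attenuation along the beam, all photoelectric energy (E_inc,
    including any would-be fluorescence) and the mean Compton recoil energy
    deposited at the interaction point."""
    expected_keV = _expected_grid(
        geometry, beam, wedge, "energy", n_angle_nodes, n_energy_nodes
    )
    n_exp = beam.flux_ph_s * wedge.exposure_time_s
    vol_m3 = float(np.prod(geometry.voxel_size_um)) * 1e-18
    rho = geometry.crystal_material.density * 1000.0
    return DoseGrid(
        energy_J=expected_keV * n_exp * KEV_TO_J,
        voxel_volume_m3=vol_m3,
        density_kg_m3=rho,
    )


def expected_elastic_scatters(
    geometry: SampleGeometry,
    beam: BeamModel,
    wedge: Wedge,
    n_angle_nodes: int | None = None,
    n_energy_nodes: int = 16,
) -> float:
    """Expected number of elastically (coherently) scattered photons in the
    crystal over the experiment, computed analytically from the coherent
    cross sections to avoid Monte Carlo variance."""
    grid = _expected_grid(
        geometry, beam, wedge, "elastic", n_angle_nodes, n_energy_nodes
    )
    return float(grid.sum() * beam.flux_ph_s * wedge.exposure_time_s)


def dose_fraction(ader_mc_MGy: float, ader_raddose_style_MGy: float) -> float:
    """MC ADER over the no-escape ADER; may exceed 1 with a feeding
    surrounding."""
    if ader_raddose_style_MGy <= 0:
        raise ZeroDivisionError("RADDOSE-style ADER must be positive")
    return ader_mc_MGy / ader_raddose_style_MGy


def diffraction_efficiency(
    elastic_count: float, ader_mc_MGy: float
) -> float:
    """Elastically scattered photons per MGy of (MC) exposed-region dose."""
    if ader_mc_MGy <= 0:
        raise ValueError("ADER must be positive")
    return elastic_count / ader_mc_MGy


def aggregate_runs(per_run: list[dict[str, float]]) -> dict[str, dict[str, float]]:
    """Mean and 95% Student-t confidence half-width per metric over runs."""
    if not per_run:
        raise ValueError("no runs to aggregate")
    keys = per_run[0].keys()
    out: dict[str, dict[str, float]] = {}
    n = len(per_run)
    if n < 2:
        warnings.warn("single run: confidence intervals unavailable", stacklevel=2)
    from scipy.stats import t as t_dist

    for k in keys:
        vals = np.array([r[k] for r in per_run], dtype=float)
        entry = {"mean": float(vals.mean()), "n": n}
        if n >= 2:
            sd = float(vals.std(ddof=1))
            entry["ci95"] = float(t_dist.ppf(0.975, n - 1) * sd / math.sqrt(n))
        out[k] = entry
    return out


def consistency_warning(
    mc_raddose_style_MGy: float,
    analytic_raddose_style_MGy: float,
    threshold: float = 0.05,
) -> str | None:
    """Warn when the MC no-escape tally disagrees with the analytic value by
    more than ``threshold`` (relative); advises more simulated photons."""
    if analytic_raddose_style_MGy <= 0 or mc_raddose_style_MGy <= 0:
        raise ValueError("doses must be positive")
    rel = abs(mc_raddose_style_MGy - analytic_raddose_style_MGy) / (
        analytic_raddose_style_MGy
    )
    if rel > threshold:
        return (
            f"Monte Carlo RADDOSE-style ADER differs from the analytic value "
            f"by {100 * rel:.1f}% (> {100 * threshold:.0f}%): increase "
            f"SIMPHOTONS for better statistics"
        )
    return None


@dataclass
class SimulationResult:
    """Aggregated metrics of a multi-run simulation (all doses in MGy)."""

    adwc_MGy: float
    ader_MGy: float
    raddose_style_ader_MGy: float
    raddose_style_ader_mc_MGy: float
    dose_fraction: float
    diffraction_efficiency_per_MGy: float
    per_run: list[dict[str, float]]
    aggregates: dict[str, dict[str, float]]
    warnings: list[str] = field(default_factory=list)
    n_runs: int = 0
    n_photons_per_run: int = 0
    seed: int = 0
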