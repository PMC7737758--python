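"""Keyword-block input files, run orchestration and output writing.

The input dialect follows the RADDOSE-3D keyword-block style: ``Crystal``,
``Beam`` and ``Wedge`` blocks of case-insensitive ``KEY value...`` lines,
with each wedge bound to the most recently defined beam. The exact dialect
is documented in the README; ``serialize_config`` writes a canonical file
that parses back to an equal configuration.
"""

from __future__ import annotations

import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np

from xtaldose import engine
from xtaldose.dose import (
    DoseGrid,
    SimulationResult,
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
from xtaldose.geometry import BeamModel, SampleGeometry, Wedge, build_geometry, region_in_beam
from xtaldose.materials import (
    ConfigurationError,
    Material,
    average_protein_crystal,
    build_crystal_material,
    build_surrounding_material,
)

__all__ = [
    "SimulationConfig",
    "parse_input",
    "serialize_config",
    "run_simulation",
    "write_outputs",
]

logger = logging.getLogger("xtaldose")


@dataclass
class CrystalSpec:
    ctype: str = "cuboid"
    dimensions_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    pixels_per_micron: float = 5.0
    subprogram: str = "montecarlo"
    runs: int = 1
    simphotons: int = 100_000
    num_residues: float | None = None
    unit_cell_volume_A3: float | None = None
    solvent_fraction: float = 0.5
    calc_surrounding: bool = False
    surrounding_thickness_um: float | None = None
    density_based: bool = False
    surrounding_elements: dict[str, float] = field(default_factory=dict)
    surrounding_density: float | None = None
    surrounding_solutes_mM: dict[str, float] = field(default_factory=dict)
    goniometer_axis_deg: float = 0.0


@dataclass
class SimulationConfig:
    crystal: CrystalSpec
    beams: list[BeamModel]
    wedges: list[tuple[int, Wedge]]  # (beam index, wedge)
    seed: int = 0

    def crystal_material(self) -> Material:
        c = self.crystal
        if c.num_residues is None:
            # average-protein composition in a cell sized for ~100 residues
            return average_protein_crystal(solvent_fraction=c.solvent_fraction)
        if c.unit_cell_volume_A3 is not None:
            return build_crystal_material(
                num_residues=c.num_residues,
                unit_cell_volume_A3=c.unit_cell_volume_A3,
                solvent_fraction=c.solvent_fraction,
            )
        return average_protein_crystal(
            solvent_fraction=c.solvent_fraction, num_residues=c.num_residues
        )

    def surrounding_material(self) -> Material | None:
        c = self.crystal
        if not (
            c.calc_surrounding
            or c.surrounding_thickness_um is not None
        ):
            return None
        if c.density_based:
            return build_surrounding_material(
                "density_based",
                elements=c.surrounding_elements,
                density=c.surrounding_density,
            )
        if c.surrounding_solutes_mM:
            return build_surrounding_material(
                "solutes_mM_in_amorphous_ice", solutes_mM=c.surrounding_solutes_mM
            )
        return build_surrounding_material("default_water")

    def build_geometry(self) -> SampleGeometry:
        c = self.crystal
        surr = self.surrounding_material()
        beam_energy = self.beams[0].energy_keV if self.beams else None
        return build_geometry(
            c.dimensions_um,
            c.pixels_per_micron,
            self.crystal_material(),
            surrounding_material=surr,
            surrounding_thickness_um=c.surrounding_thickness_um,
            calc_surrounding=c.calc_surrounding,
            beam_energy_keV=beam_energy,
            goniometer_axis_deg=c.goniometer_axis_deg,
        )


def _parse_bool(tok: str) -> bool:
    if tok.lower() in ("true", "yes", "on", "1"):
        return True
    if tok.lower() in ("false", "no", "off", "0"):
        return False
    raise ConfigurationError(f"expected a boolean, got {tok!r}")


def _elem_pairs(vals: list[str], lineno: int) -> dict[str, float]:
    if len(vals) % 2 != 0:
        raise ConfigurationError(
            f"line {lineno}: element list needs symbol/value pairs"
        )
    out: dict[str, float] = {}
    for sym, num in zip(vals[::2], vals[1::2]):
        out[sym.capitalize()] = float(num)
    return out


def parse_input(text: str) -> SimulationConfig:
    """Parse a keyword-block input file into a SimulationConfig."""
    if not text.strip():
        raise ConfigurationError("empty input")
    crystal = CrystalSpec()
    beams: list[BeamModel] = []
    wedges: list[tuple[int, Wedge]] = []
    seed = 0
    block: str | None = None
    beam_kw: dict[str, object] = {}
    wedge_kw: dict[str, object] = {}
    wedge_range: tuple[float, float] | None = None
    seen_crystal_keys: set[str] = set()

    def flush_beam():
        nonlocal beam_kw
        if block == "beam":
            if "energy" not in beam_kw:
                raise ConfigurationError("beam block missing required key ENERGY")
            if "flux" not in beam_kw:
                raise ConfigurationError("beam block missing required key FLUX")
            profile = beam_kw.get("type", "tophat")
            if profile == "gaussian":
                size = beam_kw.get("fwhm")
                if size is None:
                    raise ConfigurationError("gaussian beam needs FWHM")
                coll = beam_kw.get("collimation")
            else:
                size = beam_kw.get("collimation") or beam_kw.get("fwhm")
                if size is None:
                    raise ConfigurationError("tophat beam needs COLLIMATION")
                coll = None
            beams.append(
                BeamModel(
                    profile=profile,
                    size_um=tuple(size),
                    energy_keV=float(beam_kw["energy"]),
                    flux_ph_s=float(beam_kw["flux"]),
                    energy_fwhm_keV=float(beam_kw.get("energyfwhm", 0.0)),
                    collimation_um=tuple(coll) if coll else None,
                )
            )
            beam_kw = {}

    def flush_wedge():
        nonlocal wedge_kw, wedge_range
        if block == "wedge":
            if not beams:
                raise ConfigurationError("wedge defined before any beam")
            if "exposuretime" not in wedge_kw:
                raise ConfigurationError(
                    "wedge block missing required key EXPOSURETIME"
                )
            wedges.append(
                (
                    len(beams) - 1,
                    Wedge(
                        angle_start_deg=wedge_range[0],
                        angle_end_deg=wedge_range[1],
                        exposure_time_s=float(wedge_kw["exposuretime"]),
                        start_offset_um=tuple(
                            wedge_kw.get("startoffset", (0.0, 0.0, 0.0))
                        ),
                        translate_per_degree_um=tuple(
                            wedge_kw.get("translateperdegree", (0.0, 0.0, 0.0))
                        ),
                        angle_p_deg=float(wedge_kw.get("anglep", 0.0)),
                        angle_l_deg=float(wedge_kw.get("anglel", 0.0)),
                    ),
                )
            )
            wedge_kw = {}
            wedge_range = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#")[0].split("!")[0].strip()
        if not line:
            continue
        toks = line.split()
        key = toks[0].lower()
        vals = toks[1:]
        if key == "crystal":
            flush_beam()
            flush_wedge()
            block = "crystal"
            continue
        if key == "beam":
            flush_beam()
            flush_wedge()
            block = "beam"
            continue
        if key == "wedge":
            flush_beam()
            flush_wedge()
            block = "wedge"
            if len(vals) != 2:
                raise ConfigurationError(
                    f"line {lineno}: Wedge needs start and end angles"
                )
            wedge_range = (float(vals[0]), float(vals[1]))
            continue
        if key == "seed":
            seed = int(vals[0])
            continue
        if block == "crystal":
            seen_crystal_keys.add(key)
            if key == "type":
                if vals[0].lower() != "cuboid":
                    raise ConfigurationError(
                        f"line {lineno}: only cuboid crystals are supported"
                    )
                crystal.ctype = "cuboid"
            elif key in ("dimension", "dimensions"):
                if len(vals) != 3:
                    raise ConfigurationError(
                        f"line {lineno}: DIMENSION needs x y z in um"
                    )
                crystal.dimensions_um = tuple(float(v) for v in vals)
            elif key == "pixelspermicron":
                crystal.pixels_per_micron = float(vals[0])
            elif key == "subprogram":
                crystal.subprogram = vals[0].lower()
            elif key == "runs":
                crystal.runs = int(vals[0])
            elif key == "simphotons":
                crystal.simphotons = int(float(vals[0]))
            elif key == "numresidues":
                crystal.num_residues = float(vals[0])
            elif key == "unitcellvolume":
                crystal.unit_cell_volume_A3 = float(vals[0])
            elif key == "solventfraction":
                crystal.solvent_fraction = float(vals[0])
            elif key == "calcsurrounding":
                crystal.calc_surrounding = _parse_bool(vals[0])
            elif key == "surroundingthickness":
                crystal.surrounding_thickness_um = float(vals[0])
            elif key == "densitybased":
                crystal.density_based = _parse_bool(vals[0])
            elif key == "surroundingelements":
                crystal.surrounding_elements = _elem_pairs(vals, lineno)
            elif key == "surroundingdensity":
                crystal.surrounding_density = float(vals[0])
            elif key == "surroundingsolutes":
                crystal.surrounding_solutes_mM = _elem_pairs(vals, lineno)
            elif key == "goniometeraxis":
                crystal.goniometer_axis_deg = float(vals[0])
            else:
                raise ConfigurationError(
                    f"line {lineno}: unknown crystal keyword {toks[0]!r}"
                )
        elif block == "beam":
            if key == "type":
                prof = vals[0].lower()
                if prof not in ("tophat", "gaussian"):
                    raise ConfigurationError(
                        f"line {lineno}: unknown beam type {vals[0]!r}"
                    )
                beam_kw["type"] = prof
            elif key == "flux":
                beam_kw["flux"] = float(vals[0])
            elif key == "energy":
                beam_kw["energy"] = float(vals[0])
            elif key == "energyfwhm":
                beam_kw["energyfwhm"] = float(vals[0])
            elif key == "fwhm":
                beam_kw["fwhm"] = [float(v) for v in vals]
            elif key == "collimation":
                # accept "COLLIMATION RECTANGULAR x y" or "COLLIMATION x y"
                nums = [v for v in vals if _is_number(v)]
                if len(nums) != 2:
                    raise ConfigurationError(
                        f"line {lineno}: COLLIMATION needs x y in um"
                    )
                beam_kw["collimation"] = [float(v) for v in nums]
            else:
                raise ConfigurationError(
                    f"line {lineno}: unknown beam keyword {toks[0]!r}"
                )
        elif block == "wedge":
            if key == "exposuretime":
                wedge_kw["exposuretime"] = float(vals[0])
            elif key == "startoffset":
                wedge_kw["startoffset"] = tuple(float(v) for v in vals)
            elif key == "translateperdegree":
                wedge_kw["translateperdegree"] = tuple(float(v) for v in vals)
            elif key == "anglep":
                wedge_kw["anglep"] = float(vals[0])
            elif key == "anglel":
                wedge_kw["anglel"] = float(vals[0])
            else:
                raise ConfigurationError(
                    f"line {lineno}: unknown wedge keyword {toks[0]!r}"
                )
        else:
            raise ConfigurationError(
                f"line {lineno}: keyword {toks[0]!r} outside any block"
            )
    flush_beam()
    flush_wedge()
    if crystal.dimensions_um == (0.0, 0.0, 0.0) or "dimension" not in {
        k[:9] for k in seen_crystal_keys
    }:
        raise ConfigurationError("crystal block missing required key DIMENSION")
    if not beams:
        raise ConfigurationError("input missing a beam block (ENERGY, FLUX)")
    if not wedges:
        raise ConfigurationError("input missing a wedge block (EXPOSURETIME)")
    if crystal.simphotons < 1000:
        logger.warning(
            "SIMPHOTONS below 1000: dose metrics will be very noisy"
        )
    return SimulationConfig(crystal=crystal, beams=beams, wedges=wedges, seed=seed)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def serialize_config(config: SimulationConfig) -> str:
    """Canonical text form; parses back to an equal configuration."""
    c = config.crystal
    lines = ["Crystal", "Type Cuboid"]
    lines.append("Dimensions {} {} {}".format(*c.dimensions_um))
    lines.append(f"PixelsPerMicron {c.pixels_per_micron}")
    lines.append(f"SubProgram {c.subprogram}")
    lines.append(f"Runs {c.runs}")
    lines.append(f"SimPhotons {c.simphotons}")
    if c.num_residues is not None:
        lines.append(f"NumResidues {c.num_residues}")
    if c.unit_cell_volume_A3 is not None:
        lines.append(f"UnitCellVolume {c.unit_cell_volume_A3}")
    lines.append(f"SolventFraction {c.solvent_fraction}")
    if c.calc_surrounding:
        lines.append("CalcSurrounding true")
    if c.surrounding_thickness_um is not None:
        lines.append(f"SurroundingThickness {c.surrounding_thickness_um}")
    if c.density_based:
        lines.append("DensityBased true")
        elems = " ".join(f"{s} {n}" for s, n in c.surrounding_elements.items())
        lines.append(f"SurroundingElements {elems}")
        lines.append(f"SurroundingDensity {c.surrounding_density}")
    if c.surrounding_solutes_mM:
        sol = " ".join(f"{s} {n}" for s, n in c.surrounding_solutes_mM.items())
        lines.append(f"SurroundingSolutes {sol}")
    lines.append(f"GoniometerAxis {c.goniometer_axis_deg}")
    lines.append(f"Seed {config.seed}")
    for bi, beam in enumerate(config.beams):
        lines.append("")
        lines.append("Beam")
        lines.append(f"Type {beam.profile}")
        lines.append(f"Flux {beam.flux_ph_s}")
        lines.append(f"Energy {beam.energy_keV}")
        if beam.energy_fwhm_keV > 0:
            lines.append(f"EnergyFWHM {beam.energy_fwhm_keV}")
        if beam.profile == "gaussian":
            lines.append("FWHM {} {}".format(*beam.size_um))
            lines.append("Collimation {} {}".format(*beam.collimation_um))
        else:
            lines.append("Collimation {} {}".format(*beam.size_um))
        for wbi, wedge in config.wedges:
            if wbi != bi:
                continue
            lines.append("")
            lines.append(f"Wedge {wedge.angle_start_deg} {wedge.angle_end_deg}")
            lines.append(f"ExposureTime {wedge.exposure_time_s}")
            if any(wedge.start_offset_um):
                lines.append("StartOffset {} {} {}".format(*wedge.start_offset_um))
            if any(wedge.translate_per_degree_um):
                lines.append(
                    "TranslatePerDegree {} {} {}".format(
                        *wedge.translate_per_degree_um
                    )
                )
            if wedge.angle_p_deg:
                lines.append(f"AngleP {wedge.angle_p_deg}")
            if wedge.angle_l_deg:
                lines.append(f"AngleL {wedge.angle_l_deg}")
    return "\n".join(lines) + "\n"


def run_simulation(
    config: SimulationConfig,
    seed: int | None = None,
    photons_override: int | None = None,
    runs_override: int | None = None,
    options: engine.TransportOptions | None = None,
) -> tuple[SimulationResult, list[DoseGrid]]:
    """Run the configured Monte Carlo simulation.

    Every run gets a deterministic RNG stream derived from (seed, run index);
    rerunning with the same seed gives bit-identical results.
    """
    options = options or engine.TransportOptions()
    seed = config.seed if seed is None else seed
    n_runs = runs_override or config.crystal.runs
    n_photons = photons_override or config.crystal.simphotons
    geometry = config.build_geometry()
    tables = engine.pack_tables(
        geometry.crystal_material, geometry.surrounding_material
    )

    pairs = [(config.beams[bi], w) for bi, w in config.wedges]
    total_weight = sum(b.flux_ph_s * w.exposure_time_s for b, w in pairs)
    shares = [
        max(1, int(round(n_photons * b.flux_ph_s * w.exposure_time_s / total_weight)))
        for b, w in pairs
    ]

    # analytic no-escape reference and exposed-region mask (deterministic)
    rd_energy_J = None
    elastic_total = 0.0
    mask = np.zeros(geometry.n_voxels, dtype=bool)
    for beam, wedge in pairs:
        rd = raddose_style_dose(geometry, beam, wedge)
        rd_energy_J = rd.energy_J if rd_energy_J is None else rd_energy_J + rd.energy_J
        elastic_total += expected_elastic_scatters(geometry, beam, wedge)
        mask |= region_in_beam(geometry, beam, wedge)
    rd_grid = DoseGrid(
        energy_J=rd_energy_J,
        voxel_volume_m3=float(np.prod(geometry.voxel_size_um)) * 1e-18,
        density_kg_m3=geometry.crystal_material.density * 1000.0,
    )
    ader_rd_analytic = ader(rd_grid, mask)

    per_run: list[dict[str, float]] = []
    grids: list[DoseGrid] = []
    for r in range(n_runs):
        run_seed = (seed * 100003 + 17 * r + 1) % (2**31 - 1)
        mc_J = None
        rdmc_J = None
        for (beam, wedge), n_w in zip(pairs, shares):
            tally = engine.run_batch(
                geometry, beam, wedge, n_w, run_seed, options, tables
            )
            g_mc = scale_to_experiment(tally.grid_mc_keV, n_w, beam, wedge, geometry)
            g_rd = scale_to_experiment(tally.grid_rd_keV, n_w, beam, wedge, geometry)
            mc_J = g_mc.energy_J if mc_J is None else mc_J + g_mc.energy_J
            rdmc_J = g_rd.energy_J if rdmc_J is None else rdmc_J + g_rd.energy_J
            resid = tally.conservation_residual()
            if resid > 1e-9:
                logger.warning(
                    "run %d: energy conservation residual %.2e", r, resid
                )
        grid_mc = DoseGrid(
            energy_J=mc_J,
            voxel_volume_m3=rd_grid.voxel_volume_m3,
            density_kg_m3=rd_grid.density_kg_m3,
        )
        grid_rdmc = DoseGrid(
            energy_J=rdmc_J,
            voxel_volume_m3=rd_grid.voxel_volume_m3,
            density_kg_m3=rd_grid.density_kg_m3,
        )
        ader_mc = ader(grid_mc, mask)
        metrics = {
            "adwc": adwc(grid_mc),
            "ader": ader_mc,
            "raddose_style_ader_mc": ader(grid_rdmc, mask),
            "dose_fraction": dose_fraction(ader_mc, ader_rd_analytic),
            "diffraction_efficiency": diffraction_efficiency(
                elastic_total, ader_mc
            )
            if ader_mc > 0
            else 0.0,
        }
        per_run.append(metrics)
        grids.append(grid_mc)
        logger.info(
            "run %d/%d: seed=%d ADER=%.4g MGy dose fraction=%.4g",
            r + 1,
            n_runs,
            run_seed,
            metrics["ader"],
            metrics["dose_fraction"],
        )

    agg = aggregate_runs(per_run)
    warn_list: list[str] = []
    if agg["raddose_style_ader_mc"]["mean"] > 0:
        warn = consistency_warning(
            agg["raddose_style_ader_mc"]["mean"], ader_rd_analytic
        )
    else:
        warn = (
            "no interactions were tallied in the crystal: increase SIMPHOTONS"
        )
    if warn:
        warn_list.append(warn)
        logger.warning(warn)
    result = SimulationResult(
        adwc_MGy=agg["adwc"]["mean"],
        ader_MGy=agg["ader"]["mean"],
        raddose_style_ader_MGy=ader_rd_analytic,
        raddose_style_ader_mc_MGy=agg["raddose_style_ader_mc"]["mean"],
        dose_fraction=agg["dose_fraction"]["mean"],
        diffraction_efficiency_per_MGy=agg["diffraction_efficiency"]["mean"],
        per_run=per_run,
        aggregates=agg,
        warnings=warn_list,
        n_runs=n_runs,
        n_photons_per_run=n_photons,
        seed=seed,
    )
    return result, grids


def write_outputs(
    result: SimulationResult,
    grids: list[DoseGrid],
    outdir: str | pathlib.Path,
    geometry: SampleGeometry | None = None,
) -> list[pathlib.Path]:
    """Write summary.txt, metrics.json and per-run CSV dose maps."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[pathlib.Path] = []

    summary = outdir / "summary.txt"
    lines = [
        "xtaldose simulation summary",
        f"runs: {result.n_runs}   photons/run: {result.n_photons_per_run}   "
        f"seed: {result.seed}",
        "",
        f"ADWC                : {result.adwc_MGy:.6g} MGy",
        f"ADER                : {result.ader_MGy:.6g} MGy",
        f"RADDOSE-style ADER  : {result.raddose_style_ader_MGy:.6g} MGy (analytic)",
        f"RADDOSE-style ADER  : {result.raddose_style_ader_mc_MGy:.6g} MGy (MC)",
        f"dose fraction       : {result.dose_fraction:.6g}",
        f"diffraction eff.    : {result.diffraction_efficiency_per_MGy:.6g} "
        "photons/MGy",
    ]
    for k, v in result.aggregates.items():
        ci = v.get("ci95")
        if ci is not None:
            lines.append(f"{k}: {v['mean']:.6g} +- {ci:.3g} (95% CI, n={v['n']})")
    for w in result.warnings:
        lines.append("WARNING: " + w)
    summary.write_text("\n".join(lines) + "\n")
    written.append(summary)

    metrics = outdir / "metrics.json"
    payload = {
        "adwc_MGy": result.adwc_MGy,
        "ader_MGy": result.ader_MGy,
        "raddose_style_ader_MGy": result.raddose_style_ader_MGy,
        "raddose_style_ader_mc_MGy": result.raddose_style_ader_mc_MGy,
        "dose_fraction": result.dose_fraction,
        "diffraction_efficiency_per_MGy": result.diffraction_efficiency_per_MGy,
        "per_run": result.per_run,
        "aggregates": result.aggregates,
        "warnings": result.warnings,
        "n_runs": result.n_runs,
        "n_photons_per_run": result.n_photons_per_run,
        "seed": result.seed,
    }
    metrics.write_text(json.dumps(payload, indent=1))
    written.append(metrics)

    for k, grid in enumerate(grids):
        path = outdir / f"doses_run{k}.csv"
        dose = grid.dose_MGy
        nx, ny, nz = dose.shape
        with open(path, "w") as fh:
            fh.write(
                f"# grid shape {nx} {ny} {nz}; units um and MGy; "
                f"seed {result.seed}; photons {result.n_photons_per_run}\n"
            )
            fh.write("ix,iy,iz,x_um,y_um,z_um,dose_MGy\n")
            if geometry is not None:
                centers = geometry.voxel_centers()
            for ix in range(nx):
                for iy in range(ny):
                    for iz in range(nz):
                        if geometry is not None:
                            x, y, z = centers[ix, iy, iz]
                        else:
                            x = y = z = float("nan")
                        fh.write(
                            f"{ix},{iy},{iz},{x:.6g},{y:.6g},{z:.6g},"
                            f"{dose[ix, iy, iz]:.8g}\n"
                        )
        written.append(path)
    return written
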