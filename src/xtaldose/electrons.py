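"""Electron transport: elastic deflections, CSDA energy deposition, escape.

Electrons (photoelectrons, Compton recoils) are tracked with the detailed
single-scattering scheme: free flight to the next elastic event sampled from
the elastic MFPL, continuous energy loss along the flight at the collision
stopping power of the medium, screened-Rutherford angular deflection at each
event, and termination when the energy falls below the 50 eV cutoff (the
remainder is deposited in the current voxel) or the electron leaves the
outermost material boundary (the remainder is scored as escaped). Auger
electrons are not tracked; their energy is deposited in the voxel of origin
by the photon-transport layer.

Energy deposited along a flight segment is apportioned to the traversed
crystal voxels in proportion to the path length inside each; energy deposited
in the surrounding (or beyond the grid) is scored to an outside marker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from xtaldose import _kernels
from xtaldose.engine import TransportOptions, pack_tables, step_cap_um
from xtaldose.geometry import SampleGeometry
from xtaldose.materials import (
    ELEMENTS,
    Material,
    elastic_element_weights,
    elastic_screening_alpha,
)

__all__ = [
    "ElectronState",
    "DepositRecord",
    "deflect",
    "sample_elastic_angle",
    "deposit_along_segment",
    "trace_electron",
]

OUTSIDE = (-1, -1, -1)  # voxel marker for energy deposited outside the grid


@dataclass
class ElectronState:
    position_um: np.ndarray
    direction: np.ndarray
    energy_keV: float
    medium: str = "crystal"  # "crystal" | "surrounding" | "outside"

    def __post_init__(self):
        self.position_um = np.asarray(self.position_um, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if n > 0:
            self.direction = self.direction / n


@dataclass(frozen=True)
class DepositRecord:
    voxel: tuple[int, int, int]  # OUTSIDE marks the outside-marker bucket
    energy_keV: float
    source: str = "photoelectron"  # | "auger" | "compton_recoil"


def deflect(
    direction: np.ndarray, scatter_polar_angle: float, scatter_azimuth: float
) -> np.ndarray:
    """Rotate a unit direction by the scattering polar angle, with the
    azimuth setting the rotation plane perpendicular to the old direction."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    nx, ny, nz = _kernels._rotate_direction(
        d[0], d[1], d[2], math.cos(scatter_polar_angle), scatter_azimuth
    )
    return np.array([nx, ny, nz])


def sample_elastic_angle(
    material: Material,
    energy_keV: float,
    rnd: float,
    element_rnd: float = 0.0,
) -> float:
    """Polar deflection angle from the screened-Rutherford DCS via its
    closed-form inverse CDF: cos(theta) = 1 - 2 a R / (1 + a - R) with
    screening parameter a = 3.4e-3 Z^(2/3) / E. The scattering element is
    picked from the composition-weighted elastic cross sections via
    ``element_rnd``."""
    if not 0.0 <= rnd <= 1.0:
        raise ValueError("rnd must lie in [0, 1]")
    weights = elastic_element_weights(material, energy_keV)
    acc = 0.0
    elem = next(iter(weights))
    for s, w in weights.items():
        acc += w
        if element_rnd <= acc:
            elem = s
            break
    alpha = elastic_screening_alpha(ELEMENTS[elem].atomic_number, energy_keV)
    cos_t = 1.0 - 2.0 * alpha * rnd / (1.0 + alpha - rnd)
    return math.acos(min(1.0, max(-1.0, cos_t)))


def screened_rutherford_mean_cos(z: int, energy_keV: float, n: int = 20000) -> float:
    """Quadrature expectation of cos(theta) under the same DCS, used as an
    independent oracle against the sampled mean."""
    alpha = elastic_screening_alpha(z, energy_keV)
    r = (np.arange(n) + 0.5) / n
    cos_t = 1.0 - 2.0 * alpha * r / (1.0 + alpha - r)
    return float(np.mean(cos_t))


def deposit_along_segment(
    grid: np.ndarray,
    geometry: SampleGeometry,
    start_um: np.ndarray,
    end_um: np.ndarray,
    energy_lost_keV: float,
    source: str = "photoelectron",
) -> list[DepositRecord]:
    """Apportion ``energy_lost_keV`` along a straight segment to the crystal
    voxels it traverses (path-length proportional); portions outside the
    crystal go to the OUTSIDE marker. ``grid`` is modified in place."""
    if energy_lost_keV < 0:
        raise ValueError("energy_lost must be >= 0")
    before = grid.copy()
    outside = _kernels.deposit_segment(
        grid,
        np.asarray(start_um, dtype=float),
        np.asarray(end_um, dtype=float),
        float(energy_lost_keV),
        geometry.half_dims_um,
        np.array(geometry.voxel_size_um),
        np.array(geometry.n_voxels, dtype=np.int64),
    )
    diff = grid - before
    records = [
        DepositRecord(voxel=tuple(int(v) for v in idx), energy_keV=float(e), source=source)
        for idx, e in np.ndenumerate(diff)
        if e > 0.0
    ]
    if outside > 0.0:
        records.append(DepositRecord(voxel=OUTSIDE, energy_keV=float(outside), source=source))
    return records


def trace_electron(
    electron: ElectronState,
    geometry: SampleGeometry,
    seed: int,
    options: TransportOptions | None = None,
    source: str = "photoelectron",
) -> tuple[list[DepositRecord], float]:
    """Track one electron history; returns its deposit records (crystal
    voxels plus an OUTSIDE marker) and the escaped energy in keV."""
    options = options or TransportOptions()
    tables = pack_tables(geometry.crystal_material, geometry.surrounding_material)
    grid = np.zeros(geometry.n_voxels)
    accum = np.zeros(_kernels.N_ACCUM)
    state = np.uint64(_kernels.seed_stream(np.uint64(seed), np.uint64(0)))
    d = electron.direction
    _, escaped = _kernels.trace_electron(
        float(electron.position_um[0]),
        float(electron.position_um[1]),
        float(electron.position_um[2]),
        float(d[0]),
        float(d[1]),
        float(d[2]),
        float(electron.energy_keV),
        1.0,
        state,
        geometry.half_dims_um,
        geometry.outer_half_dims_um,
        geometry.has_surrounding,
        np.array(geometry.voxel_size_um),
        np.array(geometry.n_voxels, dtype=np.int64),
        tables.eloge_grid,
        tables.log_s_tab,
        tables.log_invmfp_tab,
        tables.el_cum,
        tables.el_alpha,
        tables.n_elem_el,
        options.e_cutoff_keV,
        step_cap_um(geometry, options.step_cap_voxel_fraction),
        options.elastic_on,
        grid,
        accum,
    )
    records = [
        DepositRecord(voxel=tuple(int(v) for v in idx), energy_keV=float(e), source=source)
        for idx, e in np.ndenumerate(grid)
        if e > 0.0
    ]
    outside = float(accum[_kernels.ACC_OUTSIDE])
    if outside > 0.0:
        records.append(DepositRecord(voxel=OUTSIDE, energy_keV=outside, source=source))
    return records, float(escaped)
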