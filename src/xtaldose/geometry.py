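"""Voxelized sample geometry, goniometer transforms and beam sampling.

Coordinate conventions (right-handed, lengths in um):

* lab frame: z is the beam direction, y the goniometer rotation axis for an
  axis setting of 0 deg ("horizontal"), x completes the triad;
* sample frame: the crystal is an axis-aligned cuboid centred at the origin;
  the surrounding material, when present, is a rectangular shell of uniform
  thickness on all six faces;
* the rigid transform for a wedge angle maps sample coordinates to lab
  coordinates via the composition Rz(axis) . Ry(wedge) . Rz(AngleP) .
  Rx(AngleL) plus the wedge translation.

Synchrotron polarization is horizontal in the lab; for an axis setting of
0 deg it coincides with the sample y axis, and the axis setting rotates the
polarization direction within the plane perpendicular to the beam. An axis
setting of 90 deg is read as a vertical goniometer axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from xtaldose.materials import (
    ELEMENTS,
    ConfigurationError,
    Material,
    csda_range,
)

__all__ = [
    "SampleGeometry",
    "BeamModel",
    "Wedge",
    "PhotonState",
    "RigidTransform",
    "build_geometry",
    "orientation_transform",
    "sample_photon",
    "region_in_beam",
]

UPSTREAM_Z = -1.0e6  # photon launch plane, um upstream of everything


def _rot_x(a):
    c, s = math.cos(a), math.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _rot_y(a):
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def _rot_z(a):
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


@dataclass(frozen=True)
class RigidTransform:
    """Sample -> lab rigid transform: x_lab = R x_sample + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def apply_vector(self, vectors: np.ndarray) -> np.ndarray:
        return np.asarray(vectors) @ self.rotation.T

    def inverse_apply(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points) - self.translation) @ self.rotation

    def inverse_apply_vector(self, vectors: np.ndarray) -> np.ndarray:
        return np.asarray(vectors) @ self.rotation


@dataclass
class Wedge:
    """A contiguous rotation range with exposure time and translations."""

    angle_start_deg: float
    angle_end_deg: float
    exposure_time_s: float
    start_offset_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translate_per_degree_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    angle_p_deg: float = 0.0  # extra rotation about the beam (z) axis
    angle_l_deg: float = 0.0  # extra rotation about the lab x axis

    def __post_init__(self):
        if self.exposure_time_s <= 0:
            raise ConfigurationError("wedge exposure time must be positive")
        if self.angle_end_deg < self.angle_start_deg:
            raise ConfigurationError("wedge end angle must be >= start angle")

    @property
    def span_deg(self) -> float:
        return self.angle_end_deg - self.angle_start_deg


@dataclass
class BeamModel:
    """Beam profile, energy (optionally polychromatic) and flux."""

    profile: str  # "tophat" | "gaussian"
    size_um: tuple[float, float]  # collimation (tophat) or FWHM (gaussian)
    energy_keV: float
    flux_ph_s: float
    energy_fwhm_keV: float = 0.0
    collimation_um: tuple[float, float] | None = None  # gaussian truncation box

    def __post_init__(self):
        if self.profile not in ("tophat", "gaussian"):
            raise ConfigurationError(f"unknown beam profile {self.profile!r}")
        if self.flux_ph_s <= 0:
            raise ConfigurationError("beam flux must be positive")
        if self.energy_keV <= 0:
            raise ConfigurationError("beam energy must be positive")
        if self.energy_fwhm_keV < 0:
            raise ConfigurationError("energy FWHM must be >= 0")
        if self.profile == "gaussian" and self.collimation_um is None:
            # truncation box defaults to 3 x FWHM per axis
            self.collimation_um = (3.0 * self.size_um[0], 3.0 * self.size_um[1])

    @property
    def energy_sigma_keV(self) -> float:
        return self.energy_fwhm_keV / 2.3548200450309493

    def footprint_um(self) -> tuple[float, float]:
        """Rectangle used for the exposed-region (ADER) mask: collimation for
        a tophat beam, the FWHM rectangle for a Gaussian beam."""
        return tuple(self.size_um)

    def intensity(self, x, y):
        """Profile density in photons per um^2 per incident photon
        (normalized over the sampled aperture)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.profile == "tophat":
            sx, sy = self.size_um
            inside = (np.abs(x) <= sx / 2) & (np.abs(y) <= sy / 2)
            return inside / (sx * sy)
        fx, fy = self.size_um
        sigx = fx / 2.3548200450309493
        sigy = fy / 2.3548200450309493
        cx, cy = self.collimation_um
        inside = (np.abs(x) <= cx / 2) & (np.abs(y) <= cy / 2)
        normx = math.erf(cx / 2 / (sigx * math.sqrt(2.0)))
        normy = math.erf(cy / 2 / (sigy * math.sqrt(2.0)))
        g = (
            np.exp(-0.5 * (x / sigx) ** 2 - 0.5 * (y / sigy) ** 2)
            / (2.0 * math.pi * sigx * sigy)
            / (normx * normy)
        )
        return np.where(inside, g, 0.0)


@dataclass(frozen=True)
class PhotonState:
    """Position (um, lab frame), unit direction and energy of one photon."""

    position: np.ndarray
    direction: np.ndarray
    energy_keV: float


@dataclass
class SampleGeometry:
    """Crystal voxel grid plus an analytic surrounding shell."""

    crystal_dims_um: tuple[float, float, float]
    voxel_resolution_per_um: float
    crystal_material: Material
    surrounding_material: Material | None = None
    surrounding_thickness_um: float = 0.0
    goniometer_axis_deg: float = 0.0

    n_voxels: tuple[int, int, int] = field(init=False)
    voxel_size_um: tuple[float, float, float] = field(init=False)

    def __post_init__(self):
        if self.voxel_resolution_per_um <= 0:
            raise ConfigurationError("voxel resolution must be positive")
        if self.surrounding_thickness_um < 0:
            raise ConfigurationError("surrounding thickness must be >= 0")
        n = []
        for d in self.crystal_dims_um:
            if d <= 0:
                raise ConfigurationError("crystal dimensions must be positive")
            ni = int(round(d * self.voxel_resolution_per_um))
            if ni < 1:
                raise ConfigurationError(
                    f"resolution {self.voxel_resolution_per_um}/um gives no "
                    f"voxels across a {d} um dimension"
                )
            if ni < 3:
                warnings.warn(
                    "fewer than 3 voxels across a crystal dimension; consider "
                    "a larger PIXELSPERMICRON",
                    stacklevel=2,
                )
            n.append(ni)
        self.n_voxels = tuple(n)
        self.voxel_size_um = tuple(
            d / ni for d, ni in zip(self.crystal_dims_um, self.n_voxels)
        )

    @property
    def half_dims_um(self) -> np.ndarray:
        return np.array(self.crystal_dims_um) / 2.0

    @property
    def has_surrounding(self) -> bool:
        return self.surrounding_material is not None and (
            self.surrounding_thickness_um > 0
        )

    @property
    def outer_half_dims_um(self) -> np.ndarray:
        extra = self.surrounding_thickness_um if self.has_surrounding else 0.0
        return self.half_dims_um + extra

    def voxel_centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel centres in the sample frame."""
        axes = [
            (np.arange(ni) + 0.5) * vi - di / 2.0
            for ni, vi, di in zip(
                self.n_voxels, self.voxel_size_um, self.crystal_dims_um
            )
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    def polarization_lab(self) -> np.ndarray:
        a = math.radians(self.goniometer_axis_deg)
        return _rot_z(a) @ np.array([0.0, 1.0, 0.0])


def build_geometry(
    crystal_dims_um: tuple[float, float, float],
    voxel_resolution_per_um: float,
    crystal_material: Material,
    *,
    surrounding_material: Material | None = None,
    surrounding_thickness_um: float | None = None,
    calc_surrounding: bool = False,
    beam_energy_keV: float | None = None,
    goniometer_axis_deg: float = 0.0,
) -> SampleGeometry:
    """Assemble the sample geometry.

    When ``calc_surrounding`` is true and no explicit thickness is given, the
    shell thickness defaults to the maximum photoelectron CSDA range in the
    surrounding at the beam energy (photon energy minus the oxygen K-shell
    binding energy).
    """
    thickness = 0.0
    if surrounding_material is not None:
        if surrounding_thickness_um is not None:
            thickness = surrounding_thickness_um
        elif calc_surrounding:
            if beam_energy_keV is None:
                raise ConfigurationError(
                    "CSDA-derived surrounding thickness needs the beam energy"
                )
            e_pe = beam_energy_keV - ELEMENTS["O"].k_binding
            thickness = csda_range(surrounding_material, e_pe)
        else:
            raise ConfigurationError(
                "surrounding material given without thickness; set an explicit "
                "thickness or CALCSURROUNDING true"
            )
    return SampleGeometry(
        crystal_dims_um=tuple(crystal_dims_um),
        voxel_resolution_per_um=voxel_resolution_per_um,
        crystal_material=crystal_material,
        surrounding_material=surrounding_material,
        surrounding_thickness_um=thickness,
        goniometer_axis_deg=goniometer_axis_deg,
    )


def orientation_transform(
    geometry: SampleGeometry, wedge: Wedge, wedge_angle_deg: float
) -> RigidTransform:
    """Rigid sample->lab transform at one wedge angle."""
    if not (
        wedge.angle_start_deg - 1e-9
        <= wedge_angle_deg
        <= wedge.angle_end_deg + 1e-9
    ):
        raise ValueError("wedge angle outside wedge bounds")
    axis = math.radians(geometry.goniometer_axis_deg)
    phi = math.radians(wedge_angle_deg)
    p = math.radians(wedge.angle_p_deg)
    l = math.radians(wedge.angle_l_deg)
    rot = _rot_z(axis) @ _rot_y(phi) @ _rot_z(p) @ _rot_x(l)
    delta = wedge_angle_deg - wedge.angle_start_deg
    t = np.array(wedge.start_offset_um) + delta * np.array(
        wedge.translate_per_degree_um
    )
    return RigidTransform(rotation=rot, translation=t)


def sample_photon(
    beam: BeamModel,
    wedge: Wedge,
    rng: np.random.Generator,
    energy_quantile: float | None = None,
) -> PhotonState:
    """Draw one incident photon: transverse position from the beam profile by
    inverse-transform/rejection sampling, direction +z, energy fixed or from
    the systematic Gaussian quantile when the beam is polychromatic."""
    if beam.profile == "tophat":
        sx, sy = beam.size_um
        x = rng.uniform(-sx / 2, sx / 2)
        y = rng.uniform(-sy / 2, sy / 2)
    else:
        sigx = beam.size_um[0] / 2.3548200450309493
        sigy = beam.size_um[1] / 2.3548200450309493
        cx, cy = beam.collimation_um
        while True:  # truncation at the collimation box
            x = rng.normal(0.0, sigx)
            y = rng.normal(0.0, sigy)
            if abs(x) <= cx / 2 and abs(y) <= cy / 2:
                break
    energy = beam.energy_keV
    if beam.energy_fwhm_keV > 0:
        from scipy.special import ndtri

        q = energy_quantile if energy_quantile is not None else rng.random()
        energy = beam.energy_keV + beam.energy_sigma_keV * float(ndtri(q))
    return PhotonState(
        position=np.array([x, y, UPSTREAM_Z]),
        direction=np.array([0.0, 0.0, 1.0]),
        energy_keV=float(energy),
    )


def region_in_beam(
    geometry: SampleGeometry,
    beam: BeamModel,
    wedge: Wedge,
    n_angle_nodes: int | None = None,
) -> np.ndarray:
    """Boolean mask of crystal voxels whose centre, averaged over the wedge
    rotation, lies inside the beam footprint projected along z."""
    if n_angle_nodes is None:
        n_angle_nodes = max(1, min(360, int(math.ceil(wedge.span_deg)) + 1))
    angles = np.linspace(
        wedge.angle_start_deg, wedge.angle_end_deg, n_angle_nodes
    )
    centers = geometry.voxel_centers().reshape(-1, 3)
    mean_xy = np.zeros((centers.shape[0], 2))
    for a in angles:
        tr = orientation_transform(geometry, wedge, a)
        lab = tr.apply(centers)
        mean_xy += lab[:, :2]
    mean_xy /= len(angles)
    fx, fy = beam.footprint_um()
    mask = (np.abs(mean_xy[:, 0]) <= fx / 2) & (np.abs(mean_xy[:, 1]) <= fy / 2)
    return mask.reshape(geometry.n_voxels)
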