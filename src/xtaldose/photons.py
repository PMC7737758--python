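"""Photon transport: interaction sampling, photoelectric and Compton events.

The transport model terminates each photon at its first ionizing interaction:
photoelectric absorption consumes the photon, a Compton-scattered photon is
not tracked further (it has lost E_comp to the recoil electron), and elastic
(coherent) scattering is not a transport event at all -- its cross section
enters only the diffraction-efficiency accounting. Fluorescent photons are
never tracked and are scored as escaped.

The photon deflection angle in a Compton event is sampled uniformly on
[0, pi) by default, matching the reference formulation; a Klein-Nishina
weighted mode is available for sensitivity studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from xtaldose.electrons import ElectronState
from xtaldose.geometry import PhotonState, SampleGeometry
from xtaldose.materials import (
    ELEMENTS,
    Material,
    PhotonCrossSections,
    k_shell_relaxation,
    photon_cross_sections,
)

__all__ = [
    "InteractionEvent",
    "ComptonKinematics",
    "distance_to_interaction",
    "select_interaction",
    "do_photoelectric",
    "sample_photoelectron_direction",
    "do_compton",
    "trace_photon",
]

MC2 = 511.0  # electron rest energy, keV


@dataclass
class InteractionEvent:
    kind: str  # "photoelectric" | "compton"
    position_um: np.ndarray
    medium: str  # "crystal" | "surrounding"
    deposited_locally_keV: float
    electron: ElectronState | None
    escaped_fluorescence_keV: float = 0.0
    element: str | None = None
    binding_keV: float = 0.0


@dataclass(frozen=True)
class ComptonKinematics:
    e_comp_keV: float
    theta_pho_rad: float
    theta_comp_rad: float


def distance_to_interaction(
    lambda_tot: float,
    rnd: float | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Exponential free path s = -lambda ln(RND), RND in (0, 1]."""
    if lambda_tot <= 0:
        raise ValueError("mean free path must be positive")
    if rnd is None:
        if rng is None:
            raise ValueError("provide rnd or rng")
        rnd = 1.0 - rng.random()  # (0, 1]
        while rnd == 0.0:
            rnd = 1.0 - rng.random()
    if not 0.0 < rnd <= 1.0:
        raise ValueError("rnd must lie in (0, 1]")
    return -lambda_tot * math.log(rnd)


def select_interaction(xsecs: PhotonCrossSections, rnd: float) -> str:
    """Choose photoelectric vs Compton with the relative channel
    probabilities lambda_tot/lambda_photo and lambda_tot/lambda_comp."""
    p_photo = xsecs.lambda_tot_mm / xsecs.lambda_photo_mm
    return "photoelectric" if rnd < p_photo else "compton"


def sample_photoelectron_direction(
    polarization_vector: np.ndarray,
    rng: np.random.Generator,
    dipole: bool = True,
) -> np.ndarray:
    """Initial photoelectron direction: density ~ cos^2 of the angle to the
    polarization vector (dipole mode), or isotropic."""
    p = np.asarray(polarization_vector, dtype=float)
    norm = np.linalg.norm(p)
    if not math.isclose(norm, 1.0, rel_tol=1e-9):
        raise ValueError("polarization vector must be unit length")
    if not dipole:
        c = 2.0 * rng.random() - 1.0
        phi = 2.0 * math.pi * rng.random()
        s = math.sqrt(max(0.0, 1.0 - c * c))
        return np.array([s * math.cos(phi), s * math.sin(phi), c])
    u = 2.0 * rng.random() - 1.0
    cos_psi = math.copysign(abs(u) ** (1.0 / 3.0), u)
    sin_psi = math.sqrt(max(0.0, 1.0 - cos_psi * cos_psi))
    phi = 2.0 * math.pi * rng.random()
    # orthonormal basis about p
    if abs(p[2]) < 0.9:
        u1 = np.cross([0.0, 0.0, 1.0], p)
    else:
        u1 = np.cross([1.0, 0.0, 0.0], p)
    u1 /= np.linalg.norm(u1)
    u2 = np.cross(p, u1)
    d = cos_psi * p + sin_psi * (math.cos(phi) * u1 + math.sin(phi) * u2)
    return d / np.linalg.norm(d)


def do_photoelectric(
    photon: PhotonState,
    material: Material,
    polarization_vector: np.ndarray,
    rng: np.random.Generator,
    medium: str = "crystal",
    dipole: bool = True,
) -> InteractionEvent:
    """Photoelectric absorption: element sampled from the per-element
    photoelectric fractions, shell via the K-shell fraction, photoelectron
    energy E_inc minus the shell binding energy, K vacancy relaxed to a local
    Auger deposit or an escaping K-alpha photon."""
    e_inc = photon.energy_keV
    xs = photon_cross_sections(material, e_inc)
    syms = list(xs.per_element_photo_fractions)
    probs = np.array([xs.per_element_photo_fractions[s] for s in syms])
    elem = syms[int(rng.choice(len(syms), p=probs / probs.sum()))]
    rec = ELEMENTS[elem]
    binding = 0.0
    local = 0.0
    fluor = 0.0
    if e_inc > rec.k_binding and rng.random() < rec.k_shell_fraction:
        binding = rec.k_binding
        outcome = k_shell_relaxation(elem, rng)
        if outcome.branch == "fluorescence":
            fluor = outcome.fluorescent_photon_energy_keV
            local = max(binding - fluor, 0.0)
        else:
            # Auger electron plus residual vacancy energy, all local
            local = binding
    direction = sample_photoelectron_direction(polarization_vector, rng, dipole)
    electron = ElectronState(
        position_um=np.array(photon.position, dtype=float),
        direction=direction,
        energy_keV=e_inc - binding,
        medium=medium,
    )
    return InteractionEvent(
        kind="photoelectric",
        position_um=np.array(photon.position, dtype=float),
        medium=medium,
        deposited_locally_keV=local,
        electron=electron,
        escaped_fluorescence_keV=fluor,
        element=elem,
        binding_keV=binding,
    )


def compton_kinematics(e_inc: float, theta_pho: float) -> ComptonKinematics:
    """Recoil electron energy and emission angle for photon deflection
    theta_pho: E_comp = E^2 (1-cos)/mc^2 / (1 + E (1-cos)/mc^2) and
    tan(theta_comp) = 1 / [tan(theta_pho/2) (1 + E/mc^2)]."""
    if not 0.0 <= theta_pho < math.pi + 1e-12:
        raise ValueError("theta_pho must lie in [0, pi)")
    one_m_cos = 1.0 - math.cos(theta_pho)
    if one_m_cos <= 0.0:
        return ComptonKinematics(0.0, theta_pho, 0.5 * math.pi)
    k = e_inc * one_m_cos / MC2
    e_comp = e_inc * k / (1.0 + k)
    theta_comp = math.atan2(1.0, math.tan(0.5 * theta_pho) * (1.0 + e_inc / MC2))
    return ComptonKinematics(e_comp, theta_pho, theta_comp)


def mean_compton_recoil_energy(e_inc: float, n_nodes: int = 512) -> float:
    """Mean recoil energy under the uniform-angle deflection sampling,
    (1/pi) * integral of E_comp over theta_pho in [0, pi)."""
    theta = (np.arange(n_nodes) + 0.5) * math.pi / n_nodes
    one_m_cos = 1.0 - np.cos(theta)
    k = e_inc * one_m_cos / MC2
    return float(np.mean(e_inc * k / (1.0 + k)))


def do_compton(
    photon: PhotonState,
    rng: np.random.Generator,
    theta_pho: float | None = None,
    medium: str = "crystal",
) -> InteractionEvent:
    """Compton scattering: uniform photon deflection on [0, pi), recoil
    kinematics from the scattering relations, scattered photon dropped."""
    if theta_pho is None:
        theta_pho = rng.random() * math.pi
    kin = compton_kinematics(photon.energy_keV, theta_pho)
    phi = 2.0 * math.pi * rng.random()
    d = np.asarray(photon.direction, dtype=float)
    from xtaldose.electrons import deflect

    e_dir = deflect(d, kin.theta_comp_rad, phi)
    electron = ElectronState(
        position_um=np.array(photon.position, dtype=float),
        direction=e_dir,
        energy_keV=kin.e_comp_keV,
        medium=medium,
    )
    return InteractionEvent(
        kind="compton",
        position_um=np.array(photon.position, dtype=float),
        medium=medium,
        deposited_locally_keV=0.0,
        electron=electron,
    )


def trace_photon(
    photon: PhotonState,
    geometry: SampleGeometry,
    rng: np.random.Generator,
    dipole: bool = True,
) -> list[InteractionEvent]:
    """Analog transport of one photon (sample frame, no rotation applied):
    advance by exponential free paths, redrawing at each medium boundary
    (statistically exact for the memoryless exponential), and terminate at
    the first ionizing interaction or on exit."""
    from xtaldose._kernels import _ray_box  # numba funcs work from python too

    pos = np.array(photon.position, dtype=float)
    d = np.array(photon.direction, dtype=float)
    d /= np.linalg.norm(d)
    e = photon.energy_keV
    half_c = geometry.half_dims_um
    half_o = geometry.outer_half_dims_um
    events: list[InteractionEvent] = []

    def medium_at(p):
        if np.all(np.abs(p) <= half_c + 1e-12):
            return "crystal"
        if geometry.has_surrounding and np.all(np.abs(p) <= half_o + 1e-12):
            return "surrounding"
        return "outside"

    # advance to the sample if launched upstream
    if medium_at(pos) == "outside":
        tmin, tmax = _ray_box(
            pos[0], pos[1], pos[2], d[0], d[1], d[2],
            half_o[0], half_o[1], half_o[2],
        )
        if tmax <= tmin or tmax <= 0:
            return events
        pos = pos + d * (max(tmin, 0.0) + 1e-9)

    eps = 1e-9
    while True:
        med = medium_at(pos)
        if med == "outside":
            return events
        mat = (
            geometry.crystal_material
            if med == "crystal"
            else geometry.surrounding_material
        )
        xs = photon_cross_sections(mat, e)
        lam_um = xs.lambda_tot_mm * 1000.0
        s = distance_to_interaction(lam_um, rng=rng)
        half = half_c if med == "crystal" else half_o
        tmin, tmax = _ray_box(
            pos[0], pos[1], pos[2], d[0], d[1], d[2], half[0], half[1], half[2]
        )
        d_bound = max(tmax, 0.0)
        if med == "surrounding":
            ci, co = _ray_box(
                pos[0], pos[1], pos[2], d[0], d[1], d[2],
                half_c[0], half_c[1], half_c[2],
            )
            if co >= ci and ci > 0:
                d_bound = min(d_bound, ci)
        if s >= d_bound:
            pos = pos + d * (d_bound + eps)
            continue
        pos = pos + d * s
        here = PhotonState(position=pos, direction=d, energy_keV=e)
        if select_interaction(xs, rng.random()) == "photoelectric":
            pol = geometry.polarization_lab()
            events.append(
                do_photoelectric(here, mat, pol, rng, medium=med, dipole=dipole)
            )
        else:
            events.append(do_compton(here, rng, medium=med))
        return events
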