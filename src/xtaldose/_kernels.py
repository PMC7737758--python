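"""Numba-compiled transport kernels.

Everything here operates on packed float64/int64 arrays prepared by the
engine; the public modules (:mod:`xtaldose.photons`, :mod:`xtaldose.electrons`,
:mod:`xtaldose.io`) wrap these kernels. Geometry is axis-aligned in the sample
frame: the crystal is a centred cuboid with half-dimensions ``half_c`` and the
surrounding, when present, a centred cuboid with half-dimensions ``half_o``
(crystal + uniform shell thickness).

Random numbers come from a counter-seeded splitmix64 stream so that every
photon history is reproducible independently of execution order.

Accumulator slots (``accum`` array):

0. energy deposited outside the crystal grid (surrounding or beyond), keV
1. escaped electron energy, keV
2. escaped fluorescence energy, keV
3. total absorbed photon energy (photoelectric E_inc + Compton E_comp), keV
4. weighted photoelectric event count
5. weighted Compton event count
6. raw interaction count
7. sum of interaction weights
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

U64 = np.uint64
_INV_2_53 = 1.0 / 9007199254740992.0

ACC_OUTSIDE = 0
ACC_ESCAPED_E = 1
ACC_ESCAPED_FLUOR = 2
ACC_ABSORBED = 3
ACC_W_PHOTO = 4
ACC_W_COMPTON = 5
ACC_N_EVENTS = 6
ACC_SUM_W = 7
N_ACCUM = 8

MC2 = 511.0  # electron rest energy, keV


@njit(cache=True, inline="always")
def _next_u64(state):
    state = state + U64(0x9E3779B97F4A7C15)
    z = state
    z = (z ^ (z >> U64(30))) * U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> U64(27))) * U64(0x94D049BB133111EB)
    z = z ^ (z >> U64(31))
    return state, z


@njit(cache=True, inline="always")
def _rand(state):
    """Uniform in [0, 1)."""
    state, z = _next_u64(state)
    return state, float(z >> U64(11)) * _INV_2_53


@njit(cache=True, inline="always")
def _rand_open(state):
    """Uniform in (0, 1]; safe as the argument of log."""
    state, u = _rand(state)
    return state, 1.0 - u


@njit(cache=True)
def seed_stream(seed, index):
    """Decorrelated per-history stream state from (run seed, history index)."""
    s = U64(seed) * U64(0x9E3779B97F4A7C15) + U64(index) * U64(
        0xD1B54A32D192ED03
    ) + U64(0x2545F4914F6CDD1D)
    # one scrambling round
    s, z = _next_u64(s)
    return z


@njit(cache=True, inline="always")
def _interp_loglog(loge_grid, log_tab, loge):
    n = loge_grid.shape[0]
    if loge <= loge_grid[0]:
        return math.exp(log_tab[0])
    if loge >= loge_grid[n - 1]:
        return math.exp(log_tab[n - 1])
    lo = 0
    hi = n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if loge_grid[mid] <= loge:
            lo = mid
        else:
            hi = mid
    f = (loge - loge_grid[lo]) / (loge_grid[lo + 1] - loge_grid[lo])
    return math.exp(log_tab[lo] * (1.0 - f) + log_tab[lo + 1] * f)


@njit(cache=True, inline="always")
def _grid_index(loge_grid, loge):
    n = loge_grid.shape[0]
    if loge <= loge_grid[0]:
        return 0
    if loge >= loge_grid[n - 1]:
        return n - 1
    lo = 0
    hi = n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if loge_grid[mid] <= loge:
            lo = mid
        else:
            hi = mid
    return lo


@njit(cache=True, inline="always")
def _ray_box(ox, oy, oz, dx, dy, dz, hx, hy, hz):
    """Slab intersection of a ray with a centred box; returns (tmin, tmax),
    tmax < tmin when the ray misses."""
    tmin = -1.0e30
    tmax = 1.0e30
    for axis in range(3):
        if axis == 0:
            o, d, h = ox, dx, hx
        elif axis == 1:
            o, d, h = oy, dy, hy
        else:
            o, d, h = oz, dz, hz
        if abs(d) < 1.0e-14:
            if abs(o) > h:
                return 1.0, -1.0
        else:
            t1 = (-h - o) / d
            t2 = (h - o) / d
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > tmin:
                tmin = t1
            if t2 < tmax:
                tmax = t2
    return tmin, tmax


@njit(cache=True, inline="always")
def _medium(x, y, z, half_c, half_o, has_surr):
    """0 = crystal, 1 = surrounding, 2 = outside."""
    if (
        abs(x) <= half_c[0]
        and abs(y) <= half_c[1]
        and abs(z) <= half_c[2]
    ):
        return 0
    if has_surr and (
        abs(x) <= half_o[0]
        and abs(y) <= half_o[1]
        and abs(z) <= half_o[2]
    ):
        return 1
    return 2


@njit(cache=True, inline="always")
def _voxel_of(x, y, z, half_c, vs, nvox):
    ix = int((x + half_c[0]) / vs[0])
    iy = int((y + half_c[1]) / vs[1])
    iz = int((z + half_c[2]) / vs[2])
    if ix < 0:
        ix = 0
    if iy < 0:
        iy = 0
    if iz < 0:
        iz = 0
    if ix >= nvox[0]:
        ix = nvox[0] - 1
    if iy >= nvox[1]:
        iy = nvox[1] - 1
    if iz >= nvox[2]:
        iz = nvox[2] - 1
    return ix, iy, iz


@njit(cache=True)
def deposit_segment(grid, p0, p1, energy, half_c, vs, nvox):
    """Apportion ``energy`` along the segment p0 -> p1 to traversed crystal
    voxels proportionally to the path length in each; energy along portions
    outside the crystal box is returned (outside-marker share)."""
    if energy <= 0.0:
        return 0.0
    dx = p1[0] - p0[0]
    dy = p1[1] - p0[1]
    dz = p1[2] - p0[2]
    seg_len = math.sqrt(dx * dx + dy * dy + dz * dz)
    if seg_len < 1.0e-15:
        m = _medium(p0[0], p0[1], p0[2], half_c, half_c, False)
        if m == 0:
            ix, iy, iz = _voxel_of(p0[0], p0[1], p0[2], half_c, vs, nvox)
            grid[ix, iy, iz] += energy
            return 0.0
        return energy
    ux = dx / seg_len
    uy = dy / seg_len
    uz = dz / seg_len
    # clip to the crystal box
    tmin, tmax = _ray_box(p0[0], p0[1], p0[2], ux, uy, uz, half_c[0], half_c[1], half_c[2])
    t_in = max(tmin, 0.0)
    t_out = min(tmax, seg_len)
    if tmax < tmin or t_out <= t_in:
        return energy
    outside = energy * (seg_len - (t_out - t_in)) / seg_len
    e_per_len = energy / seg_len
    # walk the inside portion voxel by voxel
    t = t_in
    guard = 0
    max_guard = nvox[0] + nvox[1] + nvox[2] + 6
    while t < t_out - 1.0e-12 and guard < max_guard:
        guard += 1
        # midpoint-robust index of the current voxel
        tq = t
        px = p0[0] + ux * (tq + 1.0e-9)
        py = p0[1] + uy * (tq + 1.0e-9)
        pz = p0[2] + uz * (tq + 1.0e-9)
        ix, iy, iz = _voxel_of(px, py, pz, half_c, vs, nvox)
        # parametric exit from this voxel
        t_next = t_out
        for axis in range(3):
            if axis == 0:
                u, p, h, v, i = ux, p0[0], half_c[0], vs[0], ix
            elif axis == 1:
                u, p, h, v, i = uy, p0[1], half_c[1], vs[1], iy
            else:
                u, p, h, v, i = uz, p0[2], half_c[2], vs[2], iz
            if u > 1.0e-14:
                edge = -h + (i + 1) * v
                tc = (edge - p) / u
                if tc < t_next:
                    t_next = tc
            elif u < -1.0e-14:
                edge = -h + i * v
                tc = (edge - p) / u
                if tc < t_next:
                    t_next = tc
        if t_next <= t:
            t_next = t + 1.0e-9
        if t_next > t_out:
            t_next = t_out
        grid[ix, iy, iz] += e_per_len * (t_next - t)
        t = t_next
    if guard >= max_guard and t < t_out - 1.0e-9:
        # numerical corner: dump the remainder in the current voxel
        px = p0[0] + ux * t
        py = p0[1] + uy * t
        pz = p0[2] + uz * t
        ix, iy, iz = _voxel_of(px, py, pz, half_c, vs, nvox)
        grid[ix, iy, iz] += e_per_len * (t_out - t)
    return outside


@njit(cache=True, inline="always")
def _rotate_direction(dx, dy, dz, cos_t, phi):
    """Rotate the unit vector d by polar angle arccos(cos_t) about itself,
    with azimuth phi in the plane perpendicular to d."""
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    # orthonormal basis perpendicular to d
    if abs(dz) < 0.9:
        # u = z x d
        ux = -dy
        uy = dx
        uz = 0.0
    else:
        # u = x x d
        ux = 0.0
        uy = -dz
        uz = dy
    un = math.sqrt(ux * ux + uy * uy + uz * uz)
    ux /= un
    uy /= un
    uz /= un
    # v = d x u
    vx = dy * uz - dz * uy
    vy = dz * ux - dx * uz
    vz = dx * uy - dy * ux
    cp = math.cos(phi)
    sp = math.sin(phi)
    nx = cos_t * dx + sin_t * (cp * ux + sp * vx)
    ny = cos_t * dy + sin_t * (cp * uy + sp * vy)
    nz = cos_t * dz + sin_t * (cp * uz + sp * vz)
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, inline="always")
def _sample_screened_rutherford(alpha, u):
    """Inverse-CDF polar angle of the screened-Rutherford DCS."""
    cos_t = 1.0 - 2.0 * alpha * u / (1.0 + alpha - u)
    if cos_t < -1.0:
        cos_t = -1.0
    if cos_t > 1.0:
        cos_t = 1.0
    return cos_t


@njit(cache=True)
def trace_electron(
    x, y, z, dx, dy, dz, energy, weight, state,
    half_c, half_o, has_surr, vs, nvox,
    eloge_grid, log_s_tab, log_invmfp_tab, el_cum, el_alpha, n_elem_el,
    e_cutoff, step_cap, elastic_on,
    grid, accum,
):
    """Track one electron to escape or below the cutoff.

    Deposits weighted energy into ``grid`` (crystal voxels) and
    ``accum[ACC_OUTSIDE]`` / ``accum[ACC_ESCAPED_E]``; returns the updated RNG
    state and the (unweighted) escaped energy for bookkeeping.
    """
    escaped = 0.0
    p0 = np.empty(3)
    p1 = np.empty(3)
    guard = 0
    while True:
        guard += 1
        if guard > 2000000:
            # should never happen; conserve energy regardless
            ix, iy, iz = _voxel_of(x, y, z, half_c, vs, nvox)
            grid[ix, iy, iz] += weight * energy
            energy = 0.0
            break
        m = _medium(x, y, z, half_c, half_o, has_surr)
        if m == 2:
            accum[ACC_ESCAPED_E] += weight * energy
            escaped = energy
            break
        if energy <= e_cutoff + 1.0e-12:
            # remaining energy deposited in the current voxel
            if m == 0:
                ix, iy, iz = _voxel_of(x, y, z, half_c, vs, nvox)
                grid[ix, iy, iz] += weight * energy
            else:
                accum[ACC_OUTSIDE] += weight * energy
            break
        loge = math.log(energy)
        s_pow = _interp_loglog(eloge_grid, log_s_tab[m], loge)  # keV/um
        inv_mfp = _interp_loglog(eloge_grid, log_invmfp_tab[m], loge)
        state, u = _rand_open(state)
        if elastic_on:
            s_el = -math.log(u) / inv_mfp
        else:
            s_el = 1.0e30
        # distance to the boundary of the current region
        if m == 0:
            tmin, tmax = _ray_box(x, y, z, dx, dy, dz, half_c[0], half_c[1], half_c[2])
            d_bound = tmax
        else:
            tmin, tmax = _ray_box(x, y, z, dx, dy, dz, half_o[0], half_o[1], half_o[2])
            d_bound = tmax
            ci, co = _ray_box(x, y, z, dx, dy, dz, half_c[0], half_c[1], half_c[2])
            if co >= ci and ci > 0.0 and ci < d_bound:
                d_bound = ci
        if d_bound < 0.0:
            d_bound = 0.0
        d_bound += 1.0e-9  # land strictly in the next region
        d_stop = (energy - e_cutoff) / s_pow
        s = s_el
        hit_elastic = True
        if d_bound < s:
            s = d_bound
            hit_elastic = False
        if step_cap < s:
            s = step_cap
            hit_elastic = False
        if d_stop < s:
            s = d_stop
            hit_elastic = False
        de = s_pow * s
        if de > energy - e_cutoff:
            de = energy - e_cutoff
        p0[0] = x
        p0[1] = y
        p0[2] = z
        x += dx * s
        y += dy * s
        z += dz * s
        p1[0] = x
        p1[1] = y
        p1[2] = z
        if de > 0.0:
            if m == 0:
                out_share = deposit_segment(
                    grid, p0, p1, weight * de, half_c, vs, nvox
                )
                accum[ACC_OUTSIDE] += out_share
            else:
                accum[ACC_OUTSIDE] += weight * de
        energy -= de
        if hit_elastic:
            # element choice, then screened-Rutherford deflection
            gi = _grid_index(eloge_grid, loge)
            state, ue = _rand(state)
            ne = n_elem_el[m]
            j = ne - 1
            for k in range(ne):
                if ue <= el_cum[m, gi, k]:
                    j = k
                    break
            alpha = el_alpha[m, j] / energy if energy > 0.0 else 1.0
            state, ua = _rand(state)
            cos_t = _sample_screened_rutherford(alpha, ua)
            state, up = _rand(state)
            dx, dy, dz = _rotate_direction(dx, dy, dz, cos_t, 2.0 * math.pi * up)
    return state, escaped


@njit(cache=True, inline="always")
def _sample_dipole(px, py, pz, state):
    """Direction from the dipole density ~ cos^2(angle to polarization p)."""
    state, u = _rand(state)
    c = 2.0 * u - 1.0
    cos_psi = math.copysign(abs(c) ** (1.0 / 3.0), c)
    state, up = _rand(state)
    dx, dy, dz = _rotate_direction(px, py, pz, cos_psi, 2.0 * math.pi * up)
    return state, dx, dy, dz


@njit(cache=True, inline="always")
def _sample_isotropic(state):
    state, u = _rand(state)
    cos_t = 2.0 * u - 1.0
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    state, up = _rand(state)
    phi = 2.0 * math.pi * up
    return state, sin_t * math.cos(phi), sin_t * math.sin(phi), cos_t


@njit(cache=True, inline="always")
def _compton_kinematics(e_inc, theta_pho):
    """Recoil energy and recoil polar angle for a given photon deflection."""
    one_m_cos = 1.0 - math.cos(theta_pho)
    if one_m_cos <= 0.0:
        return 0.0, 0.5 * math.pi
    k = e_inc * one_m_cos / MC2
    e_comp = e_inc * k / (1.0 + k)
    tan_half = math.tan(0.5 * theta_pho)
    theta_comp = math.atan2(1.0, tan_half * (1.0 + e_inc / MC2))
    return e_comp, theta_comp


@njit(cache=True, inline="always")
def _sample_klein_nishina(e_inc, state):
    """Rejection sampling of the photon deflection from the Klein-Nishina
    angular distribution (optional mode)."""
    a = e_inc / MC2
    while True:
        state, u1 = _rand(state)
        x = 2.0 * u1 - 1.0  # cos(theta)
        eps = 1.0 / (1.0 + a * (1.0 - x))
        f = eps * eps * (eps + 1.0 / eps - (1.0 - x * x))
        state, u2 = _rand(state)
        if 2.0 * u2 <= f:
            return state, math.acos(x)


@njit(cache=True)
def run_photon_batch(
    org, dirv, pol, energy,
    mu_pc,          # (N, 2, 2): [photon, material, {photo, compton}] in 1/um
    pe_cum,         # (N, 2, M): cumulative per-element photoelectric fraction
    pe_kb, pe_kfrac, pe_yield, pe_kalpha, n_elem_pe,   # (2, M) / (2,)
    half_c, half_o, has_surr, vs, nvox,
    eloge_grid, log_s_tab, log_invmfp_tab, el_cum, el_alpha, n_elem_el,
    e_cutoff, step_cap,
    forced, dipole, klein_nishina, elastic_on,
    seed,
    grid_mc, grid_rd, accum,
):
    """Trace a batch of photons (already in the sample frame) and all the
    electrons they produce. With ``forced`` true every photon that crosses
    the sample is forced to interact once, with statistical weight equal to
    its analog interaction probability; otherwise the interaction distance is
    sampled per Eq.-(2)-style exponential transport."""
    n = org.shape[0]
    seg_t0 = np.empty(3)
    seg_t1 = np.empty(3)
    seg_m = np.empty(3, dtype=np.int64)
    for i in range(n):
        state = seed_stream(seed, i)
        ox, oy, oz = org[i, 0], org[i, 1], org[i, 2]
        dx, dy, dz = dirv[i, 0], dirv[i, 1], dirv[i, 2]
        e_ph = energy[i]
        # media segments along the ray
        n_seg = 0
        if has_surr:
            t0o, t1o = _ray_box(ox, oy, oz, dx, dy, dz, half_o[0], half_o[1], half_o[2])
            if t1o <= t0o:
                continue
            t0c, t1c = _ray_box(ox, oy, oz, dx, dy, dz, half_c[0], half_c[1], half_c[2])
            if t1c > t0c and t1c > t0o and t0c < t1o:
                if t0c > t0o:
                    seg_t0[n_seg] = t0o
                    seg_t1[n_seg] = t0c
                    seg_m[n_seg] = 1
                    n_seg += 1
                seg_t0[n_seg] = max(t0c, t0o)
                seg_t1[n_seg] = min(t1c, t1o)
                seg_m[n_seg] = 0
                n_seg += 1
                if t1o > t1c:
                    seg_t0[n_seg] = t1c
                    seg_t1[n_seg] = t1o
                    seg_m[n_seg] = 1
                    n_seg += 1
            else:
                seg_t0[n_seg] = t0o
                seg_t1[n_seg] = t1o
                seg_m[n_seg] = 1
                n_seg += 1
        else:
            t0c, t1c = _ray_box(ox, oy, oz, dx, dy, dz, half_c[0], half_c[1], half_c[2])
            if t1c <= t0c:
                continue
            seg_t0[n_seg] = t0c
            seg_t1[n_seg] = t1c
            seg_m[n_seg] = 0
            n_seg += 1
        # optical depth over the path (photo + Compton channels)
        tau_tot = 0.0
        for k in range(n_seg):
            m = seg_m[k]
            mu = mu_pc[i, m, 0] + mu_pc[i, m, 1]
            tau_tot += mu * (seg_t1[k] - seg_t0[k])
        if tau_tot <= 0.0:
            continue
        state, u = _rand_open(state)
        if forced:
            w = -math.expm1(-tau_tot)
            if w <= 0.0:
                continue
            tau_star = -math.log1p(-u * w)
        else:
            w = 1.0
            tau_star = -math.log(u)
            if tau_star > tau_tot:
                continue  # photon traverses without interacting
        # locate the interaction
        acc = 0.0
        m_int = seg_m[0]
        t_int = seg_t1[n_seg - 1]
        for k in range(n_seg):
            m = seg_m[k]
            mu = mu_pc[i, m, 0] + mu_pc[i, m, 1]
            seg_tau = mu * (seg_t1[k] - seg_t0[k])
            if acc + seg_tau >= tau_star or k == n_seg - 1:
                m_int = m
                t_int = seg_t0[k] + (tau_star - acc) / mu
                if t_int > seg_t1[k]:
                    t_int = seg_t1[k]
                break
            acc += seg_tau
        xi = ox + dx * t_int
        yi = oy + dy * t_int
        zi = oz + dz * t_int
        accum[ACC_N_EVENTS] += 1.0
        accum[ACC_SUM_W] += w
        mu_ph = mu_pc[i, m_int, 0]
        mu_cp = mu_pc[i, m_int, 1]
        state, uc = _rand(state)
        if uc < mu_ph / (mu_ph + mu_cp):
            # ---- photoelectric absorption
            accum[ACC_W_PHOTO] += w
            accum[ACC_ABSORBED] += w * e_ph
            if m_int == 0:
                ixv, iyv, izv = _voxel_of(xi, yi, zi, half_c, vs, nvox)
                grid_rd[ixv, iyv, izv] += w * e_ph
            state, ue = _rand(state)
            ne = n_elem_pe[m_int]
            j = ne - 1
            for k in range(ne):
                if ue <= pe_cum[i, m_int, k]:
                    j = k
                    break
            binding = 0.0
            local_dep = 0.0
            fluor = 0.0
            kb = pe_kb[m_int, j]
            if e_ph > kb:
                state, us = _rand(state)
                if us < pe_kfrac[m_int, j]:
                    binding = kb
                    state, ur = _rand(state)
                    if ur < pe_yield[m_int, j]:
                        fluor = pe_kalpha[m_int, j]
                        local_dep = kb - fluor
                        if local_dep < 0.0:
                            local_dep = 0.0
                    else:
                        local_dep = kb  # Auger + residual vacancy, local
            # L-and-higher ejection: binding treated as zero
            if fluor > 0.0:
                accum[ACC_ESCAPED_FLUOR] += w * fluor
            if local_dep > 0.0:
                if m_int == 0:
                    ixv, iyv, izv = _voxel_of(xi, yi, zi, half_c, vs, nvox)
                    grid_mc[ixv, iyv, izv] += w * local_dep
                else:
                    accum[ACC_OUTSIDE] += w * local_dep
            e_e = e_ph - binding
            if dipole:
                state, ex, ey, ez = _sample_dipole(
                    pol[i, 0], pol[i, 1], pol[i, 2], state
                )
            else:
                state, ex, ey, ez = _sample_isotropic(state)
            if e_e > e_cutoff:
                state, _ = trace_electron(
                    xi, yi, zi, ex, ey, ez, e_e, w, state,
                    half_c, half_o, has_surr, vs, nvox,
                    eloge_grid, log_s_tab, log_invmfp_tab,
                    el_cum, el_alpha, n_elem_el,
                    e_cutoff, step_cap, elastic_on,
                    grid_mc, accum,
                )
            elif e_e > 0.0:
                if m_int == 0:
                    ixv, iyv, izv = _voxel_of(xi, yi, zi, half_c, vs, nvox)
                    grid_mc[ixv, iyv, izv] += w * e_e
                else:
                    accum[ACC_OUTSIDE] += w * e_e
        else:
            # ---- Compton scattering
            accum[ACC_W_COMPTON] += w
            if klein_nishina:
                state, theta_pho = _sample_klein_nishina(e_ph, state)
            else:
                state, ut = _rand(state)
                theta_pho = ut * math.pi
            e_comp, theta_comp = _compton_kinematics(e_ph, theta_pho)
            accum[ACC_ABSORBED] += w * e_comp
            if m_int == 0:
                ixv, iyv, izv = _voxel_of(xi, yi, zi, half_c, vs, nvox)
                grid_rd[ixv, iyv, izv] += w * e_comp
            if e_comp <= 0.0:
                continue
            state, up = _rand(state)
            ex, ey, ez = _rotate_direction(
                dx, dy, dz, math.cos(theta_comp), 2.0 * math.pi * up
            )
            if e_comp > e_cutoff:
                state, _ = trace_electron(
                    xi, yi, zi, ex, ey, ez, e_comp, w, state,
                    half_c, half_o, has_surr, vs, nvox,
                    eloge_grid, log_s_tab, log_invmfp_tab,
                    el_cum, el_alpha, n_elem_el,
                    e_cutoff, step_cap, elastic_on,
                    grid_mc, accum,
                )
            else:
                if m_int == 0:
                    ixv, iyv, izv = _voxel_of(xi, yi, zi, half_c, vs, nvox)
                    grid_mc[ixv, iyv, izv] += w * e_comp
                else:
                    accum[ACC_OUTSIDE] += w * e_comp
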