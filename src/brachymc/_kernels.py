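"""Compiled (numba) transport and tally kernels.

These implement exactly the physics of :mod:`brachymc.transport` and the
estimators of :mod:`brachymc.tallies`, specialized for speed: scalar math,
flat arrays, and a single history loop per run.  The Python reference
implementations remain the readable specification; the two are
cross-checked statistically in the test suite.

Geometry is passed as scalars (all cm): core radius/half-length, gap and
capsule radii/half-lengths, cable end, phantom shape (0 cylinder about z,
1 sphere) and dimensions.  Materials are passed as log-log tables of
per-process linear attenuation coefficients on a common energy grid.
Region codes match :mod:`brachymc.geometry` (0 core .. 5 exterior).
"""

import math

import numpy as np
from numba import njit

R_E = 2.8179403262e-13
MEC2 = 0.51099895
CUTOFF = 0.010
EPS = 1e-9
INF = math.inf


# -- interpolation ---------------------------------------------------------

@njit(cache=True, inline="always")
def _interp_loglog(log_grid, log_vals, log_e):
    n = log_grid.shape[0]
    if log_e <= log_grid[0]:
        return math.exp(log_vals[0])
    if log_e >= log_grid[n - 1]:
        return math.exp(log_vals[n - 1])
    lo = 0
    hi = n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if log_grid[mid] <= log_e:
            lo = mid
        else:
            hi = mid
    f = (log_e - log_grid[lo]) / (log_grid[hi] - log_grid[lo])
    return math.exp(log_vals[lo] + f * (log_vals[hi] - log_vals[lo]))


# -- geometry --------------------------------------------------------------

@njit(cache=True, inline="always")
def _locate(x, y, z, rc, zc, rg, zg, rcap, zcap, zcab, shape, phr, phh):
    r2 = x * x + y * y
    az = abs(z)
    if r2 <= rc * rc and az <= zc:
        return 0
    if r2 <= rg * rg and az <= zg:
        return 1
    if r2 <= rcap * rcap and az <= zcap:
        return 2
    if r2 <= rcap * rcap and zcab <= z <= -zcap:
        return 3
    if shape == 0:
        if r2 <= phr * phr and az <= phh:
            return 4
    else:
        if r2 + z * z <= phr * phr:
            return 4
    return 5


@njit(cache=True, inline="always")
def _cyl_crossing(px, py, ux, uy, radius, best):
    a = ux * ux + uy * uy
    if a < 1e-30:
        return best
    b = px * ux + py * uy
    c = px * px + py * py - radius * radius
    disc = b * b - a * c
    if disc <= 0.0:
        return best
    root = math.sqrt(disc)
    t = (-b - root) / a
    if EPS < t < best:
        best = t
    t = (-b + root) / a
    if EPS < t < best:
        best = t
    return best


@njit(cache=True, inline="always")
def _plane_crossing(pz, uz, zp, best):
    if abs(uz) < 1e-30:
        return best
    t = (zp - pz) / uz
    if EPS < t < best:
        best = t
    return best


@njit(cache=True, inline="always")
def _min_crossing(px, py, pz, ux, uy, uz,
                  rc, zc, rg, zg, rcap, zcap, zcab, shape, phr, phh):
    best = INF
    best = _cyl_crossing(px, py, ux, uy, rc, best)
    best = _cyl_crossing(px, py, ux, uy, rg, best)
    best = _cyl_crossing(px, py, ux, uy, rcap, best)
    best = _plane_crossing(pz, uz, zc, best)
    best = _plane_crossing(pz, uz, -zc, best)
    best = _plane_crossing(pz, uz, zg, best)
    best = _plane_crossing(pz, uz, -zg, best)
    best = _plane_crossing(pz, uz, zcap, best)
    best = _plane_crossing(pz, uz, -zcap, best)
    best = _plane_crossing(pz, uz, zcab, best)
    if shape == 0:
        best = _cyl_crossing(px, py, ux, uy, phr, best)
        best = _plane_crossing(pz, uz, phh, best)
        best = _plane_crossing(pz, uz, -phh, best)
    else:
        b = px * ux + py * uy + pz * uz
        c = px * px + py * py + pz * pz - phr * phr
        disc = b * b - c
        if disc > 0.0:
            root = math.sqrt(disc)
            t = -b - root
            if EPS < t < best:
                best = t
            t = -b + root
            if EPS < t < best:
                best = t
    return best


# -- Compton ---------------------------------------------------------------

@njit(cache=True, inline="always")
def _sigma_kn(E):
    a = E / MEC2
    term = ((1 + a) / (a * a) * (2 * (1 + a) / (1 + 2 * a)
                                 - math.log(1 + 2 * a) / a)
            + math.log(1 + 2 * a) / (2 * a)
            - (1 + 3 * a) / ((1 + 2 * a) * (1 + 2 * a)))
    return 2 * math.pi * R_E * R_E * term


@njit(cache=True, inline="always")
def _kn_diff(E, cos_t):
    a = E / MEC2
    ratio = 1.0 / (1.0 + a * (1.0 - cos_t))
    return 0.5 * R_E * R_E * ratio * ratio * (
        ratio + 1.0 / ratio - (1.0 - cos_t * cos_t))


@njit(cache=True, inline="always")
def _sample_kn_cos(E):
    # Kahn's composition-rejection method
    a = E / MEC2
    lam = 1.0 + 2.0 * a
    x = 1.0
    while True:
        r1 = np.random.random()
        r2 = np.random.random()
        r3 = np.random.random()
        if r1 <= lam / (lam + 8.0):
            x = 1.0 + 2.0 * a * r2
            if r3 <= 4.0 * (1.0 / x - 1.0 / (x * x)):
                break
        else:
            x = lam / (1.0 + 2.0 * a * r2)
            cos_t = 1.0 - (x - 1.0) / a
            if r3 <= 0.5 * (cos_t * cos_t + 1.0 / x):
                break
    return 1.0 - (x - 1.0) / a


@njit(cache=True, inline="always")
def _rotate(ux, uy, uz, cos_t, phi):
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cp = math.cos(phi)
    sp = math.sin(phi)
    if abs(uz) < 0.999999:
        denom = math.sqrt(1.0 - uz * uz)
        vx = sin_t * (ux * uz * cp - uy * sp) / denom + ux * cos_t
        vy = sin_t * (uy * uz * cp + ux * sp) / denom + uy * cos_t
        vz = -sin_t * cp * denom + uz * cos_t
    else:
        sign = 1.0 if uz > 0 else -1.0
        vx = sin_t * cp
        vy = sign * sin_t * sp
        vz = sign * cos_t
    norm = math.sqrt(vx * vx + vy * vy + vz * vz)
    return vx / norm, vy / norm, vz / norm


# -- tally scoring ---------------------------------------------------------

@njit(cache=True)
def _score_segment(px, py, pz, ux, uy, uz, step, flu_weight, kerma_weight,
                   slab_zlo, slab_zhi, slab_ptr,
                   cell_rlo2, cell_rhi2, cell_inv_vol,
                   hist_fl, hist_k, touched_mask, touched_idx, n_touched,
                   spec, spec_bin):
    z_end = pz + step * uz
    zmin = min(pz, z_end)
    zmax = max(pz, z_end)
    a = ux * ux + uy * uy
    b = px * ux + py * uy
    c = px * px + py * py
    for s in range(slab_zlo.shape[0]):
        if slab_zhi[s] < zmin or slab_zlo[s] > zmax:
            continue
        if abs(uz) > 1e-30:
            ta = (slab_zlo[s] - pz) / uz
            tb = (slab_zhi[s] - pz) / uz
            t_in = min(ta, tb)
            t_out = max(ta, tb)
        else:
            t_in = 0.0
            t_out = step
        if t_in < 0.0:
            t_in = 0.0
        if t_out > step:
            t_out = step
        if t_out <= t_in:
            continue
        # radial range of the sub-segment, for quick cell rejection
        f_in = a * t_in * t_in + 2.0 * b * t_in + c
        f_out = a * t_out * t_out + 2.0 * b * t_out + c
        rmax2 = max(f_in, f_out)
        rmin2 = min(f_in, f_out)
        if a > 1e-30:
            t_star = -b / a
            if t_in < t_star < t_out:
                f_star = c - b * b / a
                if f_star < rmin2:
                    rmin2 = f_star
        for k in range(slab_ptr[s], slab_ptr[s + 1]):
            if cell_rhi2[k] < rmin2 or cell_rlo2[k] > rmax2:
                continue
            if a < 1e-30:
                if cell_rlo2[k] <= c <= cell_rhi2[k]:
                    length = t_out - t_in
                else:
                    continue
            else:
                disc = b * b - a * (c - cell_rhi2[k])
                if disc <= 0.0:
                    continue
                root = math.sqrt(disc)
                lo = (-b - root) / a
                hi = (-b + root) / a
                if lo < t_in:
                    lo = t_in
                if hi > t_out:
                    hi = t_out
                length = hi - lo
                if length <= 0.0:
                    continue
                if cell_rlo2[k] > 0.0:
                    disc2 = b * b - a * (c - cell_rlo2[k])
                    if disc2 > 0.0:
                        root2 = math.sqrt(disc2)
                        ilo = (-b - root2) / a
                        ihi = (-b + root2) / a
                        if ilo < lo:
                            ilo = lo
                        if ihi > hi:
                            ihi = hi
                        if ihi > ilo:
                            length -= ihi - ilo
                if length <= 0.0:
                    continue
            flu = flu_weight * length * cell_inv_vol[k]
            if touched_mask[k] == 0:
                touched_mask[k] = 1
                touched_idx[n_touched] = k
                n_touched += 1
            hist_fl[k] += flu
            hist_k[k] += flu * kerma_weight
            if spec_bin >= 0:
                spec[k, spec_bin] += flu
    return n_touched


@njit(cache=True, inline="always")
def _find_bin(edges, E):
    n = edges.shape[0]
    if n == 0 or E < edges[0] or E >= edges[n - 1]:
        return -1
    lo = 0
    hi = n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if edges[mid] <= E:
            lo = mid
        else:
            hi = mid
    return lo


# -- phantom (ring-tally) run ---------------------------------------------

@njit(cache=True)
def run_phantom(seed, n_hist,
                rc, zc, rg, zg, rcap, zcap, zcab, shape, phr, phh,
                region_mat, log_e, lmu_tr, lmu_pe, lmu_inc, lmu_coh,
                lmu_pair, use_coherent, use_pair,
                lmuen_e, lmuen_v,
                slab_zlo, slab_zhi, slab_ptr,
                cell_rlo2, cell_rhi2, cell_inv_vol, n_cells,
                spec_edges,
                e_line1, e_line2):
    """Analog transport with ring-cell track-length scoring.

    Returns per-cell history-by-history accumulators (fluence and kerma
    sums and sums of squares, per initial photon) plus the energy-binned
    fluence spectrum per cell (unnormalized) when ``spec_edges`` is
    non-empty.
    """
    np.random.seed(seed)
    n_bins = max(spec_edges.shape[0] - 1, 0)
    fl_s1 = np.zeros(n_cells)
    fl_s2 = np.zeros(n_cells)
    k_s1 = np.zeros(n_cells)
    k_s2 = np.zeros(n_cells)
    spec = np.zeros((n_cells, max(n_bins, 1)))
    hist_fl = np.zeros(n_cells)
    hist_k = np.zeros(n_cells)
    touched_mask = np.zeros(n_cells, dtype=np.uint8)
    touched_idx = np.zeros(n_cells, dtype=np.int64)

    # pair-secondary stack
    stack_pos = np.zeros((8, 3))
    stack_dir = np.zeros((8, 3))
    stack_e = np.zeros(8)

    for _ in range(n_hist):
        n_touched = 0
        # source emission: uniform in the active core, isotropic, 50/50 line
        r = rc * math.sqrt(np.random.random())
        phi = 2.0 * math.pi * np.random.random()
        px = r * math.cos(phi)
        py = r * math.sin(phi)
        pz = zc * (2.0 * np.random.random() - 1.0)
        mu_dir = 2.0 * np.random.random() - 1.0
        psi = 2.0 * math.pi * np.random.random()
        sin_d = math.sqrt(max(0.0, 1.0 - mu_dir * mu_dir))
        ux = sin_d * math.cos(psi)
        uy = sin_d * math.sin(psi)
        uz = mu_dir
        E = e_line1 if np.random.random() < 0.5 else e_line2

        n_stack = 1
        stack_pos[0, 0] = px
        stack_pos[0, 1] = py
        stack_pos[0, 2] = pz
        stack_dir[0, 0] = ux
        stack_dir[0, 1] = uy
        stack_dir[0, 2] = uz
        stack_e[0] = E

        while n_stack > 0:
            n_stack -= 1
            px = stack_pos[n_stack, 0]
            py = stack_pos[n_stack, 1]
            pz = stack_pos[n_stack, 2]
            ux = stack_dir[n_stack, 0]
            uy = stack_dir[n_stack, 1]
            uz = stack_dir[n_stack, 2]
            E = stack_e[n_stack]
            alive = True
            n_steps = 0
            while alive and n_steps < 100000:
                n_steps += 1
                region = _locate(px + EPS * ux, py + EPS * uy, pz + EPS * uz,
                                 rc, zc, rg, zg, rcap, zcap, zcab,
                                 shape, phr, phh)
                if region == 5:
                    break
                m = region_mat[region]
                log_e_val = math.log(E)
                if m >= 0:
                    mu = _interp_loglog(log_e, lmu_tr[m], log_e_val)
                else:
                    mu = 0.0
                t_bound = _min_crossing(px, py, pz, ux, uy, uz,
                                        rc, zc, rg, zg, rcap, zcap, zcab,
                                        shape, phr, phh)
                if mu > 0.0:
                    path = -math.log(1.0 - np.random.random()) / mu
                else:
                    path = INF
                step = min(path, t_bound)
                if step == INF:
                    break
                if region == 4:
                    muen = _interp_loglog(lmuen_e, lmuen_v, log_e_val)
                    sb = _find_bin(spec_edges, E) if n_bins > 0 else -1
                    n_touched = _score_segment(
                        px, py, pz, ux, uy, uz, step, 1.0, E * muen,
                        slab_zlo, slab_zhi, slab_ptr,
                        cell_rlo2, cell_rhi2, cell_inv_vol,
                        hist_fl, hist_k, touched_mask, touched_idx,
                        n_touched, spec, sb)
                px += step * ux
                py += step * uy
                pz += step * uz
                if path < t_bound:
                    # collision: select the process
                    p_pe = _interp_loglog(log_e, lmu_pe[m], log_e_val)
                    p_inc = _interp_loglog(log_e, lmu_inc[m], log_e_val)
                    p_coh = _interp_loglog(log_e, lmu_coh[m], log_e_val) \
                        if use_coherent else 0.0
                    p_pair = _interp_loglog(log_e, lmu_pair[m], log_e_val) \
                        if (use_pair and E > 1.022) else 0.0
                    xi = np.random.random() * (p_pe + p_inc + p_coh + p_pair)
                    if xi <= p_pe:
                        alive = False
                    elif xi <= p_pe + p_inc:
                        cos_t = _sample_kn_cos(E)
                        E = E / (1.0 + (E / MEC2) * (1.0 - cos_t))
                        if E < CUTOFF:
                            alive = False
                        else:
                            phi2 = 2.0 * math.pi * np.random.random()
                            ux, uy, uz = _rotate(ux, uy, uz, cos_t, phi2)
                    elif xi <= p_pe + p_inc + p_coh:
                        # Thomson-like angular law, energy unchanged
                        while True:
                            ct = 2.0 * np.random.random() - 1.0
                            if np.random.random() * 2.0 <= 1.0 + ct * ct:
                                break
                        phi2 = 2.0 * math.pi * np.random.random()
                        ux, uy, uz = _rotate(ux, uy, uz, ct, phi2)
                    else:
                        # pair: two back-to-back annihilation photons
                        mu2 = 2.0 * np.random.random() - 1.0
                        psi2 = 2.0 * math.pi * np.random.random()
                        s2 = math.sqrt(max(0.0, 1.0 - mu2 * mu2))
                        ux = s2 * math.cos(psi2)
                        uy = s2 * math.sin(psi2)
                        uz = mu2
                        E = MEC2
                        if n_stack < 8:
                            stack_pos[n_stack, 0] = px
                            stack_pos[n_stack, 1] = py
                            stack_pos[n_stack, 2] = pz
                            stack_dir[n_stack, 0] = -ux
                            stack_dir[n_stack, 1] = -uy
                            stack_dir[n_stack, 2] = -uz
                            stack_e[n_stack] = MEC2
                            n_stack += 1
        # end of history: fold the per-history scores into the accumulators
        for j in range(n_touched):
            k = touched_idx[j]
            fl_s1[k] += hist_fl[k]
            fl_s2[k] += hist_fl[k] * hist_fl[k]
            k_s1[k] += hist_k[k]
            k_s2[k] += hist_k[k] * hist_k[k]
            hist_fl[k] = 0.0
            hist_k[k] = 0.0
            touched_mask[k] = 0
    return fl_s1, fl_s2, k_s1, k_s2, spec


# -- air-kerma (next-event point detector) run -----------------------------

@njit(cache=True, inline="always")
def _optical_depth(px, py, pz, tx, ty, tz, dist, log_e_val,
                   rc, zc, rg, zg, rcap, zcap, zcab, shape, phr, phh,
                   region_mat, log_e, lmu_tr):
    tau = 0.0
    done = 0.0
    x = px
    y = py
    z = pz
    for _ in range(1000):
        region = _locate(x + EPS * tx, y + EPS * ty, z + EPS * tz,
                         rc, zc, rg, zg, rcap, zcap, zcab, shape, phr, phh)
        if region == 5:
            break
        t_bound = _min_crossing(x, y, z, tx, ty, tz,
                                rc, zc, rg, zg, rcap, zcap, zcab,
                                shape, phr, phh)
        step = min(t_bound, dist - done)
        m = region_mat[region]
        if m >= 0:
            tau += _interp_loglog(log_e, lmu_tr[m], log_e_val) * step
        done += step
        if done >= dist - 1e-9 or step == INF:
            break
        x += step * tx
        y += step * ty
        z += step * tz
    return tau


@njit(cache=True, inline="always")
def _detector_contribution(px, py, pz, det_y, pdf, E,
                           rc, zc, rg, zg, rcap, zcap, zcab, shape, phr, phh,
                           region_mat, log_e, lmu_tr, lmuen_e, lmuen_v):
    """Kerma contribution (MeV/g per photon) of an event with emission pdf
    ``pdf`` per steradian at energy E towards the detector at (0, det_y, 0)."""
    vx = -px
    vy = det_y - py
    vz = -pz
    d = math.sqrt(vx * vx + vy * vy + vz * vz)
    tx = vx / d
    ty = vy / d
    tz = vz / d
    log_e_val = math.log(E)
    tau = _optical_depth(px, py, pz, tx, ty, tz, d, log_e_val,
                         rc, zc, rg, zg, rcap, zcap, zcab, shape, phr, phh,
                         region_mat, log_e, lmu_tr)
    flu = pdf * math.exp(-tau) / (d * d)
    muen = _interp_loglog(lmuen_e, lmuen_v, log_e_val)
    return flu * E * muen


@njit(cache=True)
def run_airkerma(seed, n_hist,
                 rc, zc, rg, zg, rcap, zcap, zcab, shape, phr, phh,
                 region_mat, log_e, lmu_tr, lmu_pe, lmu_inc, lmu_coh,
                 lmu_pair, use_coherent, use_pair,
                 lmuen_e, lmuen_v, det_y,
                 e_line1, e_line2):
    """Analog transport with next-event air-kerma estimation at transverse
    point detectors.  Returns per-detector history-by-history sums and sums
    of squares of the kerma per initial photon (MeV/g)."""
    np.random.seed(seed)
    n_det = det_y.shape[0]
    s1 = np.zeros(n_det)
    s2 = np.zeros(n_det)
    hist = np.zeros(n_det)
    stack_pos = np.zeros((8, 3))
    stack_dir = np.zeros((8, 3))
    stack_e = np.zeros(8)
    inv4pi = 1.0 / (4.0 * math.pi)

    for _ in range(n_hist):
        for j in range(n_det):
            hist[j] = 0.0
        r = rc * math.sqrt(np.random.random())
        phi = 2.0 * math.pi * np.random.random()
        px = r * math.cos(phi)
        py = r * math.sin(phi)
        pz = zc * (2.0 * np.random.random() - 1.0)
        mu_dir = 2.0 * np.random.random() - 1.0
        psi = 2.0 * math.pi * np.random.random()
        sin_d = math.sqrt(max(0.0, 1.0 - mu_dir * mu_dir))
        ux = sin_d * math.cos(psi)
        uy = sin_d * math.sin(psi)
        uz = mu_dir
        E = e_line1 if np.random.random() < 0.5 else e_line2

        # next-event contribution of the source emission itself
        for j in range(n_det):
            hist[j] += _detector_contribution(
                px, py, pz, det_y[j], inv4pi, E,
                rc, zc, rg, zg, rcap, zcap, zcab, shape, phr, phh,
                region_mat, log_e, lmu_tr, lmuen_e, lmuen_v)

        n_stack = 1
        stack_pos[0, 0] = px
        stack_pos[0, 1] = py
        stack_pos[0, 2] = pz
        stack_dir[0, 0] = ux
        stack_dir[0, 1] = uy
        stack_dir[0, 2] = uz
        stack_e[0] = E

        while n_stack > 0:
            n_stack -= 1
            px = stack_pos[n_stack, 0]
            py = stack_pos[n_stack, 1]
            pz = stack_pos[n_stack, 2]
            ux = stack_dir[n_stack, 0]
            uy = stack_dir[n_stack, 1]
            uz = stack_dir[n_stack, 2]
            E = stack_e[n_stack]
            alive = True
            n_steps = 0
            while alive and n_steps < 100000:
                n_steps += 1
                region = _locate(px + EPS * ux, py + EPS * uy, pz + EPS * uz,
                                 rc, zc, rg, zg, rcap, zcap, zcab,
                                 shape, phr, phh)
                if region == 5:
                    break
                m = region_mat[region]
                log_e_val = math.log(E)
                if m >= 0:
                    mu = _interp_loglog(log_e, lmu_tr[m], log_e_val)
                else:
                    mu = 0.0
                t_bound = _min_crossing(px, py, pz, ux, uy, uz,
                                        rc, zc, rg, zg, rcap, zcap, zcab,
                                        shape, phr, phh)
                if mu > 0.0:
                    path = -math.log(1.0 - np.random.random()) / mu
                else:
                    path = INF
                step = min(path, t_bound)
                if step == INF:
                    break
                px += step * ux
                py += step * uy
                pz += step * uz
                if path < t_bound:
                    p_pe = _interp_loglog(log_e, lmu_pe[m], log_e_val)
                    p_inc = _interp_loglog(log_e, lmu_inc[m], log_e_val)
                    p_coh = _interp_loglog(log_e, lmu_coh[m], log_e_val) \
                        if use_coherent else 0.0
                    p_pair = _interp_loglog(log_e, lmu_pair[m], log_e_val) \
                        if (use_pair and E > 1.022) else 0.0
                    p_tot = p_pe + p_inc + p_coh + p_pair
                    # expected next-event contribution of this collision
                    sig_kn = _sigma_kn(E)
                    for j in range(n_det):
                        vx = -px
                        vy = det_y[j] - py
                        vz = -pz
                        d = math.sqrt(vx * vx + vy * vy + vz * vz)
                        cos_det = (ux * vx + uy * vy + uz * vz) / d
                        e_det = E / (1.0 + (E / MEC2) * (1.0 - cos_det))
                        pdf = _kn_diff(E, cos_det) / sig_kn
                        hist[j] += (p_inc / p_tot) * _detector_contribution(
                            px, py, pz, det_y[j], pdf, e_det,
                            rc, zc, rg, zg, rcap, zcap, zcab, shape, phr,
                            phh, region_mat, log_e, lmu_tr, lmuen_e, lmuen_v)
                        if p_pair > 0.0:
                            hist[j] += (p_pair / p_tot) * 2.0 * \
                                _detector_contribution(
                                    px, py, pz, det_y[j], inv4pi, MEC2,
                                    rc, zc, rg, zg, rcap, zcap, zcab, shape,
                                    phr, phh, region_mat, log_e, lmu_tr,
                                    lmuen_e, lmuen_v)
                    xi = np.random.random() * p_tot
                    if xi <= p_pe:
                        alive = False
                    elif xi <= p_pe + p_inc:
                        cos_t = _sample_kn_cos(E)
                        E = E / (1.0 + (E / MEC2) * (1.0 - cos_t))
                        if E < CUTOFF:
                            alive = False
                        else:
                            phi2 = 2.0 * math.pi * np.random.random()
                            ux, uy, uz = _rotate(ux, uy, uz, cos_t, phi2)
                    elif xi <= p_pe + p_inc + p_coh:
                        while True:
                            ct = 2.0 * np.random.random() - 1.0
                            if np.random.random() * 2.0 <= 1.0 + ct * ct:
                                break
                        phi2 = 2.0 * math.pi * np.random.random()
                        ux, uy, uz = _rotate(ux, uy, uz, ct, phi2)
                    else:
                        mu2 = 2.0 * np.random.random() - 1.0
                        psi2 = 2.0 * math.pi * np.random.random()
                        sn = math.sqrt(max(0.0, 1.0 - mu2 * mu2))
                        ux = sn * math.cos(psi2)
                        uy = sn * math.sin(psi2)
                        uz = mu2
                        E = MEC2
                        if n_stack < 8:
                            stack_pos[n_stack, 0] = px
                            stack_pos[n_stack, 1] = py
                            stack_pos[n_stack, 2] = pz
                            stack_dir[n_stack, 0] = -ux
                            stack_dir[n_stack, 1] = -uy
                            stack_dir[n_stack, 2] = -uz
                            stack_e[n_stack] = MEC2
                            n_stack += 1
        for j in range(n_det):
            s1[j] += hist[j]
            s2[j] += hist[j] * hist[j]
    return s1, s2
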