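"""Numba kernels: chain building, coarse energies, and the MC sweep loop.

Kernel-level angles are radians and coordinates Angstrom.  The Python
API (geometry, sampler modules) wraps these with degree-based signatures.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Fixed internal geometry of the coarse backbone (Angstrom / radians).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANG_N_CA_C = np.deg2rad(111.2)
ANG_CA_C_N = np.deg2rad(116.2)
ANG_C_N_CA = np.deg2rad(121.7)
ANG_CA_C_O = np.deg2rad(120.8)
SC_TILT = np.deg2rad(54.25)  # out-of-plane tilt of the CA->SC direction

R_GAS = 0.0083144626  # kJ mol^-1 K^-1


@njit(cache=True)
def wrap_angle(x):
    """Wrap an angle (radians) into [-pi, pi)."""
    return (x + np.pi) % (2.0 * np.pi) - np.pi


@njit(cache=True)
def _place(ax, ay, az, bx, by, bz, cx, cy, cz, bond, theta, chi):
    """NeRF placement: return d with |c-d| = bond, angle(b,c,d) = theta,
    dihedral(a,b,c,d) = chi."""
    bcx = cx - bx
    bcy = cy - by
    bcz = cz - bz
    nb = np.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx /= nb
    bcy /= nb
    bcz /= nb
    abx = bx - ax
    aby = by - ay
    abz = bz - az
    # n = normalize(cross(ab, bc))
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    nn = np.sqrt(nx * nx + ny * ny + nz * nz)
    nx /= nn
    ny /= nn
    nz /= nn
    # m = cross(n, bc)
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    d0 = -bond * np.cos(theta)
    st = bond * np.sin(theta)
    d1 = st * np.cos(chi)
    d2 = -st * np.sin(chi)
    return (cx + bcx * d0 + mx * d1 + nx * d2,
            cy + bcy * d0 + my * d1 + ny * d2,
            cz + bcz * d0 + mz * d1 + nz * d2)


@njit(cache=True)
def dihedral(p, i0, i1, i2, i3):
    """Signed dihedral (radians, IUPAC convention) of four rows of p."""
    b0x = p[i1, 0] - p[i0, 0]
    b0y = p[i1, 1] - p[i0, 1]
    b0z = p[i1, 2] - p[i0, 2]
    b1x = p[i2, 0] - p[i1, 0]
    b1y = p[i2, 1] - p[i1, 1]
    b1z = p[i2, 2] - p[i1, 2]
    b2x = p[i3, 0] - p[i2, 0]
    b2y = p[i3, 1] - p[i2, 1]
    b2z = p[i3, 2] - p[i2, 2]
    # n1 = b0 x b1 ; n2 = b1 x b2
    n1x = b0y * b1z - b0z * b1y
    n1y = b0z * b1x - b0x * b1z
    n1z = b0x * b1y - b0y * b1x
    n2x = b1y * b2z - b1z * b2y
    n2y = b1z * b2x - b1x * b2z
    n2z = b1x * b2y - b1y * b2x
    nb1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
    # m = n1 x (b1 / |b1|)
    mx = (n1y * b1z - n1z * b1y) / nb1
    my = (n1z * b1x - n1x * b1z) / nb1
    mz = (n1x * b1y - n1y * b1x) / nb1
    x = n1x * n2x + n1y * n2y + n1z * n2z
    y = mx * n2x + my * n2y + mz * n2z
    return np.arctan2(y, x)


@njit(cache=True)
def build_chain_from(phi, psi, sc_dist, coords, start):
    """Rebuild coarse coordinates from residue ``start`` onward, assuming
    coords of residues < start are valid for the current torsions.

    phi, psi : (n,) radians.  phi[0] does not affect any coordinate (no
    preceding carbonyl carbon exists).  psi[i] positions both O_i and, for
    i < n-1, the next residue.  coords : (n, 5, 3), atom order
    N, CA, C, O, SC.
    """
    n = phi.shape[0]
    if start == 0:
        # first residue: N at origin, CA on +x, C in the xy plane
        coords[0, 0, 0] = 0.0
        coords[0, 0, 1] = 0.0
        coords[0, 0, 2] = 0.0
        coords[0, 1, 0] = BOND_N_CA
        coords[0, 1, 1] = 0.0
        coords[0, 1, 2] = 0.0
        coords[0, 2, 0] = BOND_N_CA + BOND_CA_C * np.cos(np.pi - ANG_N_CA_C)
        coords[0, 2, 1] = BOND_CA_C * np.sin(np.pi - ANG_N_CA_C)
        coords[0, 2, 2] = 0.0
    for i in range(start, n):
        if i > 0:
            # N_i from psi_{i-1}
            x, y, z = _place(
                coords[i - 1, 0, 0], coords[i - 1, 0, 1], coords[i - 1, 0, 2],
                coords[i - 1, 1, 0], coords[i - 1, 1, 1], coords[i - 1, 1, 2],
                coords[i - 1, 2, 0], coords[i - 1, 2, 1], coords[i - 1, 2, 2],
                BOND_C_N, ANG_CA_C_N, psi[i - 1])
            coords[i, 0, 0] = x
            coords[i, 0, 1] = y
            coords[i, 0, 2] = z
            # CA_i, omega fixed trans
            x, y, z = _place(
                coords[i - 1, 1, 0], coords[i - 1, 1, 1], coords[i - 1, 1, 2],
                coords[i - 1, 2, 0], coords[i - 1, 2, 1], coords[i - 1, 2, 2],
                coords[i, 0, 0], coords[i, 0, 1], coords[i, 0, 2],
                BOND_N_CA, ANG_C_N_CA, np.pi)
            coords[i, 1, 0] = x
            coords[i, 1, 1] = y
            coords[i, 1, 2] = z
            # C_i from phi_i
            x, y, z = _place(
                coords[i - 1, 2, 0], coords[i - 1, 2, 1], coords[i - 1, 2, 2],
                coords[i, 0, 0], coords[i, 0, 1], coords[i, 0, 2],
                coords[i, 1, 0], coords[i, 1, 1], coords[i, 1, 2],
                BOND_CA_C, ANG_N_CA_C, phi[i])
            coords[i, 2, 0] = x
            coords[i, 2, 1] = y
            coords[i, 2, 2] = z
        # O_i anti to the next N: dihedral N-CA-C-O = psi_i + pi
        x, y, z = _place(
            coords[i, 0, 0], coords[i, 0, 1], coords[i, 0, 2],
            coords[i, 1, 0], coords[i, 1, 1], coords[i, 1, 2],
            coords[i, 2, 0], coords[i, 2, 1], coords[i, 2, 2],
            BOND_C_O, ANG_CA_C_O, psi[i] + np.pi)
        coords[i, 3, 0] = x
        coords[i, 3, 1] = y
        coords[i, 3, 2] = z
        # SC centroid: rigid-frame construction off CA
        if sc_dist[i] > 0.0:
            ux = coords[i, 0, 0] - coords[i, 1, 0]
            uy = coords[i, 0, 1] - coords[i, 1, 1]
            uz = coords[i, 0, 2] - coords[i, 1, 2]
            nu = np.sqrt(ux * ux + uy * uy + uz * uz)
            ux /= nu
            uy /= nu
            uz /= nu
            vx = coords[i, 2, 0] - coords[i, 1, 0]
            vy = coords[i, 2, 1] - coords[i, 1, 1]
            vz = coords[i, 2, 2] - coords[i, 1, 2]
            nv = np.sqrt(vx * vx + vy * vy + vz * vz)
            vx /= nv
            vy /= nv
            vz /= nv
            bx = -(ux + vx)
            by = -(uy + vy)
            bz = -(uz + vz)
            nb = np.sqrt(bx * bx + by * by + bz * bz)
            bx /= nb
            by /= nb
            bz /= nb
            px = uy * vz - uz * vy
            py = uz * vx - ux * vz
            pz = ux * vy - uy * vx
            npp = np.sqrt(px * px + py * py + pz * pz)
            px /= npp
            py /= npp
            pz /= npp
            ct = np.cos(SC_TILT)
            st = np.sin(SC_TILT)
            dx = bx * ct + px * st
            dy = by * ct + py * st
            dz = bz * ct + pz * st
            coords[i, 4, 0] = coords[i, 1, 0] + sc_dist[i] * dx
            coords[i, 4, 1] = coords[i, 1, 1] + sc_dist[i] * dy
            coords[i, 4, 2] = coords[i, 1, 2] + sc_dist[i] * dz
        else:
            coords[i, 4, 0] = coords[i, 1, 0]
            coords[i, 4, 1] = coords[i, 1, 1]
            coords[i, 4, 2] = coords[i, 1, 2]


@njit(cache=True)
def build_chain(phi, psi, sc_dist, coords):
    """Build coarse coordinates from torsions (full chain)."""
    build_chain_from(phi, psi, sc_dist, coords, 0)


@njit(cache=True)
def extract_torsions(coords, phi_out, psi_out):
    """Extract (phi, psi) in radians from coarse coordinates.

    phi[0] is reported as NaN (geometrically undefined: nothing depends on
    it).  psi of every residue, including the last, is recovered from the
    carbonyl O placement (O is anti to psi).
    """
    n = coords.shape[0]
    flat = coords.reshape(n * 5, 3)
    phi_out[0] = np.nan
    for i in range(n):
        if i > 0:
            # C_{i-1}, N_i, CA_i, C_i
            phi_out[i] = dihedral(flat, (i - 1) * 5 + 2, i * 5 + 0,
                                  i * 5 + 1, i * 5 + 2)
        # N_i, CA_i, C_i, O_i  ->  psi + pi
        psi_out[i] = wrap_angle(
            dihedral(flat, i * 5 + 0, i * 5 + 1, i * 5 + 2, i * 5 + 3)
            - np.pi)


# ---------------------------------------------------------------------------
# Coarse energies
# ---------------------------------------------------------------------------

@njit(cache=True)
def gaussian_basin(phi, psi, c_phi, c_psi, s):
    """exp(-(dphi^2 + dpsi^2) / (2 s^2)) with circular differences."""
    dphi = wrap_angle(phi - c_phi)
    dpsi = wrap_angle(psi - c_psi)
    return np.exp(-(dphi * dphi + dpsi * dpsi) / (2.0 * s * s))


@njit(cache=True)
def torsion_energy_residue(phi, psi, h_depth, h_sigma, e_depth, e_sigma,
                           hc_phi, hc_psi, ec_phi, ec_psi):
    """Per-residue torsion propensity: two attractive Gaussian basins."""
    return (-h_depth * gaussian_basin(phi, psi, hc_phi, hc_psi, h_sigma)
            - e_depth * gaussian_basin(phi, psi, ec_phi, ec_psi, e_sigma))


@njit(cache=True)
def excluded_volume(sc, d0, k):
    """Soft-sphere repulsion between sidechain centroids, pairs |i-j| >= 2.

    E = k * sum max(0, d0 - r)^2 ; finite (clamped quadratic) even at r=0.
    """
    n = sc.shape[0]
    d0sq = d0 * d0
    e = 0.0
    for i in range(n - 2):
        for j in range(i + 2, n):
            dx = sc[i, 0] - sc[j, 0]
            dy = sc[i, 1] - sc[j, 1]
            dz = sc[i, 2] - sc[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < d0sq:
                ov = d0 - np.sqrt(r2)
                e += k * ov * ov
    return e


@njit(cache=True)
def ev_sc_view(coords, d0, k):
    """Excluded volume from a (n, 5, 3) coordinate array (SC column)."""
    n = coords.shape[0]
    d0sq = d0 * d0
    e = 0.0
    for i in range(n - 2):
        for j in range(i + 2, n):
            dx = coords[i, 4, 0] - coords[j, 4, 0]
            dy = coords[i, 4, 1] - coords[j, 4, 1]
            dz = coords[i, 4, 2] - coords[j, 4, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < d0sq:
                ov = d0 - np.sqrt(r2)
                e += k * ov * ov
    return e


@njit(cache=True)
def restraint_energy_from_wsum(wsum, m_replicas, nuc_res, nuc_dh, nuc_target,
                               nuc_eps, nuc_coil, k_rest):
    """Flat-bottom harmonic on the replica-mean predicted shifts.

    Predicted shift of nucleus j in replica m is coil_j + w[m, res_j]*dh_j;
    wsum holds sum_m w[m, i].
    """
    e = 0.0
    for j in range(nuc_res.shape[0]):
        mean = nuc_coil[j] + (wsum[nuc_res[j]] / m_replicas) * nuc_dh[j]
        d = abs(mean - nuc_target[j]) - nuc_eps[j]
        if d > 0.0:
            e += d * d
    return k_rest * e


# ---------------------------------------------------------------------------
# Metropolis Monte Carlo in torsion space, M replicas coupled through
# the replica-averaged chemical-shift restraint.
# ---------------------------------------------------------------------------

@njit(cache=True)
def mc_run(phi, psi, sc_dist,
           h_depth, h_sigma, e_depth, e_sigma,
           hc_phi, hc_psi, ec_phi, ec_psi, w_tors,
           coop_j, coop_sigma,
           ev_d0, ev_k, w_ev,
           pw_sigma, pw_cphi, pw_cpsi,
           nuc_res, nuc_dh, nuc_target, nuc_eps, nuc_coil, k_rest,
           temps, collect, adapt_until, width0, seed):
    """Run the replica MC.  phi/psi (M, n) in radians are evolved in place.

    temps : (S,) temperature per sweep; collect : (S,) uint8 flags.  One
    sweep proposes one single-angle Gaussian move per residue per replica,
    accepted by Metropolis on the physical energy of that replica plus the
    shared replica-averaged restraint energy.  The physical energy adds a
    nearest-neighbour helix-cooperativity term -coop_j * sum h_i h_{i+1}
    (h = helical basin weight of width coop_sigma), the coarse analogue of
    the cooperative hydrogen-bond network of a real helix.  Move widths adapt toward a
    30-50% acceptance rate during the first ``adapt_until`` sweeps only,
    so the collected portion of the run uses fixed widths.

    Returns (frames_phi, frames_psi, e_phys, e_rest_trace, acc_trace,
    widths) with frames_(phi|psi) shaped (n_collect, M, n).
    """
    np.random.seed(seed)
    M, n = phi.shape
    S = temps.shape[0]
    n_nuc = nuc_res.shape[0]
    use_rest = n_nuc > 0 and k_rest > 0.0
    use_ev = w_ev != 0.0 and ev_k != 0.0

    coords = np.empty((M, n, 5, 3))
    backup = np.empty((n, 5, 3))
    # caches
    e_tors_res = np.empty((M, n))
    e_ev = np.zeros(M)
    w = np.zeros((M, n))
    hcoop = np.zeros((M, n))
    for m in range(M):
        build_chain(phi[m], psi[m], sc_dist, coords[m])
        if use_ev:
            e_ev[m] = ev_sc_view(coords[m], ev_d0, ev_k)
        for i in range(n):
            e_tors_res[m, i] = torsion_energy_residue(
                phi[m, i], psi[m, i], h_depth, h_sigma, e_depth, e_sigma,
                hc_phi, hc_psi, ec_phi, ec_psi)
            w[m, i] = gaussian_basin(phi[m, i], psi[m, i], pw_cphi, pw_cpsi,
                                     pw_sigma)
            hcoop[m, i] = gaussian_basin(phi[m, i], psi[m, i], hc_phi,
                                         hc_psi, coop_sigma)
    wsum = np.zeros(n)
    for i in range(n):
        for m in range(M):
            wsum[i] += w[m, i]
    e_rest = 0.0
    if use_rest:
        e_rest = restraint_energy_from_wsum(
            wsum, M, nuc_res, nuc_dh, nuc_target, nuc_eps, nuc_coil, k_rest)

    n_collect = 0
    for s in range(S):
        if collect[s]:
            n_collect += 1
    frames_phi = np.empty((n_collect, M, n))
    frames_psi = np.empty((n_collect, M, n))
    e_phys_out = np.empty((n_collect, M))
    e_rest_out = np.empty(n_collect)
    acc_trace = np.empty(S)
    widths = np.full(M, width0)
    acc_window = np.zeros(M)
    win_len = 50

    ci = 0
    for s in range(S):
        beta = 1.0 / (R_GAS * temps[s])
        n_acc_sweep = 0
        for m in range(M):
            for i in range(n):
                move_phi = np.random.random() < 0.5
                if move_phi:
                    old = phi[m, i]
                else:
                    old = psi[m, i]
                new = wrap_angle(old + np.random.normal() * widths[m])
                if move_phi:
                    phi[m, i] = new
                else:
                    psi[m, i] = new
                ut_new = torsion_energy_residue(
                    phi[m, i], psi[m, i], h_depth, h_sigma, e_depth, e_sigma,
                    hc_phi, hc_psi, ec_phi, ec_psi)
                de = w_tors * (ut_new - e_tors_res[m, i])
                h_new = hcoop[m, i]
                if coop_j != 0.0:
                    h_new = gaussian_basin(phi[m, i], psi[m, i], hc_phi,
                                           hc_psi, coop_sigma)
                    dh = h_new - hcoop[m, i]
                    neigh = 0.0
                    if i > 0:
                        neigh += hcoop[m, i - 1]
                    if i < n - 1:
                        neigh += hcoop[m, i + 1]
                    de += -coop_j * dh * neigh * w_tors
                ev_new = e_ev[m]
                if use_ev:
                    # only residues >= i move; back up and rebuild in place
                    backup[i:] = coords[m, i:]
                    build_chain_from(phi[m], psi[m], sc_dist, coords[m], i)
                    ev_new = ev_sc_view(coords[m], ev_d0, ev_k)
                    de += w_ev * (ev_new - e_ev[m])
                w_new = w[m, i]
                e_rest_new = e_rest
                wsum_i_old = wsum[i]
                if use_rest:
                    w_new = gaussian_basin(phi[m, i], psi[m, i], pw_cphi,
                                           pw_cpsi, pw_sigma)
                    wsum[i] = wsum_i_old - w[m, i] + w_new
                    e_rest_new = restraint_energy_from_wsum(
                        wsum, M, nuc_res, nuc_dh, nuc_target, nuc_eps,
                        nuc_coil, k_rest)
                    de += e_rest_new - e_rest
                accept = de <= 0.0 or np.random.random() < np.exp(-de * beta)
                if accept:
                    e_tors_res[m, i] = ut_new
                    e_ev[m] = ev_new
                    hcoop[m, i] = h_new
                    if use_rest:
                        w[m, i] = w_new
                        e_rest = e_rest_new
                    acc_window[m] += 1.0
                    n_acc_sweep += 1
                else:
                    if move_phi:
                        phi[m, i] = old
                    else:
                        psi[m, i] = old
                    if use_ev:
                        coords[m, i:] = backup[i:]
                    if use_rest:
                        wsum[i] = wsum_i_old
        acc_trace[s] = n_acc_sweep / (M * n)
        # width adaptation (burn-in only), deterministic rule
        if s < adapt_until and (s + 1) % win_len == 0:
            for m in range(M):
                rate = acc_window[m] / (win_len * n)
                if rate < 0.30:
                    widths[m] *= 0.9
                elif rate > 0.50:
                    widths[m] *= 1.1
                if widths[m] < np.deg2rad(2.0):
                    widths[m] = np.deg2rad(2.0)
                elif widths[m] > np.deg2rad(60.0):
                    widths[m] = np.deg2rad(60.0)
                acc_window[m] = 0.0
        elif (s + 1) % win_len == 0:
            for m in range(M):
                acc_window[m] = 0.0
        if collect[s]:
            for m in range(M):
                frames_phi[ci, m] = phi[m]
                frames_psi[ci, m] = psi[m]
                tot = 0.0
                for i in range(n):
                    tot += e_tors_res[m, i]
                coop = 0.0
                for i in range(n - 1):
                    coop += hcoop[m, i] * hcoop[m, i + 1]
                e_phys_out[ci, m] = (w_tors * (tot - coop_j * coop)
                                     + w_ev * e_ev[m])
            e_rest_out[ci] = e_rest
            ci += 1
    return frames_phi, frames_psi, e_phys_out, e_rest_out, acc_trace, widths
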