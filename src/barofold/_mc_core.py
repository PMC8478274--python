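"""Compiled Monte Carlo kernels.

Everything here operates on plain arrays so numba can compile it:
``coords`` is the (N, 3) bead array, ``dnat`` the dense (N, N) native
distance matrix (-1.0 marks non-contact pairs), ``a`` the well
half-width, ``sigma`` the hard-sphere diameter and ``eps`` the well
depth.  The RNG is an explicit xorshift128+ stream seeded through
splitmix64, so every trajectory is a pure function of its seed.

Sign conventions match the model module: contact wells are negative,
excluded-volume overlaps return +inf and are never accepted.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = np.inf

# ---------------------------------------------------------------- RNG


@njit(cache=True)
def seed_state(seed):
    """Initialise an xorshift128+ state from a 64-bit seed (splitmix64)."""
    state = np.empty(2, dtype=np.uint64)
    x = np.uint64(seed)
    for i in range(2):
        x = x + np.uint64(0x9E3779B97F4A7C15)
        z = x
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        state[i] = z ^ (z >> np.uint64(31))
    if state[0] == np.uint64(0) and state[1] == np.uint64(0):
        state[0] = np.uint64(1)
    return state


@njit(cache=True, inline="always")
def _next_u64(state):
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= s1 << np.uint64(23)
    s1 ^= s1 >> np.uint64(17)
    s1 ^= s0
    s1 ^= s0 >> np.uint64(26)
    state[1] = s1
    return s0 + s1


@njit(cache=True, inline="always")
def rand_u01(state):
    """Uniform double in [0, 1)."""
    return float(_next_u64(state) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def _rand_unit_vector(state):
    while True:
        x = 2.0 * rand_u01(state) - 1.0
        y = 2.0 * rand_u01(state) - 1.0
        z = 2.0 * rand_u01(state) - 1.0
        n2 = x * x + y * y + z * z
        if 1e-12 < n2 <= 1.0:
            n = np.sqrt(n2)
            return x / n, y / n, z / n


# ------------------------------------------------------------- energy


@njit(cache=True)
def total_energy_arr(coords, dnat, a, sigma, eps):
    """Full reduced energy; +inf on excluded-volume overlap."""
    n = coords.shape[0]
    e = 0.0
    for i in range(n - 1):
        for j in range(i + 2, n):
            dx = coords[j, 0] - coords[i, 0]
            dy = coords[j, 1] - coords[i, 1]
            dz = coords[j, 2] - coords[i, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            dn = dnat[i, j]
            if dn > 0.0:
                if r < sigma and r < dn - a:
                    return INF
                x = r - dn
                if -a <= x <= a:
                    e += eps * ((x / a) * (x / a) - 1.0)
            elif r < sigma:
                return INF
    return e


@njit(cache=True)
def _bead_energy(coords, i, px, py, pz, dnat, a, sigma, eps):
    """Interaction energy of bead i placed at (px, py, pz); +inf on overlap."""
    n = coords.shape[0]
    e = 0.0
    for j in range(n):
        if j == i or j == i - 1 or j == i + 1:
            continue
        dx = coords[j, 0] - px
        dy = coords[j, 1] - py
        dz = coords[j, 2] - pz
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dn = dnat[i, j]
        if dn > 0.0:
            if r < sigma and r < dn - a:
                return INF
            x = r - dn
            if -a <= x <= a:
                e += eps * ((x / a) * (x / a) - 1.0)
        elif r < sigma:
            return INF
    return e


@njit(cache=True)
def _cross_energy(coords, k, sx, sy, sz, nkx, nky, nkz, dnat, a, sigma, eps, moved):
    """Energy between head beads (< k) and block beads (>= k).

    With ``moved`` true the block is evaluated at its proposed position:
    bead k at (nkx, nky, nkz), beads > k shifted by (sx, sy, sz).
    """
    n = coords.shape[0]
    e = 0.0
    for i in range(k):
        for j in range(k, n):
            if j == i + 1:
                continue  # the (k-1, k) bond
            if moved:
                if j == k:
                    qx, qy, qz = nkx, nky, nkz
                else:
                    qx = coords[j, 0] + sx
                    qy = coords[j, 1] + sy
                    qz = coords[j, 2] + sz
            else:
                qx, qy, qz = coords[j, 0], coords[j, 1], coords[j, 2]
            dx = qx - coords[i, 0]
            dy = qy - coords[i, 1]
            dz = qz - coords[i, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            dn = dnat[i, j]
            if dn > 0.0:
                if r < sigma and r < dn - a:
                    return INF
                x = r - dn
                if -a <= x <= a:
                    e += eps * ((x / a) * (x / a) - 1.0)
            elif r < sigma:
                return INF
    return e


# --------------------------------------------------------------- moves


@njit(cache=True)
def _rotate_about_axis(vx, vy, vz, ux, uy, uz, theta):
    """Rodrigues rotation of v about unit axis u by theta."""
    c = np.cos(theta)
    s = np.sin(theta)
    dot = ux * vx + uy * vy + uz * vz
    cx = uy * vz - uz * vy
    cy = uz * vx - ux * vz
    cz = ux * vy - uy * vx
    rx = vx * c + cx * s + ux * dot * (1.0 - c)
    ry = vy * c + cy * s + uy * dot * (1.0 - c)
    rz = vz * c + cz * s + uz * dot * (1.0 - c)
    return rx, ry, rz


@njit(cache=True)
def propose_local(coords, i, max_angle, state):
    """New position for bead i; both adjacent bond lengths are preserved.

    Interior beads rotate about the axis through beads i-1 and i+1
    (crankshaft); terminal beads rotate about a random axis through
    their single neighbour.  Returns (x, y, z).
    """
    n = coords.shape[0]
    theta = (2.0 * rand_u01(state) - 1.0) * max_angle
    if i == 0 or i == n - 1:
        nb = 1 if i == 0 else n - 2
        ux, uy, uz = _rand_unit_vector(state)
        vx = coords[i, 0] - coords[nb, 0]
        vy = coords[i, 1] - coords[nb, 1]
        vz = coords[i, 2] - coords[nb, 2]
        rx, ry, rz = _rotate_about_axis(vx, vy, vz, ux, uy, uz, theta)
        return coords[nb, 0] + rx, coords[nb, 1] + ry, coords[nb, 2] + rz
    ax = coords[i + 1, 0] - coords[i - 1, 0]
    ay = coords[i + 1, 1] - coords[i - 1, 1]
    az = coords[i + 1, 2] - coords[i - 1, 2]
    an = np.sqrt(ax * ax + ay * ay + az * az)
    if an < 1e-9:
        # degenerate axis (neighbours coincide): no displacement
        return coords[i, 0], coords[i, 1], coords[i, 2]
    ax, ay, az = ax / an, ay / an, az / an
    vx = coords[i, 0] - coords[i - 1, 0]
    vy = coords[i, 1] - coords[i - 1, 1]
    vz = coords[i, 2] - coords[i - 1, 2]
    rx, ry, rz = _rotate_about_axis(vx, vy, vz, ax, ay, az, theta)
    return coords[i - 1, 0] + rx, coords[i - 1, 1] + ry, coords[i - 1, 2] + rz


@njit(cache=True)
def _one_trial(coords, e_cur, dnat, a, sigma, eps, t, max_angle, p_collective, state):
    """One Metropolis trial (local or collective move); returns new energy."""
    n = coords.shape[0]
    i = int(rand_u01(state) * n)
    if i >= n:
        i = n - 1
    collective = rand_u01(state) < p_collective and i < n - 1
    nx, ny, nz = propose_local(coords, i, max_angle, state)
    if collective:
        sx = nx - coords[i, 0]
        sy = ny - coords[i, 1]
        sz = nz - coords[i, 2]
        e_new = _cross_energy(coords, i, sx, sy, sz, nx, ny, nz, dnat, a, sigma, eps, True)
        if e_new == INF:
            return e_cur
        e_old = _cross_energy(coords, i, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, dnat, a, sigma, eps, False)
        de = e_new - e_old
        if de <= 0.0 or rand_u01(state) < np.exp(-de / t):
            coords[i, 0], coords[i, 1], coords[i, 2] = nx, ny, nz
            for j in range(i + 1, n):
                coords[j, 0] += sx
                coords[j, 1] += sy
                coords[j, 2] += sz
            return e_cur + de
        return e_cur
    e_new = _bead_energy(coords, i, nx, ny, nz, dnat, a, sigma, eps)
    if e_new == INF:
        return e_cur
    e_old = _bead_energy(coords, i, coords[i, 0], coords[i, 1], coords[i, 2], dnat, a, sigma, eps)
    de = e_new - e_old
    if de <= 0.0 or rand_u01(state) < np.exp(-de / t):
        coords[i, 0], coords[i, 1], coords[i, 2] = nx, ny, nz
        return e_cur + de
    return e_cur


@njit(cache=True)
def run_cycles(coords, e_cur, dnat, a, sigma, eps, t, max_angle, p_collective, n_cycles, state):
    """Run n_cycles Monte Carlo cycles (one cycle = N trials) in place."""
    n = coords.shape[0]
    for _ in range(n_cycles):
        for _ in range(n):
            e_cur = _one_trial(coords, e_cur, dnat, a, sigma, eps, t, max_angle, p_collective, state)
    return e_cur


# ------------------------------------------------------ RMSD (Kabsch)


@njit(cache=True)
def rmsd_to_ref(coords, ref):
    """Minimal Cα RMSD between coords and ref (proper rotations only)."""
    n = coords.shape[0]
    cax = 0.0
    cay = 0.0
    caz = 0.0
    cbx = 0.0
    cby = 0.0
    cbz = 0.0
    for i in range(n):
        cax += coords[i, 0]
        cay += coords[i, 1]
        caz += coords[i, 2]
        cbx += ref[i, 0]
        cby += ref[i, 1]
        cbz += ref[i, 2]
    cax /= n
    cay /= n
    caz /= n
    cbx /= n
    cby /= n
    cbz /= n
    h = np.zeros((3, 3))
    ga = 0.0
    gb = 0.0
    for i in range(n):
        ax = coords[i, 0] - cax
        ay = coords[i, 1] - cay
        az = coords[i, 2] - caz
        bx = ref[i, 0] - cbx
        by = ref[i, 1] - cby
        bz = ref[i, 2] - cbz
        ga += ax * ax + ay * ay + az * az
        gb += bx * bx + by * by + bz * bz
        h[0, 0] += ax * bx
        h[0, 1] += ax * by
        h[0, 2] += ax * bz
        h[1, 0] += ay * bx
        h[1, 1] += ay * by
        h[1, 2] += ay * bz
        h[2, 0] += az * bx
        h[2, 1] += az * by
        h[2, 2] += az * bz
    u, s, vt = np.linalg.svd(h)
    det = np.linalg.det(u) * np.linalg.det(vt)
    trace = s[0] + s[1]
    if det < 0.0:
        trace -= s[2]
    else:
        trace += s[2]
    msd = (ga + gb - 2.0 * trace) / n
    if msd < 0.0:
        msd = 0.0
    return np.sqrt(msd)


# ---------------------------------------------------------- kinetics


@njit(cache=True)
def _fold_rmsd(coords, ref, ref_mirror, use_mirror):
    r = rmsd_to_ref(coords, ref)
    if use_mirror:
        r2 = rmsd_to_ref(coords, ref_mirror)
        if r2 < r:
            return r2
    return r


@njit(cache=True)
def first_passage(coords, dnat, a, sigma, eps, t, max_angle, threshold, cap,
                  sample_every, ref, ref_mirror, use_mirror, seed):
    """Local-move-only Metropolis run until RMSD <= threshold.

    With ``use_mirror`` the folding RMSD is the minimum over the
    reference and its mirror image (the two are iso-energetic under a
    distance-only potential).  Returns (cycles_to_fold, q_samples,
    rmsd_samples, n_samples); cycles_to_fold is -1 when the trajectory
    is censored at ``cap``.  (Q, RMSD) pairs are recorded every
    ``sample_every`` cycles for the population histograms.
    """
    state = seed_state(seed)
    e_cur = total_energy_arr(coords, dnat, a, sigma, eps)
    n = coords.shape[0]
    n_contacts = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            if dnat[i, j] > 0.0:
                n_contacts += 1
    e_pdb = -float(n_contacts) * eps
    max_samples = cap // sample_every + 2
    q_samples = np.empty(max_samples)
    rmsd_samples = np.empty(max_samples)
    n_samples = 0
    r = _fold_rmsd(coords, ref, ref_mirror, use_mirror)
    if r <= threshold:
        return 0, q_samples, rmsd_samples, 0
    for cycle in range(1, cap + 1):
        for _ in range(n):
            e_cur = _one_trial(coords, e_cur, dnat, a, sigma, eps, t, max_angle, 0.0, state)
        r = _fold_rmsd(coords, ref, ref_mirror, use_mirror)
        if cycle % sample_every == 0:
            q_samples[n_samples] = e_cur / e_pdb
            rmsd_samples[n_samples] = r
            n_samples += 1
        if r <= threshold:
            return cycle, q_samples, rmsd_samples, n_samples
    return -1, q_samples, rmsd_samples, n_samples
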