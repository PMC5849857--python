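"""Numba-compiled Monte Carlo transport kernel.

Analog photon transport by Woodcock delta-tracking with region-wise
majorants (the Lipiodol bounding box carries its own majorant so that
low-energy photons in the surrounding water are not drowned in virtual
collisions).  Secondary electrons are not tracked: their kinetic energy is
deposited at the creation voxel (kerma approximation) or, optionally,
spread uniformly along a straight line of CSDA length.  Iodine K-shell
photoelectric events can emit a K x ray (Kalpha or Kbeta) which is
transported; pair production deposits the charged-pair energy and emits two
back-to-back 511 keV annihilation photons.

All sampling uses a counter-based per-history PRNG (splitmix64-seeded
xorshift128+): the random stream of history ``i`` depends only on the run
seed and ``i``, so runs are bit-reproducible, independent of chunking, and
paired runs that share a seed stay history-by-history correlated.
"""
import numpy as np
from numba import njit

MEC2 = 0.51099895
_EPS = 1e-6
_STACK = 256

_U64_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_INV_2_53 = 1.0 / 9007199254740992.0


@njit(cache=True, inline="always")
def _splitmix64(z):
    z = z + _U64_GOLDEN
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _init_state(st, seed, history_index):
    st[0] = _splitmix64(np.uint64(seed) * _U64_GOLDEN + np.uint64(history_index))
    st[1] = _splitmix64(st[0] ^ np.uint64(0x5851F42D4C957F2D))
    if st[0] == np.uint64(0) and st[1] == np.uint64(0):
        st[0] = np.uint64(1)


@njit(cache=True, inline="always")
def _rand(st):
    """xorshift128+ double in [0, 1)."""
    x = st[0]
    y = st[1]
    st[0] = y
    x ^= x << np.uint64(23)
    st[1] = x ^ y ^ (x >> np.uint64(17)) ^ (y >> np.uint64(26))
    return float((st[1] + y) >> np.uint64(11)) * _INV_2_53


@njit(cache=True, inline="always")
def _lookup(tab, f):
    """Linear interpolation on the fine log-energy grid; f = fractional idx."""
    n = tab.shape[0]
    if f <= 0.0:
        return tab[0]
    if f >= n - 1:
        return tab[n - 1]
    i = int(f)
    w = f - i
    return tab[i] * (1.0 - w) + tab[i + 1] * w


@njit(cache=True, inline="always")
def _grid_f(e, ln_e0, inv_dln):
    return (np.log(e) - ln_e0) * inv_dln


@njit(cache=True)
def sample_compton(e, st):
    """Kahn's rejection sampling of the Klein-Nishina distribution.

    Returns (scattered energy, cos(theta)).
    """
    a = e / MEC2
    x = 1.0
    while True:
        r1 = _rand(st)
        r2 = _rand(st)
        r3 = _rand(st)
        if r1 <= (1.0 + 2.0 * a) / (9.0 + 2.0 * a):
            x = 1.0 + 2.0 * a * r2
            if r3 <= 4.0 * (1.0 / x - 1.0 / (x * x)):
                break
        else:
            x = (1.0 + 2.0 * a) / (1.0 + 2.0 * a * r2)
            c = 1.0 - (x - 1.0) / a
            if r3 <= 0.5 * (c * c + 1.0 / x):
                break
    cost = 1.0 - (x - 1.0) / a
    if cost > 1.0:
        cost = 1.0
    elif cost < -1.0:
        cost = -1.0
    return e / x, cost


@njit(cache=True)
def sample_compton_batch(e, n, seed):
    """Batch Compton sampling for statistical verification."""
    out = np.empty(n)
    cos = np.empty(n)
    st = np.empty(2, dtype=np.uint64)
    for i in range(n):
        _init_state(st, seed, i)
        ep, c = sample_compton(e, st)
        out[i] = ep
        cos[i] = c
    return out, cos


@njit(cache=True, inline="always")
def _rotate(ux, uy, uz, cost, phi):
    sint = np.sqrt(max(0.0, 1.0 - cost * cost))
    cphi = np.cos(phi)
    sphi = np.sin(phi)
    if abs(uz) < 0.999999:
        den = np.sqrt(1.0 - uz * uz)
        nx = sint * (ux * uz * cphi - uy * sphi) / den + ux * cost
        ny = sint * (uy * uz * cphi + ux * sphi) / den + uy * cost
        nz = -sint * cphi * den + uz * cost
    else:
        sign = 1.0 if uz > 0 else -1.0
        nx = sint * cphi
        ny = sign * sint * sphi
        nz = sign * cost
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, inline="always")
def _iso_direction(st):
    cost = 2.0 * _rand(st) - 1.0
    sint = np.sqrt(max(0.0, 1.0 - cost * cost))
    phi = 2.0 * np.pi * _rand(st)
    return sint * np.cos(phi), sint * np.sin(phi), cost


@njit(cache=True, inline="always")
def _ray_aabb(px, py, pz, ux, uy, uz, x0, x1, y0, y1, z0, z1):
    """Entry/exit distances of a ray with an axis-aligned box (miss: tmin>tmax)."""
    tmin = -1.0e30
    tmax = 1.0e30
    for ax in range(3):
        if ax == 0:
            p, u, lo, hi = px, ux, x0, x1
        elif ax == 1:
            p, u, lo, hi = py, uy, y0, y1
        else:
            p, u, lo, hi = pz, uz, z0, z1
        if abs(u) < 1e-12:
            if p < lo or p >= hi:
                return 1.0, -1.0
        else:
            t1 = (lo - p) / u
            t2 = (hi - p) / u
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > tmin:
                tmin = t1
            if t2 < tmax:
                tmax = t2
    return tmin, tmax


@njit(cache=True)
def run_chunk(
    n_histories,
    seed,
    history_offset,
    # source model
    cdf,
    bin_lo,
    bin_hi,
    half_field,
    ssd,
    # phantom voxel grid
    mat_map,
    ox,
    oy,
    oz,
    h,
    # majorant region (high-attenuation bounding box); box_on = 0 disables
    box_on,
    bx0,
    bx1,
    by0,
    by1,
    bz0,
    bz1,
    # fine log-energy grid and per-material linear coefficients (1/cm)
    ln_e0,
    inv_dln,
    t_tot,
    t_pe,
    t_inc,
    t_pp,
    t_iodk,
    maj_out,
    maj_in,
    t_csda,
    # physics parameters
    cutoff,
    e_kedge,
    omega_k,
    p_kalpha,
    e_kalpha,
    e_kbeta,
    electron_mode,  # 0 = local (kerma), 1 = csda line
    primaries_only,
    # tally box and binnings
    tx0,
    tx1,
    ty0,
    ty1,
    tz0,
    tz1,
    ln_t0,
    inv_dln_t,
    n_tlog,
    lin_emax,
    n_tlin,
    # outputs (accumulated in place)
    edep,
    ph_log,
    ph_lin,
    el_log,
    el_lin,
    counters,
    accounting,
):
    nx, ny, nz = mat_map.shape
    st = np.empty(2, dtype=np.uint64)
    px0, px1 = ox, ox + nx * h
    py0, py1 = oy, oy + ny * h
    pz0, pz1 = oz, oz + nz * h

    sx = np.empty(_STACK)
    sy = np.empty(_STACK)
    sz = np.empty(_STACK)
    sux = np.empty(_STACK)
    suy = np.empty(_STACK)
    suz = np.empty(_STACK)
    se = np.empty(_STACK)

    for hist in range(n_histories):
        _init_state(st, seed, history_offset + hist)
        # --- source sampling -------------------------------------------
        r = _rand(st)
        j = np.searchsorted(cdf, r)
        if j >= bin_lo.shape[0]:
            j = bin_lo.shape[0] - 1
        e0 = bin_lo[j] + _rand(st) * (bin_hi[j] - bin_lo[j])
        txs = (_rand(st) - 0.5) * 2.0 * half_field
        tys = (_rand(st) - 0.5) * 2.0 * half_field
        dn = np.sqrt(txs * txs + tys * tys + ssd * ssd)
        accounting[0] += e0

        sp = 0
        sx[sp] = 0.0
        sy[sp] = 0.0
        sz[sp] = -ssd
        sux[sp] = txs / dn
        suy[sp] = tys / dn
        suz[sp] = ssd / dn
        se[sp] = e0
        sp += 1

        while sp > 0:
            sp -= 1
            x = sx[sp]
            y = sy[sp]
            z = sz[sp]
            ux = sux[sp]
            uy = suy[sp]
            uz = suz[sp]
            e = se[sp]

            alive = True
            while alive:
                inside = (
                    px0 <= x < px1 and py0 <= y < py1 and pz0 <= z < pz1
                )
                if not inside:
                    tmin, tmax = _ray_aabb(
                        x, y, z, ux, uy, uz, px0, px1, py0, py1, pz0, pz1
                    )
                    if tmax <= tmin or tmax <= 0.0:
                        accounting[1] += e
                        alive = False
                        break
                    step = (tmin if tmin > 0.0 else 0.0) + _EPS
                    x += step * ux
                    y += step * uy
                    z += step * uz
                    continue

                f = _grid_f(e, ln_e0, inv_dln)
                in_box = box_on == 1 and (
                    bx0 <= x < bx1 and by0 <= y < by1 and bz0 <= z < bz1
                )
                mu_maj = _lookup(maj_in, f) if in_box else _lookup(maj_out, f)

                # distance to the nearest region boundary along the flight
                _, t_exit = _ray_aabb(
                    x, y, z, ux, uy, uz, px0, px1, py0, py1, pz0, pz1
                )
                t_bound = t_exit
                if box_on == 1:
                    btmin, btmax = _ray_aabb(
                        x, y, z, ux, uy, uz, bx0, bx1, by0, by1, bz0, bz1
                    )
                    if in_box:
                        if btmax < t_bound:
                            t_bound = btmax
                    elif btmin < btmax and btmin > 0.0 and btmin < t_bound:
                        t_bound = btmin

                s = -np.log(1.0 - _rand(st)) / mu_maj
                travel = s if s < t_bound else t_bound

                # track-length photon tally on the traversed segment
                ttmin, ttmax = _ray_aabb(
                    x, y, z, ux, uy, uz, tx0, tx1, ty0, ty1, tz0, tz1
                )
                if ttmin < ttmax:
                    a = ttmin if ttmin > 0.0 else 0.0
                    b = ttmax if ttmax < travel else travel
                    if b > a:
                        bl = int(_grid_f(e, ln_t0, inv_dln_t))
                        if bl < 0:
                            bl = 0
                        elif bl >= n_tlog:
                            bl = n_tlog - 1
                        ph_log[bl] += b - a
                        bi = int(e / lin_emax * n_tlin)
                        if bi >= n_tlin:
                            bi = n_tlin - 1
                        ph_lin[bi] += b - a

                if s >= t_bound:
                    step = t_bound + _EPS
                    x += step * ux
                    y += step * uy
                    z += step * uz
                    continue

                x += s * ux
                y += s * uy
                z += s * uz

                ix = int((x - ox) / h)
                iy = int((y - oy) / h)
                iz = int((z - oz) / h)
                if ix < 0:
                    ix = 0
                elif ix >= nx:
                    ix = nx - 1
                if iy < 0:
                    iy = 0
                elif iy >= ny:
                    iy = ny - 1
                if iz < 0:
                    iz = 0
                elif iz >= nz:
                    iz = nz - 1
                m = mat_map[ix, iy, iz]

                if _rand(st) * mu_maj > _lookup(t_tot[m], f):
                    continue  # virtual collision

                # --- real collision ------------------------------------
                if primaries_only == 1:
                    edep[ix, iy, iz] += e
                    alive = False
                    break

                c_pe = _lookup(t_pe[m], f)
                c_in = _lookup(t_inc[m], f)
                c_pp = _lookup(t_pp[m], f)
                rc = _rand(st) * (c_pe + c_in + c_pp)
                in_tally = (
                    tx0 <= x < tx1 and ty0 <= y < ty1 and tz0 <= z < tz1
                )

                if rc < c_pe:
                    # photoelectric absorption
                    e_elec = e
                    local_rem = 0.0
                    fl_e = 0.0
                    if e >= e_kedge and _rand(st) < _lookup(t_iodk[m], f):
                        e_elec = e - e_kedge
                        if _rand(st) < omega_k:
                            fl_e = (
                                e_kalpha
                                if _rand(st) < p_kalpha
                                else e_kbeta
                            )
                        local_rem = e_kedge - fl_e
                    _deposit_electron(
                        e_elec, x, y, z, ux, uy, uz, m, electron_mode,
                        t_csda, ln_e0, inv_dln, edep, ix, iy, iz,
                        ox, oy, oz, h, accounting,
                    )
                    edep[ix, iy, iz] += local_rem
                    if in_tally and e_elec > 0.0:
                        _tally_electron(
                            e_elec, 0, el_log, el_lin, counters,
                            ln_t0, inv_dln_t, n_tlog, lin_emax, n_tlin,
                        )
                    if fl_e > 0.0 and sp < _STACK - 1:
                        wx, wy, wz = _iso_direction(st)
                        sx[sp] = x
                        sy[sp] = y
                        sz[sp] = z
                        sux[sp] = wx
                        suy[sp] = wy
                        suz[sp] = wz
                        se[sp] = fl_e
                        sp += 1
                    elif fl_e > 0.0:
                        edep[ix, iy, iz] += fl_e
                    alive = False
                elif rc < c_pe + c_in:
                    # Compton scattering
                    ep, cost = sample_compton(e, st)
                    e_elec = e - ep
                    phi = 2.0 * np.pi * _rand(st)
                    nux, nuy, nuz = _rotate(ux, uy, uz, cost, phi)
                    # electron direction from momentum balance
                    ex = e * ux - ep * nux
                    ey = e * uy - ep * nuy
                    ez = e * uz - ep * nuz
                    en = np.sqrt(ex * ex + ey * ey + ez * ez)
                    if en < 1e-12:
                        ex, ey, ez = ux, uy, uz
                        en = 1.0
                    _deposit_electron(
                        e_elec, x, y, z, ex / en, ey / en, ez / en, m,
                        electron_mode, t_csda, ln_e0, inv_dln, edep,
                        ix, iy, iz, ox, oy, oz, h, accounting,
                    )
                    if in_tally and e_elec > 0.0:
                        _tally_electron(
                            e_elec, 1, el_log, el_lin, counters,
                            ln_t0, inv_dln_t, n_tlog, lin_emax, n_tlin,
                        )
                    if ep < cutoff:
                        edep[ix, iy, iz] += ep
                        alive = False
                    else:
                        e = ep
                        ux, uy, uz = nux, nuy, nuz
                else:
                    # pair production: local pair energy + two 511 keV photons
                    e_elec = e - 2.0 * MEC2
                    _deposit_electron(
                        e_elec, x, y, z, ux, uy, uz, m, electron_mode,
                        t_csda, ln_e0, inv_dln, edep, ix, iy, iz,
                        ox, oy, oz, h, accounting,
                    )
                    if in_tally and e_elec > 0.0:
                        _tally_electron(
                            e_elec, 2, el_log, el_lin, counters,
                            ln_t0, inv_dln_t, n_tlog, lin_emax, n_tlin,
                        )
                    wx, wy, wz = _iso_direction(st)
                    if sp < _STACK - 1:
                        sx[sp] = x
                        sy[sp] = y
                        sz[sp] = z
                        sux[sp] = wx
                        suy[sp] = wy
                        suz[sp] = wz
                        se[sp] = MEC2
                        sp += 1
                    else:
                        edep[ix, iy, iz] += MEC2
                    ux, uy, uz = -wx, -wy, -wz
                    e = MEC2


@njit(cache=True, inline="always")
def _tally_electron(
    e_elec, channel, el_log, el_lin, counters,
    ln_t0, inv_dln_t, n_tlog, lin_emax, n_tlin,
):
    bl = int(_grid_f(e_elec, ln_t0, inv_dln_t))
    if bl < 0:
        bl = 0
    elif bl >= n_tlog:
        bl = n_tlog - 1
    el_log[bl] += 1.0
    bi = int(e_elec / lin_emax * n_tlin)
    if bi < 0:
        bi = 0
    elif bi >= n_tlin:
        bi = n_tlin - 1
    el_lin[bi] += 1.0
    counters[channel] += 1.0


@njit(cache=True, inline="always")
def _deposit_electron(
    e_elec, x, y, z, ux, uy, uz, m, mode, t_csda, ln_e0, inv_dln,
    edep, ix, iy, iz, ox, oy, oz, h, accounting,
):
    if e_elec <= 0.0:
        return
    nx, ny, nz = edep.shape
    if mode == 0 or e_elec < 0.01:
        edep[ix, iy, iz] += e_elec
        return
    rng_cm = _lookup(t_csda[m], _grid_f(e_elec, ln_e0, inv_dln))
    nstep = 4 + int(rng_cm / h * 4.0)
    de = e_elec / nstep
    for k in range(nstep):
        t = (k + 0.5) * rng_cm / nstep
        qx = x + t * ux
        qy = y + t * uy
        qz = z + t * uz
        jx = int((qx - ox) / h)
        jy = int((qy - oy) / h)
        jz = int((qz - oz) / h)
        if (
            qx < ox or jx >= nx or qy < oy or jy >= ny or qz < oz or jz >= nz
        ):
            accounting[1] += de  # electron energy leaves the phantom
        else:
            edep[jx, jy, jz] += de
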