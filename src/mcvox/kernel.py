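"""Monte Carlo photon-packet transport through a voxelated medium.

One photon packet at a time is marched through the label grid.  The hop
length to the next scattering site is sampled as a dimensionless path
``s* = -ln(xi)`` and converted to geometric length through the local μs;
each hop is split into segments at every voxel-boundary crossing
(Amanatides–Woo style incremental traversal), and within a segment of
length ℓ the packet deposits ``w·(1 − exp(−μa·ℓ))`` into the fluence bin
of the current voxel and time gate while its weight attenuates
continuously (Beer–Lambert).  Scattering directions come from the
Henyey–Greenstein phase function with the local anisotropy g.  The six
bounding-box faces each carry one of four boundary conditions — total
absorption, Fresnel reflection against the ambient index, total (mirror)
reflection, or cyclic wrap-around (infinite-medium emulation).  Voxels
labelled 0 are ambient/background: crossing into one terminates the
photon there exactly like leaving the grid through an absorbing face.

Low-weight packets are terminated unbiasedly by Russian roulette.  The
exact weight ledger (launched = absorbed + escaped + terminated-in-flight)
treats a roulette kill as termination in flight and the survivor's weight
boost as a negative entry of the same bucket, so the balance closes to
floating-point round-off on every run.

Determinism: photon *i* owns the RNG stream ``(seed, i)`` (see
:mod:`mcvox.rng`), so any detected photon can be replayed bit-exactly from
its stored index, and splitting a run across workers never changes any
photon's trajectory.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .rng import PhotonRNG, rand_open, rand_uniform, seed_state
from .sources import launch_photon, rotate_frame

__all__ = [
    "transport_run",
    "replay_run",
    "sample_scattering_path",
    "sample_hg_direction",
    "fresnel_reflectance",
    "refract_through_face",
    "russian_roulette",
    "C0_MM_S",
    "STATUS_ESCAPED",
    "STATUS_EXPIRED",
    "STATUS_KILLED",
]

C0_MM_S = 299792458000.0  # speed of light in vacuum, mm/s

_INF = 1e30
_EPS_TIE = 1e-12

STATUS_ESCAPED = 1   # left the medium (absorbing face, Fresnel transmission, label-0 voxel)
STATUS_EXPIRED = 2   # reached the end of the last time gate in flight
STATUS_KILLED = 3    # terminated by Russian roulette
STATUS_MISSED = 4    # launched outside and never hit the grid

# boundary-condition codes (per face, order x0,x1,y0,y1,z0,z1)
BC_ABSORB, BC_FRESNEL, BC_MIRROR, BC_CYCLIC = 0, 1, 2, 3
BC_CODES = {"absorb": BC_ABSORB, "fresnel": BC_FRESNEL, "mirror": BC_MIRROR, "cyclic": BC_CYCLIC}


# ---------------------------------------------------------------------------
# elementary physics (shared by kernel and unit tests)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _one_minus_exp(arg):
    # 1 - exp(-arg), full double precision also for tiny arg
    if arg < 1e-3:
        return arg * (1.0 - arg * (0.5 - arg * (1.0 / 6.0 - arg / 24.0)))
    return 1.0 - math.exp(-arg)


@njit(cache=True, inline="always")
def _hg_cos(g, state):
    if g > 0.999999 or g < -0.999999:
        return 1.0 if g > 0 else -1.0
    if abs(g) < 1e-7:
        return 1.0 - 2.0 * rand_open(state)
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * rand_open(state))
    ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(cache=True, inline="always")
def _rand_azimuth(state):
    # cos/sin of a uniform azimuth without trig calls (Marsaglia rejection)
    while True:
        a = 2.0 * rand_open(state) - 1.0
        b = 2.0 * rand_open(state) - 1.0
        d2 = a * a + b * b
        if d2 <= 1.0 and d2 > 1e-12:
            inv = 1.0 / d2
            return (a * a - b * b) * inv, 2.0 * a * b * inv


@njit(cache=True)
def _fresnel_unpolarized(n1, n2, ci):
    """Unpolarized Fresnel reflectance for |cos(theta_in)| = ci; 1.0 on TIR."""
    if n1 == n2:
        return 0.0
    si2 = 1.0 - ci * ci
    st2 = (n1 / n2) * (n1 / n2) * si2
    if st2 >= 1.0:
        return 1.0
    ct = math.sqrt(1.0 - st2)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def _refract_axis(dx, dy, dz, axis, n1, n2):
    """Refract across a voxel face whose normal is the given axis.

    Tangential direction components scale by n1/n2, the normal component is
    rebuilt from Snell's law keeping its sign; returns a unit vector.
    Caller must have excluded total internal reflection.
    """
    eta = n1 / n2
    if axis == 0:
        ci = abs(dx)
    elif axis == 1:
        ci = abs(dy)
    else:
        ci = abs(dz)
    st2 = eta * eta * (1.0 - ci * ci)
    ct = math.sqrt(max(0.0, 1.0 - st2))
    if axis == 0:
        s = 1.0 if dx >= 0 else -1.0
        nx, ny, nz = s * ct, eta * dy, eta * dz
    elif axis == 1:
        s = 1.0 if dy >= 0 else -1.0
        nx, ny, nz = eta * dx, s * ct, eta * dz
    else:
        s = 1.0 if dz >= 0 else -1.0
        nx, ny, nz = eta * dx, eta * dy, s * ct
    inv = 1.0 / math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx * inv, ny * inv, nz * inv


# ------------------------------ Python-facing wrappers ----------------------

def sample_scattering_path(rng: PhotonRNG) -> float:
    """Dimensionless scattering path s* = -ln(xi), xi in (0,1]; mean 1."""
    return -math.log(rand_uniform(rng.state))


def sample_hg_direction(direction, g: float, rng: PhotonRNG):
    """New unit direction after one Henyey–Greenstein deflection."""
    d = np.asarray(direction, dtype=np.float64)
    ct = _hg_cos(g, rng.state)
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    cp, sp = _rand_azimuth(rng.state)
    return np.array(rotate_frame(d[0], d[1], d[2], ct, st, cp, sp))


def fresnel_reflectance(n_in: float, n_out: float, cos_in: float) -> float:
    """Unpolarized Fresnel reflectance; returns 1.0 beyond the critical angle."""
    return _fresnel_unpolarized(n_in, n_out, abs(cos_in))


def refract_through_face(direction, axis: int, n_in: float, n_out: float):
    """Snell refraction across a face with normal along *axis* (0/1/2)."""
    d = np.asarray(direction, dtype=np.float64)
    ci = abs(d[axis])
    if _fresnel_unpolarized(n_in, n_out, ci) >= 1.0:
        raise ValueError("total internal reflection: no transmitted direction")
    return np.array(_refract_axis(d[0], d[1], d[2], axis, n_in, n_out))


def russian_roulette(weight, threshold, survive_chance, rng: PhotonRNG):
    """Return the post-roulette weight (0.0 = terminated); unbiased in expectation."""
    if weight >= threshold:
        return weight
    if rand_open(rng.state) < survive_chance:
        return weight / survive_chance
    return 0.0


# ---------------------------------------------------------------------------
# the per-photon simulation
# ---------------------------------------------------------------------------
# acct layout: [launched, absorbed, escaped, expired_in_flight(+roulette net)]

@njit(cache=True, fastmath=True)
def _simulate_one(
    idx, seed,
    labels, fprops, float_mode,
    mua_g, mus_g, g_arr, n_arr, tstep_arr,
    bc, do_mismatch,
    src_code, spos, sdir, p1, p2, phase, has_focus, focus, pattern,
    t0, t1, dt, ngates,
    rr_thresh, rr_p,
    fluence, accumulate,
    jac, jac_w,
    ppath, pnscat,
    acct,
):
    nx, ny, nz = labels.shape
    state = np.empty(2, dtype=np.uint64)
    seed_state(state, seed, idx)
    x, y, z, dx, dy, dz, w = launch_photon(
        src_code, spos, sdir, p1, p2, phase, has_focus, focus, pattern, state
    )
    w0 = w
    acct[0] += w
    mom = 0.0
    t = 0.0
    n_amb = n_arr[0]
    amb_tstep = tstep_arr[0]

    if w <= 0.0:
        return STATUS_KILLED, x, y, z, dx, dy, dz, 0.0, 0.0

    # --- move a photon starting outside the grid onto the bounding box ---
    entry_axis = -1
    if x < 0.0 or x >= nx or y < 0.0 or y >= ny or z < 0.0 or z >= nz:
        tnear = -_INF
        tfar = _INF
        for axis in range(3):
            p = x if axis == 0 else (y if axis == 1 else z)
            d = dx if axis == 0 else (dy if axis == 1 else dz)
            ext = float(nx if axis == 0 else (ny if axis == 1 else nz))
            if abs(d) < 1e-14:
                if p < 0.0 or p > ext:
                    acct[2] += w
                    return STATUS_MISSED, x, y, z, dx, dy, dz, w, mom
            else:
                ta = (0.0 - p) / d
                tb = (ext - p) / d
                if ta > tb:
                    ta, tb = tb, ta
                if ta > tnear:
                    tnear = ta
                    entry_axis = axis
                if tb < tfar:
                    tfar = tb
        if tnear > tfar or tfar < 0.0 or tnear < 0.0:
            acct[2] += w
            return STATUS_MISSED, x, y, z, dx, dy, dz, w, mom
        x += tnear * dx
        y += tnear * dy
        z += tnear * dz
        t += tnear * amb_tstep

    ix = int(x)
    iy = int(y)
    iz = int(z)
    if ix < 0:
        ix = 0
    elif ix > nx - 1:
        ix = nx - 1
    if iy < 0:
        iy = 0
    elif iy > ny - 1:
        iy = ny - 1
    if iz < 0:
        iz = 0
    elif iz > nz - 1:
        iz = nz - 1

    # --- ballistic advance through background (label-0) voxels at launch ---
    if not float_mode:
        guard = 0
        while labels[ix, iy, iz] == 0:
            guard += 1
            if guard > 2 * (nx + ny + nz):
                acct[2] += w
                return STATUS_MISSED, x, y, z, dx, dy, dz, w, mom
            tbx = ((ix + 1.0 - x) / dx) if dx > 0.0 else (((ix - x) / dx) if dx < 0.0 else _INF)
            tby = ((iy + 1.0 - y) / dy) if dy > 0.0 else (((iy - y) / dy) if dy < 0.0 else _INF)
            tbz = ((iz + 1.0 - z) / dz) if dz > 0.0 else (((iz - z) / dz) if dz < 0.0 else _INF)
            tminb = tbx
            axisb = 0
            if tby < tminb:
                tminb = tby
                axisb = 1
            if tbz < tminb:
                tminb = tbz
                axisb = 2
            if tminb < 0.0:
                tminb = 0.0
            x += tminb * dx
            y += tminb * dy
            z += tminb * dz
            t += tminb * amb_tstep
            if axisb == 0:
                step = 1 if dx > 0.0 else -1
                x = float(ix + 1) if step > 0 else float(ix)
                ix += step
            elif axisb == 1:
                step = 1 if dy > 0.0 else -1
                y = float(iy + 1) if step > 0 else float(iy)
                iy += step
            else:
                step = 1 if dz > 0.0 else -1
                z = float(iz + 1) if step > 0 else float(iz)
                iz += step
            entry_axis = axisb
            if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
                acct[2] += w
                return STATUS_MISSED, x, y, z, dx, dy, dz, w, mom

    # --- specular reflection when entering from the ambient medium ---
    if do_mismatch and entry_axis >= 0:
        if float_mode:
            n_in_med = n_arr[1]
        else:
            n_in_med = n_arr[labels[ix, iy, iz]]
        if n_in_med != n_amb:
            if entry_axis == 0:
                ci = abs(dx)
            elif entry_axis == 1:
                ci = abs(dy)
            else:
                ci = abs(dz)
            refl = _fresnel_unpolarized(n_amb, n_in_med, ci)
            if refl >= 1.0:
                acct[2] += w
                return STATUS_MISSED, x, y, z, dx, dy, dz, w, mom
            acct[2] += w * refl
            w *= 1.0 - refl
            dx, dy, dz = _refract_axis(dx, dy, dz, entry_axis, n_amb, n_in_med)

    # --- main transport loop ---
    rscat = -math.log(rand_uniform(state))
    while True:
        if float_mode:
            mua = float(fprops[ix, iy, iz, 0])
            mus = float(fprops[ix, iy, iz, 1])
            g = g_arr[1]
            n_cur = n_arr[1]
            tstep = tstep_arr[1]
            med = 0
        else:
            lab = labels[ix, iy, iz]
            mua = mua_g[lab]
            mus = mus_g[lab]
            g = g_arr[lab]
            n_cur = n_arr[lab]
            tstep = tstep_arr[lab]
            med = lab - 1

        # distances (grid units) to voxel faces, scattering site and time cap
        tbx = _INF
        tby = _INF
        tbz = _INF
        if dx > 0.0:
            tbx = (ix + 1.0 - x) / dx
        elif dx < 0.0:
            tbx = (ix - x) / dx
        if dy > 0.0:
            tby = (iy + 1.0 - y) / dy
        elif dy < 0.0:
            tby = (iy - y) / dy
        if dz > 0.0:
            tbz = (iz + 1.0 - z) / dz
        elif dz < 0.0:
            tbz = (iz - z) / dz
        tbound = tbx
        if tby < tbound:
            tbound = tby
        if tbz < tbound:
            tbound = tbz
        if tbound < 0.0:
            tbound = 0.0
        dscat = rscat / mus if mus > 0.0 else _INF
        dtime = (t1 - t) / tstep

        seg = tbound
        kind = 0  # 0 boundary, 1 scatter, 2 expire
        if dscat < seg:
            seg = dscat
            kind = 1
        if dtime <= seg:
            seg = dtime
            kind = 2
        if seg < 0.0:
            seg = 0.0

        # deposit into (voxel, gate of segment-start time)
        if seg > 0.0:
            gate = int((t - t0) / dt)
            ok_gate = t >= t0 and gate >= 0
            if gate >= ngates:
                gate = ngates - 1
            if mua > 0.0:
                dw = w * _one_minus_exp(mua * seg)
                acct[1] += dw
                if accumulate and ok_gate:
                    fluence[ix, iy, iz, gate] += dw
                w -= dw
            else:
                if accumulate and ok_gate:
                    fluence[ix, iy, iz, gate] += w * seg
            if jac_w > 0.0:
                jac[ix, iy, iz] += seg * jac_w
            x += seg * dx
            y += seg * dy
            z += seg * dz
            t += seg * tstep
            ppath[med] += seg
            rscat -= seg * mus

        if kind == 2:
            acct[3] += w
            return STATUS_EXPIRED, x, y, z, dx, dy, dz, w, mom

        if kind == 1:
            ct = _hg_cos(g, state)
            st = math.sqrt(max(0.0, 1.0 - ct * ct))
            cp, sp = _rand_azimuth(state)
            dx, dy, dz = rotate_frame(dx, dy, dz, ct, st, cp, sp)
            mom += 1.0 - ct
            pnscat[med] += 1.0
            rscat = -math.log(rand_uniform(state))
            if w < rr_thresh * w0:
                if rand_open(state) < rr_p:
                    boost = w / rr_p - w
                    acct[3] -= boost
                    w += boost
                else:
                    acct[3] += w
                    return STATUS_KILLED, x, y, z, dx, dy, dz, 0.0, mom
            continue

        # voxel-boundary crossing; exact ties advance every tied axis
        hit_x = tbx <= tbound + _EPS_TIE
        hit_y = tby <= tbound + _EPS_TIE
        hit_z = tbz <= tbound + _EPS_TIE
        for axis in range(3):
            if axis == 0:
                if not hit_x:
                    continue
                step = 1 if dx > 0.0 else -1
            elif axis == 1:
                if not hit_y:
                    continue
                step = 1 if dy > 0.0 else -1
            else:
                if not hit_z:
                    continue
                step = 1 if dz > 0.0 else -1

            if axis == 0:
                cur, ext = ix, nx
            elif axis == 1:
                cur, ext = iy, ny
            else:
                cur, ext = iz, nz
            nxt = cur + step

            # snap the crossed coordinate onto the face
            face_coord = float(cur + 1) if step > 0 else float(cur)
            if axis == 0:
                x = face_coord
            elif axis == 1:
                y = face_coord
            else:
                z = face_coord

            if nxt < 0 or nxt >= ext:
                code = bc[2 * axis + (1 if step > 0 else 0)]
                if code == BC_MIRROR:
                    if axis == 0:
                        dx = -dx
                    elif axis == 1:
                        dy = -dy
                    else:
                        dz = -dz
                    continue
                if code == BC_CYCLIC:
                    if step > 0:
                        nxt = 0
                        if axis == 0:
                            x = 0.0
                        elif axis == 1:
                            y = 0.0
                        else:
                            z = 0.0
                    else:
                        nxt = ext - 1
                        if axis == 0:
                            x = float(ext)
                        elif axis == 1:
                            y = float(ext)
                        else:
                            z = float(ext)
                    if axis == 0:
                        ix = nxt
                    elif axis == 1:
                        iy = nxt
                    else:
                        iz = nxt
                    continue
                if code == BC_FRESNEL and do_mismatch and n_cur != n_amb:
                    if axis == 0:
                        ci = abs(dx)
                    elif axis == 1:
                        ci = abs(dy)
                    else:
                        ci = abs(dz)
                    refl = _fresnel_unpolarized(n_cur, n_amb, ci)
                    if rand_open(state) < refl:
                        if axis == 0:
                            dx = -dx
                        elif axis == 1:
                            dy = -dy
                        else:
                            dz = -dz
                        continue
                    dx, dy, dz = _refract_axis(dx, dy, dz, axis, n_cur, n_amb)
                # absorbing face, or Fresnel transmission: the photon escapes
                acct[2] += w
                return STATUS_ESCAPED, x, y, z, dx, dy, dz, w, mom

            # interior crossing
            if not float_mode:
                if axis == 0:
                    lab2 = labels[nxt, iy, iz]
                elif axis == 1:
                    lab2 = labels[ix, nxt, iz]
                else:
                    lab2 = labels[ix, iy, nxt]
                if lab2 == 0:
                    # stepping into background: leaves the medium here
                    if do_mismatch and n_cur != n_amb:
                        if axis == 0:
                            ci = abs(dx)
                        elif axis == 1:
                            ci = abs(dy)
                        else:
                            ci = abs(dz)
                        refl = _fresnel_unpolarized(n_cur, n_amb, ci)
                        if rand_open(state) < refl:
                            if axis == 0:
                                dx = -dx
                            elif axis == 1:
                                dy = -dy
                            else:
                                dz = -dz
                            continue
                        dx, dy, dz = _refract_axis(dx, dy, dz, axis, n_cur, n_amb)
                    acct[2] += w
                    return STATUS_ESCAPED, x, y, z, dx, dy, dz, w, mom
                if do_mismatch:
                    n_next = n_arr[lab2]
                    if n_next != n_cur:
                        if axis == 0:
                            ci = abs(dx)
                        elif axis == 1:
                            ci = abs(dy)
                        else:
                            ci = abs(dz)
                        refl = _fresnel_unpolarized(n_cur, n_next, ci)
                        if rand_open(state) < refl:
                            if axis == 0:
                                dx = -dx
                            elif axis == 1:
                                dy = -dy
                            else:
                                dz = -dz
                            continue
                        dx, dy, dz = _refract_axis(dx, dy, dz, axis, n_cur, n_next)
            if axis == 0:
                ix = nxt
            elif axis == 1:
                iy = nxt
            else:
                iz = nxt


@njit(cache=True)
def _run_photons(
    i0, i1, seed,
    labels, fprops, float_mode,
    mua_g, mus_g, g_arr, n_arr, tstep_arr,
    bc, do_mismatch,
    src_code, spos, sdir, p1, p2, phase, has_focus, focus, pattern,
    t0, t1, dt, ngates,
    rr_thresh, rr_p,
    length_unit,
    det_pos, det_r2,
    fluence, det_buf,
    acct,
):
    nmedia = ppath_len(mua_g, float_mode)
    ppath = np.zeros(nmedia, dtype=np.float64)
    pnscat = np.zeros(nmedia, dtype=np.float64)
    ndet = 0
    cap = det_buf.shape[0]
    kdet = det_pos.shape[0]
    jac_dummy = np.zeros((1, 1, 1), dtype=np.float64)
    for idx in range(i0, i1):
        for m in range(nmedia):
            ppath[m] = 0.0
            pnscat[m] = 0.0
        w_before = acct[0]
        status, ex, ey, ez, edx, edy, edz, wexit, mom = _simulate_one(
            idx, seed,
            labels, fprops, float_mode,
            mua_g, mus_g, g_arr, n_arr, tstep_arr,
            bc, do_mismatch,
            src_code, spos, sdir, p1, p2, phase, has_focus, focus, pattern,
            t0, t1, dt, ngates,
            rr_thresh, rr_p,
            fluence, True,
            jac_dummy, 0.0,
            ppath, pnscat,
            acct,
        )
        w0 = acct[0] - w_before
        if status == STATUS_ESCAPED and kdet > 0 and ndet < cap:
            for k in range(kdet):
                ddx = ex - det_pos[k, 0]
                ddy = ey - det_pos[k, 1]
                ddz = ez - det_pos[k, 2]
                if ddx * ddx + ddy * ddy + ddz * ddz <= det_r2[k]:
                    row = det_buf[ndet]
                    row[0] = float(k)
                    for m in range(nmedia):
                        row[1 + m] = ppath[m] * length_unit
                        row[1 + nmedia + m] = pnscat[m]
                    base = 1 + 2 * nmedia
                    row[base + 0] = ex
                    row[base + 1] = ey
                    row[base + 2] = ez
                    row[base + 3] = edx
                    row[base + 4] = edy
                    row[base + 5] = edz
                    row[base + 6] = mom
                    row[base + 7] = w0
                    row[base + 8] = float(idx)
                    ndet += 1
                    break
    return ndet


@njit(cache=True, inline="always")
def ppath_len(mua_g, float_mode):
    return 1 if float_mode else max(1, mua_g.shape[0] - 1)


@njit(cache=True)
def _replay_photons(
    indices, seed,
    labels, fprops, float_mode,
    mua_g, mus_g, g_arr, n_arr, tstep_arr,
    bc, do_mismatch,
    src_code, spos, sdir, p1, p2, phase, has_focus, focus, pattern,
    t0, t1, dt, ngates,
    rr_thresh, rr_p,
    jac, exit_out,
):
    nmedia = ppath_len(mua_g, float_mode)
    ppath = np.zeros(nmedia, dtype=np.float64)
    pnscat = np.zeros(nmedia, dtype=np.float64)
    acct = np.zeros(4, dtype=np.float64)
    flu_dummy = np.zeros((1, 1, 1, 1), dtype=np.float64)
    jac_dummy = np.zeros((1, 1, 1), dtype=np.float64)
    for m in range(indices.shape[0]):
        idx = indices[m]
        for q in range(nmedia):
            ppath[q] = 0.0
            pnscat[q] = 0.0
        # pass A: recover the detected weight at exit
        status, ex, ey, ez, edx, edy, edz, wexit, mom = _simulate_one(
            idx, seed,
            labels, fprops, float_mode,
            mua_g, mus_g, g_arr, n_arr, tstep_arr,
            bc, do_mismatch,
            src_code, spos, sdir, p1, p2, phase, has_focus, focus, pattern,
            t0, t1, dt, ngates,
            rr_thresh, rr_p,
            flu_dummy, False,
            jac_dummy, 0.0,
            ppath, pnscat,
            acct,
        )
        exit_out[m, 0] = ex
        exit_out[m, 1] = ey
        exit_out[m, 2] = ez
        exit_out[m, 3] = edx
        exit_out[m, 4] = edy
        exit_out[m, 5] = edz
        exit_out[m, 6] = float(status)
        total = 0.0
        for q in range(nmedia):
            total += ppath[q]
            ppath[q] = 0.0
            pnscat[q] = 0.0
        exit_out[m, 7] = total
        exit_out[m, 8] = wexit
        # pass B: accumulate pathlength x detected-weight into the Jacobian
        _simulate_one(
            idx, seed,
            labels, fprops, float_mode,
            mua_g, mus_g, g_arr, n_arr, tstep_arr,
            bc, do_mismatch,
            src_code, spos, sdir, p1, p2, phase, has_focus, focus, pattern,
            t0, t1, dt, ngates,
            rr_thresh, rr_p,
            flu_dummy, False,
            jac, wexit,
            ppath, pnscat,
            acct,
        )


@njit(cache=True)
def hg_cos_samples(g, n, seed):
    """n Henyey–Greenstein deflection cosines from stream (seed, 0)."""
    state = np.empty(2, dtype=np.uint64)
    seed_state(state, seed, 0)
    out = np.empty(n, dtype=np.float64)
    for i in range(n):
        out[i] = _hg_cos(g, state)
    return out


@njit(cache=True)
def scattering_path_samples(n, seed):
    """n dimensionless scattering paths -ln(xi) from stream (seed, 0)."""
    state = np.empty(2, dtype=np.uint64)
    seed_state(state, seed, 0)
    out = np.empty(n, dtype=np.float64)
    for i in range(n):
        out[i] = -math.log(rand_uniform(state))
    return out


@njit(cache=True)
def roulette_samples(w, threshold, survive_chance, n, seed):
    """Post-roulette weights for n trials at weight w (0 = terminated)."""
    state = np.empty(2, dtype=np.uint64)
    seed_state(state, seed, 0)
    out = np.empty(n, dtype=np.float64)
    for i in range(n):
        if w >= threshold:
            out[i] = w
        elif rand_open(state) < survive_chance:
            out[i] = w / survive_chance
        else:
            out[i] = 0.0
    return out


# ---------------------------------------------------------------------------
# Python driver
# ---------------------------------------------------------------------------

def _kernel_args(config, volume):
    """Translate a parsed SimConfig + label volume into kernel arrays."""
    from .sources import SRC_CODES, _check_geometry, _pattern_3d

    dom = config.domain
    lu = dom.length_unit
    float_mode = dom.media_format == "muamus_float"
    if float_mode and len(dom.media) < 2:
        raise ValueError(
            "muamus_float domains need Media[1] to carry the global g and n"
        )
    if float_mode:
        fprops = np.ascontiguousarray(volume, dtype=np.float32) * np.float32(lu)
        labels = np.ones(dom.dim, dtype=np.int32)
    else:
        labels = np.ascontiguousarray(volume, dtype=np.int32)
        fprops = np.zeros((1, 1, 1, 2), dtype=np.float32)
    nmed = len(dom.media)
    mua_g = np.zeros(nmed, dtype=np.float64)
    mus_g = np.zeros(nmed, dtype=np.float64)
    g_arr = np.zeros(nmed, dtype=np.float64)
    n_arr = np.ones(nmed, dtype=np.float64)
    tstep = np.zeros(nmed, dtype=np.float64)
    for i, m in enumerate(dom.media):
        mua_g[i] = m.mua * lu
        mus_g[i] = m.mus * lu
        g_arr[i] = m.g
        n_arr[i] = m.n
        tstep[i] = m.n * lu / C0_MM_S
    bc = np.array([BC_CODES[b] for b in dom.boundary], dtype=np.int8)
    src = config.source
    _check_geometry(src)
    has_focus = src.focus is not None and math.isfinite(src.focus)
    if src.focus is not None and math.isfinite(src.focus) and src.focus == 0.0:
        raise ValueError("focal length must be nonzero (omit Focus for collimated)")
    det_pos = np.zeros((len(config.detectors), 3), dtype=np.float64)
    det_r2 = np.zeros(len(config.detectors), dtype=np.float64)
    for i, d in enumerate(config.detectors):
        det_pos[i] = d.pos
        det_r2[i] = d.radius * d.radius
    fwd = config.forward
    return dict(
        labels=labels,
        fprops=fprops,
        float_mode=float_mode,
        mua_g=mua_g,
        mus_g=mus_g,
        g_arr=g_arr,
        n_arr=n_arr,
        tstep_arr=tstep,
        bc=bc,
        do_mismatch=config.session.do_mismatch,
        src_code=SRC_CODES[src.type],
        spos=np.ascontiguousarray(src.pos),
        sdir=np.ascontiguousarray(src.dir),
        p1=np.ascontiguousarray(src.param1),
        p2=np.ascontiguousarray(src.param2),
        phase=src.phase,
        has_focus=has_focus,
        focus=src.focus if has_focus else 0.0,
        pattern=_pattern_3d(src),
        t0=fwd.t0,
        t1=fwd.t1,
        dt=fwd.dt,
        ngates=fwd.gates,
        det_pos=det_pos,
        det_r2=det_r2,
        length_unit=lu,
    )


DEFAULT_RR_THRESHOLD = 1e-4
DEFAULT_RR_SURVIVE = 0.1


def transport_run(
    config,
    volume,
    *,
    photon_offset: int = 0,
    n_photons: int | None = None,
    seed: int | None = None,
    rr_threshold: float = DEFAULT_RR_THRESHOLD,
    rr_survive: float = DEFAULT_RR_SURVIVE,
):
    """Run photons ``photon_offset .. photon_offset+n_photons`` and return
    ``(fluence_raw, detected_rows, accounting)``.

    *fluence_raw* is the 4D (x,y,z,gate) deposited-energy grid (pathlength
    density where μa = 0); *detected_rows* a float64 table (one row per
    detected photon); *accounting* a dict with the exact weight ledger.
    """
    args = _kernel_args(config, volume)
    if n_photons is None:
        n_photons = config.session.photons
    if seed is None:
        seed = config.session.rng_seed
    dim = config.domain.dim
    fluence = np.zeros(dim + (args["ngates"],), dtype=np.float64)
    nmedia = 1 if args["float_mode"] else max(1, len(config.domain.media) - 1)
    ncol = 2 * nmedia + 10
    cap = n_photons if len(config.detectors) > 0 else 1
    det_buf = np.zeros((cap, ncol), dtype=np.float64)
    acct = np.zeros(4, dtype=np.float64)
    ndet = _run_photons(
        photon_offset, photon_offset + n_photons, seed,
        args["labels"], args["fprops"], args["float_mode"],
        args["mua_g"], args["mus_g"], args["g_arr"], args["n_arr"], args["tstep_arr"],
        args["bc"], args["do_mismatch"],
        args["src_code"], args["spos"], args["sdir"], args["p1"], args["p2"],
        args["phase"], args["has_focus"], args["focus"], args["pattern"],
        args["t0"], args["t1"], args["dt"], args["ngates"],
        rr_threshold, rr_survive,
        args["length_unit"],
        args["det_pos"], args["det_r2"],
        fluence, det_buf,
        acct,
    )
    accounting = {
        "launched": float(acct[0]),
        "absorbed": float(acct[1]),
        "escaped": float(acct[2]),
        "terminated_in_flight": float(acct[3]),
    }
    return fluence, det_buf[:ndet].copy(), accounting


def replay_run(
    config,
    volume,
    detected_rows: np.ndarray,
    *,
    seed: int | None = None,
    rr_threshold: float = DEFAULT_RR_THRESHOLD,
    rr_survive: float = DEFAULT_RR_SURVIVE,
):
    """Re-simulate detected photons from their stored stream indices.

    Returns ``(jacobian, exit_records)``: *jacobian* is the 3D grid of
    pathlength (mm) × detected weight; *exit_records* has one row per
    replayed photon: exit position (3), exit direction (3), status, total
    pathlength (grid units) and exit weight, for integrity checks against
    the forward table.
    """
    args = _kernel_args(config, volume)
    if seed is None:
        seed = config.session.rng_seed
    indices = detected_rows[:, -1].astype(np.int64)
    jac = np.zeros(config.domain.dim, dtype=np.float64)
    exit_out = np.zeros((len(indices), 9), dtype=np.float64)
    _replay_photons(
        indices, seed,
        args["labels"], args["fprops"], args["float_mode"],
        args["mua_g"], args["mus_g"], args["g_arr"], args["n_arr"], args["tstep_arr"],
        args["bc"], args["do_mismatch"],
        args["src_code"], args["spos"], args["sdir"], args["p1"], args["p2"],
        args["phase"], args["has_focus"], args["focus"], args["pattern"],
        args["t0"], args["t1"], args["dt"], args["ngates"],
        rr_threshold, rr_survive,
        jac, exit_out,
    )
    jac *= args["length_unit"]
    return jac, exit_out
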