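"""Launch sampling for the full source family.

Every source type maps a handful of uniform variates to an initial photon
position (grid units), unit direction, statistical weight and launch time.
The mapping is one numba-compiled function, :func:`launch_photon`, used both
by the transport kernel (per-photon streams) and by the Python API
:func:`sample_launch` — so unit tests exercise the exact code the kernel
runs.

Parameter packing (``Param1``/``Param2`` are 4-vectors):

====================  =====================================================
type                  geometry
====================  =====================================================
pencil / isotropic    ``Pos`` only
cone                  ``Param1[0]`` = half-angle (radians) about ``Dir``
planar / fourier /    ``Param1[:3]``, ``Param2[:3]`` = patch edge vectors
pattern               from ``Pos``; fourier adds ``Param1[3]``/``Param2[3]``
                      = spatial frequencies fx, fy (cycles per patch) and
                      an optional ``Phase`` (radians)
disk                  ``Param1[0]`` = radius, disk ⊥ ``Dir`` centred at Pos
gaussian              ``Param1[0]`` = 1/e² beam waist w0 (grid units)
line / slit           segment from ``Pos`` to ``Pos + Param1[:3]``
pattern3d             box at ``Pos`` with size ``Param1[:3]``
====================  =====================================================

Area sources honour a signed focal length: rays are redirected through
(f > 0) or away from (f < 0) the point ``center + f*Dir``; ``Focus``
omitted means collimated.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from numba import njit

from .rng import PhotonRNG, rand_open, rand_uniform
from .scene import SourceCfg

__all__ = ["LaunchSample", "sample_launch", "apply_focus", "SRC_CODES", "launch_photon"]

SRC_CODES = {
    "pencil": 0,
    "isotropic": 1,
    "cone": 2,
    "planar": 3,
    "disk": 4,
    "gaussian": 5,
    "fourier": 6,
    "line": 7,
    "slit": 8,
    "pattern": 9,
    "pattern3d": 10,
}
_AREA_TYPES = {"planar", "disk", "gaussian", "fourier", "line", "slit", "pattern"}

_TWO_PI = 2.0 * math.pi


@dataclasses.dataclass
class LaunchSample:
    pos: np.ndarray
    dir: np.ndarray
    weight: float
    t: float = 0.0


@njit(cache=True, inline="always")
def _perp_basis(dx, dy, dz):
    # orthonormal pair spanning the plane normal to (dx,dy,dz)
    if abs(dz) < 0.9:
        ax, ay, az = 0.0, 0.0, 1.0
    else:
        ax, ay, az = 1.0, 0.0, 0.0
    e1x = ay * dz - az * dy
    e1y = az * dx - ax * dz
    e1z = ax * dy - ay * dx
    inv = 1.0 / math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
    e1x *= inv
    e1y *= inv
    e1z *= inv
    e2x = dy * e1z - dz * e1y
    e2y = dz * e1x - dx * e1z
    e2z = dx * e1y - dy * e1x
    return e1x, e1y, e1z, e2x, e2y, e2z


@njit(cache=True, inline="always")
def rotate_frame(dx, dy, dz, ct, st, cp, sp):
    """Rotate the unit vector that makes polar angle (ct, st) and azimuth
    (cp, sp) with the z-axis into the frame whose pole is (dx, dy, dz)."""
    if abs(dz) > 0.999999:
        sign = 1.0 if dz > 0.0 else -1.0
        return st * cp, sign * st * sp, sign * ct
    den = math.sqrt(1.0 - dz * dz)
    nx = st * (dx * dz * cp - dy * sp) / den + dx * ct
    ny = st * (dy * dz * cp + dx * sp) / den + dy * ct
    nz = -st * cp * den + dz * ct
    inv = 1.0 / math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx * inv, ny * inv, nz * inv


@njit(cache=True)
def launch_photon(src_code, spos, sdir, p1, p2, phase, has_focus, focus, pattern, state):
    """Draw one launch: returns (x, y, z, dx, dy, dz, weight).

    ``pattern`` is a C-contiguous float64 array (2D or 3D as the type
    requires; a dummy (1,1,1) array otherwise).
    """
    x, y, z = spos[0], spos[1], spos[2]
    dx, dy, dz = sdir[0], sdir[1], sdir[2]
    w = 1.0
    # patch center for focusing, defaults to source position
    cx, cy, cz = x, y, z

    if src_code == 0:  # pencil
        pass
    elif src_code == 1:  # isotropic
        ct = 1.0 - 2.0 * rand_open(state)
        st = math.sqrt(max(0.0, 1.0 - ct * ct))
        phi = _TWO_PI * rand_open(state)
        dx, dy, dz = st * math.cos(phi), st * math.sin(phi), ct
    elif src_code == 2:  # cone, uniform solid angle of half-angle p1[0]
        ct0 = math.cos(p1[0])
        ct = 1.0 - rand_open(state) * (1.0 - ct0)
        st = math.sqrt(max(0.0, 1.0 - ct * ct))
        phi = _TWO_PI * rand_open(state)
        dx, dy, dz = rotate_frame(dx, dy, dz, ct, st, math.cos(phi), math.sin(phi))
    elif src_code == 3 or src_code == 6 or src_code == 9:  # planar/fourier/pattern
        u = rand_open(state)
        v = rand_open(state)
        x += u * p1[0] + v * p2[0]
        y += u * p1[1] + v * p2[1]
        z += u * p1[2] + v * p2[2]
        cx += 0.5 * (p1[0] + p2[0])
        cy += 0.5 * (p1[1] + p2[1])
        cz += 0.5 * (p1[2] + p2[2])
        if src_code == 6:
            w = 0.5 * (1.0 + math.cos(_TWO_PI * (p1[3] * u + p2[3] * v) + phase))
            if w < 0.0:
                w = 0.0
        elif src_code == 9:
            n1 = pattern.shape[0]
            n2 = pattern.shape[1]
            iu = min(int(u * n1), n1 - 1)
            iv = min(int(v * n2), n2 - 1)
            w = pattern[iu, iv, 0]
    elif src_code == 4 or src_code == 5:  # disk / gaussian, plane normal to dir
        if src_code == 4:
            r = p1[0] * math.sqrt(rand_open(state))
        else:
            # intensity ~ exp(-2 r^2 / w0^2)
            r = p1[0] * math.sqrt(-0.5 * math.log(rand_uniform(state)))
        phi = _TWO_PI * rand_open(state)
        e1x, e1y, e1z, e2x, e2y, e2z = _perp_basis(dx, dy, dz)
        ca, sa = math.cos(phi), math.sin(phi)
        x += r * (ca * e1x + sa * e2x)
        y += r * (ca * e1y + sa * e2y)
        z += r * (ca * e1z + sa * e2z)
    elif src_code == 7 or src_code == 8:  # line / slit
        u = rand_open(state)
        x += u * p1[0]
        y += u * p1[1]
        z += u * p1[2]
        cx += 0.5 * p1[0]
        cy += 0.5 * p1[1]
        cz += 0.5 * p1[2]
    elif src_code == 10:  # pattern3d: box of size p1[:3] at pos
        u = rand_open(state)
        v = rand_open(state)
        s = rand_open(state)
        x += u * p1[0]
        y += v * p1[1]
        z += s * p1[2]
        n1, n2, n3 = pattern.shape
        iu = min(int(u * n1), n1 - 1)
        iv = min(int(v * n2), n2 - 1)
        iw = min(int(s * n3), n3 - 1)
        w = pattern[iu, iv, iw]

    if has_focus and src_code != 0 and src_code != 1 and src_code != 2 and src_code != 10:
        fx = cx + focus * sdir[0]
        fy = cy + focus * sdir[1]
        fz = cz + focus * sdir[2]
        vx, vy, vz = fx - x, fy - y, fz - z
        if focus < 0.0:
            vx, vy, vz = -vx, -vy, -vz
        norm = math.sqrt(vx * vx + vy * vy + vz * vz)
        if norm > 1e-12:
            dx, dy, dz = vx / norm, vy / norm, vz / norm
    return x, y, z, dx, dy, dz, w


def _pattern_3d(src: SourceCfg) -> np.ndarray:
    """Kernel-ready pattern array: always 3D C-contiguous float64."""
    if src.pattern is None:
        return np.ones((1, 1, 1), dtype=np.float64)
    pat = np.asarray(src.pattern, dtype=np.float64)
    if src.type == "pattern":
        if pat.ndim != 2:
            raise ValueError("2D pattern source requires a 2D array")
        pat = pat[:, :, None]
    elif src.type == "pattern3d" and pat.ndim != 3:
        raise ValueError("pattern3d source requires a 3D array")
    return np.ascontiguousarray(pat)


def _check_geometry(src: SourceCfg) -> None:
    p1 = src.param1
    if src.type in ("planar", "fourier", "pattern"):
        area = np.linalg.norm(np.cross(p1[:3], src.param2[:3]))
        if area <= 0:
            raise ValueError(f"{src.type} source has a zero-area patch")
    elif src.type in ("disk", "gaussian") and p1[0] <= 0:
        raise ValueError(f"{src.type} source needs a positive radius/waist")
    elif src.type in ("line", "slit") and np.linalg.norm(p1[:3]) <= 0:
        raise ValueError(f"{src.type} source has zero length")
    if src.type in ("pattern", "pattern3d") and src.pattern is None:
        raise ValueError(f"{src.type} source requires a pattern array")


def sample_launch(src: SourceCfg, rng: PhotonRNG) -> LaunchSample:
    """Draw one launch sample for *src* from the given photon stream."""
    _check_geometry(src)
    x, y, z, dx, dy, dz, w = launch_photon(
        SRC_CODES[src.type],
        np.ascontiguousarray(src.pos),
        np.ascontiguousarray(src.dir),
        np.ascontiguousarray(src.param1),
        np.ascontiguousarray(src.param2),
        src.phase,
        src.focus is not None and math.isfinite(src.focus),
        0.0 if src.focus is None or not math.isfinite(src.focus) else src.focus,
        _pattern_3d(src),
        rng.state,
    )
    return LaunchSample(
        pos=np.array([x, y, z]), dir=np.array([dx, dy, dz]), weight=w, t=0.0
    )


def apply_focus(sample: LaunchSample, focal_length: float, src: SourceCfg) -> LaunchSample:
    """Redirect an area-source ray through (f>0) or away from (f<0) the
    focal point ``center + f*Dir``; infinite *focal_length* is collimated."""
    if src.type not in _AREA_TYPES:
        raise ValueError(f"focus applies to area sources, not {src.type!r}")
    if not math.isfinite(focal_length):
        return sample
    if focal_length == 0.0:
        raise ValueError("focal length must be nonzero (use +/-inf for collimated)")
    center = np.asarray(src.pos, dtype=np.float64).copy()
    if src.type in ("planar", "fourier", "pattern"):
        center += 0.5 * (src.param1[:3] + src.param2[:3])
    elif src.type in ("line", "slit"):
        center += 0.5 * src.param1[:3]
    focal_point = center + focal_length * src.dir
    v = focal_point - sample.pos
    if focal_length < 0:
        v = -v
    norm = np.linalg.norm(v)
    if norm <= 1e-12:
        raise ValueError("sample position coincides with the focal point")
    return dataclasses.replace(sample, dir=v / norm)
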