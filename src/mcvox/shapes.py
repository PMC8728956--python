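"""Rasterize CSG shape descriptors into voxel label volumes.

Shapes are applied in list order, last writer wins.  Membership is tested
at the voxel center ``(i+0.5, j+0.5, k+0.5)`` with closed inequalities, so
a center exactly on a surface counts as inside.  Layer ranges are 0-based
inclusive ``[start, end, label]`` index triples.

Supported primitives (one-key JSON objects)::

    {"Grid":     {"Tag": 1, "Size": [nx, ny, nz]}}
    {"Sphere":   {"Tag": 2, "O": [cx, cy, cz], "R": r}}
    {"Box":      {"Tag": 2, "O": [x, y, z], "Size": [sx, sy, sz]}}
    {"Cylinder": {"Tag": 2, "C0": [...], "C1": [...], "R": r}}
    {"XLayers":  [[start, end, tag], ...]}   (likewise YLayers, ZLayers)
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["rasterize", "UnsupportedShapeError"]


class UnsupportedShapeError(ValueError):
    """Shape object with an unknown primitive kind."""


def _centers(dim):
    ax = [np.arange(n, dtype=np.float64) + 0.5 for n in dim]
    return np.meshgrid(*ax, indexing="ij")


def _apply_sphere(labels, cx, cy, cz, spec):
    o = np.asarray(spec["O"], dtype=np.float64)
    r = float(spec["R"])
    if r <= 0:
        raise ValueError("sphere radius must be > 0")
    m = (cx - o[0]) ** 2 + (cy - o[1]) ** 2 + (cz - o[2]) ** 2 <= r * r
    labels[m] = int(spec["Tag"])


def _apply_box(labels, cx, cy, cz, spec):
    o = np.asarray(spec["O"], dtype=np.float64)
    s = np.asarray(spec["Size"], dtype=np.float64)
    m = (
        (cx >= o[0]) & (cx <= o[0] + s[0])
        & (cy >= o[1]) & (cy <= o[1] + s[1])
        & (cz >= o[2]) & (cz <= o[2] + s[2])
    )
    labels[m] = int(spec["Tag"])


def _apply_cylinder(labels, cx, cy, cz, spec):
    c0 = np.asarray(spec["C0"], dtype=np.float64)
    c1 = np.asarray(spec["C1"], dtype=np.float64)
    r = float(spec["R"])
    if r <= 0:
        raise ValueError("cylinder radius must be > 0")
    axis = c1 - c0
    L2 = float(axis @ axis)
    if L2 <= 0:
        raise ValueError("cylinder endpoints coincide")
    px, py, pz = cx - c0[0], cy - c0[1], cz - c0[2]
    t = (px * axis[0] + py * axis[1] + pz * axis[2]) / L2  # 0..1 along axis
    d2 = (
        (px - t * axis[0]) ** 2
        + (py - t * axis[1]) ** 2
        + (pz - t * axis[2]) ** 2
    )
    m = (t >= 0.0) & (t <= 1.0) & (d2 <= r * r)
    labels[m] = int(spec["Tag"])


def _apply_layers(labels, axis, ranges, dim):
    n = dim[axis]
    for entry in ranges:
        start, end, tag = (int(v) for v in entry)
        if start > end:
            raise ValueError(f"layer range [{start}, {end}] is reversed")
        lo, hi = max(start, 0), min(end, n - 1)
        if lo != start or hi != end:
            logger.warning(
                "layer range [%d, %d] clipped to grid extent %d", start, end, n
            )
        if lo > hi:
            continue
        sl = [slice(None)] * 3
        sl[axis] = slice(lo, hi + 1)
        labels[tuple(sl)] = tag


def rasterize(shapes: list[dict], dim=None) -> np.ndarray:
    """Rasterize a shape list into an int32 label array of shape *dim*.

    The grid extent comes from an initial ``Grid`` item or from *dim*;
    shapes are painted in order onto the running label volume, so later
    shapes overwrite earlier ones wherever they overlap.  Voxels no shape
    touches keep the ``Grid`` tag (or 0 when only *dim* was given).
    """
    grid_tag = 0
    rest = list(shapes)
    if rest and isinstance(rest[0], dict) and "Grid" in rest[0]:
        g = rest[0]["Grid"]
        dim = tuple(int(v) for v in g["Size"])
        grid_tag = int(g.get("Tag", 1))
        rest = rest[1:]
    if dim is None:
        raise ValueError("grid extent unknown: provide dim or a leading Grid shape")
    dim = tuple(int(v) for v in dim)
    labels = np.full(dim, grid_tag, dtype=np.int32)
    cx, cy, cz = _centers(dim)
    for item in rest:
        if not isinstance(item, dict) or len(item) != 1:
            raise UnsupportedShapeError(f"shape entry must be a one-key object: {item!r}")
        kind, spec = next(iter(item.items()))
        if kind == "Grid":
            labels[:] = int(spec.get("Tag", 1))
        elif kind == "Sphere":
            _apply_sphere(labels, cx, cy, cz, spec)
        elif kind == "Box":
            _apply_box(labels, cx, cy, cz, spec)
        elif kind == "Cylinder":
            _apply_cylinder(labels, cx, cy, cz, spec)
        elif kind == "XLayers":
            _apply_layers(labels, 0, spec, dim)
        elif kind == "YLayers":
            _apply_layers(labels, 1, spec, dim)
        elif kind == "ZLayers":
            _apply_layers(labels, 2, spec, dim)
        else:
            raise UnsupportedShapeError(f"unknown shape kind {kind!r}")
    return labels
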