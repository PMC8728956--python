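"""Independent brute-force references used by several test modules.

These deliberately avoid the package's vectorized code paths: membership
is evaluated one voxel center at a time with plain Python arithmetic.
"""

import math

import numpy as np


def brute_force_labels(shapes, dim):
    """Per-voxel-center CSG rasterization by direct membership tests."""
    grid_tag = 0
    rest = list(shapes)
    if rest and "Grid" in rest[0]:
        g = rest[0]["Grid"]
        dim = tuple(g["Size"])
        grid_tag = int(g.get("Tag", 1))
        rest = rest[1:]
    labels = np.full(dim, grid_tag, dtype=np.int32)
    for i in range(dim[0]):
        for j in range(dim[1]):
            for k in range(dim[2]):
                cx, cy, cz = i + 0.5, j + 0.5, k + 0.5
                for item in rest:
                    kind, spec = next(iter(item.items()))
                    if kind == "Sphere":
                        o, r = spec["O"], spec["R"]
                        if (cx - o[0]) ** 2 + (cy - o[1]) ** 2 + (cz - o[2]) ** 2 <= r * r:
                            labels[i, j, k] = spec["Tag"]
                    elif kind == "Box":
                        o, s = spec["O"], spec["Size"]
                        if (
                            o[0] <= cx <= o[0] + s[0]
                            and o[1] <= cy <= o[1] + s[1]
                            and o[2] <= cz <= o[2] + s[2]
                        ):
                            labels[i, j, k] = spec["Tag"]
                    elif kind == "Cylinder":
                        c0, c1, r = spec["C0"], spec["C1"], spec["R"]
                        ax = [c1[q] - c0[q] for q in range(3)]
                        L2 = sum(a * a for a in ax)
                        p = [cx - c0[0], cy - c0[1], cz - c0[2]]
                        t = sum(p[q] * ax[q] for q in range(3)) / L2
                        d2 = sum((p[q] - t * ax[q]) ** 2 for q in range(3))
                        if 0.0 <= t <= 1.0 and d2 <= r * r:
                            labels[i, j, k] = spec["Tag"]
                    elif kind in ("XLayers", "YLayers", "ZLayers"):
                        axis = {"XLayers": 0, "YLayers": 1, "ZLayers": 2}[kind]
                        idx = (i, j, k)[axis]
                        for start, end, tag in spec:
                            if start <= idx <= end:
                                labels[i, j, k] = tag
    return labels


def sphere_center_count(center, radius, dim):
    """Count voxel centers strictly closer than radius (analytic cross-check)."""
    n = 0
    for i in range(dim[0]):
        for j in range(dim[1]):
            for k in range(dim[2]):
                d2 = (
                    (i + 0.5 - center[0]) ** 2
                    + (j + 0.5 - center[1]) ** 2
                    + (k + 0.5 - center[2]) ** 2
                )
                if d2 <= radius * radius:
                    n += 1
    return n


def snell_angle_deg(n1, n2, theta_in_deg):
    return math.degrees(math.asin(n1 * math.sin(math.radians(theta_in_deg)) / n2))
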