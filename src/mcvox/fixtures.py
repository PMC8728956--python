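"""Built-in scene generators used by examples, tests and the CLI.

Each fixture is a complete, schema-valid input document.  Optical
properties are representative of soft tissue at near-infrared wavelengths
(absorption of order 0.005–0.05 mm⁻¹, scattering 1–10 mm⁻¹, anisotropy
0.9); the ``infinite_cyclic`` fixture reproduces the classic
diffusion-validation condition μa = 0.005 mm⁻¹, μs = 10 mm⁻¹, g = 0.9,
n = 1 (μs′ = 1 mm⁻¹) on a 60³ grid of 1-mm voxels with cyclic faces and
an isotropic point source at the centre, run time-window 2 ns (which
captures >98% of the CW fluence out to r = 15 mm).
"""

from __future__ import annotations

import copy

__all__ = ["make_fixture", "FIXTURE_KINDS"]

_AMBIENT = {"mua": 0.0, "mus": 0.0, "g": 1.0, "n": 1.0}

_FIXTURES = {
    "homogeneous_cube": {
        "Session": {"ID": "homogeneous_cube", "Photons": 100000, "RNGSeed": 1},
        "Forward": {"T0": 0.0, "T1": 1e-9, "Dt": 1e-9},
        "Optode": {
            "Source": {"Type": "pencil", "Pos": [30.0, 30.0, 0.0], "Dir": [0.0, 0.0, 1.0]},
            "Detector": [{"Pos": [30.0, 34.0, 0.0], "R": 2.0}],
        },
        "Domain": {
            "Dim": [60, 60, 60],
            "Media": [_AMBIENT, {"mua": 0.01, "mus": 1.0, "g": 0.9, "n": 1.0}],
        },
        "Shapes": [{"Grid": {"Tag": 1, "Size": [60, 60, 60]}}],
    },
    "layered_slab": {
        "Session": {"ID": "layered_slab", "Photons": 100000, "RNGSeed": 1},
        "Forward": {"T0": 0.0, "T1": 1e-9, "Dt": 1e-9},
        "Optode": {
            "Source": {"Type": "pencil", "Pos": [30.0, 30.0, 0.0], "Dir": [0.0, 0.0, 1.0]},
            "Detector": [{"Pos": [30.0, 34.0, 0.0], "R": 2.0}],
        },
        "Domain": {
            "Dim": [60, 60, 60],
            "Media": [
                _AMBIENT,
                {"mua": 0.01, "mus": 5.0, "g": 0.9, "n": 1.0},
                {"mua": 0.02, "mus": 7.0, "g": 0.9, "n": 1.0},
                {"mua": 0.005, "mus": 4.0, "g": 0.9, "n": 1.0},
            ],
        },
        "Shapes": [
            {"Grid": {"Tag": 1, "Size": [60, 60, 60]}},
            {"ZLayers": [[0, 19, 1], [20, 39, 2], [40, 59, 3]]},
        ],
    },
    "embedded_sphere": {
        "Session": {"ID": "embedded_sphere", "Photons": 100000, "RNGSeed": 1},
        "Forward": {"T0": 0.0, "T1": 1e-9, "Dt": 1e-9},
        "Optode": {
            "Source": {"Type": "pencil", "Pos": [30.0, 30.0, 0.0], "Dir": [0.0, 0.0, 1.0]},
            "Detector": [{"Pos": [30.0, 34.0, 0.0], "R": 2.0}],
        },
        "Domain": {
            "Dim": [60, 60, 60],
            "Media": [
                _AMBIENT,
                {"mua": 0.01, "mus": 5.0, "g": 0.9, "n": 1.0},
                {"mua": 0.05, "mus": 10.0, "g": 0.9, "n": 1.0},
            ],
        },
        "Shapes": [
            {"Grid": {"Tag": 1, "Size": [60, 60, 60]}},
            {"Sphere": {"Tag": 2, "O": [30.0, 30.0, 30.0], "R": 10.0}},
        ],
    },
    "infinite_cyclic": {
        "Session": {"ID": "infinite_cyclic", "Photons": 1000000, "RNGSeed": 1},
        "Forward": {"T0": 0.0, "T1": 2e-9, "Dt": 2e-9},
        "Optode": {
            "Source": {
                "Type": "isotropic",
                "Pos": [30.0, 30.0, 30.0],
                "Dir": [0.0, 0.0, 1.0],
            },
        },
        "Domain": {
            "Dim": [60, 60, 60],
            "Media": [_AMBIENT, {"mua": 0.005, "mus": 10.0, "g": 0.9, "n": 1.0}],
            "Boundary": {f: "cyclic" for f in ("x0", "x1", "y0", "y1", "z0", "z1")},
        },
        "Shapes": [{"Grid": {"Tag": 1, "Size": [60, 60, 60]}}],
    },
    # ballistic Beer-Lambert check: no scattering, 10-mm straight path
    "ballistic_slab": {
        "Session": {"ID": "ballistic_slab", "Photons": 1000, "RNGSeed": 1},
        "Forward": {"T0": 0.0, "T1": 1e-9, "Dt": 1e-9},
        "Optode": {
            "Source": {"Type": "pencil", "Pos": [30.0, 30.0, 0.0], "Dir": [0.0, 0.0, 1.0]},
        },
        "Domain": {
            "Dim": [60, 60, 10],
            "Media": [_AMBIENT, {"mua": 0.1, "mus": 0.0, "g": 1.0, "n": 1.0}],
        },
        "Shapes": [{"Grid": {"Tag": 1, "Size": [60, 60, 10]}}],
    },
}

FIXTURE_KINDS = tuple(_FIXTURES)


def make_fixture(kind: str, photons: int | None = None, seed: int | None = None) -> dict:
    """Return a fresh input document for one of the built-in scenes."""
    try:
        doc = copy.deepcopy(_FIXTURES[kind])
    except KeyError:
        raise ValueError(
            f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}"
        ) from None
    if photons is not None:
        doc["Session"]["Photons"] = int(photons)
    if seed is not None:
        doc["Session"]["RNGSeed"] = int(seed)
    return doc
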