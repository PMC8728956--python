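"""Transport kernel behaviour on constructed scenes: Beer–Lambert decay,
chord-exact voxel traversal, boundary conditions, interfaces, time gating,
energy bookkeeping and determinism."""

import math

import numpy as np
import pytest

import mcvox
from mcvox.kernel import C0_MM_S, transport_run


def _doc(dim=(60, 60, 60), media=None, shapes=None, source=None, detectors=None,
         boundary=None, t1=1e-9, dt=None, photons=1000, mismatch=False):
    media = media or [{"mua": 0.0, "mus": 0.0, "g": 1.0, "n": 1.0},
                      {"mua": 0.1, "mus": 0.0, "g": 1.0, "n": 1.0}]
    doc = {
        "Session": {"Photons": photons, "RNGSeed": 1, "DoMismatch": mismatch},
        "Forward": {"T0": 0.0, "T1": t1, "Dt": dt or t1},
        "Optode": {
            "Source": source
            or {"Type": "pencil", "Pos": [30.0, 30.0, 0.0], "Dir": [0.0, 0.0, 1.0]},
        },
        "Domain": {"Dim": list(dim), "Media": media},
        "Shapes": shapes or [{"Grid": {"Tag": 1, "Size": list(dim)}}],
    }
    if detectors:
        doc["Optode"]["Detector"] = detectors
    if boundary:
        doc["Domain"]["Boundary"] = boundary
    return doc


def _run(doc, **kw):
    return mcvox.run_simulation(mcvox.parse_config(doc), **kw)


def _balance(acct):
    return abs(
        acct["launched"]
        - acct["absorbed"]
        - acct["escaped"]
        - acct["terminated_in_flight"]
    ) / acct["launched"]


def test_beer_lambert_exact_through_10mm():
    doc = _doc(dim=(60, 60, 10), photons=200)
    res = _run(doc, normalize=False)
    a = res.accounting
    assert abs(a["escaped"] / a["launched"] - math.exp(-1.0)) < 1e-6
    assert abs(a["absorbed"] / a["launched"] - (1 - math.exp(-1.0))) < 1e-6
    assert _balance(a) < 1e-12


def test_oblique_chord_length_recorded_exactly():
    # ballistic path at an angle crossing many voxel boundaries: the sum of
    # DDA segment lengths must equal the Euclidean chord
    d = np.array([1.0, 0.0, 2.0]) / math.sqrt(5.0)
    doc = _doc(
        dim=(60, 60, 10),
        photons=50,
        source={"Type": "pencil", "Pos": [20.0, 20.0, 0.0], "Dir": list(d)},
        detectors=[{"Pos": [25.0, 20.0, 10.0], "R": 1.0}],
    )
    res = _run(doc, normalize=False)
    assert res.detected.shape[0] == 50
    chord = 10.0 / d[2]
    np.testing.assert_allclose(res.detected[:, 1], chord, rtol=1e-9)


def test_zero_absorption_conserves_weight_in_mirror_box():
    media = [{"mua": 0, "mus": 0, "g": 1, "n": 1},
             {"mua": 0.0, "mus": 1.0, "g": 0.9, "n": 1.0}]
    doc = _doc(
        media=media,
        photons=500,
        boundary={f: "mirror" for f in ("x0", "x1", "y0", "y1", "z0", "z1")},
    )
    res = _run(doc, normalize=False)
    a = res.accounting
    assert a["absorbed"] == 0.0
    assert a["escaped"] == 0.0
    assert abs(a["terminated_in_flight"] - a["launched"]) < 1e-9
    # pathlength estimator: total recorded path = c * t1 per unit weight
    np.testing.assert_allclose(res.raw.sum(), a["launched"] * C0_MM_S * 1e-9, rtol=1e-9)


def test_cyclic_faces_wrap_without_loss():
    media = [{"mua": 0, "mus": 0, "g": 1, "n": 1},
             {"mua": 0.05, "mus": 0.0, "g": 1.0, "n": 1.0}]
    doc = _doc(
        media=media,
        photons=100,
        boundary={f: "cyclic" for f in ("x0", "x1", "y0", "y1", "z0", "z1")},
    )
    res = _run(doc, normalize=False)
    a = res.accounting
    assert a["escaped"] == 0.0
    # ballistic wrap-around path of c*t1 mm with continuous attenuation
    expected = 1.0 - math.exp(-0.05 * C0_MM_S * 1e-9)
    assert abs(a["absorbed"] / a["launched"] - expected) < 1e-9


def test_label_zero_voxels_terminate_photons():
    shapes = [
        {"Grid": {"Tag": 1, "Size": [60, 60, 60]}},
        {"ZLayers": [[30, 59, 0]]},  # upper half is background
    ]
    media = [{"mua": 0, "mus": 0, "g": 1, "n": 1},
             {"mua": 0.0, "mus": 0.0, "g": 1.0, "n": 1.0}]
    doc = _doc(media=media, shapes=shapes, photons=50,
               detectors=[{"Pos": [30.0, 30.0, 30.0], "R": 1.0}])
    res = _run(doc, normalize=False)
    assert res.accounting["escaped"] == res.accounting["launched"]
    assert res.detected.shape[0] == 50
    from mcvox.output import detected_columns

    zcol = detected_columns(res.config).index("exit_z")
    np.testing.assert_allclose(res.detected[:, zcol], 30.0)


def test_launch_outside_advances_to_entry_with_specular_loss():
    media = [{"mua": 0, "mus": 0, "g": 1, "n": 1},
             {"mua": 1.0, "mus": 0.0, "g": 1.0, "n": 1.5}]
    doc = _doc(
        media=media,
        photons=400,
        source={"Type": "pencil", "Pos": [30.0, 30.0, -10.0], "Dir": [0.0, 0.0, 1.0]},
        mismatch=True,
        t1=2e-9,
    )
    res = _run(doc, normalize=False)
    a = res.accounting
    # normal-incidence specular reflection (n 1.0 -> 1.5) is deterministic:
    r = ((1.5 - 1.0) / (1.5 + 1.0)) ** 2
    assert abs(a["escaped"] / a["launched"] - r) < 1e-9  # interior absorbs the rest
    assert _balance(a) < 1e-12


def test_internal_index_step_reflects_fresnel_fraction():
    shapes = [
        {"Grid": {"Tag": 1, "Size": [60, 60, 60]}},
        {"ZLayers": [[30, 59, 2]]},
    ]
    media = [
        {"mua": 0, "mus": 0, "g": 1, "n": 1},
        {"mua": 0.0, "mus": 0.0, "g": 1.0, "n": 1.0},
        {"mua": 0.0, "mus": 0.0, "g": 1.0, "n": 1.5},
    ]
    doc = _doc(
        media=media, shapes=shapes, photons=100000, mismatch=True, t1=2e-9,
        detectors=[{"Pos": [30.0, 30.0, 0.0], "R": 1.0}],
    )
    res = _run(doc, normalize=False)
    r = ((1.5 - 1.0) / (1.5 + 1.0)) ** 2
    n = 100000
    frac = res.detected.shape[0] / n
    assert abs(frac - r) < 4 * math.sqrt(r * (1 - r) / n)


def test_time_gate_partition_sums_to_single_gate():
    doc1 = _doc(media=[{"mua": 0, "mus": 0, "g": 1, "n": 1},
                       {"mua": 0.01, "mus": 1.0, "g": 0.9, "n": 1.0}],
                photons=2000)
    doc5 = {**doc1, "Forward": {"T0": 0.0, "T1": 1e-9, "Dt": 2e-10}}
    r1 = _run(doc1, normalize=False)
    r5 = _run(doc5, normalize=False)
    assert r5.raw.shape[3] == 5
    np.testing.assert_allclose(r5.raw.sum(axis=3), r1.raw[:, :, :, 0], rtol=1e-12, atol=1e-12)


def test_seed_determinism_bitwise():
    cfg = mcvox.parse_config(mcvox.make_fixture("homogeneous_cube", photons=5000))
    vol = mcvox.build_volume(cfg)
    f1, d1, a1 = transport_run(cfg, vol)
    f2, d2, a2 = transport_run(cfg, vol)
    assert np.array_equal(f1, f2)
    assert np.array_equal(d1, d2)
    assert a1 == a2
    f3, _, _ = transport_run(cfg, vol, seed=99)
    assert not np.array_equal(f1, f3)


def test_energy_balance_closes_on_scattering_scene():
    cfg = mcvox.parse_config(mcvox.make_fixture("embedded_sphere", photons=20000))
    res = mcvox.run_simulation(cfg, normalize=False)
    assert _balance(res.accounting) < 1e-6


def test_continuous_property_volume_matches_label_volume():
    # per-voxel (mua, mus) float domain equivalent to a homogeneous label run
    from mcvox import jdata

    dim = (20, 20, 20)
    base = _doc(dim=dim, photons=3000,
                media=[{"mua": 0, "mus": 0, "g": 1, "n": 1},
                       {"mua": 0.02, "mus": 2.0, "g": 0.9, "n": 1.0}])
    r_label = _run(base, normalize=False)
    props = np.zeros(dim + (2,), dtype=np.float32)
    props[..., 0] = 0.02
    props[..., 1] = 2.0
    doc_f = {k: v for k, v in base.items() if k != "Shapes"}
    doc_f["Domain"] = dict(base["Domain"])
    doc_f["Domain"]["MediaFormat"] = "muamus_float"
    doc_f["Domain"]["Volume"] = jdata.encode_ndarray(props)
    r_float = _run(doc_f, normalize=False)
    np.testing.assert_allclose(
        r_float.raw.sum(), r_label.raw.sum(), rtol=1e-6
    )
    assert _balance(r_float.accounting) < 1e-9
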