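"""Launch sampling: geometry containment, moments, weights, focusing."""

import math

import numpy as np
import pytest

import mcvox
from mcvox import jdata
from mcvox.scene import SourceCfg


def _src(type_, pos=(10, 10, 0), dir_=(0, 0, 1), p1=(0, 0, 0, 0), p2=(0, 0, 0, 0),
         focus=None, phase=0.0, pattern=None):
    d = np.asarray(dir_, dtype=float)
    return SourceCfg(
        type=type_,
        pos=np.asarray(pos, dtype=float),
        dir=d / np.linalg.norm(d),
        param1=np.asarray(p1, dtype=float),
        param2=np.asarray(p2, dtype=float),
        focus=focus,
        phase=phase,
        pattern=pattern,
    )


def _draws(src, n, seed=3):
    rng = mcvox.PhotonRNG(seed)
    return [mcvox.sample_launch(src, rng) for _ in range(n)]


def test_pencil_is_deterministic_delta():
    src = _src("pencil", pos=(30, 30, 0))
    for s in _draws(src, 5, seed=11):
        np.testing.assert_array_equal(s.pos, [30, 30, 0])
        np.testing.assert_array_equal(s.dir, [0, 0, 1])
        assert s.weight == 1.0 and s.t == 0.0


def test_isotropic_moments_match_uniform_sphere():
    n = 20000
    dirs = np.array([s.dir for s in _draws(_src("isotropic"), n)])
    np.testing.assert_allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-9)
    # each component: mean 0 (sigma = 1/sqrt(3n)); z^2: mean 1/3
    assert np.all(np.abs(dirs.mean(axis=0)) < 4 / math.sqrt(3 * n))
    var_sigma = math.sqrt(4.0 / 45.0 / n)  # Var(z^2) = 4/45 on the sphere
    assert abs((dirs[:, 2] ** 2).mean() - 1.0 / 3.0) < 4 * var_sigma


def test_cone_contained_in_half_angle():
    half = 0.3
    src = _src("cone", p1=(half, 0, 0, 0))
    dirs = np.array([s.dir for s in _draws(src, 3000)])
    assert np.all(dirs[:, 2] >= math.cos(half) - 1e-12)
    assert dirs[:, 2].min() < math.cos(half * 0.5)  # actually spreads


def test_planar_samples_inside_patch():
    src = _src("planar", p1=(6, 0, 0, 0), p2=(0, 4, 0, 0))
    for s in _draws(src, 2000):
        u = (s.pos[0] - 10) / 6
        v = (s.pos[1] - 10) / 4
        assert 0 <= u < 1 and 0 <= v < 1 and s.pos[2] == 0
        np.testing.assert_array_equal(s.dir, [0, 0, 1])


def test_disk_radius_and_plane():
    src = _src("disk", p1=(5, 0, 0, 0))
    pts = np.array([s.pos for s in _draws(src, 3000)])
    r = np.linalg.norm(pts[:, :2] - [10, 10], axis=1)
    assert np.all(r <= 5 + 1e-12)
    assert np.all(np.abs(pts[:, 2]) < 1e-12)
    # uniform disk: E[r^2] = R^2/2
    assert abs((r**2).mean() - 12.5) < 4 * np.std(r**2) / math.sqrt(len(r))


def test_gaussian_waist_second_moment():
    w0 = 2.0
    src = _src("gaussian", p1=(w0, 0, 0, 0))
    pts = np.array([s.pos for s in _draws(src, 20000)])
    r2 = ((pts[:, :2] - [10, 10]) ** 2).sum(axis=1)
    # intensity ~ exp(-2 r^2/w0^2): E[r^2] = w0^2/2
    assert abs(r2.mean() - w0**2 / 2) < 4 * r2.std() / math.sqrt(len(r2))


def test_fourier_mean_weight_is_half():
    src = _src("fourier", p1=(1, 0, 0, 1.0), p2=(0, 1, 0, 0.0))
    w = np.array([s.weight for s in _draws(src, 20000)])
    assert np.all((w >= 0) & (w <= 1))
    # mean over u of (1+cos 2pi u)/2 = 1/2; sd of one draw = sqrt(1/8)
    assert abs(w.mean() - 0.5) < 4 * math.sqrt(1 / 8 / len(w))


def test_fourier_phase_shifts_pattern():
    n = 20000
    w0 = np.array([s.weight for s in _draws(_src("fourier", p1=(1, 0, 0, 1.0), p2=(0, 1, 0, 0)), n)])
    wpi = np.array([s.weight for s in _draws(_src("fourier", p1=(1, 0, 0, 1.0), p2=(0, 1, 0, 0), phase=math.pi), n)])
    # same mean, but anticorrelated spatial structure; check means only
    assert abs(w0.mean() - wpi.mean()) < 0.02


def test_pattern_weight_follows_cell_value():
    pat = np.array([[0.25, 1.0], [2.0, 0.5]])
    src = _src("pattern", p1=(4, 0, 0, 0), p2=(0, 4, 0, 0), pattern=pat)
    for s in _draws(src, 500):
        iu = int((s.pos[0] - 10) / 4 * 2)
        iv = int((s.pos[1] - 10) / 4 * 2)
        assert s.weight == pat[iu, iv]


def test_line_samples_on_segment():
    src = _src("line", p1=(8, 2, 0, 0))
    for s in _draws(src, 500):
        u = (s.pos[0] - 10) / 8
        assert 0 <= u < 1
        np.testing.assert_allclose(s.pos[1], 10 + 2 * u, atol=1e-12)


def test_focus_converges_rays_to_focal_point():
    f = 25.0
    src = _src("planar", p1=(6, 0, 0, 0), p2=(0, 4, 0, 0), focus=f)
    center = np.array([10 + 3, 10 + 2, 0.0])
    focal = center + f * np.array([0, 0, 1.0])
    for s in _draws(src, 300):
        # advance the ray to the focal plane; it must pass through the point
        tau = (focal[2] - s.pos[2]) / s.dir[2]
        hit = s.pos + tau * s.dir
        np.testing.assert_allclose(hit, focal, atol=1e-9)


def test_negative_focus_diverges_from_virtual_point():
    f = -25.0
    src = _src("planar", p1=(6, 0, 0, 0), p2=(0, 4, 0, 0), focus=f)
    virtual = np.array([13.0, 12.0, 0.0]) + f * np.array([0, 0, 1.0])
    for s in _draws(src, 300):
        v = s.pos - virtual
        np.testing.assert_allclose(s.dir, v / np.linalg.norm(v), atol=1e-9)
        assert s.dir[2] > 0


def test_infinite_focus_is_collimated():
    src = _src("planar", p1=(6, 0, 0, 0), p2=(0, 4, 0, 0), focus=math.inf)
    sample = _draws(src, 1)[0]
    np.testing.assert_array_equal(sample.dir, [0, 0, 1])
    refocused = mcvox.apply_focus(sample, math.inf, src)
    np.testing.assert_array_equal(refocused.dir, sample.dir)


def test_apply_focus_matches_inline_focusing():
    src_plain = _src("disk", p1=(5, 0, 0, 0))
    src_foc = _src("disk", p1=(5, 0, 0, 0), focus=30.0)
    s = _draws(src_plain, 1, seed=9)[0]
    s2 = _draws(src_foc, 1, seed=9)[0]
    np.testing.assert_allclose(mcvox.apply_focus(s, 30.0, src_plain).dir, s2.dir, atol=1e-12)


def test_unit_weight_sources_launch_exactly_n():
    for t, kw in [("pencil", {}), ("isotropic", {}), ("disk", {"p1": (3, 0, 0, 0)})]:
        total = sum(s.weight for s in _draws(_src(t, **kw), 200))
        assert total == 200.0


def test_degenerate_geometries_rejected():
    with pytest.raises(ValueError):
        mcvox.sample_launch(_src("planar"), mcvox.PhotonRNG(1))  # zero-area patch
    with pytest.raises(ValueError):
        mcvox.sample_launch(_src("disk"), mcvox.PhotonRNG(1))
    with pytest.raises(ValueError):
        mcvox.sample_launch(_src("pattern", p1=(4, 0, 0, 0), p2=(0, 4, 0, 0)), mcvox.PhotonRNG(1))


def test_pattern_decoded_from_jdata_in_config(cube_config):
    doc = mcvox.make_fixture("homogeneous_cube")
    pat = np.array([[1.0, 0.5], [0.0, 2.0]])
    doc["Optode"]["Source"] = {
        "Type": "pattern",
        "Pos": [20.0, 20.0, 0.0],
        "Dir": [0.0, 0.0, 1.0],
        "Param1": [8.0, 0, 0, 0],
        "Param2": [0, 8.0, 0, 0],
        "Pattern": jdata.encode_ndarray(pat),
    }
    cfg = mcvox.parse_config(doc)
    np.testing.assert_array_equal(cfg.source.pattern, pat)
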