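"""Integration and cuts against brute-force per-pixel oracles.

The oracles re-implement the binning contract directly with Python loops:
half-open bins [lo, hi), last bin closed, pixel-center assignment, masked
pixels excluded — so any divergence in the vectorized path is caught.
"""

import numpy as np
import pytest

from scatterkit.corrections import from_frame
from scatterkit.geometry import build_qmap
from scatterkit.image_io import Frame
from scatterkit.profiles import (Curve, azimuthal_profile, gisaxs_cut,
                                 radial_profile, roi_stats)


def _loop_bin_means(coord, data, good, edges):
    """Brute-force binning oracle shared by all profile tests."""
    nb = len(edges) - 1
    sums = np.zeros(nb)
    counts = np.zeros(nb, dtype=int)
    for value, c, ok in zip(data.ravel(), coord.ravel(), good.ravel()):
        if not ok:
            continue
        if c < edges[0] or c > edges[-1]:
            continue
        b = nb - 1 if c == edges[-1] else int(np.searchsorted(edges, c, side="right")) - 1
        sums[b] += value
        counts[b] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts


def test_uniform_image_gives_constant_profile(saxs_geom):
    frame = Frame(data=np.full((64, 64), 3.25))
    qmap = build_qmap((64, 64), saxs_geom)
    curve = radial_profile(frame, qmap, 25)
    good = curve.n_pix > 0
    np.testing.assert_allclose(curve.y[good], 3.25)


def test_radial_profile_matches_smooth_function(saxs_geom):
    qmap = build_qmap((64, 64), saxs_geom)
    f = lambda q: 100.0 / (1.0 + q ** 2)
    frame = Frame(data=f(qmap.q))
    curve = radial_profile(frame, qmap, 40).dropna()
    # binning error bounded by max|f'| * binwidth
    binwidth = np.diff(curve.x).max()
    max_slope = 100.0 * 0.65  # max |d/dq (1+q^2)^-1| = 3 sqrt(3) / 8 < 0.65
    assert np.max(np.abs(curve.y - f(curve.x))) <= max_slope * binwidth


def test_radial_profile_brute_force_equivalence(random_frame, saxs_geom):
    qmap = build_qmap((64, 64), saxs_geom)
    edges = np.linspace(0.5, 10.0, 23)
    curve = radial_profile(random_frame, qmap, edges)
    means, counts = _loop_bin_means(qmap.q, random_frame.data,
                                    random_frame.mask == 0, edges)
    np.testing.assert_array_equal(curve.n_pix, counts)
    np.testing.assert_allclose(curve.y[counts > 0], means[counts > 0], rtol=1e-13)


def test_radial_profile_intensity_conservation(random_frame, saxs_geom):
    qmap = build_qmap((64, 64), saxs_geom)
    edges = np.linspace(qmap.q.min(), qmap.q.max(), 31)
    curve = radial_profile(random_frame, qmap, edges)
    lhs = np.nansum(curve.y * curve.n_pix)
    rhs = random_frame.data[random_frame.mask == 0].sum()
    assert lhs == pytest.approx(rhs, rel=1e-12)


def test_radial_chi_restriction_matches_oracle(random_frame, saxs_geom):
    qmap = build_qmap((64, 64), saxs_geom)
    edges = np.linspace(1.0, 9.0, 15)
    curve = radial_profile(random_frame, qmap, edges, chi_range=(300.0, 30.0))
    chi = qmap.chi
    sector = (chi >= 300.0) | (chi < 30.0)  # wraps through 0
    means, counts = _loop_bin_means(qmap.q, random_frame.data,
                                    (random_frame.mask == 0) & sector, edges)
    np.testing.assert_array_equal(curve.n_pix, counts)
    np.testing.assert_allclose(curve.y[counts > 0], means[counts > 0], rtol=1e-13)


def test_all_masked_selection_warns_all_nan(caplog):
    from scatterkit.geometry import ExperimentGeometry

    geom = ExperimentGeometry(wavelength=0.1, distance=500.0,
                              beam_center=(3.5, 3.5), pixel_size=(1.0, 1.0))
    mask = np.zeros((8, 8), dtype=np.uint8)
    mask[:4, :] = 1  # upper half (chi in (0, 180)) fully masked
    frame = Frame(data=np.ones((8, 8)), mask=mask)
    qmap = build_qmap((8, 8), geom)
    with caplog.at_level("WARNING"):
        curve = radial_profile(frame, qmap, 5, chi_range=(60.0, 120.0))
    assert np.isnan(curve.y).all()
    assert curve.n_pix.sum() == 0


def test_azimuthal_profile_brute_force_equivalence(random_frame, saxs_geom):
    qmap = build_qmap((64, 64), saxs_geom)
    curve = azimuthal_profile(random_frame, qmap, (2.0, 8.0), 36)
    edges = np.linspace(0, 360, 37)
    in_annulus = (qmap.q >= 2.0) & (qmap.q < 8.0)
    means, counts = _loop_bin_means(qmap.chi, random_frame.data,
                                    (random_frame.mask == 0) & in_annulus, edges)
    np.testing.assert_array_equal(curve.n_pix, counts)
    np.testing.assert_allclose(curve.y[counts > 0], means[counts > 0], rtol=1e-13)


def test_isotropic_pattern_has_flat_azimuthal_profile(sphere_frame_truth):
    frame, _, geom = sphere_frame_truth
    qmap = build_qmap(frame.data.shape, geom)
    curve = azimuthal_profile(frame, qmap, (1.0, 3.0), 24).dropna()
    rel_spread = np.std(curve.y) / np.mean(curve.y)
    assert rel_spread < 0.05  # counting noise only


def test_anisotropic_pattern_two_maxima_180_apart(aniso_frame_truth):
    frame, truth, geom = aniso_frame_truth
    qmap = build_qmap(frame.data.shape, geom)
    curve = azimuthal_profile(frame, qmap, (2.0, 4.0), 72).dropna()
    order = np.argsort(curve.y)[::-1]
    first = curve.x[order[0]]
    # best peak away from the first
    far = [x for x in curve.x[order[:12]] if 90 < abs(x - first) % 360 < 270]
    assert far, "no second maximum found"
    separation = abs(far[0] - first) % 360
    assert separation == pytest.approx(180.0, abs=10.0)


def test_empty_annulus_is_an_error(random_frame, saxs_geom):
    qmap = build_qmap((64, 64), saxs_geom)
    with pytest.raises(ValueError, match="empty annulus"):
        azimuthal_profile(random_frame, qmap, (100.0, 200.0), 36)


def test_degenerate_roi_cut_equals_single_row(gisaxs_geom):
    qmap = build_qmap((64, 80), gisaxs_geom)
    rng = np.random.default_rng(3)
    data = rng.integers(0, 100, size=(64, 80)).astype(float)
    frame = Frame(data=data)
    row = 30
    at = float(qmap.qz[row, 0])
    row_spacing = abs(qmap.qz[row - 1, 0] - qmap.qz[row, 0])
    curve = gisaxs_cut(frame, qmap, "horizontal", at=at,
                       roi_width=0.9 * row_spacing, bins="pixel")
    assert len(curve) == 80
    np.testing.assert_allclose(np.sort(curve.y), np.sort(data[row]), rtol=1e-12)


def test_gisaxs_cut_brute_force_equivalence(gisaxs_geom, rng):
    qmap = build_qmap((64, 80), gisaxs_geom)
    data = rng.integers(0, 300, size=(64, 80)).astype(float)
    mask = (rng.random((64, 80)) < 0.07).astype(np.uint8)
    frame = Frame(data=data, mask=mask)
    at, width = 0.2, 0.12
    curve = gisaxs_cut(frame, qmap, "horizontal", at=at, roi_width=width, bins=40)
    band = np.abs(qmap.qz - at) <= width / 2
    sel = band & (mask == 0)
    edges = np.linspace(qmap.qy[sel].min(), qmap.qy[sel].max(), 41)
    means, counts = _loop_bin_means(qmap.qy, data, sel, edges)
    np.testing.assert_array_equal(curve.n_pix, counts)
    np.testing.assert_allclose(curve.y[counts > 0], means[counts > 0], rtol=1e-13)


def test_vertical_cut_brute_force_equivalence(gisaxs_geom, rng):
    qmap = build_qmap((64, 80), gisaxs_geom)
    data = rng.integers(0, 300, size=(64, 80)).astype(float)
    frame = Frame(data=data)
    curve = gisaxs_cut(frame, qmap, "vertical", at=0.1, roi_width=0.08, bins=30)
    band = np.abs(qmap.qy - 0.1) <= 0.04
    edges = np.linspace(qmap.qz[band].min(), qmap.qz[band].max(), 31)
    means, counts = _loop_bin_means(qmap.qz, data, band, edges)
    np.testing.assert_array_equal(curve.n_pix, counts)
    np.testing.assert_allclose(curve.y[counts > 0], means[counts > 0], rtol=1e-13)


def test_cut_outside_detector_errors(gisaxs_geom):
    qmap = build_qmap((64, 80), gisaxs_geom)
    frame = Frame(data=np.ones((64, 80)))
    with pytest.raises(ValueError, match="selects no pixels"):
        gisaxs_cut(frame, qmap, "horizontal", at=50.0, roi_width=0.01)


def test_cut_finds_planted_side_maximum(gisaxs_geom):
    from scatterkit import synthgen

    spec = synthgen.SynthSpec(kind="g", geometry=gisaxs_geom, shape=(64, 80),
                              seed=21, background=2.0)
    manifest = None
    import tempfile
    with tempfile.TemporaryDirectory() as d:
        manifest = synthgen.gisaxs_series(spec, d, n_frames=1, qy_start=0.15,
                                          qy_end=0.15)
        from scatterkit.image_io import read_frame
        frame = read_frame(f"{d}/{manifest[0]['file']}")
    qmap = build_qmap((64, 80), gisaxs_geom)
    curve = gisaxs_cut(frame, qmap, "horizontal", at=0.2, roi_width=0.15, bins=60)
    pos = curve.x > 0.05
    argmax_x = curve.x[pos][np.nanargmax(curve.y[pos])]
    binwidth = np.diff(curve.x).max()
    assert abs(argmax_x - 0.15) <= binwidth


def test_roi_stats_constant_region():
    frame = Frame(data=np.full((10, 10), 2.0))
    s = roi_stats(frame, 2, 3, 5, 5)
    assert s.min == s.max == s.average == 2.0
    assert s.sum == 50.0
    assert s.n_pix == 25


def test_roi_stats_brute_force(random_frame):
    s = roi_stats(random_frame, 5, 7, 12, 9)
    vals = []
    for yy in range(7, 16):
        for xx in range(5, 17):
            if random_frame.mask[yy, xx] == 0:
                vals.append(random_frame.data[yy, xx])
    assert s.min == min(vals)
    assert s.max == max(vals)
    assert s.average == pytest.approx(np.mean(vals))
    assert s.sum == pytest.approx(np.sum(vals))
    assert s.min <= s.average <= s.max
    assert s.sum == pytest.approx(s.average * s.n_pix)


def test_roi_clipped_to_image(random_frame):
    s = roi_stats(random_frame, 60, 60, 20, 20)  # clipped to 4x4
    assert s.n_pix <= 16


def test_roi_errors():
    frame = Frame(data=np.ones((8, 8)))
    with pytest.raises(ValueError):
        roi_stats(frame, 20, 20, 4, 4)
    mask = np.zeros((8, 8), dtype=np.uint8)
    mask[0:4, 0:4] = 1
    frame2 = Frame(data=np.ones((8, 8)), mask=mask)
    with pytest.raises(ValueError, match="fully masked"):
        roi_stats(frame2, 0, 0, 4, 4)


def test_enlarging_mask_leaves_untouched_bins_unchanged(random_frame, saxs_geom):
    qmap = build_qmap((64, 64), saxs_geom)
    edges = np.linspace(0.5, 10.0, 21)
    base = radial_profile(random_frame, qmap, edges)
    bigger = random_frame.mask.copy()
    bigger[40, 40] = 1  # one more excluded pixel
    frame2 = Frame(data=random_frame.data, mask=bigger)
    touched_bin = int(np.searchsorted(edges, qmap.q[40, 40], side="right")) - 1
    after = radial_profile(frame2, qmap, edges)
    for b in range(20):
        if b == touched_bin:
            continue
        if base.n_pix[b] > 0:
            assert after.y[b] == base.y[b]


def test_curve_validation():
    with pytest.raises(ValueError, match="strictly increasing"):
        Curve(x=np.array([1.0, 1.0]), y=np.zeros(2), sigma=np.zeros(2),
              n_pix=np.zeros(2, int))
    with pytest.raises(ValueError, match="equal length"):
        Curve(x=np.array([1.0]), y=np.zeros(2), sigma=np.zeros(2),
              n_pix=np.zeros(2, int))
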