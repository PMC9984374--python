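import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from confspec.pamm import MergeTree
from confspec.spectra import (
    AMIDE_REGION,
    GridSpectrum,
    StickSpectrum,
    broaden,
    ensemble_average,
    hierarchical_series,
    pendry_r,
    region_report,
    smooth,
)

from _oracles import pendry_bruteforce

GRID = np.arange(500.0, 2000.5, 1.0)


def _gauss_spectrum(centers, amps, fwhm=10.0, grid=GRID):
    lines = np.column_stack([centers, amps])
    return broaden(StickSpectrum(lines), fwhm, grid)


# -- broadening --------------------------------------------------------------

def test_broaden_peak_and_half_maximum_positions():
    s = broaden(StickSpectrum([[1000.0, 1.0]]), 10.0,
                np.arange(900.0, 1100.01, 0.01))
    g = np.arange(900.0, 1100.01, 0.01)
    peak = g[np.argmax(s.intensity)]
    assert peak == pytest.approx(1000.0, abs=0.01)
    half = s.intensity.max() / 2.0
    crossings = g[np.isclose(s.intensity, half, rtol=2e-3)]
    assert np.any(np.abs(crossings - 995.0) < 0.1)
    assert np.any(np.abs(crossings - 1005.0) < 0.1)


def test_broaden_is_linear_in_lines():
    a = StickSpectrum([[800.0, 1.0], [900.0, 0.5]])
    b = StickSpectrum([[1200.0, 2.0]])
    ab = StickSpectrum(np.vstack([a.lines, b.lines]))
    ya = broaden(a, 10.0, GRID).intensity
    yb = broaden(b, 10.0, GRID).intensity
    yab = broaden(ab, 10.0, GRID).intensity
    assert np.max(np.abs(yab - (ya + yb))) <= 1e-12


def test_broaden_area_equals_intensity_sum():
    grid = np.arange(200.0, 3000.0, 0.5)
    s = StickSpectrum([[1000.0, 1.2], [1500.0, 0.3], [2000.0, 2.0]])
    y = broaden(s, 10.0, grid)
    area = np.trapezoid(y.intensity, grid)
    assert area == pytest.approx(3.5, rel=1e-4)


def test_broaden_applies_scale_factor():
    s = StickSpectrum([[1000.0, 1.0]], scale_factor=0.96)
    g = np.arange(900.0, 1010.0, 0.1)
    y = broaden(s, 10.0, g)
    assert g[np.argmax(y.intensity)] == pytest.approx(960.0, abs=0.1)


def test_broaden_empty_sticks_warns_and_is_zero():
    with pytest.warns(UserWarning, match="empty"):
        y = broaden(StickSpectrum(np.empty((0, 2))), 10.0, GRID)
    assert not np.any(y.intensity)


# -- averaging ---------------------------------------------------------------

def test_average_of_identical_spectra_is_identity():
    s = _gauss_spectrum([1000.0], [1.0])
    avg = ensemble_average([s, s, s], [0.2, 0.5, 0.3])
    assert np.allclose(avg.intensity, s.intensity, atol=1e-14)


def test_average_degenerate_weights_select_first():
    a = _gauss_spectrum([1000.0], [1.0])
    b = _gauss_spectrum([1500.0], [2.0])
    avg = ensemble_average([a, b], [1.0, 0.0])
    assert np.array_equal(avg.intensity, a.intensity)


def test_average_is_pointwise_convex_combination(rng):
    ya = rng.uniform(size=GRID.size)
    yb = rng.uniform(size=GRID.size)
    avg = ensemble_average(
        [GridSpectrum(GRID, ya), GridSpectrum(GRID, yb)], [0.7, 0.3]
    )
    assert np.allclose(avg.intensity, 0.7 * ya + 0.3 * yb, atol=1e-15)


def test_average_rejects_mismatched_grids():
    a = GridSpectrum(GRID, np.ones_like(GRID))
    b = GridSpectrum(GRID + 0.5, np.ones_like(GRID))
    with pytest.raises(ValueError, match="common grid"):
        ensemble_average([a, b], [0.5, 0.5])


def test_average_commutes_with_broadening():
    sa = StickSpectrum([[900.0, 1.0], [1300.0, 0.4]])
    sb = StickSpectrum([[1100.0, 0.8]])
    w = [0.6, 0.4]
    avg_then = ensemble_average(
        [broaden(sa, 10.0, GRID), broaden(sb, 10.0, GRID)], w
    )
    merged = StickSpectrum(
        np.vstack([
            np.column_stack([sa.lines[:, 0], w[0] * sa.lines[:, 1]]),
            np.column_stack([sb.lines[:, 0], w[1] * sb.lines[:, 1]]),
        ])
    )
    broaden_then = broaden(merged, 10.0, GRID)
    assert np.max(np.abs(avg_then.intensity - broaden_then.intensity)) <= 1e-10


# -- hierarchical series -----------------------------------------------------

def test_hierarchical_series_three_leaves_manual_oracle():
    # leaves 0,1,2 with representative energies 0.5, 0.1, 0.9;
    # merges: (0,1)->3 then (3,2)->4
    tree = MergeTree(3, [(0, 1, 1.0), (3, 2, 2.0)], [0.5, 0.1, 0.9])
    w = np.array([0.2, 0.5, 0.3])
    specs = {
        0: _gauss_spectrum([900.0], [1.0]),
        1: _gauss_spectrum([1200.0], [1.0]),
        2: _gauss_spectrum([1600.0], [1.0]),
    }
    series = hierarchical_series(tree, specs, w)
    assert len(series) == 3
    # level 3: plain ensemble average of the leaves
    lvl3 = ensemble_average([specs[0], specs[1], specs[2]], w)
    assert np.allclose(series[0].intensity, lvl3.intensity)
    # level 2: node 3 = {0,1} represented by leaf 1 (lower rep energy)
    lvl2 = ensemble_average([specs[1], specs[2]], [0.7, 0.3])
    assert np.allclose(series[1].intensity, lvl2.intensity)
    # level 1: root represented by leaf 1
    assert np.allclose(series[2].intensity, specs[1].intensity)


def test_hierarchical_series_missing_leaf_spectrum():
    tree = MergeTree(2, [(0, 1, 1.0)], [0.0, 1.0])
    with pytest.raises(ValueError, match="leaf cluster 1"):
        hierarchical_series(tree, {0: _gauss_spectrum([900.0], [1.0])},
                            [0.5, 0.5])


# -- smoothing ---------------------------------------------------------------

def test_smooth_constant_unchanged():
    s = GridSpectrum(GRID, np.full_like(GRID, 2.5))
    y = smooth(s, 10.0)
    assert np.allclose(y.intensity, 2.5, atol=1e-12)


def test_smooth_spike_conserves_mass():
    inten = np.zeros_like(GRID)
    inten[700] = 1.0
    s = GridSpectrum(GRID, inten)
    y = smooth(s, 15.0)
    assert y.intensity.max() < 1.0
    assert abs(y.intensity.sum() - 1.0) <= 1e-6


def test_smooth_matches_windowed_mean_oracle(rng):
    g = np.arange(20.0)
    vals = rng.uniform(size=20)
    s = GridSpectrum(g, vals)
    y = smooth(s, 3.0)  # 3-point moving average
    padded = np.concatenate([[vals[1]], vals, [vals[-2]]])  # reflect
    expected = np.array(
        [padded[i : i + 3].mean() for i in range(20)]
    )
    expected *= vals.sum() / expected.sum()
    assert np.allclose(y.intensity, expected, atol=1e-12)


def test_smooth_window_below_spacing_is_identity():
    s = GridSpectrum(GRID, np.sin(GRID / 100.0) ** 2)
    with pytest.warns(UserWarning, match="window"):
        y = smooth(s, 0.1)
    assert np.array_equal(y.intensity, s.intensity)


# -- Pendry reliability factor -----------------------------------------------

def test_pendry_identity_is_zero():
    s = _gauss_spectrum([900.0, 1400.0], [1.0, 0.7])
    res = pendry_r(s, s, v_oi=5.0, region=(600.0, 1800.0))
    assert res.r_p <= 1e-12


def test_pendry_disjoint_support_is_one():
    a = _gauss_spectrum([850.0], [1.0])
    b = _gauss_spectrum([1250.0], [0.6])
    res = pendry_r(a, b, v_oi=5.0, region=(600.0, 1800.0))
    assert res.r_p == pytest.approx(1.0, abs=1e-9)


@settings(deadline=None, max_examples=20)
@given(
    c1=st.floats(0.1, 40.0),
    c2=st.floats(0.1, 40.0),
)
def test_pendry_scale_invariance(c1, c2):
    a = _gauss_spectrum([900.0, 1200.0], [1.0, 0.4])
    b = _gauss_spectrum([950.0, 1150.0], [0.8, 0.9])
    r0 = pendry_r(a, b, region=(600.0, 1800.0)).r_p
    ra = GridSpectrum(a.grid, c1 * a.intensity)
    rb = GridSpectrum(b.grid, c2 * b.intensity)
    r1 = pendry_r(ra, rb, region=(600.0, 1800.0)).r_p
    assert r1 == pytest.approx(r0, abs=1e-10)


def test_pendry_is_symmetric():
    a = _gauss_spectrum([900.0, 1200.0], [1.0, 0.4])
    b = _gauss_spectrum([950.0], [0.8])
    rab = pendry_r(a, b, region=(700.0, 1500.0)).r_p
    rba = pendry_r(b, a, region=(700.0, 1500.0)).r_p
    assert rab == pytest.approx(rba, abs=1e-12)


def test_pendry_matches_bruteforce_formula():
    a = _gauss_spectrum([1000.0], [1.0])
    b = _gauss_spectrum([1015.0], [1.0])
    res = pendry_r(a, b, v_oi=5.0, region=(900.0, 1100.0))
    mask = (GRID >= 900.0) & (GRID <= 1100.0)
    expected = pendry_bruteforce(
        GRID[mask], a.intensity[mask], b.intensity[mask], 5.0
    )
    assert res.r_p == pytest.approx(expected, abs=1e-12)
    assert res.r_p > 0.0


def test_pendry_rejects_zero_spectra():
    z = GridSpectrum(GRID, np.zeros_like(GRID))
    with pytest.raises(ValueError):
        pendry_r(z, z, region=(600.0, 1800.0))


# -- region report -----------------------------------------------------------

def _wide_spectrum(extra_high=0.0):
    grid = np.arange(500.0, 4000.5, 1.0)
    lines = [[800.0, 1.0], [1650.0, 0.8], [3000.0, 0.5 + extra_high]]
    return broaden(StickSpectrum(np.array(lines)), 10.0, grid)


def test_region_report_identical_both_zero():
    s = _wide_spectrum()
    results = region_report(s, s)
    assert [r.r_p for r in results] == [0.0, 0.0]
    assert results[0].region == AMIDE_REGION
    assert results[1].region == (2700.0, 3600.0)


def test_region_report_localises_differences():
    a = _wide_spectrum()
    b = _wide_spectrum(extra_high=0.4)
    low, high = region_report(a, b)
    assert low.r_p <= 1e-12  # spectra only differ above 2700
    assert high.r_p > 0.0


def test_region_report_composes_from_pendry_r():
    a = _wide_spectrum()
    b = _wide_spectrum(extra_high=0.2)
    results = region_report(a, b, v_oi=4.0)
    for res in results:
        direct = pendry_r(a, b, v_oi=4.0, region=res.region)
        assert res.r_p == pytest.approx(direct.r_p, abs=1e-14)


def test_region_outside_grid_is_an_error():
    s = _gauss_spectrum([1000.0], [1.0])  # grid only reaches 2000
    with pytest.raises(ValueError):
        pendry_r(s, s, region=(2700.0, 3600.0))
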