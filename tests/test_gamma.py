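import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree

from linacvsm.gamma import (
    Plane2D,
    PlaneError,
    extract_profile,
    gamma_analysis,
    read_plane,
    write_plane,
)


def _field_plane(nx=48, ny=48, spacing=1.0, fwhm=30.0):
    """A smooth square-field-like dose plane: flat core, soft penumbra."""
    p = Plane2D.centered(np.zeros((ny, nx)), (spacing, spacing))
    X, Y = np.meshgrid(p.x, p.y)
    vals = 1.0 / ((1 + np.exp((np.abs(X) - fwhm / 2) / 2.5))
                  * (1 + np.exp((np.abs(Y) - fwhm / 2) / 2.5)))
    return Plane2D(vals * 100.0, p.spacing, p.origin)


def brute_force_gamma(ref, ev, dose_pct, dist_mm, threshold_pct=10.0):
    """Exhaustive gamma oracle: densely upsample the evaluated plane and
    take the true minimum over all points within the search radius."""
    step = 0.1 * dist_mm
    fx = np.clip(np.arange(ev.x.min(), ev.x.max() + step / 2, step), ev.x.min(), ev.x.max())
    fy = np.clip(np.arange(ev.y.min(), ev.y.max() + step / 2, step), ev.y.min(), ev.y.max())
    interp = RegularGridInterpolator((ev.y, ev.x), ev.values)
    FX, FY = np.meshgrid(fx, fy)
    pts = np.column_stack([FX.ravel(), FY.ravel()])
    dose = interp(np.column_stack([pts[:, 1], pts[:, 0]]))
    tree = cKDTree(pts)
    ref_max = ref.values.max()
    ddmax = dose_pct / 100.0 * ref_max
    out = np.full(ref.values.shape, np.nan)
    X, Y = np.meshgrid(ref.x, ref.y)
    radius = 3.0 * dist_mm
    for iy in range(ref.values.shape[0]):
        for ix in range(ref.values.shape[1]):
            d0 = ref.values[iy, ix]
            if d0 < threshold_pct / 100.0 * ref_max:
                continue
            idx = tree.query_ball_point([X[iy, ix], Y[iy, ix]], radius)
            if not idx:
                continue
            idx = np.asarray(idx)
            dd = (dose[idx] - d0) / ddmax
            rr = np.linalg.norm(pts[idx] - [X[iy, ix], Y[iy, ix]], axis=1) / dist_mm
            out[iy, ix] = np.sqrt(np.min(dd**2 + rr**2))
    return out


def test_identical_planes_pass_perfectly():
    p = _field_plane()
    res = gamma_analysis(p, p, 3.0, 1.0)
    assert res.pass_rate == 100.0
    assert np.nanmax(res.gamma) == pytest.approx(0.0, abs=1e-12)


def test_half_millimetre_shift_within_dta():
    p = _field_plane()
    shifted = Plane2D(p.values, p.spacing, (p.origin[0] + 0.5, p.origin[1]))
    res = gamma_analysis(p, shifted, 3.0, 1.0)
    assert res.pass_rate == 100.0


def test_flat_plane_scaled_ten_percent_fails():
    vals = np.full((40, 40), 50.0)
    ref = Plane2D.centered(vals, (1.0, 1.0))
    ev = Plane2D.centered(vals * 1.10, (1.0, 1.0))
    res = gamma_analysis(ref, ev, 3.0, 1.0)
    # no gradient anywhere: the 10% dose error cannot be rescued by DTA
    assert res.pass_rate == 0.0


def test_matches_brute_force_oracle():
    ref = _field_plane(nx=48, ny=48)
    rng = np.random.default_rng(12)
    ev = Plane2D(ref.values * (1.0 + rng.normal(0, 0.02, ref.values.shape)),
                 ref.spacing, (ref.origin[0] + 0.4, ref.origin[1] - 0.3))
    res = gamma_analysis(ref, ev, 3.0, 1.0)
    oracle = brute_force_gamma(ref, ev, 3.0, 1.0)
    both = np.isfinite(res.gamma) & np.isfinite(oracle)
    assert both.sum() > 100
    assert np.abs(res.gamma - oracle)[both].max() < 0.01


def test_pass_rate_monotone_in_criteria():
    ref = _field_plane()
    rng = np.random.default_rng(3)
    ev = Plane2D(ref.values * (1.0 + rng.normal(0, 0.03, ref.values.shape)),
                 ref.spacing, ref.origin)
    r_tight = gamma_analysis(ref, ev, 2.0, 1.0).pass_rate
    r_dose = gamma_analysis(ref, ev, 4.0, 1.0).pass_rate
    r_dist = gamma_analysis(ref, ev, 2.0, 2.0).pass_rate
    assert r_dose >= r_tight
    assert r_dist >= r_tight


def test_threshold_excludes_low_dose_pixels():
    p = _field_plane()
    res = gamma_analysis(p, p, 3.0, 1.0, threshold_pct=10.0)
    below = p.values < 0.10 * p.values.max()
    assert np.all(np.isnan(res.gamma[below]))
    assert res.n_evaluated == int((~below).sum())


def test_non_overlapping_planes_rejected():
    a = Plane2D(np.ones((10, 10)), (1.0, 1.0), (0.0, 0.0))
    b = Plane2D(np.ones((10, 10)), (1.0, 1.0), (1000.0, 1000.0))
    with pytest.raises(PlaneError, match="overlap"):
        gamma_analysis(a, b, 3.0, 1.0)


def test_all_below_threshold_rejected():
    a = Plane2D(np.ones((10, 10)), (1.0, 1.0))
    b = Plane2D(np.ones((10, 10)), (1.0, 1.0))
    with pytest.raises(PlaneError):
        gamma_analysis(a, b, 3.0, 1.0, threshold_pct=200.0)


def test_profile_extraction_symmetry_and_identity():
    p = _field_plane()
    coords, vals = extract_profile(p, "x", 0.0)
    np.testing.assert_allclose(vals, vals[::-1], rtol=1e-12)
    iy = int(np.argmin(np.abs(p.y)))
    np.testing.assert_array_equal(vals, p.values[iy, :])
    const = Plane2D.centered(np.full((5, 5), 2.0), (1.0, 1.0))
    _, cv = extract_profile(const, "y", 0.0)
    np.testing.assert_array_equal(cv, 2.0)


def test_profile_position_outside_rejected():
    p = _field_plane()
    with pytest.raises(PlaneError):
        extract_profile(p, "x", 1e4)


def test_plane_io_round_trip(tmp_path):
    p = _field_plane(nx=12, ny=9, spacing=2.0)
    f = tmp_path / "plane.txt"
    write_plane(p, f)
    back = read_plane(f)
    np.testing.assert_allclose(back.values, p.values, rtol=1e-8)
    assert back.spacing == p.spacing
    assert back.origin == pytest.approx(p.origin)


def test_headerless_plane_needs_spacing(tmp_path):
    f = tmp_path / "raw.txt"
    np.savetxt(f, np.ones((4, 4)))
    with pytest.raises(PlaneError, match="spacing"):
        read_plane(f)
    p = read_plane(f, spacing=(2.0, 2.0))
    assert p.values.shape == (4, 4)
    assert p.origin == (-3.0, -3.0)
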