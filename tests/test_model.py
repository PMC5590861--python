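import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import linacvsm as lv
from linacvsm.model import (
    ModelBuildError,
    PolySurface,
    build_direction_grid,
    build_energy_model,
    build_radial_model,
    build_vsm,
    determine_primary_region,
    energy_bin_index,
    fit_direction_surfaces,
    fit_poly_surface,
)
from linacvsm.phsp import ParticleSet
from linacvsm.synthetic import SyntheticBeamParams, make_synthetic_phsp


def _photon_set(x, y, vx, vy, e=None):
    n = len(x)
    e = np.ones(n) if e is None else np.asarray(e, float)
    return ParticleSet(np.ones(n, int), e, x, y, vx, vy, validate=False)


# ---------------------------------------------------------------------------
# radial model
# ---------------------------------------------------------------------------

def test_radial_model_degenerate_constant():
    n = 2000
    ps = _photon_set(np.full(n, 5.0), np.zeros(n), np.zeros(n), np.zeros(n))
    m = build_radial_model(ps)
    u = np.linspace(0, 1, 50)
    assert np.all(np.abs(m(u) - 5.0) <= 0.05 + 1e-12)


def test_radial_model_monotone_and_bounded(synthetic_set):
    m = build_radial_model(synthetic_set)
    u = np.linspace(0, 1, 10_000)
    vals = m(u)
    assert np.all(np.diff(vals) >= 0)
    assert vals[0] >= 0
    assert vals[-1] <= m.r_max + 0.1


def test_radial_model_needs_enough_particles():
    ps = _photon_set(np.ones(10), np.zeros(10), np.zeros(10), np.zeros(10))
    with pytest.raises(ModelBuildError):
        build_radial_model(ps)


# ---------------------------------------------------------------------------
# energy model
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "r,expected",
    [(0.0, 0), (1.0, 0), (2.0, 0), (2.1, 1), (50.0, 24), (51.0, 25),
     (95.0, 33), (95.01, 34), (200.0, 34)],
)
def test_energy_bin_lookup(r, expected):
    assert energy_bin_index(r) == expected


@given(st.floats(0, 500))
def test_energy_bin_lookup_total(r):
    h = int(energy_bin_index(r))
    assert 0 <= h <= 34


def test_energy_bin_lookup_monotone():
    r = np.linspace(0, 150, 2000)
    h = energy_bin_index(r)
    assert np.all(np.diff(h) >= 0)


def test_monoenergetic_spectra_are_constant(rng):
    n = 50_000
    r = 100 * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2 * np.pi
    ps = _photon_set(r * np.cos(theta), r * np.sin(theta),
                     np.zeros(n), np.zeros(n), e=np.full(n, 6.0))
    m = build_energy_model(ps)
    u = np.linspace(0, 1, 20)
    for h in range(35):
        assert np.all(np.abs(m.spectra[h](u) - 6.0) < 0.01)


def test_underpopulated_bin_borrows_neighbour(rng):
    n = 20_000
    r = 10 * np.sqrt(rng.random(n))  # only bins 0..4 populated
    ps = _photon_set(r, np.zeros(n), np.zeros(n), np.zeros(n),
                     e=rng.gamma(2.0, 1.0, n) + 0.01)
    with pytest.warns(UserWarning, match="borrowing"):
        m = build_energy_model(ps)
    assert m.source_bins[34] == m.source_bins[30]


def test_off_axis_softening_recovered(synthetic_set, rng):
    m = build_energy_model(synthetic_set)
    u = rng.random(20_000)
    mean_inner = m.spectra[0](u).mean()
    mean_outer = m.spectra[24](u).mean()
    assert mean_outer < mean_inner


# ---------------------------------------------------------------------------
# direction grid
# ---------------------------------------------------------------------------

def test_grid_statistics_match_brute_force(rng):
    """Vectorized accumulation equals a per-cell loop to 1e-12."""
    n = 10_000
    x = rng.uniform(-5, 5, n)
    y = rng.uniform(-5, 5, n)
    vx = rng.normal(0, 0.02, n)
    vy = rng.normal(0, 0.02, n)
    e = rng.gamma(2.0, 1.0, n)
    ps = _photon_set(x, y, vx, vy, e=e)
    g = build_direction_grid(ps, grid=11, cell=1.0)
    cx = g.centers()
    for iy in range(11):
        for ix in range(11):
            m = (np.abs(x - cx[ix]) <= 0.5) & (np.abs(y - cx[iy]) <= 0.5)
            m &= (x >= cx[ix] - 0.5) & (x < cx[ix] + 0.5)
            m &= (y >= cx[iy] - 0.5) & (y < cx[iy] + 0.5)
            cnt = m.sum()
            assert g.n[iy, ix] == cnt
            if cnt >= 2:
                assert g.vbar_x[iy, ix] == pytest.approx(vx[m].mean(), abs=1e-12)
                assert g.sd_x[iy, ix] == pytest.approx(vx[m].std(), abs=1e-12)
                if vx[m].std() > 0 and vy[m].std() > 0:
                    assert g.rho_v[iy, ix] == pytest.approx(
                        np.corrcoef(vx[m], vy[m])[0, 1], abs=1e-9)


def test_two_particle_cell_mean():
    ps = _photon_set([0.1, 0.2], [0.1, 0.2], [0.1, 0.3], [0.0, 0.0])
    g = build_direction_grid(ps, grid=3, cell=1.0)
    assert g.vbar_x[1, 1] == pytest.approx(0.2)


def test_perfect_linear_energy_cosine_correlation():
    e = np.linspace(1, 2, 50)
    ps = _photon_set(np.zeros(50), np.zeros(50), 0.01 * e, np.linspace(0, 0.01, 50), e=e)
    g = build_direction_grid(ps, grid=3, cell=1.0)
    assert g.rho_ex[1, 1] == pytest.approx(1.0)


def test_noise_free_focal_beam_cell_means():
    p = SyntheticBeamParams(n=200_000, seed=4, ang_sigma=0.0, halo_fraction=0.0,
                            rho_ev_target=0.0, rho_v_target=0.0, electron_fraction=0.0)
    ps = make_synthetic_phsp(p)
    g = build_direction_grid(ps)
    cx = g.centers()
    X, Y = np.meshgrid(cx, cx)
    expect = X / np.sqrt(X**2 + Y**2 + 160.0**2)
    # with zero angular noise the only deviation is the sub-cell position
    # average, ~0.3 mm / sqrt(n) / focus_dist per cell
    sel = g.n >= 100
    assert sel.sum() > 100
    assert np.abs(g.vbar_x - expect)[sel].max() < 1e-3


# ---------------------------------------------------------------------------
# primary region
# ---------------------------------------------------------------------------

def _grid_with_counts(counts):
    g = lv.DirectionGrid(
        cells=counts.shape[0], cell_mm=1.0, n=counts.astype(float),
        vbar_x=np.zeros_like(counts, dtype=float), vbar_y=np.zeros_like(counts, dtype=float),
        sd_x=np.ones_like(counts, dtype=float), sd_y=np.ones_like(counts, dtype=float),
        se_x=np.ones_like(counts, dtype=float), se_y=np.ones_like(counts, dtype=float),
        rho_ex=np.zeros_like(counts, dtype=float), rho_ey=np.zeros_like(counts, dtype=float),
        rho_v=np.zeros_like(counts, dtype=float), valid=counts > 1,
    )
    return g


def test_uniform_counts_entirely_primary():
    g = _grid_with_counts(np.full((21, 21), 50))
    mask, T, frac = determine_primary_region(g)
    assert mask.all()
    assert T == pytest.approx(g.center_radius().max())
    assert frac == 1.0


def test_single_occupied_cell():
    counts = np.zeros((21, 21))
    counts[10, 10] = 100
    mask, T, frac = determine_primary_region(_grid_with_counts(counts))
    assert mask.sum() == 1
    assert mask[10, 10]
    assert frac == 1.0


def test_primary_fraction_nonincreasing_in_frac(synthetic_set):
    g = build_direction_grid(synthetic_set)
    fracs = [determine_primary_region(g, frac=f)[2] for f in (0.05, 0.2, 0.5, 0.8)]
    assert all(a >= b for a, b in zip(fracs, fracs[1:]))


def test_threshold_radius_from_occupancy_profile():
    """A fluence profile whose 20%-of-max crossing sits at a known radius
    yields T at that radius."""
    cells = 141
    c = (np.arange(cells) + 0.5) - cells / 2.0
    X, Y = np.meshgrid(c, c)
    R = np.hypot(X, Y)
    r20 = 43.0
    counts = 1e4 * np.exp(-np.log(5.0) * (R / r20) ** 8)
    mask, T, _ = determine_primary_region(_grid_with_counts(np.round(counts)))
    assert T == pytest.approx(r20, abs=1.0)


# ---------------------------------------------------------------------------
# weighted surface fits
# ---------------------------------------------------------------------------

def test_wls_exact_linear_recovery(rng):
    x = rng.uniform(-10, 10, 200)
    y = rng.uniform(-10, 10, 200)
    z = 0.5 + 0.25 * x - 0.125 * y
    s = fit_poly_surface(x, y, z, np.ones(200), [(0, 0), (1, 0), (0, 1)])
    np.testing.assert_allclose(s.coeffs, [0.5, 0.25, -0.125], atol=1e-9)


def test_wls_weight_scale_invariance(rng):
    x = rng.uniform(-10, 10, 100)
    y = rng.uniform(-10, 10, 100)
    z = 1.0 + 0.1 * x + rng.normal(0, 0.1, 100)
    w = rng.uniform(0.5, 2.0, 100)
    a = fit_poly_surface(x, y, z, w, [(0, 0), (1, 0), (0, 1)])
    b = fit_poly_surface(x, y, z, 2.0 * w, [(0, 0), (1, 0), (0, 1)])
    np.testing.assert_allclose(a.coeffs, b.coeffs, rtol=1e-12)


def test_singular_fit_raises():
    x = np.zeros(20)
    y = np.zeros(20)
    with pytest.raises(ModelBuildError, match="singular"):
        fit_poly_surface(x, y, np.ones(20), np.ones(20),
                         [(0, 0), (1, 0), (0, 1)], name="degenerate")


def test_surface_clamping():
    s = PolySurface([(0, 0)], np.array([5.0]), clamp=(-1.0, 1.0))
    assert s(0.0, 0.0) == 1.0


def test_fitted_focal_slope(vsm, beam_params):
    """In the primary region the mean-cosine surface slope along its own
    axis approximates 1/focus_dist (small-angle focal geometry)."""
    surf = vsm.directions
    x = np.linspace(-10, 10, 21)
    vx, _ = surf.mean_cosines(x, np.zeros_like(x))
    slope = np.polyfit(x, vx, 1)[0]
    assert slope == pytest.approx(1.0 / beam_params.focus_dist, rel=0.05)


# ---------------------------------------------------------------------------
# assembled model
# ---------------------------------------------------------------------------

def test_all_photon_input_gives_unit_photon_fraction(rng):
    n = 50_000
    r = 10 * np.sqrt(rng.random(n))
    th = rng.random(n) * 2 * np.pi
    ps = _photon_set(r * np.cos(th), r * np.sin(th),
                     rng.normal(0, 0.02, n), rng.normal(0, 0.02, n),
                     e=rng.gamma(2.0, 1.0, n) + 0.01)
    vsm = build_vsm(ps, sou_n=20_000)
    assert vsm.p_gamma == 1.0


def test_vsm_photon_fraction(vsm, beam_params, synthetic_set):
    assert vsm.p_gamma == pytest.approx(
        np.mean(synthetic_set.t == 1), abs=1e-12)


def test_save_load_identical_sampling(vsm, tmp_path):
    path = tmp_path / "model.vsm"
    vsm.save(path)
    back = lv.VirtualSourceModel.load(path)
    a = lv.generate(vsm, 2000, seed=77)
    b = lv.generate(back, 2000, seed=77)
    np.testing.assert_array_equal(a.as_matrix(), b.as_matrix())


def test_direction_surfaces_serialization(vsm):
    d = vsm.directions.to_dict()
    back = lv.DirectionSurfaces.from_dict(d)
    x = np.linspace(-50, 50, 31)
    y = np.linspace(-50, 50, 31)
    for k, v in vsm.directions.evaluate(x, y).items():
        np.testing.assert_array_equal(back.evaluate(x, y)[k], v)
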