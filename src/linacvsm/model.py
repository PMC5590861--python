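"""Derivation of the virtual source model from a phase-space particle set.

The source model has four independent parts, each derived by analysing
the reference phase space:

* a radial-position model — the empirical CDF of radial distance,
  histogrammed at 0.1 mm, inverted and fitted with a 30-segment
  degree-4 spline;
* 35 radially binned energy spectra — 25 bins of 2 mm covering
  0 <= r <= 50 mm, 9 bins of 5 mm covering 50 < r <= 95 mm, and one
  open bin for r > 95 mm, each stored as a degree-5 inverse-CDF spline;
* a direction model — per-cell statistics on a 141 x 141 grid of
  1 x 1 mm^2 cells (mean direction cosines, their spread, the
  energy-cosine correlations and the cosine-cosine correlation),
  condensed into seven weighted polynomial surfaces.  The plane is
  split into a primary region (cell occupancy >= 20% of the maximum,
  radius <= T) fitted with a linear surface and a secondary region
  fitted with a cubic-by-design term set; the five sigma/correlation
  surfaces are single full-plane polynomials of total degree 4, 3 and
  5 respectively.  Inverse-variance weights (1/SE^2 of the cell mean)
  correct for heteroscedasticity across cells;
* the photon fraction P_gamma for the particle-type channel.

Cells are square, the grid is centred on the beam axis (extent
[-70.5, +70.5) mm, half-open upper edges) and direction statistics use
photons only; particles outside the grid do not enter the direction fit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .invcdf import InverseCDF, fit_inverse_cdf
from .phsp import PHOTON, ParticleSet
from .sou import SOUCalibration, calibrate

__all__ = [
    "RadialPositionModel",
    "EnergySpectrumModel",
    "DirectionGrid",
    "PolySurface",
    "DirectionSurfaces",
    "VirtualSourceModel",
    "build_radial_model",
    "build_energy_model",
    "build_direction_grid",
    "determine_primary_region",
    "fit_direction_surfaces",
    "build_vsm",
    "energy_bin_edges",
    "energy_bin_index",
]

GRID_CELLS = 141
CELL_MM = 1.0


class ModelBuildError(RuntimeError):
    """Raised when a model component cannot be derived from the data."""


# ---------------------------------------------------------------------------
# radial position
# ---------------------------------------------------------------------------

@dataclass
class RadialPositionModel:
    """Inverse CDF of radial position; sampling is ``r = F^-1(U1)``."""

    inv_cdf: InverseCDF
    r_max: float

    def __call__(self, u):
        return self.inv_cdf(u)

    def to_dict(self) -> dict:
        return {"inv_cdf": self.inv_cdf.to_dict(), "r_max": self.r_max}

    @classmethod
    def from_dict(cls, d: dict) -> "RadialPositionModel":
        return cls(InverseCDF.from_dict(d["inv_cdf"]), d["r_max"])


def build_radial_model(
    ps: ParticleSet, bin_width: float = 0.1, segments: int = 30, order: int = 4
) -> RadialPositionModel:
    """Fit the radial-position inverse CDF (0.1 mm histogram, 30-segment
    degree-4 spline, monotone by construction)."""
    if ps.n < 10 * segments:
        raise ModelBuildError(f"need at least {10 * segments} particles for {segments} segments")
    r = ps.r
    inv = fit_inverse_cdf(r, bin_width=bin_width, segments=segments, degree=order)
    r_max = float(r.max())
    if inv.values[-1] > r_max + bin_width + 1e-9:
        raise ModelBuildError("fitted inverse CDF overshoots the data range")
    return RadialPositionModel(inv, r_max)


# ---------------------------------------------------------------------------
# energy spectra
# ---------------------------------------------------------------------------

def energy_bin_edges() -> np.ndarray:
    """Interior edges of the 35 radial intervals (upper edges, mm).

    Intervals are (edge[h-1], edge[h]] except the first, which includes 0,
    and the last, which is open beyond 95 mm.
    """
    return np.concatenate([np.arange(2.0, 52.0, 2.0), np.arange(55.0, 100.0, 5.0)])


def energy_bin_index(r) -> np.ndarray:
    """Map radial distance to spectrum index 0..34 (total: every r >= 0
    maps to exactly one bin; upper edges inclusive, r > 95 -> 34)."""
    r = np.asarray(r, dtype=np.float64)
    low = np.maximum(np.ceil(r / 2.0).astype(np.int64) - 1, 0)        # 0..24 for r <= 50
    mid = 25 + np.ceil((r - 50.0) / 5.0).astype(np.int64) - 1         # 25..33 for 50 < r <= 95
    out = np.where(r <= 50.0, low, np.where(r <= 95.0, mid, 34))
    return out if out.ndim else np.int64(out)


@dataclass
class EnergySpectrumModel:
    """35 radially binned inverse-CDF energy spectra."""

    spectra: list  # list[InverseCDF], length 35
    source_bins: list  # which radial bin each spectrum came from (fallbacks)

    def spectrum_for(self, r):
        return self.spectra[int(energy_bin_index(r))]

    def sample(self, r, u3):
        """Vectorized inverse-transform sampling of the spectrum of the
        bin containing each particle's radius."""
        r = np.atleast_1d(np.asarray(r, dtype=np.float64))
        u3 = np.atleast_1d(np.asarray(u3, dtype=np.float64))
        h = energy_bin_index(r)
        e = np.empty_like(u3)
        for hb in np.unique(h):
            m = h == hb
            e[m] = self.spectra[hb](u3[m])
        return e

    def to_dict(self) -> dict:
        return {
            "spectra": [s.to_dict() for s in self.spectra],
            "source_bins": list(self.source_bins),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnergySpectrumModel":
        return cls([InverseCDF.from_dict(s) for s in d["spectra"]], d["source_bins"])


def build_energy_model(
    ps: ParticleSet, order: int = 5, segments: int = 12, min_count: int = 100
) -> EnergySpectrumModel:
    """Derive the 35 radially binned energy spectra.

    Under-populated bins (< ``min_count`` particles) borrow the nearest
    populated bin's spectrum; a warning records the substitution.
    """
    r = ps.r
    e = ps.e
    h = energy_bin_index(r)
    spectra: list = [None] * 35
    source: list = [None] * 35
    populated = []
    for hb in range(35):
        m = h == hb
        cnt = int(m.sum())
        if cnt >= min_count:
            vals = e[m]
            span = float(vals.max() - vals.min())
            bw = span / 200.0 if span > 0 else max(float(vals[0]) * 1e-6, 1e-9)
            spectra[hb] = fit_inverse_cdf(vals, bin_width=bw, segments=segments, degree=order)
            source[hb] = hb
            populated.append(hb)
    if not populated:
        raise ModelBuildError("no radial bin holds enough particles for an energy spectrum")
    for hb in range(35):
        if spectra[hb] is None:
            nearest = min(populated, key=lambda p: abs(p - hb))
            warnings.warn(
                f"energy bin {hb} under-populated; borrowing spectrum of bin {nearest}",
                stacklevel=2,
            )
            spectra[hb] = spectra[nearest]
            source[hb] = nearest
    return EnergySpectrumModel(spectra, source)


# ---------------------------------------------------------------------------
# direction grid
# ---------------------------------------------------------------------------

@dataclass
class DirectionGrid:
    """Per-cell direction statistics on the phase-space plane.

    All arrays are (cells, cells), indexed [iy, ix]; ``valid`` marks cells
    with at least two particles and nonzero variance on both cosines.
    sd is the per-cell sample standard deviation (the sampling spread),
    se = sd/sqrt(n) the standard error of the cell mean (the fit-weight
    statistic).
    """

    cells: int
    cell_mm: float
    n: np.ndarray
    vbar_x: np.ndarray
    vbar_y: np.ndarray
    sd_x: np.ndarray
    sd_y: np.ndarray
    se_x: np.ndarray
    se_y: np.ndarray
    rho_ex: np.ndarray
    rho_ey: np.ndarray
    rho_v: np.ndarray
    valid: np.ndarray
    n_in_grid: int = 0
    n_total: int = 0

    @property
    def extent(self) -> float:
        """Half-width of the grid, mm."""
        return self.cells * self.cell_mm / 2.0

    def centers(self) -> np.ndarray:
        """Cell-centre coordinates along one axis, mm."""
        return (np.arange(self.cells) + 0.5) * self.cell_mm - self.extent

    def center_radius(self) -> np.ndarray:
        cx = self.centers()
        return np.hypot(cx[None, :], cx[:, None])


def _cell_index(coord: np.ndarray, cells: int, cell_mm: float) -> np.ndarray:
    return np.floor(coord / cell_mm + cells / 2.0).astype(np.int64)


def build_direction_grid(
    ps: ParticleSet, grid: int = GRID_CELLS, cell: float = CELL_MM, photons_only: bool = True
) -> DirectionGrid:
    """Accumulate per-cell direction statistics from a particle set.

    Photons only by default (the direction model describes the photon
    field; the sampler reuses it for the small electron contamination).
    Particles outside the grid extent are excluded from the statistics.
    """
    sub = ps.photons() if photons_only else ps
    ix = _cell_index(sub.x, grid, cell)
    iy = _cell_index(sub.y, grid, cell)
    inside = (ix >= 0) & (ix < grid) & (iy >= 0) & (iy < grid)
    ix, iy = ix[inside], iy[inside]
    e, vx, vy = sub.e[inside], sub.vx[inside], sub.vy[inside]
    flat = iy * grid + ix
    size = grid * grid

    def acc(w=None):
        return np.bincount(flat, weights=w, minlength=size).reshape(grid, grid)

    n = acc()
    with np.errstate(invalid="ignore", divide="ignore"):
        s_vx, s_vy, s_e = acc(vx), acc(vy), acc(e)
        mean_vx, mean_vy, mean_e = s_vx / n, s_vy / n, s_e / n
        var_vx = acc(vx**2) / n - mean_vx**2
        var_vy = acc(vy**2) / n - mean_vy**2
        var_e = acc(e**2) / n - mean_e**2
        cov_evx = acc(e * vx) / n - mean_e * mean_vx
        cov_evy = acc(e * vy) / n - mean_e * mean_vy
        cov_vxy = acc(vx * vy) / n - mean_vx * mean_vy
        var_vx, var_vy, var_e = (np.clip(v, 0.0, None) for v in (var_vx, var_vy, var_e))
        sd_x, sd_y, sd_e = np.sqrt(var_vx), np.sqrt(var_vy), np.sqrt(var_e)
        rho_ex = cov_evx / (sd_e * sd_x)
        rho_ey = cov_evy / (sd_e * sd_y)
        rho_v = cov_vxy / (sd_x * sd_y)
        se_x = sd_x / np.sqrt(n)
        se_y = sd_y / np.sqrt(n)

    valid = (n >= 2) & (var_vx > 0) & (var_vy > 0)
    for a in (mean_vx, mean_vy, sd_x, sd_y, se_x, se_y):
        a[n == 0] = 0.0
    # undefined correlations (constant sequences) are stored as 0, invalid
    for a in (rho_ex, rho_ey, rho_v):
        a[~np.isfinite(a)] = 0.0
        np.clip(a, -1.0, 1.0, out=a)
    return DirectionGrid(
        grid, cell, n, mean_vx, mean_vy, sd_x, sd_y, se_x, se_y,
        rho_ex, rho_ey, rho_v, valid,
        n_in_grid=int(inside.sum()), n_total=int(sub.n),
    )


def determine_primary_region(g: DirectionGrid, frac: float = 0.2):
    """Split the plane into primary/secondary regions by cell occupancy.

    The primary region is every cell holding at least ``frac`` of the
    maximum cell count.  T is the radius of the largest origin-centred
    circle fully inside the primary mask (the boundary radius used by the
    piecewise mean-cosine fit).

    Returns
    -------
    mask : (cells, cells) bool array
    T : float, mm
    primary_fraction : fraction of in-grid photons in primary cells
    """
    nmax = g.n.max()
    if nmax <= 0:
        raise ModelBuildError("direction grid is empty")
    mask = g.n >= frac * nmax
    rc = g.center_radius()
    outside = ~mask
    if outside.any():
        T = float(rc[outside].min())
    else:
        T = float(rc.max())
    primary_fraction = float(g.n[mask].sum() / g.n.sum())
    return mask, T, primary_fraction


# ---------------------------------------------------------------------------
# polynomial surfaces
# ---------------------------------------------------------------------------

def _total_degree_terms(degree: int):
    return [(i, j) for d in range(degree + 1) for i in range(d + 1) for j in [d - i]]


@dataclass
class PolySurface:
    """A fitted 2D polynomial ``z(x, y) = sum c_ij x^i y^j`` with optional
    clamping of the evaluated value (correlations to [-1, 1], spreads
    to >= 0)."""

    exponents: list
    coeffs: np.ndarray
    clamp: tuple | None = None
    adj_r2: float = float("nan")

    def __call__(self, x, y):
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        z = np.zeros(np.broadcast(x, y).shape)
        for (i, j), c in zip(self.exponents, self.coeffs):
            z += c * x**i * y**j
        if self.clamp is not None:
            z = np.clip(z, self.clamp[0], self.clamp[1])
        return z

    def to_dict(self) -> dict:
        return {
            "exponents": [list(t) for t in self.exponents],
            "coeffs": self.coeffs.tolist(),
            "clamp": list(self.clamp) if self.clamp else None,
            "adj_r2": self.adj_r2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PolySurface":
        return cls(
            [tuple(t) for t in d["exponents"]], np.array(d["coeffs"]),
            tuple(d["clamp"]) if d["clamp"] else None, d["adj_r2"],
        )


def fit_poly_surface(x, y, z, w, exponents, clamp=None, name: str = "surface") -> PolySurface:
    """Weighted least-squares fit of a polynomial surface.

    The weights enter as sqrt(w) row scaling, so doubling all weights
    leaves the coefficients unchanged.  Adjusted R^2 (weighted) is
    recorded for model-order diagnostics.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    w = np.asarray(w, float)
    a = np.column_stack([x**i * y**j for i, j in exponents])
    sw = np.sqrt(w)
    coeffs, _, rank, _ = np.linalg.lstsq(a * sw[:, None], z * sw, rcond=None)
    if rank < len(exponents):
        raise ModelBuildError(f"singular normal equations fitting {name}")
    resid = z - a @ coeffs
    wmean = np.average(z, weights=w)
    ss_res = float(np.sum(w * resid**2))
    ss_tot = float(np.sum(w * (z - wmean) ** 2))
    n, p = len(z), len(exponents)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n > p + 1 else r2
    return PolySurface(list(exponents), coeffs, clamp=clamp, adj_r2=adj)


@dataclass
class DirectionSurfaces:
    """The seven fitted surfaces of the direction model plus the region split.

    Mean-cosine surfaces are piecewise: a linear surface inside the
    primary radius T, a restricted cubic term set outside.  The spread
    and correlation surfaces are single full-plane polynomials.
    """

    T: float
    mask: np.ndarray
    vhat_x_primary: PolySurface
    vhat_x_secondary: PolySurface
    vhat_y_primary: PolySurface
    vhat_y_secondary: PolySurface
    sigma_x: PolySurface
    sigma_y: PolySurface
    rho_ex: PolySurface
    rho_ey: PolySurface
    rho_v: PolySurface
    sigma_mode: str = "sd"
    primary_fraction: float = float("nan")

    def mean_cosines(self, x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        r = np.hypot(x, y)
        primary = r <= self.T
        vx = np.where(primary, self.vhat_x_primary(x, y), self.vhat_x_secondary(x, y))
        vy = np.where(primary, self.vhat_y_primary(x, y), self.vhat_y_secondary(x, y))
        return vx, vy

    def evaluate(self, x, y):
        """All seven surfaces at (x, y): vbar_x, vbar_y, sigma_x, sigma_y,
        rho_ex, rho_ey, rho_v — the per-particle inputs of the sampler."""
        vx, vy = self.mean_cosines(x, y)
        return {
            "vbar_x": vx,
            "vbar_y": vy,
            "sigma_x": self.sigma_x(x, y),
            "sigma_y": self.sigma_y(x, y),
            "rho_ex": self.rho_ex(x, y),
            "rho_ey": self.rho_ey(x, y),
            "rho_v": self.rho_v(x, y),
        }

    def to_dict(self) -> dict:
        d = {
            "T": self.T,
            "mask": np.asarray(self.mask, dtype=int).tolist(),
            "sigma_mode": self.sigma_mode,
            "primary_fraction": self.primary_fraction,
        }
        for k in ("vhat_x_primary", "vhat_x_secondary", "vhat_y_primary", "vhat_y_secondary",
                  "sigma_x", "sigma_y", "rho_ex", "rho_ey", "rho_v"):
            d[k] = getattr(self, k).to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DirectionSurfaces":
        kw = {
            k: PolySurface.from_dict(d[k])
            for k in ("vhat_x_primary", "vhat_x_secondary", "vhat_y_primary", "vhat_y_secondary",
                      "sigma_x", "sigma_y", "rho_ex", "rho_ey", "rho_v")
        }
        return cls(
            T=d["T"], mask=np.array(d["mask"], dtype=bool), sigma_mode=d["sigma_mode"],
            primary_fraction=d["primary_fraction"], **kw,
        )


# term sets of the piecewise mean-cosine fit, in (k, k') exponents:
# primary {1, k, k'}; secondary {1, k, k', k^2, k k', k^3, k^2 k'}
_PRIMARY_TERMS_KKP = [(0, 0), (1, 0), (0, 1)]
_SECONDARY_TERMS_KKP = [(0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (3, 0), (2, 1)]


def _kkp_to_xy(terms, k_axis: str):
    """Translate (k, k') exponents to (x, y) exponents; k' is the other axis."""
    if k_axis == "x":
        return [(i, j) for i, j in terms]
    return [(j, i) for i, j in terms]


def fit_direction_surfaces(
    g: DirectionGrid,
    mask: np.ndarray,
    T: float,
    sigma_mode: str = "sd",
    min_bin_count: int = 10,
    primary_fraction: float = float("nan"),
) -> DirectionSurfaces:
    """Fit the seven weighted surfaces of the direction model.

    Weights are the inverse variance of the cell mean (1/SE^2); the
    cosine-cosine correlation surface, which has no spread of its own,
    uses 1/(SE_x * SE_y).  Cells with fewer than ``min_bin_count``
    particles or zero variance are excluded from every fit.
    """
    if sigma_mode not in ("sd", "se"):
        raise ValueError("sigma_mode must be 'sd' or 'se'")
    cx = g.centers()
    X, Y = np.meshgrid(cx, cx)  # [iy, ix] indexing matches the grid arrays
    rc = g.center_radius()
    usable = g.valid & (g.n >= min_bin_count)
    if usable.sum() < 10:
        raise ModelBuildError("too few usable cells to fit direction surfaces")
    primary = usable & (rc <= T)
    secondary = usable & (rc > T)

    wx = 1.0 / g.se_x[usable] ** 2
    wy = 1.0 / g.se_y[usable] ** 2

    def fit_v(k_axis: str):
        data = g.vbar_x if k_axis == "x" else g.vbar_y
        with np.errstate(divide="ignore"):
            w_all = 1.0 / (g.se_x if k_axis == "x" else g.se_y) ** 2
        fits = []
        # regions too sparse for their term set fall back to all usable cells
        for region, terms in ((primary, _PRIMARY_TERMS_KKP), (secondary, _SECONDARY_TERMS_KKP)):
            sel = region if region.sum() > 2 * len(terms) else usable
            fits.append(
                fit_poly_surface(
                    X[sel], Y[sel], data[sel], w_all[sel],
                    _kkp_to_xy(terms, k_axis), clamp=(-1.0, 1.0),
                    name=f"vhat_{k_axis} ({'primary' if region is primary else 'secondary'})",
                )
            )
        return fits

    vxp, vxs = fit_v("x")
    vyp, vys = fit_v("y")

    sig_x_data = (g.sd_x if sigma_mode == "sd" else g.se_x)[usable]
    sig_y_data = (g.sd_y if sigma_mode == "sd" else g.se_y)[usable]
    xs, ys = X[usable], Y[usable]
    sigma_x = fit_poly_surface(xs, ys, sig_x_data, wx, _total_degree_terms(4),
                               clamp=(0.0, np.inf), name="sigma_x")
    sigma_y = fit_poly_surface(xs, ys, sig_y_data, wy, _total_degree_terms(4),
                               clamp=(0.0, np.inf), name="sigma_y")
    rho_ex = fit_poly_surface(xs, ys, g.rho_ex[usable], wx, _total_degree_terms(3),
                              clamp=(-1.0, 1.0), name="rho_ex")
    rho_ey = fit_poly_surface(xs, ys, g.rho_ey[usable], wy, _total_degree_terms(3),
                              clamp=(-1.0, 1.0), name="rho_ey")
    w_v = 1.0 / (g.se_x[usable] * g.se_y[usable])
    rho_v = fit_poly_surface(xs, ys, g.rho_v[usable], w_v, _total_degree_terms(5),
                             clamp=(-1.0, 1.0), name="rho_v")

    return DirectionSurfaces(
        T=T, mask=mask,
        vhat_x_primary=vxp, vhat_x_secondary=vxs,
        vhat_y_primary=vyp, vhat_y_secondary=vys,
        sigma_x=sigma_x, sigma_y=sigma_y,
        rho_ex=rho_ex, rho_ey=rho_ey, rho_v=rho_v,
        sigma_mode=sigma_mode, primary_fraction=primary_fraction,
    )


# ---------------------------------------------------------------------------
# the assembled model
# ---------------------------------------------------------------------------

SCHEMA_VERSION = 1


@dataclass
class VirtualSourceModel:
    """Everything needed to generate particles: the four sub-models plus
    the SOU calibration table and provenance metadata."""

    radial: RadialPositionModel
    energy: EnergySpectrumModel
    directions: DirectionSurfaces
    sou: SOUCalibration
    p_gamma: float
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema": SCHEMA_VERSION,
            "radial": self.radial.to_dict(),
            "energy": self.energy.to_dict(),
            "directions": self.directions.to_dict(),
            "sou": self.sou.to_dict(),
            "p_gamma": self.p_gamma,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VirtualSourceModel":
        if d.get("schema") != SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema {d.get('schema')!r}")
        return cls(
            RadialPositionModel.from_dict(d["radial"]),
            EnergySpectrumModel.from_dict(d["energy"]),
            DirectionSurfaces.from_dict(d["directions"]),
            SOUCalibration.from_dict(d["sou"]),
            d["p_gamma"],
            d.get("provenance", {}),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "VirtualSourceModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_vsm(
    ps: ParticleSet,
    frac: float = 0.2,
    grid: int = GRID_CELLS,
    cell: float = CELL_MM,
    sigma_mode: str = "sd",
    sou_seed: int = 0,
    sou_n: int = 1_000_000,
    source: str = "",
) -> VirtualSourceModel:
    """Derive the complete virtual source model from a phase space.

    Radial and energy models use all particles; the direction grid uses
    photons only.  P_gamma is the photon count over N (positrons, if any,
    are counted with the electrons).
    """
    radial = build_radial_model(ps)
    energy = build_energy_model(ps)
    dgrid = build_direction_grid(ps, grid=grid, cell=cell)
    mask, T, pfrac = determine_primary_region(dgrid, frac=frac)
    surfaces = fit_direction_surfaces(dgrid, mask, T, sigma_mode=sigma_mode,
                                      primary_fraction=pfrac)
    cal = calibrate(seed=sou_seed, n=sou_n)
    p_gamma = float(np.count_nonzero(ps.t == PHOTON)) / ps.n
    prov = {"source": source, "n": ps.n, "frac": frac, "grid": grid,
            "cell": cell, "sigma_mode": sigma_mode}
    return VirtualSourceModel(radial, energy, surfaces, cal, p_gamma, prov)
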