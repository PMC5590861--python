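"""Monotone inverse-CDF models fitted to empirical histograms.

The sampling distributions of the source model (radial position, per-bin
energy spectra) are stored as fitted inverses of empirical cumulative
distribution functions: histogram the data, accumulate to a CDF, swap the
axes, resample the inverted CDF onto a uniform probability grid, and fit
a least-squares polynomial spline.  The resampling matters: histogram
edges are uniform in the value domain, so the raw inverted-CDF points
pile up wherever the density is low and an unweighted fit would be
dominated by the distribution tail.

Interior knots are split between the probability axis and the value
axis (half equally spaced in u, half at the u-locations of equally
spaced values), so steep stretches of the inverse CDF — low-density
tails, fluence-core-to-halo transitions — receive knots as well as the
body.  Monotonicity is enforced by projecting the fitted curve onto
nondecreasing values at a dense evaluation grid; the projected curve is
what gets evaluated, so the invariant holds exactly, not approximately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import LSQUnivariateSpline

__all__ = ["InverseCDF", "fit_inverse_cdf"]

#: number of points of the dense evaluation grid the monotone projection uses
_GRID_SIZE = 4097


class InverseCDFError(ValueError):
    """Raised when an inverse-CDF fit cannot be constructed."""


@dataclass
class InverseCDF:
    """A nondecreasing map from [0, 1] to sample values.

    Stored as values on a fixed uniform probability grid; evaluation is
    linear interpolation, which preserves monotonicity exactly.
    """

    u_grid: np.ndarray
    values: np.ndarray
    bin_width: float = 0.0
    segments: int = 0
    degree: int = 0
    vmin: float = field(default=np.nan)
    vmax: float = field(default=np.nan)

    def __post_init__(self) -> None:
        self.u_grid = np.asarray(self.u_grid, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(np.diff(self.values) < 0):
            raise InverseCDFError("inverse CDF values are not nondecreasing")
        if np.isnan(self.vmin):
            self.vmin = float(self.values[0])
        if np.isnan(self.vmax):
            self.vmax = float(self.values[-1])

    def __call__(self, u):
        return np.interp(u, self.u_grid, self.values)

    def to_dict(self) -> dict:
        return {
            "u_grid": self.u_grid.tolist(),
            "values": self.values.tolist(),
            "bin_width": self.bin_width,
            "segments": self.segments,
            "degree": self.degree,
            "vmin": self.vmin,
            "vmax": self.vmax,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InverseCDF":
        return cls(
            np.array(d["u_grid"]), np.array(d["values"]),
            d["bin_width"], d["segments"], d["degree"], d["vmin"], d["vmax"],
        )


def _empirical_inverse_points(values: np.ndarray, bin_width: float):
    """Histogram ``values``, accumulate, and return the inverted CDF as
    one (u, v) point per occupied bin.

    The histogram is anchored half a bin below the data minimum, so the
    minimum sits mid-bin and a degenerate (single-valued) distribution
    inverts to a constant.  Each occupied bin contributes the point
    (cumulative mass at the bin centre, bin midpoint) — the mid-bin mass
    pairing keeps the piecewise-linear inverse consistent with data
    spread uniformly within bins; endpoints anchor at the exact data
    minimum (u = 0) and maximum (u = 1).
    """
    vmin, vmax = float(values.min()), float(values.max())
    lo = vmin - bin_width / 2.0
    nbins = max(int(np.ceil((vmax - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(nbins + 1)
    counts, _ = np.histogram(values, bins=edges)
    frac = counts / counts.sum()
    cdf = np.cumsum(frac)
    occ = np.flatnonzero(counts)
    u = np.concatenate([[0.0], cdf[occ] - frac[occ] / 2.0, [1.0]])
    v = np.concatenate([
        [vmin], np.clip(edges[occ] + bin_width / 2.0, vmin, vmax), [vmax],
    ])
    return u, v


def fit_inverse_cdf(
    values: np.ndarray,
    bin_width: float,
    segments: int = 30,
    degree: int = 4,
) -> InverseCDF:
    """Fit a monotone inverse CDF to sampled values.

    Parameters
    ----------
    values : array
        Raw observations (e.g. radial distances in mm or energies in MeV).
    bin_width : float
        Histogram bin width used to build the empirical CDF.
    segments : int
        Number of polynomial segments of the least-squares spline; interior
        knots are equally spaced on the probability axis.
    degree : int
        Spline degree (4 for the radial model, 5 for energy spectra).

    Notes
    -----
    Data whose empirical CDF has too few distinct steps to support the
    requested spline (degenerate or near-degenerate distributions) fall
    back to linear interpolation of the inverted CDF, which is already
    monotone.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise InverseCDFError("no values to fit")
    if bin_width <= 0:
        raise InverseCDFError("bin_width must be positive")
    u, v = _empirical_inverse_points(values, bin_width)

    # resample the (piecewise-linear) inverted CDF uniformly in probability
    m = _GRID_SIZE
    ug = np.linspace(0.0, 1.0, m)
    vg = np.interp(ug, u, v)

    u_grid = np.linspace(0.0, 1.0, _GRID_SIZE)
    fitted = None
    if len(u) > segments + degree + 1 and v[-1] > v[0]:
        k_u = np.linspace(0.0, 1.0, segments // 2 + 1)[1:-1]
        vk = np.linspace(v[0], v[-1], segments - segments // 2 + 1)[1:-1]
        k_v = np.interp(vk, v, u)
        interior = np.sort(np.concatenate([k_u, k_v]))
        # enforce knot separation so Schoenberg-Whitney holds on the grid
        minsep = 3.0 / (m - 1)
        kept: list = []
        for t in interior:
            if (not kept or t - kept[-1] >= minsep) and minsep <= t <= 1.0 - minsep:
                kept.append(t)
        if kept:
            try:
                spl = LSQUnivariateSpline(ug, vg, np.array(kept), k=degree)
                fitted = spl(u_grid)
            except Exception:
                fitted = None
    if fitted is None:
        fitted = np.interp(u_grid, u, v)

    # monotone projection: pool adjacent violators via running maximum;
    # endpoints pinned so u=0 / u=1 map to the spectrum min / max exactly
    fitted = np.maximum.accumulate(fitted)
    fitted = np.clip(fitted, v[0], v[-1])
    fitted[0], fitted[-1] = v[0], v[-1]
    model = InverseCDF(
        u_grid, fitted, bin_width=bin_width, segments=segments, degree=degree,
        vmin=float(v[0]), vmax=float(v[-1]),
    )
    return model
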