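"""Sum-of-uniforms (SOU) correlation induction between uniform variates.

To correlate two uniform random numbers U3 and U4 to a chosen Pearson
correlation, U4 is built from U3 as ``s = U3 + c*V`` with ``V ~ U(0,1)``
independent and ``c >= 0`` the SOU parameter, then mapped back to a
uniform marginal through the exact CDF of the sum,

    F_s trapezoidal on [0, 1+c]:
        quadratic ramp on [0, min(1, c)],
        linear plateau on [min(1, c), max(1, c)],
        quadratic ramp on [max(1, c), 1+c].

``c = 0`` reproduces U3 exactly (correlation 1); increasing ``c`` drowns
U3 in noise and the correlation decays toward 0.  The map between c and
the realized correlation has no convenient closed form, so it is
calibrated numerically: rho(c) is measured by Monte Carlo on a grid of c
values and inverted by monotone interpolation (the function ``g``).
Negative correlations are induced by the reflection ``1 - U4``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["sou_cdf", "sou_pair", "SOUCalibration", "calibrate", "correlated_pair_for_rho"]

#: calibration grid for the SOU parameter: [0, 10] at step 0.2 (51 values)
C_GRID = np.round(np.arange(0, 10.2, 0.2), 10)


def sou_cdf(s, c: float):
    """Exact CDF of ``U(0,1) + c*U(0,1)``, the probability-integral
    transform that restores a uniform marginal.  Vectorized in ``s``."""
    if c < 0:
        raise ValueError("c must be nonnegative")
    s = np.asarray(s, dtype=np.float64)
    if c == 0:
        return np.clip(s, 0.0, 1.0)
    a, b = min(1.0, c), max(1.0, c)
    out = np.empty_like(s)
    lo = s <= a
    hi = s >= b
    mid = ~lo & ~hi
    out[lo] = np.clip(s[lo], 0.0, None) ** 2 / (2.0 * c)
    if c < 1.0:
        out[mid] = s[mid] - c / 2.0
    else:
        out[mid] = (2.0 * s[mid] - 1.0) / (2.0 * c)
    out[hi] = 1.0 - np.clip(1.0 + c - s[hi], 0.0, None) ** 2 / (2.0 * c)
    return np.clip(out, 0.0, 1.0)


def sou_pair(u, c, rng: np.random.Generator):
    """Return U4 correlated to ``u`` with SOU parameter ``c``.

    ``u`` and ``c`` may be scalars or matching arrays (per-particle c).
    The returned variate is marginally uniform on [0, 1] for every c —
    the probability-integral transform is exact.
    """
    u = np.asarray(u, dtype=np.float64)
    c = np.asarray(c, dtype=np.float64)
    if np.any(c < 0):
        raise ValueError("c must be nonnegative")
    v = rng.uniform(size=u.shape if u.shape else None)
    s = u + c * v
    if c.ndim == 0:
        return sou_cdf(s, float(c))
    out = np.empty_like(s)
    # group identical c values (the calibration grid keeps these few)
    for cv in np.unique(c):
        m = c == cv
        out[m] = sou_cdf(s[m], float(cv))
    return out


@dataclass
class SOUCalibration:
    """Tabulated map between the SOU parameter c and the realized PCC.

    ``g(|rho|)`` returns the c that achieves correlation ``|rho|``;
    requests below the weakest calibrated correlation (at c = 10) are
    treated as independent draws.
    """

    c_grid: np.ndarray
    rho_of_c: np.ndarray
    n: int
    seed: int

    def __post_init__(self) -> None:
        self.c_grid = np.asarray(self.c_grid, dtype=np.float64)
        self.rho_of_c = np.asarray(self.rho_of_c, dtype=np.float64)

    @property
    def rho_min(self) -> float:
        """Weakest correlation the calibrated range can induce."""
        return float(self.rho_of_c[-1])

    def g(self, rho):
        """SOU parameter achieving |rho|; clamped to the calibrated range."""
        rho = np.abs(np.asarray(rho, dtype=np.float64))
        # rho_of_c is decreasing in c; np.interp needs ascending x
        return np.interp(rho, self.rho_of_c[::-1], self.c_grid[::-1])

    def to_dict(self) -> dict:
        return {
            "c_grid": self.c_grid.tolist(),
            "rho_of_c": self.rho_of_c.tolist(),
            "n": self.n,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SOUCalibration":
        return cls(np.array(d["c_grid"]), np.array(d["rho_of_c"]), d["n"], d["seed"])


def calibrate(seed: int = 0, n: int = 1_000_000, c_grid=None) -> SOUCalibration:
    """Measure rho(c) over the c grid by Monte Carlo.

    For each c, two independent sequences of ``n`` uniforms are coupled by
    the SOU construction and their sample Pearson correlation recorded.
    ``c = 0`` is pinned to exactly 1 (the construction is the identity).
    """
    if n < 10_000:
        raise ValueError("calibration needs n >= 1e4 for a stable table")
    c_grid = C_GRID if c_grid is None else np.asarray(c_grid, dtype=np.float64)
    rng = np.random.default_rng(seed)
    rho = np.empty(len(c_grid))
    for i, c in enumerate(c_grid):
        u3 = rng.uniform(size=n)
        if c == 0:
            rho[i] = 1.0
            continue
        u4 = sou_pair(u3, float(c), rng)
        rho[i] = np.corrcoef(u3, u4)[0, 1]
    # enforce a strictly decreasing table (single-valued inverse): pool
    # any Monte-Carlo inversions, then break exact ties infinitesimally
    rho = np.minimum.accumulate(rho) - 1e-12 * np.arange(len(c_grid))
    rho[0] = 1.0
    return SOUCalibration(c_grid, rho, n=n, seed=seed)


def correlated_pair_for_rho(u3, rho, cal: SOUCalibration, rng: np.random.Generator):
    """Return U4 with corr(U3, U4) ~ rho, using the calibrated map g.

    rho may be a per-particle array.  Negative rho is induced by the
    reflection ``1 - U4``; |rho| below the calibrated minimum is induced
    by the endpoint-mixing construction described in the module docstring.
    """
    u3 = np.asarray(u3, dtype=np.float64)
    rho = np.asarray(rho, dtype=np.float64)
    scalar = u3.ndim == 0
    u3v = np.atleast_1d(u3)
    rhov = np.broadcast_to(np.atleast_1d(rho), u3v.shape).astype(np.float64)
    if np.any(np.abs(rhov) > 1):
        raise ValueError("|rho| must be <= 1")
    c = cal.g(np.abs(rhov))
    # correlations weaker than the c = 10 endpoint are induced by randomly
    # mixing the endpoint coupling (probability |rho|/rho_min) with an
    # independent draw: the realized PCC is then |rho| exactly, the
    # marginal stays uniform, and c never leaves the calibrated range
    weak = np.abs(rhov) < cal.rho_min
    mix_independent = np.zeros(u3v.shape, dtype=bool)
    if np.any(weak):
        p = np.abs(rhov[weak]) / cal.rho_min
        mix_independent[weak] = rng.uniform(size=int(weak.sum())) >= p
        c[weak] = cal.c_grid[-1]
    v = rng.uniform(size=u3v.shape)
    s = u3v + c * v
    u4 = np.empty_like(u3v)
    pos = c == 0
    u4[pos] = u3v[pos]
    np_ = ~pos
    if np.any(np_):
        # vectorized trapezoidal CDF with per-element c
        cc, ss = c[np_], s[np_]
        a = np.minimum(1.0, cc)
        b = np.maximum(1.0, cc)
        res = np.where(
            ss <= a,
            np.clip(ss, 0.0, None) ** 2 / (2.0 * cc),
            np.where(
                ss >= b,
                1.0 - np.clip(1.0 + cc - ss, 0.0, None) ** 2 / (2.0 * cc),
                np.where(cc < 1.0, ss - cc / 2.0, (2.0 * ss - 1.0) / (2.0 * cc)),
            ),
        )
        u4[np_] = np.clip(res, 0.0, 1.0)
    if np.any(mix_independent):
        u4[mix_independent] = rng.uniform(size=int(mix_independent.sum()))
    u4 = np.where(rhov < 0, 1.0 - u4, u4)
    return float(u4[0]) if scalar else u4
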