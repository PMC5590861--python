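"""2D plane container, profile extraction and gamma-index analysis.

The gamma index compares an evaluated dose (or fluence) plane against a
reference plane by combining a dose-difference criterion with a
distance-to-agreement (DTA) criterion: for each reference pixel above
the low-dose threshold,

    gamma = min over eval positions p of
            sqrt( (D_eval(p) - D_ref)^2 / dDmax^2  +  |p - p_ref|^2 / DTA^2 )

with ``dDmax`` a percentage of the global reference maximum (global
normalization).  A pixel passes when gamma <= 1; the pass rate is the
percentage of evaluated (above-threshold) pixels that pass.  The search
interpolates the evaluated plane on a sub-grid of step 0.1 x DTA within
a radius of 3 x DTA, the usual discretization for plane comparison.
Evaluation is one-sided (reference against evaluated), matching standard
practice; swapping the planes changes the result slightly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = ["Plane2D", "GammaResult", "gamma_analysis", "extract_profile",
           "read_plane", "write_plane"]


class PlaneError(ValueError):
    """Raised for invalid plane data or incompatible plane pairs."""


@dataclass
class Plane2D:
    """A 2D scalar field sampled on a regular grid.

    ``values[iy, ix]`` sits at ``(origin[0] + ix*spacing[0],
    origin[1] + iy*spacing[1])`` — origin is the centre of pixel (0, 0).
    """

    values: np.ndarray
    spacing: tuple  # (dx, dy), mm
    origin: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise PlaneError("plane values must be a 2D array")
        if not np.all(np.isfinite(self.values)):
            raise PlaneError("plane contains non-finite values")
        self.spacing = (float(self.spacing[0]), float(self.spacing[1]))
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise PlaneError("pixel spacing must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def x(self) -> np.ndarray:
        return self.origin[0] + self.spacing[0] * np.arange(self.values.shape[1])

    @property
    def y(self) -> np.ndarray:
        return self.origin[1] + self.spacing[1] * np.arange(self.values.shape[0])

    @classmethod
    def centered(cls, values, spacing) -> "Plane2D":
        """A plane whose pixel grid is centred on (0, 0)."""
        values = np.asarray(values, dtype=np.float64)
        ny, nx = values.shape
        dx, dy = float(spacing[0]), float(spacing[1])
        return cls(values, (dx, dy), (-(nx - 1) / 2.0 * dx, -(ny - 1) / 2.0 * dy))


@dataclass
class GammaResult:
    """Gamma map and pass statistics for one criterion pair."""

    gamma: np.ndarray        # NaN where below threshold
    pass_rate: float         # percent of evaluated pixels with gamma <= 1
    dose_pct: float
    dist_mm: float
    threshold_pct: float
    n_evaluated: int


def extract_profile(p: Plane2D, axis: str, position_mm: float = 0.0):
    """Nearest-row (axis='x') or nearest-column (axis='y') profile.

    axis='x' returns the values along x at the row closest to
    ``position_mm`` in y, and vice versa.  Returns (coords, values).
    """
    if axis == "x":
        coords = p.y
        if not (coords.min() - p.spacing[1] / 2 <= position_mm <= coords.max() + p.spacing[1] / 2):
            raise PlaneError(f"position {position_mm} mm outside the plane")
        i = int(np.argmin(np.abs(coords - position_mm)))
        return p.x, p.values[i, :]
    if axis == "y":
        coords = p.x
        if not (coords.min() - p.spacing[0] / 2 <= position_mm <= coords.max() + p.spacing[0] / 2):
            raise PlaneError(f"position {position_mm} mm outside the plane")
        i = int(np.argmin(np.abs(coords - position_mm)))
        return p.y, p.values[:, i]
    raise ValueError("axis must be 'x' or 'y'")


def gamma_analysis(
    ref: Plane2D,
    eval_plane: Plane2D,
    dose_pct: float = 3.0,
    dist_mm: float = 1.0,
    threshold_pct: float = 10.0,
    global_norm: bool = True,
) -> GammaResult:
    """Gamma-index comparison of an evaluated plane against a reference.

    Parameters
    ----------
    dose_pct, dist_mm : float
        The criterion pair, e.g. 3%/1 mm.
    threshold_pct : float
        Reference pixels below this percentage of the reference maximum
        are excluded from the pass rate.
    global_norm : bool
        Normalize dose differences by the global reference maximum
        (the default); otherwise by the local reference dose.
    """
    if dose_pct <= 0 or dist_mm <= 0:
        raise ValueError("dose_pct and dist_mm must be positive")
    if (ref.x.max() < eval_plane.x.min() or eval_plane.x.max() < ref.x.min()
            or ref.y.max() < eval_plane.y.min() or eval_plane.y.max() < ref.y.min()):
        raise PlaneError("reference and evaluated planes do not overlap")

    ref_max = float(ref.values.max())
    if ref_max <= 0:
        raise PlaneError("reference plane has no positive dose")
    evaluated = ref.values >= threshold_pct / 100.0 * ref_max
    if not evaluated.any():
        raise PlaneError("every reference pixel is below the dose threshold")

    interp = RegularGridInterpolator(
        (eval_plane.y, eval_plane.x), eval_plane.values,
        bounds_error=False, fill_value=np.nan,
    )

    xs, ys = np.meshgrid(ref.x, ref.y)
    px = xs[evaluated]
    py = ys[evaluated]
    pdose = ref.values[evaluated]
    if global_norm:
        ddmax = dose_pct / 100.0 * ref_max
        ddmax = np.full_like(pdose, ddmax)
    else:
        ddmax = dose_pct / 100.0 * pdose

    step = 0.1 * dist_mm
    radius = 3.0 * dist_mm
    k = int(np.floor(radius / step))
    offs = step * np.arange(-k, k + 1)
    ox, oy = np.meshgrid(offs, offs)
    d2 = ox**2 + oy**2
    keep = d2 <= radius**2 + 1e-12
    ox, oy, d2 = ox[keep], oy[keep], d2[keep]
    order = np.argsort(d2)  # near offsets first: cheap early exits
    ox, oy, d2 = ox[order], oy[order], d2[order]

    g2 = np.full(px.shape, np.inf)
    dta2 = dist_mm**2
    for dx_off, dy_off, dd2 in zip(ox, oy, d2):
        dist_term = dd2 / dta2
        live = g2 > dist_term  # pixels this offset could still improve
        if not live.any():
            break
        de = interp(np.column_stack([py[live] + dy_off, px[live] + dx_off]))
        cand = dist_term + np.where(np.isnan(de), np.inf,
                                    ((de - pdose[live]) / ddmax[live]) ** 2)
        g2[live] = np.minimum(g2[live], cand)

    gamma_flat = np.sqrt(g2)
    gamma_map = np.full(ref.values.shape, np.nan)
    gamma_map[evaluated] = gamma_flat
    finite = np.isfinite(gamma_flat)
    n_eval = int(finite.sum())
    if n_eval == 0:
        raise PlaneError("no reference pixel could be evaluated against the plane")
    pass_rate = 100.0 * float(np.count_nonzero(gamma_flat[finite] <= 1.0)) / n_eval
    return GammaResult(gamma_map, pass_rate, dose_pct, dist_mm, threshold_pct, n_eval)


# ---------------------------------------------------------------------------
# plane file I/O: delimited text grid with a two-line header
# ---------------------------------------------------------------------------

def write_plane(p: Plane2D, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# spacing: {p.spacing[0]:.9g} {p.spacing[1]:.9g}\n")
        fh.write(f"# origin: {p.origin[0]:.9g} {p.origin[1]:.9g}\n")
        np.savetxt(fh, p.values, fmt="%.9g")


def read_plane(path, spacing=None, origin=None) -> Plane2D:
    """Read a plane file; headerless matrices need ``spacing`` supplied
    (the grid is then centred on the origin unless given)."""
    path = Path(path)
    hdr_spacing = hdr_origin = None
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        s = line.strip()
        if s.startswith("#"):
            low = s[1:].strip().lower()
            if low.startswith("spacing:"):
                hdr_spacing = tuple(float(v) for v in low.split(":")[1].split())
            elif low.startswith("origin:"):
                hdr_origin = tuple(float(v) for v in low.split(":")[1].split())
        elif s:
            body.append(s)
    if not body:
        raise PlaneError(f"{path}: no data rows")
    values = np.array([[float(v) for v in row.replace(",", " ").split()] for row in body])
    sp = hdr_spacing or spacing
    if sp is None:
        raise PlaneError(f"{path}: no spacing header; pass spacing explicitly")
    if len(sp) == 1:
        sp = (sp[0], sp[0])
    org = hdr_origin if hdr_origin is not None else origin
    if org is None:
        return Plane2D.centered(values, sp)
    return Plane2D(values, sp, org)
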