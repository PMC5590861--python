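"""Phase-space file I/O and the particle container.

A phase space is an N x 6 matrix, one particle per row:

======  =========================================================
column  meaning
======  =========================================================
1       species code: |1| photon, |2| electron, |3| positron
2       kinetic energy, MeV (some legends write "MV"; the values
        are particle kinetic energies in MeV by the usual
        phase-space convention)
3, 4    x and y position on the scoring plane, mm
5, 6    direction cosines along x and y, dimensionless
======  =========================================================

The direction cosine along z is never stored: every particle travels
downstream, so ``vz = +sqrt(1 - vx^2 - vy^2)`` is recomputed on demand.
Species codes may be written signed in some conventions; the absolute
value is taken on read.

Two on-disk dialects are supported: ``matrix_text`` (whitespace- or
comma-delimited rows, optional ``#`` comment header, optional gzip) and
``matrix_binary`` (raw little-endian float64, C order, N x 6).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PhspError",
    "ParticleSet",
    "radial_distance",
    "read_phsp",
    "write_phsp",
    "PHOTON",
    "ELECTRON",
    "POSITRON",
]

PHOTON = 1
ELECTRON = 2
POSITRON = 3

_VALID_CODES = (PHOTON, ELECTRON, POSITRON)

#: tolerance on the lateral cosine norm when validating input files
COSINE_NORM_TOL = 1e-9


class PhspError(ValueError):
    """Raised for malformed or physically invalid phase-space data."""


def radial_distance(x, y):
    """Radial distance from the beam axis, ``r = sqrt(x^2 + y^2)``.

    Accepts scalars or arrays; invariant under sign flips and axis swap.
    """
    return np.hypot(x, y)


@dataclass
class ParticleSet:
    """An ordered collection of phase-space particles.

    Parameters
    ----------
    t : (N,) int array
        Species codes (1 photon, 2 electron, 3 positron).
    e : (N,) float array
        Kinetic energies, MeV; strictly positive.
    x, y : (N,) float arrays
        Positions on the scoring plane, mm.
    vx, vy : (N,) float arrays
        Direction cosines along x and y; ``vx^2 + vy^2 <= 1``.
    """

    t: np.ndarray
    e: np.ndarray
    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.int64)
        for name in ("e", "x", "y", "vx", "vy"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        n = len(self.t)
        for name in ("e", "x", "y", "vx", "vy"):
            if len(getattr(self, name)) != n:
                raise PhspError(f"column '{name}' has length {len(getattr(self, name))}, expected {n}")
        if self.validate:
            self._validate()

    def _validate(self) -> None:
        bad = ~np.isin(np.abs(self.t), _VALID_CODES)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise PhspError(f"unknown species code {self.t[i]} at row {i}")
        self.t = np.abs(self.t)
        norm2 = self.vx**2 + self.vy**2
        bad = norm2 > 1.0 + COSINE_NORM_TOL
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise PhspError(
                f"lateral cosine norm {norm2[i]:.12g} > 1 at row {i}; particle is not physical"
            )
        # norms within tolerance of 1 (storage rounding) are snapped back
        snap = norm2 > 1.0
        if snap.any():
            s = np.sqrt(norm2[snap])
            self.vx[snap] /= s
            self.vy[snap] /= s
        if not np.all(np.isfinite(self.e)) or np.any(self.e <= 0):
            i = int(np.flatnonzero(~(np.isfinite(self.e) & (self.e > 0)))[0])
            raise PhspError(f"non-positive or non-finite energy at row {i}")

    # -- derived quantities -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.t)

    def __len__(self) -> int:
        return self.n

    @property
    def r(self) -> np.ndarray:
        """Radial distance from the beam axis, mm."""
        return radial_distance(self.x, self.y)

    @property
    def vz(self) -> np.ndarray:
        """Direction cosine along z, the positive root of ``1 - vx^2 - vy^2``."""
        return np.sqrt(np.clip(1.0 - self.vx**2 - self.vy**2, 0.0, None))

    def species_fractions(self) -> dict[str, float]:
        n = max(self.n, 1)
        return {
            "photon": float(np.count_nonzero(self.t == PHOTON)) / n,
            "electron": float(np.count_nonzero(self.t == ELECTRON)) / n,
            "positron": float(np.count_nonzero(self.t == POSITRON)) / n,
        }

    def select(self, mask: np.ndarray) -> "ParticleSet":
        return ParticleSet(
            self.t[mask], self.e[mask], self.x[mask], self.y[mask],
            self.vx[mask], self.vy[mask], validate=False,
        )

    def photons(self) -> "ParticleSet":
        return self.select(self.t == PHOTON)

    def as_matrix(self) -> np.ndarray:
        """The stored six columns as an (N, 6) float64 matrix."""
        return np.column_stack([self.t.astype(np.float64), self.e, self.x, self.y, self.vx, self.vy])

    @classmethod
    def from_matrix(cls, m: np.ndarray, validate: bool = True) -> "ParticleSet":
        m = np.atleast_2d(np.asarray(m, dtype=np.float64))
        if m.shape[1] != 6:
            raise PhspError(f"expected 6 columns, got {m.shape[1]}")
        t = m[:, 0]
        if not np.allclose(t, np.round(t)):
            raise PhspError("species column contains non-integer values")
        return cls(np.round(t).astype(np.int64), m[:, 1], m[:, 2], m[:, 3], m[:, 4], m[:, 5],
                   validate=validate)


def _open_maybe_gzip(path: Path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_phsp(path, format: str = "auto") -> ParticleSet:
    """Read a phase-space file.

    Parameters
    ----------
    path : str or Path
    format : {"auto", "matrix_text", "matrix_binary"}
        ``auto`` sniffs the first bytes: printable ASCII rows are parsed as
        text, anything else as raw float64.

    Returns
    -------
    ParticleSet
        Row order preserved; species codes stored unsigned.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        with _open_maybe_gzip(path, "rb") as fh:
            head = fh.read(4096)
        sample = head.replace(b"\r", b"").replace(b"\n", b"").replace(b"\t", b"")
        is_text = all(32 <= b < 127 for b in sample[:1024]) and len(sample) > 0
        format = "matrix_text" if is_text else "matrix_binary"
    if format == "matrix_text":
        return _read_text(path)
    if format == "matrix_binary":
        return _read_binary(path)
    raise ValueError(f"unknown format {format!r}")


def _read_text(path: Path) -> ParticleSet:
    rows = []
    with _open_maybe_gzip(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.replace(",", " ").split()
            if len(parts) != 6:
                raise PhspError(f"{path}: row {lineno}: expected 6 columns, got {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise PhspError(f"{path}: row {lineno}: {exc}") from None
    if not rows:
        raise PhspError(f"{path}: no particle rows found")
    return ParticleSet.from_matrix(np.array(rows))


def _read_binary(path: Path) -> ParticleSet:
    with _open_maybe_gzip(path, "rb") as fh:
        raw = fh.read()
    data = np.frombuffer(raw, dtype="<f8")
    if data.size == 0 or data.size % 6 != 0:
        raise PhspError(f"{path}: byte length does not form an N x 6 float64 matrix")
    return ParticleSet.from_matrix(data.reshape(-1, 6))


def write_phsp(ps: ParticleSet, path, format: str = "matrix_text") -> None:
    """Write a ParticleSet to disk; ``read_phsp`` round-trips losslessly
    in binary mode and to >= 6 significant digits in text mode."""
    if ps.n == 0:
        raise PhspError("refusing to write an empty particle set")
    path = Path(path)
    m = ps.as_matrix()
    if format == "matrix_text":
        header = "# t e[MeV] x[mm] y[mm] vx vy"
        with _open_maybe_gzip(path, "wt") as fh:
            fh.write(header + "\n")
            np.savetxt(fh, m, fmt=["%d", "%.12g", "%.12g", "%.12g", "%.12g", "%.12g"])
    elif format == "matrix_binary":
        with _open_maybe_gzip(path, "wb") as fh:
            fh.write(m.astype("<f8").tobytes(order="C"))
    else:
        raise ValueError(f"unknown format {format!r}")
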