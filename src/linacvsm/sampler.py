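"""Particle generation from a virtual source model.

Each particle consumes six uniform random numbers, in this order:

1. ``U1`` — radial position ``r = F^-1(U1)``;
2. ``U2`` — azimuth ``theta = 360 * U2``; ``(x, y) = r (cos, sin)``;
3. ``U3`` — energy from the radial bin's inverse spectrum; retained;
4. ``U4x, U4y`` — two uniforms, each SOU-correlated to ``U3`` with the
   parameter achieving the local energy-cosine correlation, scaled to
   (-1, 1), and pushed through ``sqrt(2) * erfinv`` to standard-normal
   deviates ``N_Ux, N_Uy``; after the one-sided normal mixing
   ``N_Ux <- rho_v N_Uy + sqrt(1 - rho_v^2) N_Ux`` the cosine deviations
   are ``eps_k = N_Uk * sigma_k`` and ``v_k = vbar_k + eps_k``;
5. ``U5`` — particle type: photon iff ``U5 <= P_gamma``.

``vz`` completes the unit vector with the positive root.  The erfinv
transform carries the factor sqrt(2) so that ``eps_k`` has standard
deviation exactly ``sigma_k``; a compatibility flag drops the factor to
mimic implementations that scale only to the erfinv domain.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.special import erfinv

from .model import VirtualSourceModel
from .phsp import ELECTRON, PHOTON, ParticleSet
from .sou import correlated_pair_for_rho

__all__ = [
    "sample_position",
    "sample_energy",
    "sample_direction",
    "sample_type",
    "generate",
]

log = logging.getLogger(__name__)

#: open-interval clamp keeping erfinv finite at U4 in {0, 1}
_ERFINV_CLIP = 1.0 - 1e-12
#: redraw budget before lateral cosines are renormalized into the unit disc
_MAX_REDRAWS = 100


def sample_position(radial, rng: np.random.Generator, n: int):
    """Draw positions: ``r = F^-1(U1)``, azimuth ``theta = 360 U2`` degrees."""
    u1 = rng.random(n)
    u2 = rng.random(n)
    r = np.asarray(radial(u1), dtype=np.float64)
    theta = 2.0 * np.pi * u2
    return r * np.cos(theta), r * np.sin(theta), r


def sample_energy(energy_model, r, rng: np.random.Generator):
    """Draw energies from the per-radial-bin inverse spectra; U3 is
    returned because the direction chain reuses it."""
    r = np.atleast_1d(r)
    u3 = rng.random(r.shape)
    e = energy_model.sample(r, u3)
    return e, u3


def _normal_from_uniform(u4, sqrt2: bool = True):
    scaled = np.clip(2.0 * u4 - 1.0, -_ERFINV_CLIP, _ERFINV_CLIP)
    z = erfinv(scaled)
    return np.sqrt(2.0) * z if sqrt2 else z


def sample_direction(surfaces, cal, x, y, u3, rng: np.random.Generator, sqrt2: bool = True):
    """Draw direction cosines for particles at (x, y) with energy variate u3.

    Returns (vx, vy, vz, n_renormalized); the renormalization path — for
    sampled lateral norms that exceed 1 even after redraws — is counted so
    its rarity can be verified.
    """
    x = np.atleast_1d(np.asarray(x, dtype=np.float64))
    y = np.atleast_1d(np.asarray(y, dtype=np.float64))
    u3 = np.atleast_1d(np.asarray(u3, dtype=np.float64))
    loc = surfaces.evaluate(x, y)
    vbx, vby = loc["vbar_x"], loc["vbar_y"]
    sx, sy = loc["sigma_x"], loc["sigma_y"]
    rex, rey, rv = loc["rho_ex"], loc["rho_ey"], loc["rho_v"]

    def draw(idx):
        u4x = correlated_pair_for_rho(u3[idx], rex[idx], cal, rng)
        u4y = correlated_pair_for_rho(u3[idx], rey[idx], cal, rng)
        nx = _normal_from_uniform(u4x, sqrt2)
        ny = _normal_from_uniform(u4y, sqrt2)
        nx = rv[idx] * ny + np.sqrt(1.0 - rv[idx] ** 2) * nx
        return vbx[idx] + nx * sx[idx], vby[idx] + ny * sy[idx]

    idx = np.arange(len(x))
    vx = np.empty_like(vbx)
    vy = np.empty_like(vby)
    vx[idx], vy[idx] = draw(idx)
    for _ in range(_MAX_REDRAWS):
        bad = np.flatnonzero(vx**2 + vy**2 > 1.0)
        if bad.size == 0:
            break
        vx[bad], vy[bad] = draw(bad)
    bad = np.flatnonzero(vx**2 + vy**2 > 1.0)
    n_renorm = int(bad.size)
    if n_renorm:
        norm = np.sqrt(vx[bad] ** 2 + vy[bad] ** 2) / np.sqrt(1.0 - 1e-12)
        vx[bad] /= norm
        vy[bad] /= norm
        log.warning("renormalized %d lateral cosine pairs exceeding unit norm", n_renorm)
    vz = np.sqrt(np.clip(1.0 - vx**2 - vy**2, 0.0, None))
    return vx, vy, vz, n_renorm


def sample_type(p_gamma: float, rng: np.random.Generator, n: int):
    """Species channel: photon iff U5 <= P_gamma, independent of all else."""
    if not 0.0 <= p_gamma <= 1.0:
        raise ValueError("p_gamma must be in [0, 1]")
    u5 = rng.random(n)
    return np.where(u5 <= p_gamma, PHOTON, ELECTRON)


def generate(vsm: VirtualSourceModel, n: int, seed: int) -> ParticleSet:
    """Generate ``n`` particles from the model; deterministic per seed.

    Stage order (position, energy, direction, type) fixes the random
    stream layout, so the same seed always yields the identical file.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    x, y, r = sample_position(vsm.radial, rng, n)
    e, u3 = sample_energy(vsm.energy, r, rng)
    vx, vy, vz, n_renorm = sample_direction(vsm.directions, vsm.sou, x, y, u3, rng)
    t = sample_type(vsm.p_gamma, rng, n)
    if n_renorm:
        log.info("generate: %d / %d particles needed lateral renormalization", n_renorm, n)
    return ParticleSet(t, e, x, y, vx, vy, validate=False)
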