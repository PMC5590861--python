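# linacvsm

A single-source **virtual source model (VSM)** of a linear-accelerator
photon beam, derived from a phase-space file (PSF), for Monte Carlo dose
calculation workflows.

A PSF records every particle crossing a scoring plane below the linac
head — position `(x, y)` in mm, direction cosines `(vx, vy)`, kinetic
energy `e` in MeV and species `t` — and typically weighs gigabytes. A
VSM replaces it with a few kilobytes of fitted distributions that can
emit *any* number of statistically equivalent particles, free of the
latent variance that comes from recycling a finite PSF. This package
implements the whole chain for medical physicists and Monte Carlo
developers: read/analyse a PSF, derive the model, sample particles, and
quantify the agreement with distribution comparisons and gamma analysis.

## The model

All model components are derived on the scoring plane itself; no
pre-phase-space geometry (target, jaws, flattening filter) is needed.

**Position.** Radial symmetry upstream of the MLC makes the particle
fluence a function of `r = √(x²+y²)` alone. The empirical radial CDF
(0.1 mm histogram) is inverted and fitted with a 30-segment degree-4
monotone spline `F⁻¹`; sampling is inverse-transform:

```
r = F⁻¹(U₁),   θ = 360°·U₂,   (x, y) = r (cos θ, sin θ)
```

**Energy.** Thirty-five radially binned spectra — 25 bins of 2 mm
covering 0–50 mm, 9 bins of 5 mm covering 50–95 mm, one open bin beyond
95 mm — each stored as a degree-5 inverse-CDF spline `E_h⁻¹`, sampled as
`e = E_h⁻¹(U₃)` with `h` the bin containing `r`.

**Direction.** The plane is divided into a 141×141 grid of 1 mm² cells.
Per cell the model records the mean direction cosines `v̄ˣ, v̄ʸ`, their
spread `σˣ, σʸ`, the energy–cosine correlations `ρᵉˣ, ρᵉʸ` and the
cosine–cosine correlation `ρᵛ`. Seven polynomial surfaces are fitted to
these maps by weighted least squares (weights `1/SE²` of the cell mean,
correcting heteroscedasticity): a piecewise linear/cubic surface for
each mean cosine — linear inside the *primary region* (cells holding
≥ 20 % of the maximum cell count, radius ≤ T), a restricted cubic term
set outside — and full-plane surfaces of total degree 4 (σ), 3 (ρᵉᵛ)
and 5 (ρᵛ). Sampling draws two uniforms `U₄ₓ, U₄ᵧ`, each correlated to
the energy variate `U₃` by the **sum-of-uniforms (SOU)** method with the
parameter `c = g(|ρ̂ᵉᵛ(x,y)|)` taken from a Monte-Carlo-calibrated map,
maps them through `√2·erfinv` to normal deviates, mixes them to the
local `ρ̂ᵛ`, and sets

```
vᵏ = v̂ᵏ(x,y) + N_Uᵏ · σ̂ᵏ(x,y),   vz = +√(1 − vx² − vy²)
```

**Species.** Photon iff `U₅ ≤ P_γ`, with `P_γ` the photon fraction of
the PSF. Six uniform random numbers generate each particle.

**Validation.** Phase-space pairs are compared by radial and per-bin
energy Kolmogorov–Smirnov distances, fluence profiles, per-cell
direction statistics, and 2D planes by the gamma index (dose difference
⊕ distance-to-agreement, e.g. 3 %/1 mm, 10 % low-dose threshold, ≥ 95 %
pixel pass criterion).

A synthetic-beam generator with analytic ground truth (divergent
point-like source, off-axis energy softening, energy–direction and
direction–direction correlations, electron contamination) makes the
entire chain testable without any external data.

## Worked example

```
$ vsm synth --n 200000 --seed 7 -o beam.phsp
$ vsm info beam.phsp
particles: 200000
species:   photon 99.3300%  electron 0.6700%  positron 0.0000%
energy:    0.001873 - 11.35 MeV
radius:    0.07481 - 110 mm

$ vsm build beam.phsp -o model.vsm --sou-n 200000
P_gamma = 0.9933; T = 15.6 mm; primary photon fraction = 75.03%

$ vsm sample model.vsm -n 200000 --seed 8 -o sampled.phsp
$ vsm compare beam.phsp sampled.phsp -o report --no-plots
{
  "n_ref": 200000,
  "n_eval": 200000,
  "radial_ks": 0.0028799999999999937,
  "energy_ks_max": 0.010408201734345535,
  ...
}
```

`P_gamma` is the photon fraction the type channel will reproduce; `T`
is the primary/secondary boundary radius found by the 20 %-of-max rule
(for this narrow synthetic beam the boundary falls at 15.6 mm — a real
flattened clinical beam puts it near the field edge); `radial_ks` is
the Kolmogorov–Smirnov distance between the reference and regenerated
radial distributions (0.003 here: the spline model reproduces the
fluence to a fraction of a percent), and `energy_ks_max` the worst
per-radial-bin spectrum distance. `vsm gamma ref.plane eval.plane
--dose 3 --dist 1` compares two dose planes and exits non-zero below a
95 % pass rate; `vsm pipeline` chains synth → build → sample → compare.

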