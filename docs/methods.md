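# Methods

This note documents the model implemented by `linacvsm`, the numerical
choices behind it, what the synthetic beam does and does not emulate,
and the conventions of the validation statistics.

## Model overview and assumptions

The virtual source model is a *single* generative source located on the
phase-space scoring plane. It assumes:

1. **Rotational symmetry of the fluence** upstream of the MLC: particle
   positions depend only on the radius `r`, so position sampling
   factorizes into a radial inverse CDF and a uniform azimuth.
2. **Energy depends on position only through `r`** — captured by 35
   radially binned spectra (2 mm bins to 50 mm, 5 mm bins to 95 mm, one
   open bin beyond). Bins are upper-edge inclusive; every `r ≥ 0` maps
   to exactly one bin.
3. **Directions depend on position, with residual dependence on
   energy.** Per 1 mm² cell, the direction distribution is modelled as
   the cell-mean cosine plus a normal deviation whose spread, energy
   coupling and x–y coupling vary smoothly across the plane (the seven
   fitted surfaces).
4. **Species is independent of everything else**: a single photon
   fraction `P_γ`. Positrons, if present in the input, are counted with
   the electrons; the direction model is built from photons only and
   reused for the contamination electrons (they are < 1 % of particles
   and their dosimetric impact at the plane is second-order).

All particles travel downstream: `vz = +√(1 − vx² − vy²) ≥ 0` is never
stored and is recomputed on demand.

## Inverse-CDF representation

Empirical CDFs (radial: 0.1 mm histogram; energy: 200 bins per
spectrum) are inverted and fitted with least-squares splines — degree 4
with 30 segments for the radius, degree 5 with 12 segments per energy
spectrum. Two numerical details matter:

* **Uniform-probability resampling.** Histogram edges are uniform in
  the *value* domain, so the raw inverted-CDF points pile up wherever
  the density is low; an unweighted spline fit through them is
  dominated by the distribution tail. The inverted CDF is therefore
  resampled onto a uniform probability grid (4097 points) before
  fitting.
* **Knot placement.** Interior knots are split half equally spaced in
  probability and half at the probability locations of equally spaced
  values. Steep stretches of the inverse CDF (low-density tails, the
  fluence core-to-halo transition) then receive knots as well as the
  body. With equal-probability knots alone the radial closed-loop KS
  distance is ≈ 0.013; the split placement brings it to ≈ 0.001 at the
  same segment count.

Histogram points pair each occupied bin's midpoint with the cumulative
mass at the bin *centre* (consistent with data spread uniformly within
a bin); the endpoints anchor at the exact sample minimum (u = 0) and
maximum (u = 1). Monotonicity is enforced by projecting the fitted
curve onto nondecreasing values on the evaluation grid (running
maximum), so the stored inverse is monotone exactly. Distributions too
degenerate to support the spline fall back to linear interpolation of
the inverted CDF.

## Direction model

Grid geometry: 141 cells × 1.0 mm per axis, centred on the beam axis
(extent [−70.5, +70.5) mm, half-open upper edges). Photons outside the
grid are excluded from the statistics.

**σ convention.** The per-cell dispersion enters twice with different
roles: as the *sampling spread* of the cosine deviation and as the
*fit weight* of the cell mean. We store both the sample standard
deviation (sd) and the standard error of the mean (se = sd/√n). The
sampled spread is sd by default (`sigma_mode="sd"`); using se would
shrink the beam divergence as the input PSF grows, which is unphysical.
Fit weights are always 1/se² — the inverse variance of the quantity
being fitted. A `sigma_mode="se"` build flag reproduces the literal
"standard error everywhere" reading for comparison.

**Surfaces.** Mean cosines use the piecewise form: terms {1, k, k′} in
the primary region (r ≤ T), {1, k, k′, k², k·k′, k³, k²·k′} outside,
where k is the surface's own axis and k′ the other. The σ, ρᵉᵛ and ρᵛ
surfaces are single full-plane polynomials of total degree 4, 3 and 5
(the MATLAB `polyNN` convention). The ρᵛ surface, which has no spread
of its own, is weighted by 1/(se_x·se_y). Cells with fewer than 10
particles or zero variance are excluded from all fits; correlations of
constant sequences are stored as 0 and flagged invalid. Evaluated
surfaces are clamped (correlations to [−1, 1], spreads to ≥ 0).
Weighted adjusted R² is recorded per fit.

**Primary region.** Cells holding ≥ 20 % of the maximum cell count form
the primary mask; `T` is the radius of the largest origin-centred
circle inside the mask (the minimum centre radius over excluded cells).
For a radial occupancy profile this recovers the 20 %-crossing radius
to within one cell.

## Sum-of-uniforms correlation

`U₄ = F_s(U₃ + c·V)` with `V ~ U(0,1)` and `F_s` the exact trapezoidal
CDF of the sum — the probability-integral transform makes the marginal
of `U₄` exactly uniform for every `c`. The map between `c` and the
realized Pearson correlation is calibrated by Monte Carlo on the grid
c ∈ [0, 10] step 0.2 with 10⁶ pairs per point, pinned to ρ(0) = 1 and
made strictly decreasing; `g` inverts it by monotone interpolation.

The calibrated range bottoms out at ρ(c = 10) ≈ 0.099. Requests below
that are induced by **randomized endpoint mixing**: with probability
|ρ|/ρ(10) the particle uses the c = 10 coupling, otherwise an
independent draw. The mixture realizes the requested correlation
exactly, keeps the marginal uniform, and keeps c inside the calibrated
interval. (Treating weak requests as fully independent instead zeroes
every |ρ| < 0.1 and biases the recovered energy–cosine correlation
maps by up to 0.1 — measurable in the closed loop.) Negative
correlations use the reflection `1 − U₄`.

**erfinv scaling.** `U₄` is scaled to the open interval (−1, 1)
(clamped at ±(1 − 10⁻¹²)) and mapped through `√2·erfinv` so the result
is a unit-variance standard normal and the cosine deviation has
standard deviation exactly σ̂. A compatibility flag (`sqrt2=False` in
`sample_direction`) drops the √2 for implementations that scale only
to the erfinv domain. The x–y coupling is the one-sided normal mix
`N_Ux ← ρᵛ·N_Uy + √(1−ρᵛ²)·N_Ux` (y drives x). Sampled lateral norms
above 1 are redrawn (up to 100 attempts, then renormalized and
counted); for realistic σ maps this path triggers on ≪ 0.1 % of
particles.

## Synthetic beam

The generator emulates a divergent point-like 6 MV-class source scored
160 mm downstream of the focus:

| parameter | default | meaning |
|---|---|---|
| `focus_dist` | 160 mm | focus-to-plane distance; mean cosines are the focal-ray values `x/√(x²+y²+f²)` |
| `core_sigma` | 10 mm | Gaussian fluence core (Rayleigh radial density); bright enough that 1 mm² cells collect ≥ 10³ photons at n = 10⁶ |
| `halo_fraction`, `halo_radius` | 8 %, 110 mm | uniform scatter halo; populates all 35 radial energy bins |
| `e_mean_axis`, `softening_rate` | 1.7 MeV, 0.005 /mm | on-axis mean energy and fractional off-axis softening of a 6 MV-class spectrum |
| `e_shape` | 2.0 | gamma-distribution shape of the local spectrum |
| `ang_sigma` | 0.01 | angular cosine noise about the focal ray |
| `rho_ev_target` | 0.3 | energy–direction correlation magnitude realized at r = 20 mm |
| `rho_v_target` | 0.2 | x–y noise correlation |
| `electron_fraction` | 0.7 % | contamination electrons (3× angular noise, spectrum softened ×2) |

The energy–direction correlation is injected physically: the lateral
cosines are scaled by `1 − λ(2q − 1)` with `q` the particle's energy
quantile, so energetic particles diverge less — giving the sign
structure of a real beam (ρᵉᵛ positive where the mean cosine is
negative and vice versa). λ is solved analytically from
`rho_ev_target`; the `ground_truth` accessor returns the resulting
per-cell mean-cosine field, spreads and correlations so tests can score
recovery without re-deriving them.

What the synthetic beam does **not** emulate: a flattening-filter
flat-top fluence (its 20 %-of-max boundary falls at ≈ 17 mm rather than
at a clinical field edge near 43 mm — the primary-region *rule* is
therefore additionally verified on a constructed flat-top profile with
a known crossing), bremsstrahlung spectral shape beyond a gamma
surrogate, collimator scatter anisotropy, and any dose deposition.
Passing the closed loop demonstrates that the model recovers the
statistical structure the generator contains, not that it reproduces
any particular clinical beam.

## Validation statistics

`compare_phase_spaces` scores an evaluated set against a reference:

* radial KS distance and per-radial-bin energy KS distances — the
  energy table is restricted to bins with ≥ 10⁴ particles per side
  (two-sample KS noise at 10³ particles is ≈ 0.05 at the 95 % level,
  which would swamp model error);
* per-1 mm²-cell mean-cosine differences where both sides hold ≥ 10³
  particles (the cell-mean SE ≈ 0.0003 supports this resolution);
* spread and correlation differences on a **3 mm analysis grid** with
  ≥ 10⁴ particles per cell per side. Per-1 mm²-cell PCC estimates at
  feasible counts carry sampling noise of several hundredths — two
  independent draws of the *same* beam differ by up to 0.16 in
  per-cell ρᵉᵛ at n = 10⁶ — so the coarser grid is the finest
  resolution at which the comparison measures the model rather than
  the estimator.

The gamma engine evaluates, per reference pixel above the low-dose
threshold (default 10 % of the global maximum), the minimum over
evaluated-plane positions of the combined dose-difference /
distance-to-agreement metric, with the evaluated plane interpolated at
0.1·DTA steps within a 3·DTA search radius, global normalization by
default, and one-sided evaluation (reference → evaluated) as in
standard practice. On ≤ 64×64 planes it agrees with an exhaustive
brute-force oracle to < 0.01.

## Problem sizes and determinism

The closed-loop study uses n = 10⁶ particles for build and generation
and 10⁶ pairs per SOU calibration point — sizes at which every
tolerance sits at least a factor of two above its estimator noise floor
while the full acceptance run stays around a minute. All stages are
driven by `numpy.random.default_rng` with explicit seeds; a saved model
reloaded from JSON generates a bit-identical particle stream.

## Known limitations

* Grid geometry (141 × 1 mm) is fixed by default; the effect of grid
  size on model fidelity is not explored.
* Electrons share the photon position/energy/direction model; only the
  species label differs. Adequate at sub-percent contamination, wrong
  for electron-rich beams.
* The energy–direction coupling acts through a single uniform variate
  per axis; correlation structure beyond the Pearson coefficient (tail
  dependence, nonmonotone coupling) is not modelled.
* Positions outside the grid extent evaluate the secondary-region
  polynomial extrapolation; far outside the fitted domain the clamps,
  not the data, bound the values.
* Dose deposition is out of scope: planes are consumed, never
  computed, and the central-plane gamma check compares smoothed
  fluence planes, not transported dose.
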