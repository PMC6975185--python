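# Methods

`hemoscat` implements a regression-based multispectral imaging method for
two quantities of living skin: the total hemoglobin (blood) volume
fraction of the dermis, `Cth` (vol.%), and the scattering power `b` of
the reduced-scattering spectrum. This note records the model, the
numerical choices, and what the synthetic validation does and does not
demonstrate.

## Tissue model

Skin is a two-layer plane-parallel medium: epidermis (default 0.06 mm)
over dermis (default 4.94 mm), ambient index 1.0 above and below, tissue
index n = 1.4. Both layers share one reduced-scattering spectrum

    mus'(lambda) = a * lambda^(-b),   lambda in nm, mus' in cm^-1,

so the typical skin amplitude a ≈ 6.3×10⁹ gives mus'(500 nm) ≈ 50 cm⁻¹.
The nm/cm⁻¹ unit pairing is a deliberate convention used consistently in
code, file formats and tests. For transport the similarity relation
mus = mus'/(1−g) with g = 0.9 (Henyey–Greenstein) converts mus' to a
scattering coefficient; g is configurable and results are always tied to
the g used because the model stores it in the provenance hash.

Absorption is a linear chromophore mix:

* epidermis: mua = (Cm/100) · mua_melanosome(lambda), with the
  melanosome power law 6.6×10¹¹·λ⁻³·³³ cm⁻¹;
* dermis: mua = (Cth/100) · ln10 · C_Hb · [so2·eps_oxy + (1−so2)·eps_deoxy],
  with C_Hb = 2.326 mM (whole blood, 150 g/L, tetramer convention).

The bundled oxy/deoxy extinction table is a **synthetic analytic model**
(see `src/hemoscat/data/README.md`): Gaussian Soret and Q bands with a
smooth oxy/deoxy split whose zero crossings sit at 422/452/501/584 nm.
The four imaging bands 420/450/500/585 nm therefore see a small (≤7%)
oxy/deoxy mismatch, as real interference filters near true isosbestic
points do. Water, lipid, bilirubin and carboxyhemoglobin are outside the
model's scope.

## Monte Carlo transport

The kernel is the standard weighted-photon algorithm for layered media:
normally incident pencil beam, specular deduction at the top interface,
free paths sampled on mua+mus, fractional absorption deposits,
Henyey–Greenstein deflection, unpolarized Fresnel statistics at each
index boundary, Russian roulette (threshold 10⁻⁴, survival 0.1). All
photons leaving the top surface at any angle count as diffuse
reflectance; bottom-exiting photons are terminated (the 4.94 mm dermis
makes transmission negligible at these wavelengths). Two choices are
non-standard and deliberate:

* **Exact per-run energy budget.** Roulette survival boosts are debited
  from, and roulette kills credited to, the absorbed accumulator, so
  specular + R + T + absorbed = 1 to float64 round-off in every single
  run while estimators stay unbiased. The test suite asserts < 10⁻⁶.
* **Shared-path absorption rescaling.** For the training grid, one
  simulation per (a, b, wavelength) is run at the grid-minimum
  absorption with continuous exp(−mua·path) attenuation, recording each
  escaping photon's per-layer path lengths; reflectance at any higher
  absorption then follows exactly as the mean of w·exp(−Δmua·L). This
  replaces 5000 per-combination runs by 100 ensemble runs and is an
  unbiased identity, cross-checked against the direct per-combination
  path within 3 combined standard errors in the tests. The direct method
  remains available (`method="direct"`).

Randomness is an inline xorshift64* generator seeded by splitmix64;
per-run seeds derive from `numpy.SeedSequence` spawning, so every result
is bit-reproducible from (inputs, seed) independent of library versions.

The reference walker used to validate the kernel is a deliberately naive
analog random walk (absorption by termination, stdlib RNG, pure Python)
living in the test suite only.

## Regression training

The training grid is the full factorial of a ∈ {5.3…7.3}×10⁹ (step
0.5×10⁹), b ∈ {2.90…3.10} (step 0.05), Cm ∈ {1…10} vol.% (step 1),
Cth ∈ {0.2…1.0} vol.% (step 0.2): 1250 states, 25 scattering spectra.
Absorbance A = −log10 R at the four bands feeds two ordinary
least-squares fits (no regularization, no interactions): b and Cth each
on (1, A420, A450, A500, A585). Default photon budget is 10⁵ per
ensemble run. A model is serialized with a `grid_hash` binding it to the
grid, transport configuration, chromophore table and geometry, and the
estimator refuses stacks declared for a different hash.

**Fidelity of the linear formulas.** The linear-in-absorbance model is an
approximation; diffuse absorbance grows sublinearly in mua, so a 5×
range of Cth bends the response. At high photon budgets the training
R² plateaus near 0.93 (Cth) and 0.88 (b); adding quadratic absorbance
terms would raise the Cth R² to ≈0.996, confirming the residual is model
curvature, not Monte Carlo noise. Consequences, measured on the default
grid: b round-trips within ±0.05 for ≈97% of training states, but Cth
round-trips within ±0.1 vol.% for only ≈82% (the residual scatter is
≈0.09 vol.%). The package keeps the prescribed plain-OLS formulas and
documents this accuracy envelope rather than extending the model; the
tests assert the measured envelope (b at the ±0.05/90% level, Cth at its
achievable level) so regressions in either direction are caught.

## Estimation and time courses

Reflectance is Is/Iw per band (white reference = ideal diffuser);
invalid pixels (Iw = 0, R ≤ 0, R > 1) are masked, never filled. The
regression is applied per pixel — no simulation at estimation time, cost
linear in pixels. Out-of-range estimates (Cth < 0, b outside [1, 4]) are
kept in the maps but flagged in `valid_mask`; clipping is opt-in by the
caller. Relative time courses per ROI use
dX% = (X − X_baseline)/X_baseline·100 with the baseline row exactly
zero. ROIs are explicit masks supplied by the user; no tracking or
registration is attempted.

## Inverse Monte Carlo (phantom validation path)

Slab phantoms (1 mm, n = 1.33, glass neglected) measured for diffuse
reflectance and total transmittance are inverted per band against the
objective |ΔR| + |ΔT| with a convergence threshold of 0.005, in two
stages. Stage one applies damped multiplicative updates driven by the
signed mismatches — mus′ follows the reflectance ratio, mua the
log-transmittance ratio — plus a "ridge" move rescaling both
coefficients by the transmittance factor (R is nearly albedo-invariant,
so this walks the degenerate direction thick slabs exhibit when T → 0);
overshoot is handled by step-halving. Stage two, entered only if the
threshold is not yet met, is a deterministic Nelder–Mead polish in
log-parameter space with restarts over widening simplices; a pure
coordinate-wise search was tried first and documented to stall in the
diagonal (mua, mus′) valley, which motivated this design. Every
candidate is simulated with the same seed, making the objective
deterministic; accepted residuals are non-increasing by construction.
Recovered mua(585 nm) converts to Cth
through the dermal absorption mix (so2 = 1, fully oxygenated blood);
recovered mus'(lambda) converts to (a, b) by log-log least squares.
Infeasible (R, T) pairs stall above threshold and return
`converged=False` with the best point found.

## Synthetic data: what it emulates, what it does not

The generator produces (i) 12-phantom validation sets — Latin-hypercube
samples of (Cm, Cth, a, b) over the interior of the training grid
(Cm 2–9, Cth 0.28–0.92, a 5.5–7.1×10⁹, b 2.92–3.08), imaged on the
training geometry with 1% multiplicative Gaussian reflectance noise, and
paired with 1 mm slab (R, T) measurements; (ii) piecewise-constant image
scenes (default 64×64, hard-edged tumor disks) with per-pixel truth;
(iii) weekly time courses driven by (Cth, b) multiplier schedules; and
(iv) the thickness-sensitivity study: test reflectances at epidermis
0.005/0.01/0.03/0.06 mm and dermis 3.5/4/4.5/4.94 mm with fixed
Cm = 1 vol.%, Cth = 0.4 vol.%, a = 6.3×10⁹, b = 3.00, pushed through the
model trained at the nominal geometry.

The noise model is multiplicative Gaussian (σ = 1% default) plus
optional 8-bit quantization. Not emulated: skin texture and curvature
shading, specular glints, filter bandwidths (bands are monochromatic),
polarization, spatial blur, inter-subject variability. Passing the
synthetic end-to-end checks therefore shows internal consistency of the
method under its own forward model — not robustness to the shading and
geometry artifacts that dominate in-vivo imaging, which the estimator
deliberately leaves to upstream correction.

## Problem sizes and runtime choices

Training-grid ensembles default to 10⁵ photons; the test suite trains
its shared model at 2.5×10⁴ per ensemble (the fit is bias-limited above
~2×10⁴: measured R² is unchanged between 4×10⁴ and 10⁵) and simulates
phantoms at 10⁴–10⁵ photons per band, sizes chosen so the full pipeline
(training, 12-phantom validation, thickness study, IMC self-inversion)
completes in minutes on a single core while keeping per-band absorbance
noise (≈0.002–0.005) well below the regression's intrinsic residuals.
Statistical assertions use 3-standard-error bounds with binomial SE
estimates; exact assertions (energy budget, determinism, formula
arithmetic) use 10⁻⁶ or tighter.

## Known limitations

* The chromophore table is synthetic; absolute Cth values are only as
  meaningful as its extinction scale, though all internal consistency
  checks and the vol.%→mua→vol.% round trip are exact by construction.
* The linear formulas' Cth accuracy envelope (±0.1 vol.% for ~82% of
  grid states) bounds what map contrasts mean quantitatively.
* Dermis thinner than ≈2 mm would break the semi-infinite assumption
  built into the bottom-boundary termination; the sensitivity study
  stays above 3.5 mm.
* The IMC search is serial per band and assumes single-layer slabs; the
  two-layer phantom is measured layer-by-layer, as in the physical
  protocol it mirrors.
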