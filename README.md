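# hemoscat

Multispectral diffuse-reflectance imaging of **total hemoglobin
concentration** (Cth, vol.%) and **scattering power** (b) of skin, using
reflectance images at four near-isosbestic wavelengths of hemoglobin:
420, 450, 500 and 585 nm.

## Who this is for

Researchers in tissue optics and preclinical imaging who want to monitor
dermal hemodynamics (angiogenesis, hyperemia) and tissue morphology
(cell swelling, fibrosis) noninvasively over time — for example weekly
imaging of mouse skin during chemically induced carcinogenesis — with a
camera, four narrow-band filters and a white reference, and no per-image
simulation cost.

## The method

Skin is modeled as epidermis (melanin, fraction Cm) over dermis (blood,
fraction Cth), both sharing the reduced-scattering power law

    μs′(λ) = a·λ⁻ᵇ        (λ in nm, μs′ in cm⁻¹)

Diffuse reflectance R(λ) of this model is simulated by Monte Carlo
photon transport for all 1250 combinations of a grid over (Cm, Cth, a, b).
Absorbance A(λ) = −log₁₀ R(λ) at the four bands then trains two
ordinary-least-squares formulas

    b   = α₀ + α₁A(420) + α₂A(450) + α₃A(500) + α₄A(585)
    Cth = β₀ + β₁A(420) + β₂A(450) + β₃A(500) + β₄A(585)

which are applied **per pixel** to measured image stacks (R = Is/Iw
against a white reference). Because the four bands sit at (near-)
isosbestic points of hemoglobin, the estimates are independent of oxygen
saturation. Time courses are reported as relative changes against a
pre-treatment baseline, ΔCth% = (Cth−Cth,c)/Cth,c·100 and likewise Δb%.

The package also implements the validation path: inverse Monte Carlo
recovery of (μa, μs′) from slab-phantom reflectance/transmittance pairs,
with Cth from μa(585 nm) and b from the log-log slope of μs′(λ).

All inputs can be generated in-package (synthetic phantom sets, tumor
scenes, weekly schedules) with recorded ground truth and seeds.

## Worked example

`examples/` holds one short script per capability. From the repository
root:

```
$ python examples/01_forward_reflectance.py
two-layer skin model, SkinParameters(cm=5.0, cth=0.6, a=6300000000.0, b=3.0)
   nm   R_diff   R_spec         T  absorbed      sum-1
  420   0.0764   0.0278  0.00e+00    0.8958   -1.0e-12
  450   0.1282   0.0278  1.05e-07    0.8440   -1.2e-13
  500   0.2339   0.0278  2.55e-03    0.7358   -3.7e-13
  585   0.2428   0.0278  2.03e-03    0.7274   -7.7e-13
```

Each row is the energy partition of one simulation: 2.78% specular
(n = 1.4 against air), diffuse reflectance rising with wavelength as
hemoglobin/melanin absorption weakens, transmission through 5 mm of
tissue essentially zero, and the recorded fractions summing to 1 to
machine precision.

`02_train_regression.py` trains the regression on a reduced grid and
prints the fitted α/β with training R²; `03_estimate_maps.py` builds a
synthetic tumor scene (elevated Cth, depressed b), estimates the maps
and prints the inside/outside contrast plus a three-week ΔCth%/Δb% time
course; `04_imc_phantom.py` closes the inverse-Monte-Carlo loop on a
synthetic slab; `05_thickness_sensitivity.py` reproduces the
layer-thickness robustness study.

A thin CLI wraps the same library calls:

```
hemoscat train --photons 100000 --seed 1 --out model.json
hemoscat estimate --model model.json --stack scene/stack.yaml --out maps/
hemoscat timecourse --maps-dir maps/ --labels wk0,wk5,wk6 --rois rois/ --baseline 0 --out tc.csv
hemoscat imc --measurements phantom.csv --out props.csv
hemoscat simulate scene.yaml --photons 50000 --seed 2 --out scene/
```

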