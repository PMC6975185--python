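"""Train the empirical absorbance regression on a reduced grid.

The full method simulates all 1250 combinations of (Cm, Cth, a, b) on the
default grid; this example trims the grid to 72 combinations so it runs
in about a minute while exercising the identical pipeline: forward Monte
Carlo -> absorbance A = -log10 R -> ordinary least squares for

    b   = alpha . (1, A420, A450, A500, A585)
    Cth = beta  . (1, A420, A450, A500, A585)

The printed R^2 values are the training fit quality; the coefficient
signs show the method at work (Cth loads positively on the blood-dominated
585 nm band, b on the scattering-dominated short-wavelength slope).
"""

from hemoscat import TransportConfig, build_training_grid, default_library, train_model

lib = default_library()
grid = build_training_grid(
    a_values=[5.3e9, 6.3e9, 7.3e9],
    b_values=[2.90, 3.00, 3.10],
    cm_values=[1.0, 4.0, 7.0, 10.0],
    cth_values=[0.2, 0.6, 1.0],
)
print(f"grid: {len(grid)} combinations, {grid.n_scattering_spectra()} scattering spectra")

model, records = train_model(grid, TransportConfig(n_photons=20_000, rng_seed=7), lib)

print(f"records simulated: {len(records)}")
print(f"alpha (b):   " + " ".join(f"{v:+.3f}" for v in model.alpha))
print(f"beta  (Cth): " + " ".join(f"{v:+.3f}" for v in model.beta))
print(f"training R^2: b = {model.training_r2_b:.3f}, Cth = {model.training_r2_cth:.3f}")
print(f"grid hash: {model.grid_hash} (binds the model to this grid + optics)")
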