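"""Forward Monte Carlo: diffuse reflectance of a two-layer skin model.

Builds the default epidermis/dermis model at grid-center parameters
(Cm = 5 vol.%, Cth = 0.6 vol.%, a = 6.3e9, b = 3.0) and simulates the
diffuse reflectance at the four near-isosbestic hemoglobin wavelengths.
The printed fractions are the energy partition of each run; their sum is
1 to float64 round-off (exact weight bookkeeping).
"""

from hemoscat import (
    ISOSBESTIC_WAVELENGTHS,
    SkinParameters,
    TransportConfig,
    build_skin_model,
    default_library,
    simulate_stack_at_wavelengths,
)

lib = default_library()
params = SkinParameters(cm=5.0, cth=0.6, a=6.3e9, b=3.0)
stack = build_skin_model(params, lib)
cfg = TransportConfig(n_photons=20_000, rng_seed=1)

print(f"two-layer skin model, {params}")
print(f"{'nm':>5} {'R_diff':>8} {'R_spec':>8} {'T':>9} {'absorbed':>9} {'sum-1':>10}")
for res in simulate_stack_at_wavelengths(stack, ISOSBESTIC_WAVELENGTHS, cfg):
    print(
        f"{res.wavelength:5.0f} {res.diffuse_reflectance:8.4f} "
        f"{res.specular_reflectance:8.4f} {res.total_transmittance:9.2e} "
        f"{res.absorbed_fraction:9.4f} {res.energy_sum() - 1.0:10.1e}"
    )
print(
    "\nReflectance rises from 420 to 585 nm as hemoglobin and melanin "
    "absorption weaken;\nthe 4.94 mm dermis transmits almost nothing."
)
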