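"""Estimate Cth and b maps of a synthetic tumor scene, then a time course.

A 32x32 scene holds a background of normal skin and a circular region of
elevated blood volume (angiogenesis) and reduced scattering power (cell
swelling).  The scene is forward-simulated into a four-band reflectance
stack with 1% multiplicative noise, and the regression model (trained
here on a small grid, for speed) maps it back to per-pixel (Cth, b).
A three-week schedule then demonstrates the dCth% / db% time-course
readout used to monitor carcinogenesis.
"""

import numpy as np

from hemoscat import (
    SkinParameters,
    TransportConfig,
    build_training_grid,
    default_library,
    estimate_maps,
    generate_image_stack,
    generate_timecourse,
    relative_change,
    train_model,
    tumor_scene,
    uniform_scene,
)

lib = default_library()

model, _ = train_model(
    build_training_grid(
        a_values=[5.3e9, 6.3e9, 7.3e9],
        b_values=[2.90, 3.00, 3.10],
        cm_values=[1.0, 5.0, 9.0],
        cth_values=[0.2, 0.6, 1.0],
    ),
    TransportConfig(n_photons=20_000, rng_seed=3),
    lib,
)

base = SkinParameters(cm=3.0, cth=0.4, a=6.3e9, b=3.05)
tumor = SkinParameters(cm=3.0, cth=0.8, a=6.3e9, b=2.92)
scene = tumor_scene(base, tumor, shape=(32, 32), radius=9, noise_sigma=0.01, seed=5)
stack, truth = generate_image_stack(scene, TransportConfig(n_photons=30_000, rng_seed=11), lib)
maps = estimate_maps(stack, model)

disk = truth.cth_map > 0.5
print("tumor scene (true Cth 0.8 / b 2.92 inside, 0.4 / 3.05 outside):")
print(f"  estimated Cth: inside {np.nanmean(maps.cth_map[disk]):.2f}, "
      f"outside {np.nanmean(maps.cth_map[~disk]):.2f} vol.%")
print(f"  estimated b:   inside {np.nanmean(maps.b_map[disk]):.3f}, "
      f"outside {np.nanmean(maps.b_map[~disk]):.3f}")

weeks = generate_timecourse(
    uniform_scene(base, (8, 8), noise_sigma=0.005, seed=6),
    [(0, 1.0, 1.0), (5, 1.0, 0.95), (7, 1.4, 0.95)],
    TransportConfig(n_photons=30_000, rng_seed=13),
    lib,
)
series = [estimate_maps(w["stack"], model) for w in weeks]
tc = relative_change(series, {"roi": np.ones((8, 8), bool)},
                     times=[w["week"] for w in weeks])
print("\nweek  dCth%   db%   (schedule: b x0.95 from week 5, Cth x1.4 at week 7)")
for i, t in enumerate(tc.times):
    print(f"{t:4d} {tc.delta_cth_pct[i, 0]:7.1f} {tc.delta_b_pct[i, 0]:6.1f}")
print("\nThe tumor disk shows higher Cth and lower b than its surround, and the"
      "\ntime course tracks the programmed hemodynamic/morphological changes.")
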