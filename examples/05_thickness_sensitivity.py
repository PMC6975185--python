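"""Layer-thickness sensitivity of the regression estimates.

The regression is trained at the nominal geometry (epidermis 0.06 mm,
dermis 4.94 mm).  Real skin varies, so this example simulates test
reflectances at perturbed thicknesses with everything else fixed
(Cm = 1 vol.%, Cth = 0.4 vol.%, a = 6.3e9, b = 3.00) and reports the
relative estimation errors.  Expected pattern: Cth error depends
systematically on epidermis thickness (thinner epidermis removes melanin
baseline absorbance, biasing Cth low), while dermis thickness in the
3.5-4.94 mm range is optically semi-infinite at these wavelengths and
leaves both estimates unchanged.
"""

from hemoscat import (
    SensitivityDesign,
    TransportConfig,
    build_training_grid,
    default_library,
    thickness_sensitivity,
    train_model,
)

lib = default_library()
model, _ = train_model(
    build_training_grid(
        a_values=[5.3e9, 6.3e9, 7.3e9],
        b_values=[2.90, 3.00, 3.10],
        cm_values=[1.0, 4.0, 7.0, 10.0],
        cth_values=[0.2, 0.6, 1.0],
    ),
    TransportConfig(n_photons=20_000, rng_seed=3),
    lib,
)

table = thickness_sensitivity(
    SensitivityDesign(), model, TransportConfig(n_photons=40_000, rng_seed=17), lib
)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(
    "\nrel_err columns are (estimate - truth)/truth; the epidermis rows show a"
    "\nmonotone Cth trend, the dermis rows only Monte Carlo noise."
)
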