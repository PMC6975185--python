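"""Regenerate the bundled synthetic chromophore extinction table.

The package ships ``src/hemoscat/data/chromophores_synthetic.csv``, a
*synthetic* spectral model of oxy-/deoxyhemoglobin molar extinction and
melanosome absorption over 400-600 nm (1 nm steps).  It is not a published
compiled table; it is an analytic stand-in with the right magnitudes and
band structure:

* a common backbone E(lambda) = Soret Gaussian (424 nm) + Q-band Gaussian
  (556 nm) + flat floor, in cm^-1/M;
* oxy = E*(1+d), deoxy = E*(1-d), where d(lambda) is a bounded smooth
  function whose zeros (isosbestic crossings) sit at 422, 452, 501 and
  584 nm -- near, but deliberately not exactly at, the four imaging
  wavelengths 420/450/500/585 nm, mimicking how real interference filters
  sit close to true isosbestic points;
* melanosome absorption as the standard power law 6.6e11 * lambda^-3.33.

Run from the repository root:  python scripts/make_chromophore_table.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

ISOSBESTIC_ZEROS = (422.0, 452.0, 501.0, 584.0)


def hemoglobin_backbone(lam: np.ndarray) -> np.ndarray:
    """Common oxy/deoxy extinction backbone, cm^-1/M."""
    soret = 4.8e5 * np.exp(-((lam - 424.0) ** 2) / (2 * 16.0**2))
    qband = 4.5e4 * np.exp(-((lam - 556.0) ** 2) / (2 * 30.0**2))
    floor = 1.2e4
    return soret + qband + floor


def oxy_deoxy_split(lam: np.ndarray) -> np.ndarray:
    """Signed relative oxy/deoxy difference with isosbestic zeros."""
    d = np.full_like(lam, 0.25, dtype=float)
    for lz in ISOSBESTIC_ZEROS:
        d *= np.tanh((lam - lz) / 15.0)
    return d


def melanosome_mua(lam: np.ndarray) -> np.ndarray:
    """Interior-melanosome absorption power law, cm^-1."""
    return 6.6e11 * lam**-3.33


def build_table(lam_min: float = 400.0, lam_max: float = 600.0) -> pd.DataFrame:
    lam = np.arange(lam_min, lam_max + 1.0, 1.0)
    e = hemoglobin_backbone(lam)
    d = oxy_deoxy_split(lam)
    return pd.DataFrame(
        {
            "wavelength_nm": lam,
            "eps_oxy": e * (1.0 + d),
            "eps_deoxy": e * (1.0 - d),
            "mua_melanin": melanosome_mua(lam),
        }
    )


if __name__ == "__main__":
    out = Path(__file__).resolve().parents[1] / "src" / "hemoscat" / "data"
    out.mkdir(parents=True, exist_ok=True)
    table = build_table()
    table.to_csv(out / "chromophores_synthetic.csv", index=False, float_format="%.6g")
    print(f"wrote {out / 'chromophores_synthetic.csv'} ({len(table)} rows)")
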