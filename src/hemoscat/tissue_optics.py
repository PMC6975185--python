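"""Wavelength-resolved optical properties of layered skin and phantoms.

The tissue model has four unknowns: melanin volume fraction ``Cm`` in the
epidermis, total hemoglobin (blood) volume fraction ``Cth`` in the dermis,
and the two parameters of the reduced-scattering power law

    mus'(lambda) = a * lambda**(-b)        [lambda in nm, mus' in cm^-1]

shared by both layers.  With the typical skin value a ~ 6.3e9 this
convention yields mus'(500 nm) ~ 50 cm^-1, the accepted magnitude for skin;
the nm/cm^-1 unit pairing is deliberate and used consistently everywhere in
the package.

Absorption is a linear mix of chromophores:

* epidermis: mua_e = (Cm/100) * mua_melanosome(lambda)
* dermis:    mua_d = (Cth/100) * ln(10) * C_Hb * [so2*eps_oxy + (1-so2)*eps_deoxy]

where C_Hb = 2.326e-3 M is whole-blood hemoglobin (150 g/L, 64.5 kDa
tetramer).  The bundled extinction table (see ``data/README.md``) is a
synthetic analytic model whose oxy/deoxy spectra cross near the four
imaging wavelengths 420/450/500/585 nm, so mua_d is nearly independent of
oxygen saturation there.

For photon transport the reduced scattering coefficient is mapped to
(mus, g) by the similarity relation mus = mus'/(1-g) with g = 0.9 by
default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

#: Whole-blood hemoglobin molar concentration, mol/L (150 g/L / 64500 g/mol,
#: tetramer convention).
HB_MOLAR_CONCENTRATION_BLOOD = 150.0 / 64500.0

#: The four imaging wavelengths (nm), near-isosbestic for hemoglobin.
ISOSBESTIC_WAVELENGTHS = (420.0, 450.0, 500.0, 585.0)

#: Default layer thicknesses of the two-layer skin model, mm.
DEFAULT_EPIDERMIS_MM = 0.06
DEFAULT_DERMIS_MM = 4.94

#: Default anisotropy and refractive indices.
DEFAULT_G = 0.9
N_SKIN = 1.4
N_PHANTOM = 1.33
N_AMBIENT = 1.0

LN10 = np.log(10.0)


class WavelengthError(LookupError):
    """Requested wavelength is outside the chromophore table."""


@dataclass(frozen=True)
class ChromophoreLibrary:
    """Molar extinction and melanin absorption spectra on a wavelength grid.

    Attributes
    ----------
    wavelengths : ndarray
        Grid in nm.
    eps_hb_oxy, eps_hb_deoxy : ndarray
        Oxy-/deoxyhemoglobin molar extinction, cm^-1/M.
    mua_melanin_ref : ndarray
        Interior-melanosome absorption, cm^-1.
    hb_molar_concentration_whole_blood : float
        Conversion constant for blood vol.% -> mua, mol/L.
    """

    wavelengths: np.ndarray
    eps_hb_oxy: np.ndarray
    eps_hb_deoxy: np.ndarray
    mua_melanin_ref: np.ndarray
    hb_molar_concentration_whole_blood: float = HB_MOLAR_CONCENTRATION_BLOOD

    def __post_init__(self) -> None:
        for name in ("eps_hb_oxy", "eps_hb_deoxy", "mua_melanin_ref"):
            if not np.all(getattr(self, name) > 0):
                raise ValueError(f"{name} must be strictly positive")
        for lam in ISOSBESTIC_WAVELENGTHS:
            if self.has_wavelength(lam):
                eo = self.lookup(lam, "eps_hb_oxy")
                ed = self.lookup(lam, "eps_hb_deoxy")
                if abs(eo - ed) / eo > 0.10:
                    raise ValueError(
                        f"oxy/deoxy mismatch at {lam} nm exceeds the 10% "
                        "isosbestic tolerance"
                    )

    def has_wavelength(self, lam: float) -> bool:
        return bool(np.any(np.isclose(self.wavelengths, lam)))

    def lookup(self, lam: float, column: str) -> float:
        idx = np.flatnonzero(np.isclose(self.wavelengths, lam))
        if idx.size == 0:
            raise WavelengthError(
                f"{lam} nm not in chromophore table "
                f"({self.wavelengths[0]:g}-{self.wavelengths[-1]:g} nm)"
            )
        return float(getattr(self, column)[idx[0]])

    def digest(self) -> str:
        """Stable hash of the table contents, for model provenance."""
        import hashlib

        h = hashlib.sha256()
        for arr in (self.wavelengths, self.eps_hb_oxy, self.eps_hb_deoxy, self.mua_melanin_ref):
            h.update(np.asarray(arr, dtype=np.float64).tobytes())
        h.update(np.float64(self.hb_molar_concentration_whole_blood).tobytes())
        return h.hexdigest()[:16]

    @classmethod
    def from_csv(cls, path: str | Path) -> "ChromophoreLibrary":
        t = pd.read_csv(path)
        return cls(
            wavelengths=t["wavelength_nm"].to_numpy(float),
            eps_hb_oxy=t["eps_oxy"].to_numpy(float),
            eps_hb_deoxy=t["eps_deoxy"].to_numpy(float),
            mua_melanin_ref=t["mua_melanin"].to_numpy(float),
        )


def default_library() -> ChromophoreLibrary:
    """Load the bundled (synthetic) chromophore table."""
    with resources.as_file(
        resources.files("hemoscat.data") / "chromophores_synthetic.csv"
    ) as p:
        return ChromophoreLibrary.from_csv(p)


@dataclass(frozen=True)
class SkinParameters:
    """One tissue state: (Cm, Cth, a, b).

    Cm, Cth in vol.%; a in units such that mus' is in cm^-1 for lambda in
    nm; b dimensionless.
    """

    cm: float
    cth: float
    a: float
    b: float

    def __post_init__(self) -> None:
        # zero concentrations are admitted as the purely-scattering limit
        if not (0.0 <= self.cm <= 100.0):
            raise ValueError(f"Cm must be in [0, 100], got {self.cm}")
        if not (0.0 <= self.cth <= 100.0):
            raise ValueError(f"Cth must be in [0, 100], got {self.cth}")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("scattering amplitude a and power b must be > 0")


@dataclass(frozen=True)
class OpticalLayer:
    """One plane-parallel layer: thickness (mm) and per-wavelength optics."""

    thickness: float  # mm
    mua: np.ndarray  # cm^-1, per wavelength
    mus: np.ndarray  # cm^-1, per wavelength
    g: float
    n: float

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("layer thickness must be > 0")
        if np.any(np.asarray(self.mua) < 0) or np.any(np.asarray(self.mus) < 0):
            raise ValueError("mua and mus must be >= 0")
        if not (-1.0 < self.g < 1.0):
            raise ValueError("anisotropy g must be in (-1, 1)")
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")


@dataclass(frozen=True)
class LayerStack:
    """Ordered optical layers, top first, sharing one wavelength grid."""

    layers: tuple[OpticalLayer, ...]
    wavelengths: np.ndarray
    n_ambient: float = N_AMBIENT

    def __post_init__(self) -> None:
        if len(self.layers) == 0:
            raise ValueError("LayerStack needs at least one layer")
        nlam = len(self.wavelengths)
        for ly in self.layers:
            if len(np.atleast_1d(ly.mua)) != nlam or len(np.atleast_1d(ly.mus)) != nlam:
                raise ValueError("all layers must share the stack wavelength grid")

    def wavelength_index(self, lam: float) -> int:
        idx = np.flatnonzero(np.isclose(self.wavelengths, lam))
        if idx.size == 0:
            raise WavelengthError(f"{lam} nm not defined on this stack")
        return int(idx[0])


def reduced_scattering(a: float, b: float, lam: float | np.ndarray) -> float | np.ndarray:
    """Reduced scattering coefficient mus'(lambda) = a * lambda**(-b).

    ``lam`` in nm, result in cm^-1 (see module docstring for the unit
    convention).  Strictly decreasing in lambda for b > 0.
    """
    lam = np.asarray(lam, dtype=float) if np.ndim(lam) else float(lam)
    if a <= 0:
        raise ValueError("scattering amplitude a must be > 0")
    if np.any(np.asarray(lam) <= 0):
        raise ValueError("wavelength must be > 0")
    return a * lam ** (-b)


def mua_epidermis(cm: float, lam: float, lib: ChromophoreLibrary) -> float:
    """Epidermal absorption from melanin, cm^-1; linear in Cm (vol.%)."""
    if cm < 0:
        raise ValueError("Cm must be >= 0")
    return (cm / 100.0) * lib.lookup(lam, "mua_melanin_ref")


def mua_dermis(cth: float, so2: float, lam: float, lib: ChromophoreLibrary) -> float:
    """Dermal absorption from blood, cm^-1; linear in Cth (vol.%).

    ``so2`` is the hemoglobin oxygen saturation fraction in [0, 1].  At the
    (near-)isosbestic imaging wavelengths the result varies by < 10% over
    the whole so2 range.
    """
    if cth < 0:
        raise ValueError("Cth must be >= 0")
    if not (0.0 <= so2 <= 1.0):
        raise ValueError("so2 must be in [0, 1]")
    eps = so2 * lib.lookup(lam, "eps_hb_oxy") + (1.0 - so2) * lib.lookup(lam, "eps_hb_deoxy")
    return (cth / 100.0) * eps * LN10 * lib.hb_molar_concentration_whole_blood


def build_skin_model(
    p: SkinParameters,
    lib: ChromophoreLibrary,
    lams: Sequence[float] = ISOSBESTIC_WAVELENGTHS,
    d_epi: float = DEFAULT_EPIDERMIS_MM,
    d_derm: float = DEFAULT_DERMIS_MM,
    so2: float = 1.0,
    g: float = DEFAULT_G,
    n: float = N_SKIN,
    n_ambient: float = N_AMBIENT,
) -> LayerStack:
    """Two-layer epidermis/dermis stack for one tissue state.

    Both layers carry the same mus'(lambda) = a*lambda^-b (the model
    assumes identical scattering in epidermis and dermis), converted to
    transport mus via the similarity relation mus = mus'/(1-g).
    """
    if d_epi <= 0 or d_derm <= 0:
        raise ValueError("layer thicknesses must be > 0")
    lams = np.asarray(list(lams), dtype=float)
    if lams.size == 0:
        raise ValueError("wavelength list must not be empty")
    musp = np.array([reduced_scattering(p.a, p.b, l) for l in lams])
    mus = musp / (1.0 - g)
    mua_e = np.array([mua_epidermis(p.cm, l, lib) for l in lams])
    mua_d = np.array([mua_dermis(p.cth, so2, l, lib) for l in lams])
    epi = OpticalLayer(thickness=d_epi, mua=mua_e, mus=mus, g=g, n=n)
    derm = OpticalLayer(thickness=d_derm, mua=mua_d, mus=mus, g=g, n=n)
    return LayerStack(layers=(epi, derm), wavelengths=lams, n_ambient=n_ambient)


def load_tissue_config(path: str | Path) -> dict:
    """Read a tissue/phantom configuration from YAML or JSON.

    Recognized keys: cm, cth, a, b, d_epi, d_derm, g, n, so2, wavelengths.
    """
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"tissue config {path} did not parse to a mapping")
    return cfg


def stack_from_config(cfg: dict, lib: ChromophoreLibrary | None = None) -> LayerStack:
    """Build a LayerStack from a configuration mapping (see load_tissue_config)."""
    lib = lib or default_library()
    p = SkinParameters(cm=cfg["cm"], cth=cfg["cth"], a=cfg["a"], b=cfg["b"])
    return build_skin_model(
        p,
        lib,
        lams=cfg.get("wavelengths", ISOSBESTIC_WAVELENGTHS),
        d_epi=cfg.get("d_epi", DEFAULT_EPIDERMIS_MM),
        d_derm=cfg.get("d_derm", DEFAULT_DERMIS_MM),
        so2=cfg.get("so2", 1.0),
        g=cfg.get("g", DEFAULT_G),
        n=cfg.get("n", N_SKIN),
        n_ambient=cfg.get("n_ambient", N_AMBIENT),
    )
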