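"""Training-grid simulation and regression fitting.

The empirical estimation formulas are linear in the four-band absorbance
A(lambda) = -log10 R(lambda):

    b   = alpha0 + alpha1*A(420) + alpha2*A(450) + alpha3*A(500) + alpha4*A(585)
    Cth = beta0  + beta1 *A(420) + beta2 *A(450) + beta3 *A(500) + beta4 *A(585)

The coefficients are fitted by ordinary least squares on a full-factorial
training grid of tissue states (defaults: a in 5.3-7.3e9 step 0.5e9, b in
2.90-3.10 step 0.05, Cm in 1-10 vol.% step 1, Cth in 0.2-1.0 vol.% step
0.2 -- 1250 combinations, 25 distinct scattering spectra), each
forward-simulated at the four imaging wavelengths.

Grid simulation has two interchangeable backends:

* ``method="rescaled"`` (default): one shared-path Monte Carlo ensemble per
  (a, b, wavelength) at the grid-minimum absorption, reweighted exactly to
  every (Cm, Cth) pair -- 100 transport runs instead of 5000, with higher
  effective photon statistics per grid point.
* ``method="direct"``: the literal loop, one MCML run per combination and
  wavelength.

Both are unbiased estimators of the same reflectances and are
cross-checked in the test suite.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import mcphoton
from .mcphoton import TransportConfig, split_seed
from .tissue_optics import (
    DEFAULT_DERMIS_MM,
    DEFAULT_EPIDERMIS_MM,
    DEFAULT_G,
    ISOSBESTIC_WAVELENGTHS,
    N_SKIN,
    ChromophoreLibrary,
    SkinParameters,
    build_skin_model,
    mua_dermis,
    mua_epidermis,
)

logger = logging.getLogger(__name__)

DEFAULT_A_VALUES = tuple(np.arange(5.3e9, 7.31e9, 0.5e9))
DEFAULT_B_VALUES = (2.90, 2.95, 3.00, 3.05, 3.10)
DEFAULT_CM_VALUES = tuple(np.arange(1.0, 10.5, 1.0))
DEFAULT_CTH_VALUES = (0.2, 0.4, 0.6, 0.8, 1.0)

_BAND_NAMES = ("A420", "A450", "A500", "A585")


@dataclass(frozen=True)
class TrainingGrid:
    """Full-factorial grid of tissue states.

    Combination order is documented and deterministic:
    a (outer) -> b -> Cm -> Cth (inner).
    """

    a_values: tuple[float, ...] = DEFAULT_A_VALUES
    b_values: tuple[float, ...] = DEFAULT_B_VALUES
    cm_values: tuple[float, ...] = DEFAULT_CM_VALUES
    cth_values: tuple[float, ...] = DEFAULT_CTH_VALUES

    def __post_init__(self) -> None:
        for name in ("a_values", "b_values", "cm_values", "cth_values"):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise ValueError(f"{name} must not be empty")
            if len(set(vals)) != len(vals):
                raise ValueError(f"duplicate values in {name}")

    def __len__(self) -> int:
        return (
            len(self.a_values) * len(self.b_values)
            * len(self.cm_values) * len(self.cth_values)
        )

    @property
    def combos(self) -> list[SkinParameters]:
        return [
            SkinParameters(cm=cm, cth=cth, a=a, b=b)
            for a, b, cm, cth in itertools.product(
                self.a_values, self.b_values, self.cm_values, self.cth_values
            )
        ]

    def n_scattering_spectra(self) -> int:
        return len({(a, b) for a in self.a_values for b in self.b_values})


def build_training_grid(
    a_values: Sequence[float] = DEFAULT_A_VALUES,
    b_values: Sequence[float] = DEFAULT_B_VALUES,
    cm_values: Sequence[float] = DEFAULT_CM_VALUES,
    cth_values: Sequence[float] = DEFAULT_CTH_VALUES,
) -> TrainingGrid:
    """Construct a TrainingGrid from explicit value lists."""
    return TrainingGrid(
        a_values=tuple(float(v) for v in a_values),
        b_values=tuple(float(v) for v in b_values),
        cm_values=tuple(float(v) for v in cm_values),
        cth_values=tuple(float(v) for v in cth_values),
    )


@dataclass(frozen=True)
class TrainingRecord:
    """One simulated tissue state with its four-band absorbances."""

    params: SkinParameters
    A420: float
    A450: float
    A500: float
    A585: float

    @property
    def absorbances(self) -> np.ndarray:
        return np.array([self.A420, self.A450, self.A500, self.A585])


@dataclass(frozen=True)
class RegressionModel:
    """Fitted alpha/beta coefficient vectors with training provenance."""

    alpha: np.ndarray  # (5,) intercept + four band coefficients, for b
    beta: np.ndarray  # (5,) same layout, for Cth
    training_r2_b: float
    training_r2_cth: float
    grid_hash: str
    wavelengths: tuple[float, ...] = ISOSBESTIC_WAVELENGTHS
    created: str = ""

    def __post_init__(self) -> None:
        if len(self.alpha) != 5 or len(self.beta) != 5:
            raise ValueError("coefficient vectors must have exactly 5 entries")

    def predict(self, absorbances: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(b, Cth) from absorbances with the four bands on the last axis."""
        A = np.asarray(absorbances, dtype=float)
        if A.shape[-1] != 4:
            raise ValueError("last axis must hold the four band absorbances")
        b = self.alpha[0] + A @ self.alpha[1:]
        cth = self.beta[0] + A @ self.beta[1:]
        return b, cth

    def to_json(self, path: str | Path) -> None:
        payload = {
            "alpha": list(map(float, self.alpha)),
            "beta": list(map(float, self.beta)),
            "r2": {"b": self.training_r2_b, "cth": self.training_r2_cth},
            "grid_hash": self.grid_hash,
            "wavelengths": list(self.wavelengths),
            "created": self.created or time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RegressionModel":
        d = json.loads(Path(path).read_text())
        return cls(
            alpha=np.asarray(d["alpha"], dtype=float),
            beta=np.asarray(d["beta"], dtype=float),
            training_r2_b=float(d["r2"]["b"]),
            training_r2_cth=float(d["r2"]["cth"]),
            grid_hash=d["grid_hash"],
            wavelengths=tuple(d.get("wavelengths", ISOSBESTIC_WAVELENGTHS)),
            created=d.get("created", ""),
        )


def grid_hash(
    grid: TrainingGrid,
    cfg: TransportConfig,
    lib: ChromophoreLibrary,
    so2: float,
    d_epi: float,
    d_derm: float,
    g: float,
    n: float,
    method: str,
) -> str:
    """Provenance digest binding a model to its grid, optics and transport."""
    h = hashlib.sha256()
    for vals in (grid.a_values, grid.b_values, grid.cm_values, grid.cth_values):
        h.update(np.asarray(vals, dtype=np.float64).tobytes())
    h.update(
        np.asarray(
            [cfg.n_photons, cfg.rng_seed, cfg.roulette_threshold,
             cfg.roulette_survival, so2, d_epi, d_derm, g, n],
            dtype=np.float64,
        ).tobytes()
    )
    h.update(lib.digest().encode())
    h.update(method.encode())
    return h.hexdigest()[:16]


def simulate_training_set(
    grid: TrainingGrid,
    cfg: TransportConfig,
    lib: ChromophoreLibrary,
    so2: float = 1.0,
    d_epi: float = DEFAULT_EPIDERMIS_MM,
    d_derm: float = DEFAULT_DERMIS_MM,
    g: float = DEFAULT_G,
    n: float = N_SKIN,
    method: str = "rescaled",
    wavelengths: Sequence[float] = ISOSBESTIC_WAVELENGTHS,
) -> list[TrainingRecord]:
    """Simulate four-band absorbances for every grid combination.

    Records whose simulated reflectance is <= 0 at any band (possible only
    at very low photon counts with ``method="direct"``) are excluded with a
    logged warning: absorbance is undefined there.
    """
    if method not in ("rescaled", "direct"):
        raise ValueError(f"unknown method {method!r}")
    lams = list(wavelengths)
    refl = _simulate_grid_reflectances(
        grid, cfg, lib, so2, d_epi, d_derm, g, n, method, lams
    )
    records: list[TrainingRecord] = []
    n_excluded = 0
    for p, R in zip(grid.combos, refl):
        if np.any(R <= 0.0):
            n_excluded += 1
            continue
        A = -np.log10(R)
        records.append(TrainingRecord(params=p, A420=A[0], A450=A[1], A500=A[2], A585=A[3]))
    if n_excluded:
        logger.warning(
            "excluded %d/%d records with nonpositive simulated reflectance",
            n_excluded, len(grid),
        )
    return records


def _simulate_grid_reflectances(grid, cfg, lib, so2, d_epi, d_derm, g, n, method, lams):
    """Reflectance matrix (n_combos, n_bands) in grid combo order."""
    combos = grid.combos
    out = np.empty((len(combos), len(lams)))
    if method == "direct":
        for i, p in enumerate(combos):
            stack = build_skin_model(
                p, lib, lams=lams, d_epi=d_epi, d_derm=d_derm, so2=so2, g=g, n=n
            )
            sub = replace(cfg, rng_seed=split_seed(cfg.rng_seed, i))
            for j, res in enumerate(mcphoton.simulate_stack_at_wavelengths(stack, lams, sub)):
                out[i, j] = res.diffuse_reflectance
        return out

    # rescaled: one shared-path ensemble per (a, b, wavelength) at the
    # grid-minimum absorption, reweighted to every (Cm, Cth)
    cm_min = min(grid.cm_values)
    cth_min = min(grid.cth_values)
    n_inner = len(grid.cm_values) * len(grid.cth_values)
    run = 0
    for ia, a in enumerate(grid.a_values):
        for ib, b in enumerate(grid.b_values):
            p_ref = SkinParameters(cm=cm_min, cth=cth_min, a=a, b=b)
            stack = build_skin_model(
                p_ref, lib, lams=lams, d_epi=d_epi, d_derm=d_derm, so2=so2, g=g, n=n
            )
            for j, lam in enumerate(lams):
                mua_ref = np.array([
                    mua_epidermis(cm_min, lam, lib),
                    mua_dermis(cth_min, so2, lam, lib),
                ])
                sub = replace(cfg, rng_seed=split_seed(cfg.rng_seed, run))
                run += 1
                scale, w, L = mcphoton.run_pathlength_ensemble(stack, lam, mua_ref, sub)
                base = (ia * len(grid.b_values) + ib) * n_inner
                k = 0
                for cm in grid.cm_values:
                    me = mua_epidermis(cm, lam, lib)
                    for cth in grid.cth_values:
                        md = mua_dermis(cth, so2, lam, lib)
                        out[base + k, j] = mcphoton.reweight_reflectance(
                            scale, w, L, np.array([me, md]), mua_ref
                        )
                        k += 1
    return out


class CollinearityError(np.linalg.LinAlgError):
    """Design matrix is rank deficient; names the offending columns."""


def fit_regression(
    records: Sequence[TrainingRecord],
    grid_hash_value: str = "",
) -> RegressionModel:
    """Ordinary least squares of b and Cth on (1, A420, A450, A500, A585)."""
    if len(records) < 6:
        raise ValueError("need at least 6 records to fit 5 coefficients")
    A = np.array([r.absorbances for r in records])
    X = np.column_stack([np.ones(len(records)), A])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X)
        raise CollinearityError(
            f"design matrix rank {rank} < 5; collinear columns: {bad}"
        )
    y_b = np.array([r.params.b for r in records])
    y_cth = np.array([r.params.cth for r in records])
    alpha, *_ = np.linalg.lstsq(X, y_b, rcond=None)
    beta, *_ = np.linalg.lstsq(X, y_cth, rcond=None)
    return RegressionModel(
        alpha=alpha,
        beta=beta,
        training_r2_b=_r2(y_b, X @ alpha),
        training_r2_cth=_r2(y_cth, X @ beta),
        grid_hash=grid_hash_value,
        created=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

def _collinear_columns(X: np.ndarray) -> list[str]:
    names = ("intercept",) + _BAND_NAMES
    bad = [names[j] for j in range(1, X.shape[1]) if np.std(X[:, j]) == 0.0]
    corr = np.corrcoef(X[:, 1:], rowvar=False)
    for i in range(corr.shape[0]):
        for j in range(i + 1, corr.shape[1]):
            if abs(corr[i, j]) > 1.0 - 1e-12:
                bad.extend([_BAND_NAMES[i], _BAND_NAMES[j]])
    return sorted(set(bad)) or ["unidentified"]


def train_model(
    grid: TrainingGrid,
    cfg: TransportConfig,
    lib: ChromophoreLibrary,
    so2: float = 1.0,
    method: str = "rescaled",
    d_epi: float = DEFAULT_EPIDERMIS_MM,
    d_derm: float = DEFAULT_DERMIS_MM,
    g: float = DEFAULT_G,
    n: float = N_SKIN,
) -> tuple[RegressionModel, list[TrainingRecord]]:
    """Simulate the grid and fit the regression in one call."""
    records = simulate_training_set(
        grid, cfg, lib, so2=so2, d_epi=d_epi, d_derm=d_derm, g=g, n=n, method=method
    )
    gh = grid_hash(grid, cfg, lib, so2, d_epi, d_derm, g, n, method)
    return fit_regression(records, grid_hash_value=gh), records


def records_to_frame(records: Sequence[TrainingRecord]) -> pd.DataFrame:
    """Training set as a DataFrame (CSV layout: params then absorbances)."""
    return pd.DataFrame(
        {
            "cm": [r.params.cm for r in records],
            "cth": [r.params.cth for r in records],
            "a": [r.params.a for r in records],
            "b": [r.params.b for r in records],
            "A420": [r.A420 for r in records],
            "A450": [r.A450 for r in records],
            "A500": [r.A500 for r in records],
            "A585": [r.A585 for r in records],
        }
    )


def frame_to_records(df: pd.DataFrame) -> list[TrainingRecord]:
    return [
        TrainingRecord(
            params=SkinParameters(cm=row.cm, cth=row.cth, a=row.a, b=row.b),
            A420=row.A420, A450=row.A450, A500=row.A500, A585=row.A585,
        )
        for row in df.itertuples()
    ]
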