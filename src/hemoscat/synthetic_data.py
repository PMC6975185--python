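"""Synthetic inputs for the whole pipeline: phantom sets, image stacks,
time courses, and the layer-thickness sensitivity study.

Everything here is generated by forward Monte Carlo simulation from known
ground truth, with the truth recorded alongside and never passed through
the estimator -- estimates and truth always come from independent code
paths.  Every artifact embeds its seed and parameterization so
regeneration is bit-identical.

Noise model: multiplicative Gaussian on reflectance (shot-dominated camera
regime), sigma defaulting to 1%; optional uniform quantization emulates an
8-bit camera.  Scenes are piecewise-constant parameter maps (<= a few
distinct classes), so one transport run per unique tissue state per band
suffices and is cached.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from . import mcphoton
from .estimator import ParameterMaps, ReflectanceStack, estimate_maps
from .imc_phantom import SlabMeasurement, forward_slab
from .mcphoton import TransportConfig, split_seed
from .tissue_optics import (
    DEFAULT_DERMIS_MM,
    DEFAULT_EPIDERMIS_MM,
    ISOSBESTIC_WAVELENGTHS,
    N_PHANTOM,
    ChromophoreLibrary,
    SkinParameters,
    build_skin_model,
    mua_dermis,
    reduced_scattering,
)
from .trainer import (
    DEFAULT_A_VALUES,
    DEFAULT_B_VALUES,
    DEFAULT_CM_VALUES,
    DEFAULT_CTH_VALUES,
    RegressionModel,
)

#: Default (low, high) sampling ranges for the phantom set's varied
#: parameters -- the interior of the default training grid.  Phantoms
#: differ in (Cth, b) only; melanin fraction and scattering amplitude are
#: held at the fixed values below, mirroring a phantom series built from
#: one epidermis recipe and one scatterer stock.
GRID_INTERIOR_RANGES = {
    "cth": (0.28, 0.92),
    "b": (2.92, 3.08),
}

#: Fixed phantom parameters (may be overridden per call).
PHANTOM_FIXED = {"cm": 5.0, "a": 6.3e9}

_GRID_HULL = {
    "cm": (min(DEFAULT_CM_VALUES), max(DEFAULT_CM_VALUES)),
    "cth": (min(DEFAULT_CTH_VALUES), max(DEFAULT_CTH_VALUES)),
    "a": (min(DEFAULT_A_VALUES), max(DEFAULT_A_VALUES)),
    "b": (min(DEFAULT_B_VALUES), max(DEFAULT_B_VALUES)),
}


@dataclass(frozen=True)
class PhantomRecord:
    """One in-silico phantom: truth, imaging reflectances, slab pairs."""

    params: SkinParameters
    wavelengths: tuple[float, ...]
    reflectance: np.ndarray  # four-band imaging reflectance, noise applied
    reflectance_clean: np.ndarray
    slab_measurements: tuple[SlabMeasurement, ...]
    noise_sigma: float
    seed: int


def generate_phantom_set(
    n: int,
    cfg: TransportConfig,
    lib: ChromophoreLibrary,
    ranges: dict | None = None,
    fixed: dict | None = None,
    seed: int | None = None,
    noise_sigma: float = 0.01,
    slab_thickness_mm: float = 1.0,
    slab_photons: int | None = None,
    include_slabs: bool = True,
) -> list[PhantomRecord]:
    """Space-filling set of two-layer phantoms with known (Cth, b).

    (Cth, b) are drawn by a seeded Latin hypercube over ``ranges``
    (default: the training-grid interior); melanin fraction and
    scattering amplitude stay at ``fixed`` values (default Cm = 5 vol.%,
    a = 6.3e9), as in a phantom series built from one epidermis recipe
    and one scatterer stock.  Each phantom yields (i) its four-band
    imaging reflectance simulated on the two-layer skin geometry with
    multiplicative Gaussian noise of ``noise_sigma`` and (ii) a 1 mm
    single-layer slab (R, T) pair per band at the phantom refractive
    index, for inverse Monte Carlo.
    """
    if n < 2:
        raise ValueError("need at least 2 phantoms")
    if seed is None:
        seed = cfg.rng_seed
    ranges = dict(ranges or GRID_INTERIOR_RANGES)
    fixed = {**PHANTOM_FIXED, **(fixed or {})}
    for key, (lo, hi) in ranges.items():
        glo, ghi = _GRID_HULL[key]
        if lo < glo or hi > ghi:
            warnings.warn(
                f"phantom range for {key} ({lo}, {hi}) extends outside the "
                f"training grid ({glo}, {ghi}); estimates will extrapolate",
                UserWarning,
            )
    keys = ("cth", "b")
    sampler = qmc.LatinHypercube(d=2, seed=seed)
    unit = sampler.random(n)
    lo = np.array([ranges[k][0] for k in keys])
    hi = np.array([ranges[k][1] for k in keys])
    samples = lo + unit * (hi - lo)  # tolerates collapsed (lo == hi) ranges
    noise_rng = np.random.default_rng(seed)

    lams = ISOSBESTIC_WAVELENGTHS
    records = []
    for i, row in enumerate(samples):
        p = SkinParameters(cm=fixed["cm"], cth=row[0], a=fixed["a"], b=row[1])
        stack = build_skin_model(p, lib, lams=lams)
        sub = replace(cfg, rng_seed=split_seed(seed, 1000 + i))
        results = mcphoton.simulate_stack_at_wavelengths(stack, lams, sub)
        r_clean = np.array([r.diffuse_reflectance for r in results])
        noise = noise_rng.normal(1.0, noise_sigma, size=r_clean.shape) if noise_sigma > 0 else 1.0
        r_noisy = r_clean * noise
        slabs = []
        if include_slabs:
            slab_cfg = replace(
                cfg,
                n_photons=slab_photons or cfg.n_photons,
                rng_seed=split_seed(seed, 2000 + i),
            )
            for j, lam in enumerate(lams):
                musp = float(reduced_scattering(p.a, p.b, lam))
                mua = mua_dermis(p.cth, 1.0, lam, lib)
                proto = SlabMeasurement(
                    wavelength=lam, reflectance=0.1, transmittance=0.1,
                    thickness=slab_thickness_mm, n=N_PHANTOM,
                )
                r_s, t_s = forward_slab(
                    mua, musp, proto,
                    replace(slab_cfg, rng_seed=split_seed(slab_cfg.rng_seed, j)),
                )
                if r_s <= 0.0 or t_s <= 0.0:
                    raise ValueError(
                        f"slab run at {lam} nm returned R={r_s}, T={t_s}; "
                        "increase slab_photons (photon-starved measurement)"
                    )
                slabs.append(
                    SlabMeasurement(
                        wavelength=lam, reflectance=r_s, transmittance=t_s,
                        thickness=slab_thickness_mm, n=N_PHANTOM,
                    )
                )
        records.append(
            PhantomRecord(
                params=p, wavelengths=lams,
                reflectance=r_noisy, reflectance_clean=r_clean,
                slab_measurements=tuple(slabs),
                noise_sigma=noise_sigma, seed=seed,
            )
        )
    return records


@dataclass
class ScenePhantom:
    """Piecewise-constant imaging scene with per-pixel ground truth.

    ``cm, cth, a, b`` are 2-D maps (same shape).  Scenes should contain
    few distinct (Cm, Cth, a, b) classes; one transport run per class per
    band is performed and cached.
    """

    cm: np.ndarray
    cth: np.ndarray
    a: np.ndarray
    b: np.ndarray
    epidermis_thickness: float = DEFAULT_EPIDERMIS_MM
    dermis_thickness: float = DEFAULT_DERMIS_MM
    noise_sigma: float = 0.01
    quantize_bits: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        shapes = {np.asarray(m).shape for m in (self.cm, self.cth, self.a, self.b)}
        if len(shapes) != 1:
            raise ValueError("all parameter maps must share one shape")
        for m in (self.cm, self.cth, self.a, self.b):
            if not np.all(np.isfinite(m)):
                raise ValueError("scene parameter maps must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return np.asarray(self.cm).shape

    def scaled(self, cth_mult: float = 1.0, b_mult: float = 1.0) -> "ScenePhantom":
        return replace(
            self, cth=np.asarray(self.cth) * cth_mult, b=np.asarray(self.b) * b_mult
        )


def uniform_scene(
    params: SkinParameters,
    shape: tuple[int, int] = (64, 64),
    noise_sigma: float = 0.01,
    quantize_bits: int | None = None,
    seed: int = 0,
) -> ScenePhantom:
    """Spatially uniform scene at one tissue state."""
    full = lambda v: np.full(shape, float(v))
    return ScenePhantom(
        cm=full(params.cm), cth=full(params.cth), a=full(params.a), b=full(params.b),
        noise_sigma=noise_sigma, quantize_bits=quantize_bits, seed=seed,
    )


def tumor_scene(
    base: SkinParameters,
    tumor: SkinParameters,
    shape: tuple[int, int] = (64, 64),
    center: tuple[int, int] | None = None,
    radius: int = 12,
    noise_sigma: float = 0.01,
    seed: int = 0,
) -> ScenePhantom:
    """Uniform background with one hard-edged circular 'tumor' disk."""
    scene = uniform_scene(base, shape, noise_sigma=noise_sigma, seed=seed)
    cy, cx = center or (shape[0] // 2, shape[1] // 2)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    for name, val in (("cm", tumor.cm), ("cth", tumor.cth), ("a", tumor.a), ("b", tumor.b)):
        m = getattr(scene, name).copy()
        m[disk] = val
        setattr(scene, name, m)
    return scene


def generate_image_stack(
    scene: ScenePhantom,
    cfg: TransportConfig,
    lib: ChromophoreLibrary,
    timestamp: str = "",
) -> tuple[ReflectanceStack, ParameterMaps]:
    """Forward-simulate a scene into a ReflectanceStack plus truth maps.

    One transport run per unique (Cm, Cth, a, b) class per band, cached;
    reflectance broadcast to pixels, multiplicative Gaussian noise and
    optional quantization applied; white reference is an exact unit field.
    """
    lams = ISOSBESTIC_WAVELENGTHS
    shape = scene.shape
    flat = np.stack(
        [np.asarray(m, float).ravel() for m in (scene.cm, scene.cth, scene.a, scene.b)],
        axis=1,
    )
    classes, inverse = np.unique(flat, axis=0, return_inverse=True)
    refl_by_class = np.empty((len(classes), 4))
    for ci, (cm, cth, a, b) in enumerate(classes):
        try:
            p = SkinParameters(cm=cm, cth=cth, a=a, b=b)
            stack = build_skin_model(
                p, lib, lams=lams,
                d_epi=scene.epidermis_thickness, d_derm=scene.dermis_thickness,
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(
                f"unreachable optical properties for pixel class "
                f"(Cm={cm}, Cth={cth}, a={a}, b={b}): {exc}"
            ) from exc
        sub = replace(cfg, rng_seed=split_seed(scene.seed, ci))
        results = mcphoton.simulate_stack_at_wavelengths(stack, lams, sub)
        refl_by_class[ci] = [r.diffuse_reflectance for r in results]
    images = refl_by_class[inverse].T.reshape((4,) + shape)
    rng = np.random.default_rng(scene.seed)
    if scene.noise_sigma > 0:
        images = images * rng.normal(1.0, scene.noise_sigma, size=images.shape)
    if scene.quantize_bits is not None:
        levels = 2**scene.quantize_bits - 1
        images = np.round(np.clip(images, 0.0, 1.0) * levels) / levels
    stack = ReflectanceStack(
        images=images,
        white_reference=np.ones((4,) + shape),
        wavelengths=lams,
        timestamp=timestamp,
    )
    truth = ParameterMaps(
        cth_map=np.asarray(scene.cth, float).copy(),
        b_map=np.asarray(scene.b, float).copy(),
        valid_mask=np.ones(shape, dtype=bool),
    )
    return stack, truth


def generate_timecourse(
    base_scene: ScenePhantom,
    schedule: Sequence[tuple[int, float, float]],
    cfg: TransportConfig,
    lib: ChromophoreLibrary,
) -> list[dict]:
    """One stack per scheduled week of (week, Cth multiplier, b multiplier).

    The schedule must include week 0 with multipliers (1, 1); truth deltas
    follow exactly from the multipliers.
    """
    schedule = sorted(schedule)
    if not any(w == 0 and mc_ == 1.0 and mb == 1.0 for w, mc_, mb in schedule):
        raise ValueError("schedule must include week 0 with multipliers (1, 1)")
    out = []
    for k, (week, cth_mult, b_mult) in enumerate(schedule):
        scene = base_scene.scaled(cth_mult, b_mult)
        scene = replace(scene, seed=split_seed(base_scene.seed, 50 + k))
        stack, truth = generate_image_stack(scene, cfg, lib, timestamp=f"week{week}")
        out.append(
            {
                "week": week,
                "stack": stack,
                "truth": truth,
                "cth_mult": cth_mult,
                "b_mult": b_mult,
            }
        )
    return out


@dataclass(frozen=True)
class SensitivityDesign:
    """Layer-thickness perturbation study around the training geometry."""

    epidermis_thicknesses: tuple[float, ...] = (0.005, 0.01, 0.03, 0.06)
    dermis_thicknesses: tuple[float, ...] = (3.5, 4.0, 4.5, 4.94)
    fixed_params: SkinParameters = field(
        default_factory=lambda: SkinParameters(cm=1.0, cth=0.4, a=6.3e9, b=3.00)
    )


def thickness_sensitivity(
    design: SensitivityDesign,
    model: RegressionModel,
    cfg: TransportConfig,
    lib: ChromophoreLibrary,
    seed: int | None = None,
) -> pd.DataFrame:
    """Relative estimation errors under layer-thickness mismatch.

    The regression is trained at the default geometry (0.06 / 4.94 mm);
    test reflectances are simulated at perturbed thicknesses and pushed
    through that model.  Rows are keyed by (varied layer, thickness) and
    report relative errors of Cth and b against the fixed true values.
    """
    p = design.fixed_params
    lams = ISOSBESTIC_WAVELENGTHS
    if seed is None:
        seed = cfg.rng_seed
    rows = []
    run = 0
    cases = [("epidermis", t, t, DEFAULT_DERMIS_MM) for t in design.epidermis_thicknesses]
    cases += [("dermis", t, DEFAULT_EPIDERMIS_MM, t) for t in design.dermis_thicknesses]
    for varied, t, d_epi, d_derm in cases:
        stack = build_skin_model(p, lib, lams=lams, d_epi=d_epi, d_derm=d_derm)
        sub = replace(cfg, rng_seed=split_seed(seed, run))
        run += 1
        results = mcphoton.simulate_stack_at_wavelengths(stack, lams, sub)
        A = -np.log10([r.diffuse_reflectance for r in results])
        b_hat, cth_hat = model.predict(A)
        rows.append(
            {
                "varied": varied,
                "thickness_mm": t,
                "cth_est": float(cth_hat),
                "b_est": float(b_hat),
                "rel_err_cth": float((cth_hat - p.cth) / p.cth),
                "rel_err_b": float((b_hat - p.b) / p.b),
            }
        )
    return pd.DataFrame(rows)
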