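"""Weighted-photon Monte Carlo transport in plane-parallel layered media.

This is an MCML-style kernel: pencil beam at normal incidence, specular
deduction at the top interface, exponential free-path sampling on the total
interaction coefficient, fractional weight deposition mua/mut at each
interaction, Henyey-Greenstein scattering, Fresnel reflection/refraction at
every refractive-index boundary, and Russian-roulette termination.

Two departures from the textbook algorithm are deliberate:

* Exact energy bookkeeping.  Plain roulette leaves the *recorded* sum
  specular + R + T + absorbed different from 1 in any single run.  Here a
  surviving photon's weight boost (w/p - w) is debited from the absorbed
  accumulator and a killed photon's weight is credited to it, so every run
  satisfies the energy budget to float64 round-off while all estimators
  remain unbiased.
* A shared-path variant (:func:`run_pathlength_ensemble`) samples steps
  from mus alone, attenuates weight continuously by a reference absorption
  and records each escaping photon's per-layer path lengths, so that
  reflectance for any other absorption pair follows exactly by
  exp(-dmua*L) reweighting.  The trainer uses this to sweep absorber
  concentrations without re-simulating (see ``hemoscat.trainer``).

Detection counts *all* photons leaving the top surface at any angle as
diffuse reflectance (the crossed-polarizer hardware is emulated solely by
the specular deduction).  Transmitted photons are terminated at the bottom
ambient boundary.

Randomness comes from an inline xorshift64* generator seeded by splitmix64,
so identical (stack, wavelength, config) gives bit-identical results
independent of library versions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit

from .tissue_optics import LayerStack

MM_TO_CM = 0.1

_U64 = np.uint64
_MASK = _U64(0xFFFFFFFFFFFFFFFF)


@dataclass(frozen=True)
class TransportConfig:
    """Run-control parameters for the transport kernel."""

    n_photons: int = 100_000
    rng_seed: int = 0
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1
    max_steps: int = 1_000_000

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if not (0.0 < self.roulette_threshold < 1.0):
            raise ValueError("roulette_threshold must be in (0, 1)")
        if not (0.0 < self.roulette_survival < 1.0):
            raise ValueError("roulette_survival must be in (0, 1)")


@dataclass(frozen=True)
class TransportResult:
    """Energy partition of one Monte Carlo run at one wavelength."""

    wavelength: float
    diffuse_reflectance: float
    specular_reflectance: float
    total_transmittance: float
    absorbed_fraction: float
    n_photons: int
    rng_seed: int

    def energy_sum(self) -> float:
        return (
            self.specular_reflectance
            + self.diffuse_reflectance
            + self.total_transmittance
            + self.absorbed_fraction
        )


@njit(cache=True)
def _rng_next(s):
    """xorshift64*; returns (new_state, uniform in (0,1))."""
    s ^= s >> _U64(12)
    s ^= (s << _U64(25)) & _MASK
    s ^= s >> _U64(27)
    v = (s * _U64(0x2545F4914F6CDD1D)) & _MASK
    # 53-bit mantissa; map 0 -> smallest positive to keep log() finite
    u = float(v >> _U64(11)) * (1.0 / 9007199254740992.0)
    if u <= 0.0:
        u = 1.1e-16
    return s, u


@njit(cache=True)
def _seed_state(seed):
    """splitmix64 scramble of a small integer seed into a nonzero state."""
    z = (_U64(seed) + _U64(0x9E3779B97F4A7C15)) & _MASK
    z = ((z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)) & _MASK
    z = ((z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)) & _MASK
    z = z ^ (z >> _U64(31))
    if z == _U64(0):
        z = _U64(0x9E3779B97F4A7C15)
    return z


@njit(cache=True)
def _fresnel(n1, n2, ca1):
    """Unpolarized Fresnel reflectance and transmitted cosine.

    ca1 is |cos| of the incidence angle.  Returns (R, ca2); ca2 is 0 under
    total internal reflection (R = 1).
    """
    if n1 == n2:
        return 0.0, ca1
    if ca1 > 0.99999:
        r = (n2 - n1) / (n2 + n1)
        return r * r, 1.0
    s1 = np.sqrt(1.0 - ca1 * ca1)
    s2 = n1 * s1 / n2
    if s2 >= 1.0:
        return 1.0, 0.0
    c2 = np.sqrt(1.0 - s2 * s2)
    sap = s1 * c2 + ca1 * s2
    sam = s1 * c2 - ca1 * s2
    cap = ca1 * c2 - s1 * s2
    cam = ca1 * c2 + s1 * s2
    r = 0.5 * sam * sam * (cap * cap + cam * cam) / (sap * sap * cam * cam)
    return r, c2


@njit(cache=True)
def _spin(ux, uy, uz, g, u1, u2):
    """Henyey-Greenstein deflection; returns the new direction."""
    if g == 0.0:
        ct = 2.0 * u1 - 1.0
    else:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u1)
        ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
    st = np.sqrt(1.0 - ct * ct)
    phi = 2.0 * np.pi * u2
    cp = np.cos(phi)
    sp = np.sin(phi)
    if abs(uz) > 0.99999:
        nx = st * cp
        ny = st * sp
        nz = ct * (1.0 if uz >= 0.0 else -1.0)
    else:
        den = np.sqrt(1.0 - uz * uz)
        nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
        ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nz = -st * cp * den + uz * ct
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True)
def _mcml_kernel(
    zb, mua, mus, g, n, n_above, n_below,
    n_photons, seed, w_th, p_surv, max_steps,
):
    """Core photon loop.  zb: layer boundaries in cm (len = nlayers+1).

    Returns (diffuse_R, T, absorbed, specular, n_guard) as weight sums over
    n_photons launched with unit weight; n_guard counts photons killed by
    the step guard (their residual weight goes to absorbed).
    """
    nl = len(mua)
    rsp, _ = _fresnel(n_above, n[0], 1.0)
    state = _seed_state(seed)

    refl = 0.0
    trans = 0.0
    absorbed = 0.0
    n_guard = 0

    for _ in range(n_photons):
        w = 1.0 - rsp
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        layer = 0
        sleft = 0.0  # dimensionless residual optical path
        alive = True
        steps = 0

        while alive:
            steps += 1
            if steps > max_steps:
                absorbed += w
                n_guard += 1
                break
            mt = mua[layer] + mus[layer]
            if sleft <= 0.0:
                state, u = _rng_next(state)
                sleft = -np.log(u)
            if mt > 0.0:
                s = sleft / mt
            else:
                s = 1.0e12  # ballistic to boundary
            # distance to the boundary ahead
            if uz > 0.0:
                db = (zb[layer + 1] - z) / uz
            elif uz < 0.0:
                db = (zb[layer] - z) / uz
            else:
                db = 1.0e12
            if db <= s:
                # move to boundary
                sleft -= db * mt
                if sleft < 0.0:
                    sleft = 0.0
                going_down = uz > 0.0
                z = zb[layer + 1] if going_down else zb[layer]
                n1 = n[layer]
                if going_down:
                    n2 = n_below if layer == nl - 1 else n[layer + 1]
                else:
                    n2 = n_above if layer == 0 else n[layer - 1]
                rF, ca2 = _fresnel(n1, n2, abs(uz))
                state, u = _rng_next(state)
                if u <= rF:
                    uz = -uz  # internal reflection
                else:
                    if going_down and layer == nl - 1:
                        trans += w
                        alive = False
                    elif (not going_down) and layer == 0:
                        refl += w
                        alive = False
                    else:
                        # refract into the neighbor layer
                        ratio = n1 / n2
                        ux *= ratio
                        uy *= ratio
                        uz = ca2 if going_down else -ca2
                        layer = layer + 1 if going_down else layer - 1
            else:
                # interaction inside the layer
                z += s * uz
                sleft = 0.0
                dw = w * mua[layer] / mt
                absorbed += dw
                w -= dw
                if w <= 0.0:
                    alive = False
                else:
                    if w < w_th:
                        state, u = _rng_next(state)
                        if u < p_surv:
                            absorbed += w - w / p_surv
                            w /= p_surv
                        else:
                            absorbed += w
                            alive = False
                    if alive:
                        state, u1 = _rng_next(state)
                        state, u2 = _rng_next(state)
                        ux, uy, uz = _spin(ux, uy, uz, g[layer], u1, u2)

    return refl, trans, absorbed, rsp * n_photons, n_guard


@njit(cache=True)
def _pathlength_kernel(
    zb, mua_ref, mus, g, n, n_above, n_below,
    n_photons, seed, w_th, p_surv, max_steps,
    w_out, l_out,
):
    """Shared-path ensemble: record (weight, per-layer path length) of every
    photon escaping the top surface.

    Steps are sampled from mus alone; weight is attenuated continuously by
    exp(-mua_ref * segment).  Escaping photons' weights are exact for the
    reference absorption; reflectance at any other per-layer absorption
    mua' follows by multiplying each record by exp(-(mua'-mua_ref) . L).
    Returns the number of recorded escapes (launch weight is 1; the caller
    applies the specular factor).
    """
    nl = len(mus)
    state = _seed_state(seed)
    count = 0

    for _ in range(n_photons):
        w = 1.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        layer = 0
        sleft = 0.0
        alive = True
        steps = 0
        lpath = np.zeros(nl)

        while alive:
            steps += 1
            if steps > max_steps:
                break
            ms = mus[layer]
            if sleft <= 0.0:
                state, u = _rng_next(state)
                sleft = -np.log(u)
            s = sleft / ms if ms > 0.0 else 1.0e12
            if uz > 0.0:
                db = (zb[layer + 1] - z) / uz
            elif uz < 0.0:
                db = (zb[layer] - z) / uz
            else:
                db = 1.0e12
            if db <= s:
                sleft -= db * ms
                if sleft < 0.0:
                    sleft = 0.0
                w *= np.exp(-mua_ref[layer] * db)
                lpath[layer] += db
                going_down = uz > 0.0
                z = zb[layer + 1] if going_down else zb[layer]
                n1 = n[layer]
                if going_down:
                    n2 = n_below if layer == nl - 1 else n[layer + 1]
                else:
                    n2 = n_above if layer == 0 else n[layer - 1]
                rF, ca2 = _fresnel(n1, n2, abs(uz))
                state, u = _rng_next(state)
                if u <= rF:
                    uz = -uz
                else:
                    if going_down and layer == nl - 1:
                        alive = False  # transmitted: not recorded
                    elif (not going_down) and layer == 0:
                        w_out[count] = w
                        for k in range(nl):
                            l_out[count, k] = lpath[k]
                        count += 1
                        alive = False
                    else:
                        ratio = n1 / n2
                        ux *= ratio
                        uy *= ratio
                        uz = ca2 if going_down else -ca2
                        layer = layer + 1 if going_down else layer - 1
            else:
                z += s * uz
                w *= np.exp(-mua_ref[layer] * s)
                lpath[layer] += s
                sleft = 0.0
                if w < w_th:
                    state, u = _rng_next(state)
                    if u < p_surv:
                        w /= p_surv
                    else:
                        alive = False
                if alive:
                    state, u1 = _rng_next(state)
                    state, u2 = _rng_next(state)
                    ux, uy, uz = _spin(ux, uy, uz, g[layer], u1, u2)

    return count


def _stack_arrays(stack: LayerStack, lam: float):
    """Per-layer kernel arrays (boundaries in cm) at one wavelength."""
    idx = stack.wavelength_index(lam)
    d = np.array([ly.thickness * MM_TO_CM for ly in stack.layers])
    zb = np.concatenate(([0.0], np.cumsum(d)))
    mua = np.array([np.atleast_1d(ly.mua)[idx] for ly in stack.layers], dtype=float)
    mus = np.array([np.atleast_1d(ly.mus)[idx] for ly in stack.layers], dtype=float)
    g = np.array([ly.g for ly in stack.layers], dtype=float)
    n = np.array([ly.n for ly in stack.layers], dtype=float)
    return zb, mua, mus, g, n


def simulate(stack: LayerStack, lam: float, cfg: TransportConfig) -> TransportResult:
    """Monte Carlo diffuse reflectance/transmittance of a layer stack.

    Identical (stack, lam, cfg) gives a bit-identical result.
    """
    zb, mua, mus, g, n = _stack_arrays(stack, lam)
    if np.all(mua + mus == 0.0):
        raise ValueError(
            "all layers have mua = mus = 0; transport would never terminate"
        )
    refl, trans, absorbed, spec, n_guard = _mcml_kernel(
        zb, mua, mus, g, n, stack.n_ambient, stack.n_ambient,
        cfg.n_photons, cfg.rng_seed, cfg.roulette_threshold,
        cfg.roulette_survival, cfg.max_steps,
    )
    if n_guard > 0:
        warnings.warn(
            f"{n_guard} photons hit the {cfg.max_steps}-step guard; their "
            "residual weight was booked as absorbed",
            RuntimeWarning,
        )
    np_ = float(cfg.n_photons)
    return TransportResult(
        wavelength=float(lam),
        diffuse_reflectance=refl / np_,
        specular_reflectance=spec / np_,
        total_transmittance=trans / np_,
        absorbed_fraction=absorbed / np_,
        n_photons=cfg.n_photons,
        rng_seed=cfg.rng_seed,
    )


def split_seed(seed: int, index: int) -> int:
    """Deterministic, collision-resistant child seed below 2**31."""
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(index,)).generate_state(1)[0] & 0x7FFFFFFF)


def simulate_stack_at_wavelengths(
    stack: LayerStack, lams: Sequence[float], cfg: TransportConfig
) -> list[TransportResult]:
    """One independent, reproducible run per wavelength (seed-splitting)."""
    lams = list(lams)
    if len(lams) == 0:
        raise ValueError("wavelength list must not be empty")
    out = []
    for i, lam in enumerate(lams):
        out.append(simulate(stack, lam, replace(cfg, rng_seed=split_seed(cfg.rng_seed, i))))
    return out


def run_pathlength_ensemble(
    stack: LayerStack, lam: float, mua_ref: np.ndarray, cfg: TransportConfig
) -> tuple[float, np.ndarray, np.ndarray]:
    """Simulate once at a reference absorption; return reweightable records.

    Returns ``(one_minus_specular, weights, pathlengths)`` where
    ``weights[i]`` is the escape weight of photon i under ``mua_ref`` and
    ``pathlengths[i, k]`` its geometric path (cm) in layer k.  Reflectance
    at per-layer absorption ``mua`` is::

        R = one_minus_specular / n_photons
            * sum_i weights[i] * exp(-(mua - mua_ref) @ pathlengths[i])

    (see :func:`reweight_reflectance`).
    """
    zb, _, mus, g, n = _stack_arrays(stack, lam)
    mua_ref = np.asarray(mua_ref, dtype=float)
    if mua_ref.shape != mus.shape:
        raise ValueError("mua_ref must have one entry per layer")
    w_out = np.empty(cfg.n_photons)
    l_out = np.empty((cfg.n_photons, len(mus)))
    count = _pathlength_kernel(
        zb, mua_ref, mus, g, n, stack.n_ambient, stack.n_ambient,
        cfg.n_photons, cfg.rng_seed, cfg.roulette_threshold,
        cfg.roulette_survival, cfg.max_steps,
        w_out, l_out,
    )
    rsp, _ = _fresnel(stack.n_ambient, n[0], 1.0)
    scale = (1.0 - rsp) / cfg.n_photons
    return scale, w_out[:count].copy(), l_out[:count].copy()


def reweight_reflectance(
    scale: float, weights: np.ndarray, pathlengths: np.ndarray,
    mua: np.ndarray, mua_ref: np.ndarray,
) -> float:
    """Exact reflectance at a new per-layer absorption from ensemble records."""
    dmua = np.asarray(mua, dtype=float) - np.asarray(mua_ref, dtype=float)
    return float(scale * np.sum(weights * np.exp(-pathlengths @ dmua)))


def results_to_records(results: Sequence[TransportResult], **extra) -> list[dict]:
    """Flatten TransportResults to plain dicts (CSV/JSON friendly)."""
    rows = []
    for r in results:
        row = dict(extra)
        row.update(
            wavelength=r.wavelength,
            diffuse_reflectance=r.diffuse_reflectance,
            specular_reflectance=r.specular_reflectance,
            total_transmittance=r.total_transmittance,
            absorbed_fraction=r.absorbed_fraction,
            n_photons=r.n_photons,
            rng_seed=r.rng_seed,
        )
        rows.append(row)
    return rows


def write_results(results: Sequence[TransportResult], path: str | Path, **extra) -> None:
    """Write batch results as CSV or JSON depending on the file suffix."""
    import pandas as pd

    path = Path(path)
    rows = results_to_records(results, **extra)
    if path.suffix == ".json":
        path.write_text(json.dumps(rows, indent=1))
    else:
        pd.DataFrame(rows).to_csv(path, index=False)
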