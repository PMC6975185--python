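import math
import random

import numpy as np
import pytest

from hemoscat import mcphoton as mc
from hemoscat import tissue_optics as to


def single_layer(mua, mus, d_mm, g=0.0, n=1.0, lam=500.0):
    layer = to.OpticalLayer(
        thickness=d_mm, mua=np.array([mua]), mus=np.array([mus]), g=g, n=n
    )
    return to.LayerStack(layers=(layer,), wavelengths=np.array([lam]), n_ambient=1.0)


def binom_se(p, n):
    return math.sqrt(max(p * (1.0 - p), 1e-12) / n)


class TestEnergyAndDeterminism:
    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_energy_bookkeeping_exact(self, default_skin_stack, seed):
        cfg = mc.TransportConfig(n_photons=5000, rng_seed=seed)
        res = mc.simulate(default_skin_stack, 500.0, cfg)
        assert abs(res.energy_sum() - 1.0) < 1e-6

    def test_bit_identical_reruns(self, default_skin_stack, fast_cfg):
        r1 = mc.simulate(default_skin_stack, 450.0, fast_cfg)
        r2 = mc.simulate(default_skin_stack, 450.0, fast_cfg)
        assert r1 == r2

    def test_different_seeds_differ(self, default_skin_stack):
        r1 = mc.simulate(default_skin_stack, 450.0, mc.TransportConfig(n_photons=2000, rng_seed=1))
        r2 = mc.simulate(default_skin_stack, 450.0, mc.TransportConfig(n_photons=2000, rng_seed=2))
        assert r1.diffuse_reflectance != r2.diffuse_reflectance

    def test_wavelength_batch_uses_independent_streams(self, default_skin_stack, fast_cfg):
        results = mc.simulate_stack_at_wavelengths(
            default_skin_stack, to.ISOSBESTIC_WAVELENGTHS, fast_cfg
        )
        assert len(results) == 4
        assert all(0.0 < r.diffuse_reflectance < 1.0 for r in results)
        rerun = mc.simulate_stack_at_wavelengths(
            default_skin_stack, to.ISOSBESTIC_WAVELENGTHS, fast_cfg
        )
        assert results == rerun

    def test_empty_wavelength_list(self, default_skin_stack, fast_cfg):
        with pytest.raises(ValueError):
            mc.simulate_stack_at_wavelengths(default_skin_stack, [], fast_cfg)

    def test_vacuum_stack_rejected(self):
        stack = single_layer(0.0, 0.0, 5.0)
        with pytest.raises(ValueError, match="never terminate"):
            mc.simulate(stack, 500.0, mc.TransportConfig(n_photons=10, rng_seed=0))


class TestPhysicalLimits:
    @pytest.mark.parametrize("mua,d_mm", [(2.0, 5.0), (5.0, 2.0), (1.0, 10.0)])
    def test_beer_lambert_transmittance(self, mua, d_mm):
        """Purely absorbing slab: T = exp(-mua*d) within 3 SE."""
        n_ph = 100_000
        stack = single_layer(mua, 0.0, d_mm)
        res = mc.simulate(stack, 500.0, mc.TransportConfig(n_photons=n_ph, rng_seed=3))
        expected = math.exp(-mua * d_mm * 0.1)
        se = binom_se(expected, n_ph)
        assert res.diffuse_reflectance == 0.0
        assert abs(res.total_transmittance - expected) < 3 * se

    def test_matched_index_no_specular(self, fast_cfg):
        stack = single_layer(1.0, 10.0, 5.0, n=1.0)
        assert mc.simulate(stack, 500.0, fast_cfg).specular_reflectance == 0.0

    def test_mismatched_index_fresnel_specular(self, fast_cfg):
        stack = single_layer(1.0, 10.0, 5.0, n=1.4)
        expected = ((1.4 - 1.0) / (1.4 + 1.0)) ** 2
        assert mc.simulate(stack, 500.0, fast_cfg).specular_reflectance == pytest.approx(expected)

    def test_conservative_scattering_reflects_everything(self):
        """Thick non-absorbing scatterer, matched boundaries: R + T = 1, R ~ 1."""
        stack = single_layer(0.0, 100.0, 20.0, g=0.0, n=1.0)
        res = mc.simulate(stack, 500.0, mc.TransportConfig(n_photons=3000, rng_seed=5))
        assert res.absorbed_fraction == pytest.approx(0.0, abs=1e-9)
        assert res.diffuse_reflectance + res.total_transmittance == pytest.approx(1.0, abs=1e-9)
        assert res.diffuse_reflectance > 0.9

    def test_more_dermal_blood_cannot_raise_reflectance(self, lib):
        """Monotonicity in the absorber at 585 nm, 3 combined SE."""
        n_ph = 40_000
        rs = []
        for cth in (0.2, 1.0):
            p = to.SkinParameters(cm=2.0, cth=cth, a=6.3e9, b=3.0)
            stack = to.build_skin_model(p, lib)
            rs.append(
                mc.simulate(stack, 585.0, mc.TransportConfig(n_photons=n_ph, rng_seed=11))
            )
        se = math.hypot(
            binom_se(rs[0].diffuse_reflectance, n_ph),
            binom_se(rs[1].diffuse_reflectance, n_ph),
        )
        assert rs[1].diffuse_reflectance < rs[0].diffuse_reflectance + 3 * se

    def test_standard_error_scales_as_inverse_sqrt_n(self):
        """SD of R over replicates should fall like 1/sqrt(n_photons)."""
        stack = single_layer(0.5, 50.0, 5.0, g=0.9, n=1.4)
        sds = []
        counts = (500, 2000, 8000)
        for n_ph in counts:
            reps = [
                mc.simulate(stack, 500.0, mc.TransportConfig(n_photons=n_ph, rng_seed=s))
                .diffuse_reflectance
                for s in range(10)
            ]
            sds.append(np.std(reps))
        slope = np.polyfit(np.log(counts), np.log(sds), 1)[0]
        assert -0.80 < slope < -0.25


def naive_reference_walker(mua, mus, d_cm, g, n_photons, seed):
    """Brute-force analog random walk in a single matched-index slab.

    Unweighted analog Monte Carlo: at each interaction the photon is
    absorbed outright with probability mua/(mua+mus), otherwise scattered
    by Henyey-Greenstein.  Same physics as the kernel, none of the
    machinery: python floats, python loops, stdlib RNG.
    """
    rng = random.Random(seed)
    mt = mua + mus
    n_refl = n_trans = 0
    for _ in range(n_photons):
        z = 0.0
        uz = 1.0
        ux = uy = 0.0
        while True:
            step = -math.log(1.0 - rng.random()) / mt
            z += step * uz
            if z < 0.0:
                n_refl += 1
                break
            if z > d_cm:
                n_trans += 1
                break
            if rng.random() < mua / mt:
                break  # absorbed
            # HG deflection
            if g == 0.0:
                ct = 2.0 * rng.random() - 1.0
            else:
                tmp = (1 - g * g) / (1 - g + 2 * g * rng.random())
                ct = (1 + g * g - tmp * tmp) / (2 * g)
            st = math.sqrt(max(0.0, 1.0 - ct * ct))
            phi = 2.0 * math.pi * rng.random()
            if abs(uz) > 0.99999:
                ux, uy, uz = st * math.cos(phi), st * math.sin(phi), ct * math.copysign(1.0, uz)
            else:
                den = math.sqrt(1.0 - uz * uz)
                ux, uy, uz = (
                    st * (ux * uz * math.cos(phi) - uy * math.sin(phi)) / den + ux * ct,
                    st * (uy * uz * math.cos(phi) + ux * math.sin(phi)) / den + uy * ct,
                    -st * math.cos(phi) * den + uz * ct,
                )
    return n_refl / n_photons, n_trans / n_photons


class TestAgainstNaiveWalker:
    @pytest.mark.parametrize("g", [0.0, 0.9])
    def test_slab_reflectance_agrees(self, g):
        mua, mus, d_cm = 1.0, 30.0, 0.5
        n_naive, n_kernel = 4000, 40_000
        r_ref, t_ref = naive_reference_walker(mua, mus, d_cm, g, n_naive, seed=17)
        stack = single_layer(mua, mus, d_cm * 10.0, g=g, n=1.0)
        res = mc.simulate(stack, 500.0, mc.TransportConfig(n_photons=n_kernel, rng_seed=23))
        for est, ref in ((res.diffuse_reflectance, r_ref), (res.total_transmittance, t_ref)):
            se = math.hypot(binom_se(ref, n_naive), binom_se(est, n_kernel))
            assert abs(est - ref) < 3 * se, f"{est} vs naive {ref} (3se={3*se})"


class TestPathlengthEnsemble:
    def test_reweighted_matches_direct_simulation(self, lib):
        """Shared-path reweighting is an unbiased estimator of R."""
        lam = 585.0
        n_ph = 30_000
        p = to.SkinParameters(cm=6.0, cth=0.8, a=6.3e9, b=3.0)
        stack = to.build_skin_model(p, lib)
        mua_ref = np.array(
            [to.mua_epidermis(1.0, lam, lib), to.mua_dermis(0.2, 1.0, lam, lib)]
        )
        scale, w, L = mc.run_pathlength_ensemble(
            stack, lam, mua_ref, mc.TransportConfig(n_photons=n_ph, rng_seed=31)
        )
        mua = np.array(
            [to.mua_epidermis(6.0, lam, lib), to.mua_dermis(0.8, 1.0, lam, lib)]
        )
        r_rw = mc.reweight_reflectance(scale, w, L, mua, mua_ref)
        r_direct = mc.simulate(
            stack, lam, mc.TransportConfig(n_photons=n_ph, rng_seed=37)
        ).diffuse_reflectance
        se = math.hypot(binom_se(r_rw, n_ph), binom_se(r_direct, n_ph))
        assert abs(r_rw - r_direct) < 3 * se

    def test_reference_absorption_reproduced_identically(self, lib):
        """Reweighting to the reference itself is the plain estimate."""
        lam = 500.0
        p = to.SkinParameters(cm=1.0, cth=0.2, a=6.3e9, b=3.0)
        stack = to.build_skin_model(p, lib)
        mua_ref = np.array(
            [to.mua_epidermis(1.0, lam, lib), to.mua_dermis(0.2, 1.0, lam, lib)]
        )
        scale, w, L = mc.run_pathlength_ensemble(
            stack, lam, mua_ref, mc.TransportConfig(n_photons=5000, rng_seed=41)
        )
        r0 = scale * w.sum()
        r1 = mc.reweight_reflectance(scale, w, L, mua_ref, mua_ref)
        assert r1 == pytest.approx(r0, rel=1e-12)


class TestResultSerialization:
    def test_write_csv_and_json(self, default_skin_stack, fast_cfg, tmp_path):
        results = mc.simulate_stack_at_wavelengths(
            default_skin_stack, to.ISOSBESTIC_WAVELENGTHS, fast_cfg
        )
        mc.write_results(results, tmp_path / "runs.csv", label="demo")
        mc.write_results(results, tmp_path / "runs.json", label="demo")
        import json

        import pandas as pd

        df = pd.read_csv(tmp_path / "runs.csv")
        assert len(df) == 4 and df["rng_seed"].nunique() == 4
        rows = json.loads((tmp_path / "runs.json").read_text())
        assert rows[0]["label"] == "demo"
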