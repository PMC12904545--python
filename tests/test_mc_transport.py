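"""Unit and property tests for the photon-transport core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octspeckle import (
    DetectorSpec,
    LayerStack,
    OpticalProperties,
    fresnel,
    run_simulation,
    sample_scatter_cosine,
    sample_step,
    trace_photon,
)


class TestSampleStep:
    def test_u_one_gives_zero_step(self):
        assert sample_step(0.1, 1.0) == 0.0

    def test_closed_form(self):
        # -ln(0.5)/0.1 = ln2/0.1
        assert sample_step(0.1, 0.5) == pytest.approx(math.log(2) / 0.1, rel=1e-12)

    def test_mean_is_mean_free_path(self, rng):
        draws = [sample_step(0.1, u) for u in rng.random(100_000)]
        # exponential law: mean 1/mu_t = 10 mm, sd 10 mm
        assert np.mean(draws) == pytest.approx(10.0, abs=3 * 10.0 / math.sqrt(100_000))

    def test_ballistic_medium_rejected(self):
        with pytest.raises(ValueError, match="ballistic"):
            sample_step(0.0, 0.5)


class TestHenyeyGreenstein:
    @pytest.mark.parametrize("g", [0.0, 0.5, 0.9, 0.99])
    def test_mean_cosine_equals_g(self, g, rng):
        n = 100_000
        draws = np.array([sample_scatter_cosine(g, u) for u in rng.random(n)])
        se = draws.std() / math.sqrt(n)
        assert abs(draws.mean() - g) < 3 * max(se, 1e-4)

    def test_isotropic_limit_uniform(self, rng):
        draws = np.array([sample_scatter_cosine(0.0, u) for u in rng.random(50_000)])
        # uniform on [-1, 1]: variance 1/3
        assert draws.min() >= -1 and draws.max() <= 1
        assert draws.var() == pytest.approx(1 / 3, rel=0.05)

    def test_strong_forward_peak(self, rng):
        draws = np.array([sample_scatter_cosine(0.99, u) for u in rng.random(100_000)])
        assert np.percentile(draws, 5) > 0.9

    @pytest.mark.parametrize("g", [-1.0, 1.0, 1.5])
    def test_degenerate_g_rejected(self, g):
        with pytest.raises(ValueError):
            sample_scatter_cosine(g, 0.5)

    @given(g=st.floats(-0.999, 0.999), u=st.floats(0.0, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_cosine_in_range(self, g, u):
        assert -1.0 <= sample_scatter_cosine(g, u) <= 1.0


class TestFresnel:
    def test_matched_media(self):
        r, ct = fresnel(1.376, 1.376, 0.7)
        assert r == 0.0 and ct == pytest.approx(0.7)

    def test_normal_incidence_air_cornea(self):
        r, ct = fresnel(1.0, 1.376, 1.0)
        assert r == pytest.approx((0.376 / 2.376) ** 2, rel=1e-6)
        assert ct == pytest.approx(1.0)

    def test_total_internal_reflection(self):
        # critical angle asin(1/1.376) = 46.6 deg; 50 deg is beyond it
        r, _ = fresnel(1.376, 1.0, math.cos(math.radians(50)))
        assert r == 1.0

    def test_snell_refraction_angle(self):
        theta_i = math.radians(30)
        _, ct = fresnel(1.0, 1.33, math.cos(theta_i))
        theta_t = math.asin(math.sin(theta_i) / 1.33)
        assert ct == pytest.approx(math.cos(theta_t), rel=1e-12)

    @given(
        n1=st.floats(1.0, 2.0),
        n2=st.floats(1.0, 2.0),
        ci=st.floats(0.01, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_reflectance_bounded(self, n1, n2, ci):
        r, ct = fresnel(n1, n2, ci)
        assert 0.0 <= r <= 1.0
        assert 0.0 <= ct <= 1.0

    def test_bad_cosine_rejected(self):
        with pytest.raises(ValueError):
            fresnel(1.0, 1.33, 0.0)


class TestTracePhoton:
    def test_clear_matched_slab_transmits(self):
        stack = LayerStack.single_layer(mu_s=0.0, g=0.9, n=1.0, n_above=1.0,
                                        n_below=1.0)
        rec = trace_photon(stack, DetectorSpec(), seed=1)
        assert rec.outcome == "transmitted"
        assert not rec.detected

    def test_deterministic_for_fixed_seed(self):
        stack = LayerStack.single_layer(mu_s=50.0, g=0.9)
        recs = [trace_photon(stack, DetectorSpec(), seed=42) for _ in range(2)]
        assert recs[0] == recs[1]


class TestRunSimulation:
    def test_counting_invariant_and_records(self):
        stack = LayerStack.single_layer(mu_s=10.0, g=0.9)
        tally = run_simulation(stack, DetectorSpec(), 20_000, seed=2)
        assert tally.n_detected <= tally.n_backscattered <= tally.n_launched
        assert len(tally.weights) == tally.n_detected
        assert tally.n_aborted == 0

    def test_unit_weights_without_absorption(self):
        stack = LayerStack.single_layer(mu_s=10.0, g=0.9, mu_a=0.0)
        tally = run_simulation(stack, DetectorSpec(), 50_000, seed=3)
        assert tally.n_detected > 0
        assert np.all(tally.weights == 1.0)

    def test_beer_lambert_ballistic_fraction(self):
        # single 600 um layer at mu_s = 0.1 mm^-1: P(>=1 scatter) = 1-exp(-0.06)
        stack = LayerStack.single_layer(mu_s=0.1, g=0.99)
        n = 1_000_000
        tally = run_simulation(stack, DetectorSpec(), n, seed=4)
        p = 1 - math.exp(-0.06)
        se = math.sqrt(p * (1 - p) / n)
        assert tally.n_scattered_once / n == pytest.approx(p, abs=4 * se)

    def test_forward_limit_no_detections(self):
        # g -> 1 forward-only scattering with matched indices: nothing returns
        stack = LayerStack.single_layer(mu_s=10.0, g=1.0, n=1.0, n_above=1.0,
                                        n_below=1.0)
        tally = run_simulation(stack, DetectorSpec(), 20_000, seed=5)
        assert tally.n_backscattered == 0
        assert tally.n_detected == 0

    def test_bitwise_determinism(self):
        stack = LayerStack.single_layer(mu_s=0.15, g=0.9)
        a = run_simulation(stack, DetectorSpec(), 100_000, seed=7)
        b = run_simulation(stack, DetectorSpec(), 100_000, seed=7)
        assert a.n_backscattered == b.n_backscattered
        assert a.n_detected == b.n_detected
        assert np.array_equal(a.pathlengths, b.pathlengths)

    def test_detection_monotone_in_mu_s_and_g(self):
        # more scatterers -> more detections; more forward -> fewer
        det = DetectorSpec()
        counts_mu = []
        for mu_s in (0.10, 0.15, 0.20):
            t = run_simulation(LayerStack.single_layer(mu_s=mu_s, g=0.90),
                               det, 500_000, seed=11)
            counts_mu.append(t.n_detected)
        assert counts_mu[0] < counts_mu[1] < counts_mu[2]
        counts_g = []
        for g in (0.85, 0.92, 0.99):
            t = run_simulation(LayerStack.single_layer(mu_s=0.10, g=g),
                               det, 500_000, seed=12)
            counts_g.append(t.n_detected)
        assert counts_g[0] > counts_g[1] > counts_g[2]

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            OpticalProperties(mu_s=-1.0)
        with pytest.raises(ValueError):
            OpticalProperties(mu_s=0.1, g=1.5)
        with pytest.raises(ValueError):
            run_simulation(LayerStack(), DetectorSpec(), 0, seed=0)
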