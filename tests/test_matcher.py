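"""Tests for the three distance measures and the ensemble matcher."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from octspeckle import (
    DensityEstimate,
    LayerStack,
    SpeckleSummary,
    build_bscan,
    d_cr,
    d_kl,
    d_rms,
    ensemble_average,
    extract_sim_roi,
    match,
    match_roi,
)
from octspeckle.matcher import PerDistancePick


def density(values, grid=None):
    values = np.asarray(values, dtype=float)
    if grid is None:
        grid = np.linspace(0, 1, len(values))
    return DensityEstimate(grid=grid, values=values, bandwidth=0.1)


def summary(cr, values):
    return SpeckleSummary(cr=cr, density=density(values))


class TestDistances:
    def test_cr_distance(self):
        a, b = summary(0.5, [1, 1]), summary(0.6, [1, 1])
        assert d_cr(a, a) == 0.0
        assert d_cr(a, b) == pytest.approx(0.1)
        assert d_cr(a, b) == d_cr(b, a)

    def test_ise_identical_zero(self):
        f = density(np.linspace(0, 2, 50))
        assert d_rms(f, f) == 0.0

    def test_ise_unit_box_oracle(self):
        # f = 1, g = 0 on [0, 1]: integral of (f-g)^2 is 1
        grid = np.linspace(0, 1, 1001)
        assert d_rms(density(np.ones(1001), grid),
                     density(np.zeros(1001), grid)) == pytest.approx(1.0)

    def test_ise_symmetric(self, rng):
        grid = np.linspace(0, 1, 100)
        f = density(rng.random(100), grid)
        g = density(rng.random(100), grid)
        assert d_rms(f, g) == pytest.approx(d_rms(g, f))

    def test_grid_mismatch_rejected(self):
        f = density(np.ones(10), np.linspace(0, 1, 10))
        g = density(np.ones(10), np.linspace(0, 2, 10))
        for dist in (d_rms, d_kl):
            with pytest.raises(ValueError):
                dist(f, g)

    def test_kl_identical_zero(self, rng):
        f = density(rng.random(64) + 0.1)
        assert d_kl(f, f) == pytest.approx(0.0, abs=1e-12)

    def test_kl_two_bin_oracle(self):
        # masses {0.5, 0.5} vs {0.25, 0.75}: 0.5 ln2 + 0.5 ln(2/3)
        grid = np.array([0.0, 1.0])
        kl = d_kl(density([0.5, 0.5], grid), density([0.25, 0.75], grid))
        assert kl == pytest.approx(0.5 * np.log(2) + 0.5 * np.log(2 / 3), rel=1e-9)

    @given(
        p=arrays(np.float64, (32,), elements=st.floats(0, 1)),
        q=arrays(np.float64, (32,), elements=st.floats(0, 1)),
    )
    @settings(max_examples=100, deadline=None)
    def test_kl_nonnegative(self, p, q):
        f = density(p)
        g = density(q)
        assert d_kl(f, g) >= -1e-12


class TestEnsembleArithmetic:
    # worked examples: printed per-distance picks and the final estimates
    # they average into, from the porcine-cornea reference table
    @pytest.mark.parametrize(
        "picks, expected",
        [
            ([(0.18, 0.85), (0.10, 0.91), (0.10, 0.91)], (0.127, 0.890)),
            ([(0.12, 0.95), (0.10, 0.91), (0.14, 0.97)], (0.120, 0.943)),
        ],
    )
    def test_reference_worked_examples(self, picks, expected):
        ps = [
            PerDistancePick(name=n, min_value=0.0, mu_s=m, g=g, index=i)
            for i, (n, (m, g)) in enumerate(zip("abc", picks))
        ]
        mu, g = ensemble_average(ps)
        assert round(mu, 3) == pytest.approx(expected[0])
        assert round(g, 3) == pytest.approx(expected[1])


class TestMatch:
    def test_self_match_exact_for_every_entry(self, tiny_map):
        for entry in tiny_map.entries:
            res = match(entry.summary, tiny_map)
            assert res.mu_s_hat == pytest.approx(entry.mu_s, abs=1e-12)
            assert res.g_hat == pytest.approx(entry.g, abs=1e-12)
            assert all(p.min_value == 0.0 for p in res.per_distance)

    def test_estimate_within_grid_hull(self, tiny_map, rng):
        grid = tiny_map.grid
        for seed in range(3):
            mu = float(rng.choice(grid.mu_s_values))
            g = float(rng.choice(grid.g_values))
            stack = LayerStack.single_layer(mu_s=mu, g=g)
            roi = extract_sim_roi(
                build_bscan(stack, n_packets=50_000, seed=1000 + seed)
            )
            res = match_roi(roi, tiny_map)
            eps = 1e-9
            assert grid.mu_s_values[0] - eps <= res.mu_s_hat <= grid.mu_s_values[-1] + eps
            assert grid.g_values[0] - eps <= res.g_hat <= grid.g_values[-1] + eps

    def test_repeatability_across_realizations(self, tiny_map):
        # repeated measurements of one sample (new speckle only) spread no
        # further than estimates across different optical parameters
        def estimates(mu, g, seeds):
            out = []
            for s in seeds:
                stack = LayerStack.single_layer(mu_s=mu, g=g)
                roi = extract_sim_roi(build_bscan(stack, n_packets=50_000, seed=s))
                r = match_roi(roi, tiny_map)
                out.append((r.mu_s_hat, r.g_hat))
            return np.array(out)

        same = estimates(0.15, 0.92, (11, 12, 13))
        across = np.array([
            estimates(0.10, 0.99, (14,))[0],
            estimates(0.15, 0.92, (15,))[0],
            estimates(0.20, 0.85, (16,))[0],
        ])
        assert np.ptp(same[:, 0]) <= np.ptp(across[:, 0]) + 1e-12
        assert np.ptp(same[:, 1]) <= np.ptp(across[:, 1]) + 1e-12

    def test_empty_map_rejected(self, tiny_map):
        import copy

        empty = copy.copy(tiny_map)
        empty.entries = []
        with pytest.raises(ValueError):
            match(tiny_map.entries[0].summary, empty)
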