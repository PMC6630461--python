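"""Graph filtration, Betti curves, IPF/SIP, kernel parameters and the KBI index."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kbinet.io import SUVTable
from kbinet.networks import WeightedNetwork, correlation_distance
from kbinet.persistence import (
    Filtration,
    IPFPlot,
    KernelParams,
    betti_at,
    betti_curve,
    bnp_index,
    graph_filtration,
    ipf,
    kbi,
    kernel_params,
    sip,
    template_from_controls,
)

from conftest import (
    components_at_threshold,
    ols_slope,
    random_complete_network,
    random_suv_table,
)


class TestGraphFiltration:
    def test_two_nodes(self):
        net = WeightedNetwork(np.array([[0.0, 0.7], [0.7, 0.0]]), ["a", "b"])
        filt = graph_filtration(net)
        assert np.allclose(filt.lam, [0.0, 0.7])
        assert filt.m == 2

    def test_merge_heights_match_threshold_sweep(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 8))
            net = random_complete_network(rng, n)
            filt = graph_filtration(net)
            # oracle: sweep every distinct weight, record where the
            # union-find component count drops
            thresholds = np.unique(net.weights[np.triu_indices(n, 1)])
            drops = []
            prev = n
            for lam in thresholds:
                c = components_at_threshold(net.weights, lam)
                drops.extend([lam] * (prev - c))
                prev = c
            assert np.allclose(np.sort(filt.lam[1:]), np.sort(drops), atol=1e-12)

    def test_equal_weights_give_tied_heights(self):
        n = 5
        w = np.full((n, n), 0.4)
        np.fill_diagonal(w, 0.0)
        net = WeightedNetwork(w, [f"r{i}" for i in range(n)])
        filt = graph_filtration(net)
        assert np.allclose(filt.lam, [0.0] + [0.4] * (n - 1))

    def test_single_node_errors(self):
        net = WeightedNetwork(np.zeros((1, 1)), ["a"])
        with pytest.raises(ValueError, match="2 nodes"):
            graph_filtration(net)

    def test_node_relabeling_leaves_filtration_unchanged(self, rng):
        net = random_complete_network(rng, 7)
        perm = rng.permutation(7)
        permuted = WeightedNetwork(
            net.weights[np.ix_(perm, perm)], [net.roi_labels[i] for i in perm]
        )
        assert np.allclose(
            graph_filtration(net).lam, graph_filtration(permuted).lam, atol=1e-12
        )


class TestBettiCurve:
    def test_endpoint_counts(self, rng):
        net = random_complete_network(rng, 6)
        filt = graph_filtration(net)
        curve = betti_curve(filt)
        assert betti_at(filt, 0.0) == 6  # all weights > 0 almost surely
        assert curve.points[-1, 1] == 1

    def test_matches_union_find_at_midpoints(self, rng):
        for _ in range(20):
            net = random_complete_network(rng, int(rng.integers(3, 9)))
            filt = graph_filtration(net)
            grid = np.unique(filt.lam)
            queries = np.concatenate([grid, (grid[:-1] + grid[1:]) / 2.0])
            for lam in queries:
                assert betti_at(filt, lam) == components_at_threshold(net.weights, lam)


class TestSlopeIndices:
    def test_constant_curve_has_zero_slope(self):
        from kbinet.persistence import BettiCurve

        curve = BettiCurve(np.array([[0.0, 3.0], [0.5, 3.0], [1.0, 3.0]]))
        assert bnp_index(curve) == 0.0

    def test_exact_line_recovered(self):
        from kbinet.persistence import BettiCurve

        lam = np.linspace(0, 0.25, 6)
        curve = BettiCurve(np.column_stack([lam, 90.0 - 300.0 * lam]))
        assert bnp_index(curve) == pytest.approx(300.0, abs=1e-10)

    def test_bnp_and_sip_match_closed_form_ols(self, rng):
        for _ in range(50):
            m = int(rng.integers(3, 12))
            lam = np.concatenate([[0.0], np.sort(rng.uniform(0.01, 2.0, m - 1))])
            filt = Filtration(lam)
            curve = betti_curve(filt)
            assert bnp_index(curve) == pytest.approx(
                abs(ols_slope(curve.points[:, 0], curve.points[:, 1])), abs=1e-10
            )
            plot = ipf(filt)
            assert sip(plot) == pytest.approx(
                abs(ols_slope(plot.lam, plot.values)), abs=1e-10
            )

    def test_degenerate_filtration_errors(self):
        filt = Filtration(np.array([0.0, 0.0, 0.0]))
        with pytest.raises(ValueError, match="identical"):
            sip(ipf(filt))


class TestIPF:
    def test_worked_example(self):
        plot = ipf(Filtration(np.array([0.0, 0.2, 0.5, 0.9])))
        assert np.allclose(plot.values, [1.6 * 4 / 12, 1.4 * 3 / 12, 0.9 * 2 / 12, 0.0])
        assert sip(plot) == pytest.approx(0.5833333333, abs=1e-9)

    def test_matches_direct_formula(self, rng):
        for _ in range(100):
            m = int(rng.integers(2, 15))
            lam = np.concatenate([[0.0], np.sort(rng.uniform(0, 2, m - 1))])
            plot = ipf(Filtration(lam))
            for i in range(m):
                expected = 0.0 if i == m - 1 else (m - i) / (m * (m - 1)) * lam[i + 1 :].sum()
                assert plot.values[i] == pytest.approx(expected, abs=1e-12)

    @given(st.lists(st.floats(0.001, 2.0), min_size=1, max_size=30),
           st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_scaling_lam_scales_ipf_linearly(self, heights, s):
        lam = np.concatenate([[0.0], np.sort(heights)])
        base = ipf(Filtration(lam))
        scaled = ipf(Filtration(lam * s))
        assert np.allclose(scaled.values, base.values * s, rtol=1e-9, atol=1e-12)

    @given(st.lists(st.floats(0.0, 2.0), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_values_nonincreasing_nonnegative_ending_at_zero(self, heights):
        lam = np.concatenate([[0.0], np.sort(heights)])
        plot = ipf(Filtration(lam))
        assert np.all(plot.values >= 0)
        assert np.all(np.diff(plot.values) <= 1e-12)
        assert plot.values[-1] == 0.0


class TestKernelParams:
    def test_default_exponent_is_five(self):
        assert KernelParams().p == 5

    def test_matches_brute_force_enumeration(self):
        # two toy plots; the lam = 0 anchor point is excluded from medians
        a = IPFPlot(np.array([[0.0, 0.6], [0.2, 0.4], [0.6, 0.1], [1.0, 0.0]]))
        b = IPFPlot(np.array([[0.0, 0.9], [0.4, 0.5], [0.8, 0.0], [1.2, 0.0]]))
        params = kernel_params([a, b], p=5)

        def plot_medians(pts):
            pts = [p for p in pts if p[0] > 0]
            dists = sorted(
                float(np.hypot(p[0] - q[0], p[1] - q[1]))
                for i, p in enumerate(pts)
                for q in pts[i + 1 :]
            )
            lams = sorted(p[0] for p in pts)
            med = lambda v: (v[len(v) // 2] if len(v) % 2 else
                             (v[len(v) // 2 - 1] + v[len(v) // 2]) / 2)
            return med(dists), med(lams)

        da, la = plot_medians(a.points)
        db, lb = plot_medians(b.points)
        assert params.sigma == pytest.approx((da + db) / 2, abs=1e-12)
        assert params.c_weight == pytest.approx(((la + lb) / 2) ** -5, abs=1e-9)

    def test_scale_equivariance(self, rng):
        pts = np.column_stack([
            np.concatenate([[0.0], np.sort(rng.uniform(0.1, 1, 5))]),
            np.sort(rng.uniform(0, 1, 6))[::-1],
        ])
        plots = [IPFPlot(pts), IPFPlot(pts * 0.5)]
        base = kernel_params(plots)
        s = 3.0
        scaled = kernel_params([IPFPlot(p.points * s) for p in plots])
        assert scaled.sigma == pytest.approx(base.sigma * s, rel=1e-12)
        assert scaled.c_weight == pytest.approx(base.c_weight * s**-5, rel=1e-9)

    def test_coincident_points_error(self):
        flat = IPFPlot(np.array([[0.0, 0.0], [0.5, 0.0], [0.5, 0.0]]))
        with pytest.raises(ValueError, match="sigma"):
            kernel_params([flat])


class TestKBI:
    def test_unit_self_match_returns_pi_squared_over_16(self):
        plot = IPFPlot(np.array([[1.0, 0.0]]))
        params = KernelParams(p=5, sigma=0.5, c_weight=1.0)
        assert kbi(plot, plot, params) == pytest.approx(np.pi**2 / 16, abs=1e-12)

    def test_zero_lam_annihilates(self, rng):
        m = 5
        x = IPFPlot(np.column_stack([np.zeros(m), np.zeros(m)]))
        t = IPFPlot(np.column_stack([np.sort(rng.uniform(0, 1, m)),
                                     np.sort(rng.uniform(0, 1, m))[::-1]]))
        params = KernelParams(p=5, sigma=1.0, c_weight=2.0)
        assert kbi(x, t, params) == 0.0

    def test_two_point_hand_evaluation(self):
        x = IPFPlot(np.array([[0.5, 0.3], [1.0, 0.0]]))
        t = IPFPlot(np.array([[0.4, 0.4], [0.9, 0.1]]))
        params = KernelParams(p=1, sigma=0.5, c_weight=1.0)
        term0 = (np.arctan(0.5) * np.arctan(0.4)
                 * np.exp(-((0.5 - 0.4) ** 2 + (0.3 - 0.4) ** 2) / (2 * 0.25)))
        term1 = (np.arctan(1.0) * np.arctan(0.9)
                 * np.exp(-((1.0 - 0.9) ** 2 + (0.0 - 0.1) ** 2) / (2 * 0.25)))
        assert kbi(x, t, params) == pytest.approx((term0 + term1) / 2, abs=1e-12)

    def test_symmetry_and_nonnegativity(self, rng):
        for _ in range(20):
            m = 6
            mk = lambda: IPFPlot(np.column_stack([
                np.concatenate([[0.0], np.sort(rng.uniform(0.05, 2, m - 1))]),
                np.sort(rng.uniform(0, 1, m))[::-1],
            ]))
            x, t = mk(), mk()
            params = kernel_params([x, t])
            assert kbi(x, t, params) == pytest.approx(kbi(t, x, params), abs=1e-14)
            assert 0.0 <= kbi(x, t, params) <= (np.pi / 2) ** 2

    def test_self_match_maximal_over_value_perturbations(self, rng):
        lam = np.concatenate([[0.0], np.sort(rng.uniform(0.1, 1.5, 7))])
        values = ipf(Filtration(lam)).values
        t = IPFPlot(np.column_stack([lam, values]))
        params = kernel_params([t])
        self_match = kbi(t, t, params)
        for _ in range(200):
            perturbed = IPFPlot(np.column_stack([
                lam, np.abs(values + rng.normal(0, 0.2, lam.size))
            ]))
            assert kbi(perturbed, t, params) <= self_match + 1e-12

    def test_unequal_cardinality_errors(self):
        x = IPFPlot(np.array([[0.5, 0.1], [1.0, 0.0]]))
        t = IPFPlot(np.array([[0.5, 0.1]]))
        with pytest.raises(ValueError, match="count"):
            kbi(x, t, KernelParams())


class TestTemplate:
    def test_equals_explicit_pipeline_composition(self, rng):
        table = random_suv_table(rng, 10, 6, group="NC")
        template = template_from_controls(table)
        net, _ = correlation_distance(table)
        explicit = ipf(graph_filtration(net))
        assert np.allclose(template.points, explicit.points, atol=1e-15)
        assert template.values[-1] == 0.0
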