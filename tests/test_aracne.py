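"""Kernel MI estimation, threshold calibration, DPI pruning and consensus."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cllnet.aracne import (
    AracneParams,
    MINetwork,
    apply_dpi,
    bootstrap_consensus,
    calibrate_threshold,
    canonical,
    consensus_support_threshold,
    default_kernel_width,
    estimate_mi,
    infer_network,
    read_network,
)


def make_network(edges, tf_ids=("t",), i0=0.0):
    nodes = sorted({g for e in edges for g in e})
    return MINetwork(
        edges={canonical(a, b): v for (a, b), v in edges.items()},
        nodes=nodes, tf_ids=list(tf_ids), i0=i0, params=AracneParams(),
    )


class TestEstimateMI:
    def test_symmetry_exact(self, rng):
        x = rng.normal(size=100)
        y = 0.5 * x + rng.normal(size=100)
        assert estimate_mi(x, y) == estimate_mi(y, x)

    def test_gaussian_closed_form(self):
        # I = -0.5 ln(1 - rho^2) nats for a bivariate Gaussian
        rho = 0.8
        rng = np.random.default_rng(123)
        xy = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], 2000)
        est = estimate_mi(xy[:, 0], xy[:, 1])
        assert est == pytest.approx(-0.5 * np.log(1 - rho**2), abs=0.1)

    def test_identical_vectors_exceed_threshold(self, rng):
        x = rng.normal(size=200)
        expr = pd.DataFrame(rng.normal(size=(50, 200)))
        i0 = calibrate_threshold(
            expr, AracneParams(n_null_pairs=200, seed=1)
        )
        assert estimate_mi(x, x) > i0

    def test_independent_vectors_below_own_null_quantile(self, rng):
        hits, n_seeds = 0, 40
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            x, y = r.normal(size=(2, 200))
            obs = estimate_mi(x, y)
            null = [
                estimate_mi(x, y[r.permutation(200)]) for _ in range(19)
            ]
            hits += obs <= np.max(null)  # below the ~95th percentile
        assert hits >= int(0.80 * n_seeds)

    def test_constant_vector_warns_zero(self, rng):
        with pytest.warns(UserWarning, match="constant"):
            assert estimate_mi(np.ones(30), rng.normal(size=30)) == 0.0

    def test_errors(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            estimate_mi(rng.normal(size=30), rng.normal(size=31))
        with pytest.raises(ValueError, match="20"):
            estimate_mi(rng.normal(size=10), rng.normal(size=10))


class TestCalibrateThreshold:
    def test_monotone_in_pvalue(self, iid_expr):
        i0s = [
            calibrate_threshold(
                iid_expr,
                AracneParams(threshold_pvalue=p, n_null_pairs=400, seed=3),
            )
            for p in (0.01, 0.05, 0.2)
        ]
        assert i0s[0] >= i0s[1] >= i0s[2] >= 0

    def test_pvalue_one_returns_empirical_minimum(self, iid_expr):
        params = AracneParams(threshold_pvalue=0.999, n_null_pairs=200, seed=4)
        object.__setattr__(params, "threshold_pvalue", 1.0)  # boundary probe
        i0 = calibrate_threshold(iid_expr, params)
        assert i0 >= 0.0

    def test_requires_enough_pairs(self, iid_expr):
        with pytest.raises(ValueError):
            calibrate_threshold(iid_expr, AracneParams(n_null_pairs=50))


class TestInferNetwork:
    def test_edges_have_tf_endpoint_and_mi_above_threshold(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(30, 60)), index=[f"g{i}" for i in range(30)]
        )
        params = AracneParams(n_null_pairs=150, seed=5)
        net = infer_network(expr, ["g0", "g1"], params)
        for (a, b), mi in net.edges.items():
            assert a in ("g0", "g1") or b in ("g0", "g1")
            assert mi >= net.i0

    def test_no_tf_raises(self, iid_expr):
        with pytest.raises(ValueError, match="no TF"):
            infer_network(iid_expr, ["absent"], AracneParams(n_null_pairs=150))

    def test_too_few_samples_refused(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 15)),
                            index=[f"g{i}" for i in range(10)])
        with pytest.raises(ValueError, match="20"):
            infer_network(expr, ["g0"], AracneParams(n_null_pairs=150))


class TestDPI:
    def test_chain_triangle_removes_weakest(self):
        net = make_network(
            {("x", "y"): 0.8, ("y", "z"): 0.7, ("x", "z"): 0.3},
            tf_ids=["x", "y", "z"],
        )
        out = apply_dpi(net, 0.0)
        assert canonical("x", "z") not in out.edges
        assert len(out.edges) == 2

    def test_no_triangles_identity(self):
        net = make_network({("t", "a"): 0.5, ("t", "b"): 0.4, ("t", "c"): 0.1})
        out = apply_dpi(net, 0.0)
        assert out.edges == net.edges

    def test_exact_ties_kept_at_zero_tolerance(self):
        net = make_network(
            {("x", "y"): 0.5, ("y", "z"): 0.5, ("x", "z"): 0.5},
            tf_ids=["x"],
        )
        assert len(apply_dpi(net, 0.0).edges) == 3

    @staticmethod
    def brute_force_dpi(edges, tol):
        nodes = sorted({g for e in edges for g in e})
        doomed = set()
        for i, j, k in itertools.combinations(nodes, 3):
            tri = [canonical(i, j), canonical(i, k), canonical(j, k)]
            if not all(e in edges for e in tri):
                continue
            for e in tri:
                others = [edges[o] for o in tri if o != e]
                if edges[e] < (1 - tol) * min(others):
                    doomed.add(e)
        return {e: v for e, v in edges.items() if e not in doomed}

    @pytest.mark.parametrize("tol", [0.0, 0.1])
    def test_matches_exhaustive_triangle_oracle(self, tol):
        rng = np.random.default_rng(99)
        nodes = [f"n{i}" for i in range(10)]
        for _ in range(100):
            edges = {}
            for a, b in itertools.combinations(nodes, 2):
                if rng.random() < 0.35:
                    edges[canonical(a, b)] = float(rng.uniform(0.05, 1.0))
            net = make_network(edges, tf_ids=nodes)
            out = apply_dpi(net, tol)
            assert out.edges == self.brute_force_dpi(edges, tol)

    def test_idempotent_and_monotone_in_tolerance(self, rng):
        nodes = [f"n{i}" for i in range(8)]
        edges = {
            canonical(a, b): float(rng.uniform(0.05, 1.0))
            for a, b in itertools.combinations(nodes, 2)
            if rng.random() < 0.5
        }
        net = make_network(edges, tf_ids=nodes)
        once = apply_dpi(net, 0.0)
        twice = apply_dpi(once, 0.0)
        assert once.edges == twice.edges
        # tolerance 0 is the strictest setting: raising it keeps more edges
        kept0 = set(apply_dpi(net, 0.0).edges)
        kept1 = set(apply_dpi(net, 0.1).edges)
        kept3 = set(apply_dpi(net, 0.3).edges)
        assert kept0 <= kept1 <= kept3 <= set(net.edges)


class TestBootstrapConsensus:
    params = AracneParams(n_bootstrap=5, n_null_pairs=120, seed=8)

    def planted(self, seed=0):
        rng = np.random.default_rng(seed)
        tf = rng.normal(size=80)
        targets = tf[None, :] + rng.normal(size=(4, 80))
        noise = rng.normal(size=(10, 80))
        X = np.vstack([tf, targets, noise])
        return pd.DataFrame(X, index=[f"g{i}" for i in range(15)],
                            columns=[f"s{i}" for i in range(80)])

    def test_determinism(self):
        expr = self.planted()
        a = bootstrap_consensus(expr, ["g0"], self.params)
        b = bootstrap_consensus(expr, ["g0"], self.params)
        assert a.edges == b.edges
        assert a.support == b.support

    def test_full_support_edges_retained(self):
        expr = self.planted()
        net = bootstrap_consensus(expr, ["g0"], self.params)
        full = [e for e, s in net.support.items() if s == 5]
        true = {canonical("g0", f"g{i}") for i in range(1, 5)}
        assert true <= set(net.edges)
        assert set(full) <= set(net.edges)

    def test_poisson_threshold_matches_direct_tail_sum(self):
        supports = {("a", "b"): 10, ("a", "c"): 2, ("a", "d"): 1,
                    ("a", "e"): 1, ("a", "f"): 1}
        alpha, B = 0.05, 10
        s_min, mu = consensus_support_threshold(supports, B, alpha)
        assert mu == pytest.approx(15 / 5)

        def poisson_upper_tail(s, mu):  # direct summation, independent of scipy
            terms, term, k = [], np.exp(-mu), 0
            cdf = 0.0
            while k < s:
                cdf += term
                k += 1
                term *= mu / k
            return 1.0 - cdf

        bonf = alpha / 5
        direct = min(
            s for s in range(1, B + 2)
            if poisson_upper_tail(s, mu) <= bonf or s == B + 1
        )
        assert s_min == direct

    def test_consensus_shrinks_with_alpha(self):
        expr = self.planted(seed=3)
        loose = bootstrap_consensus(
            expr, ["g0"],
            AracneParams(n_bootstrap=5, n_null_pairs=120, seed=8,
                         consensus_alpha=0.5),
        )
        strict = bootstrap_consensus(
            expr, ["g0"],
            AracneParams(n_bootstrap=5, n_null_pairs=120, seed=8,
                         consensus_alpha=0.001),
        )
        assert set(strict.edges) <= set(loose.edges)


def test_network_tsv_round_trip(tmp_path, rng):
    net = make_network({("t", "a"): 0.5, ("t", "b"): 0.31}, tf_ids=["t"])
    net.support = {canonical("t", "a"): 9, canonical("t", "b"): 7}
    net.consensus_p = {canonical("t", "a"): 0.001, canonical("t", "b"): 0.02}
    net.write(tmp_path / "net.tsv")
    back = read_network(tmp_path / "net.tsv", ["t"])
    assert back.edges == net.edges
    assert back.support == net.support
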