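"""Regulon extraction, FET enrichment and cross-network consensus."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from cllnet.aracne import AracneParams, MINetwork, apply_dpi, canonical, infer_network
from cllnet.metade import Signature
from cllnet.mra import (
    Regulon,
    cross_network_consensus,
    extract_regulons,
    fet_enrichment,
    run_mra,
    specificity_controls,
)
from cllnet.synthetic import generate_truth, simulate_cohort, simulate_normal_cohort


def make_signature(genes):
    return Signature(
        table=pd.DataFrame(
            {"gene": list(genes), "direction": "Up", "q": 0.01}
        )
    )


def star(edges, tf_ids):
    nodes = sorted({g for e in edges for g in e})
    return MINetwork(
        edges={canonical(a, b): v for (a, b), v in edges.items()},
        nodes=nodes, tf_ids=list(tf_ids), i0=0.0, params=AracneParams(),
    )


def hypergeom_tail_exact(k, M, n_sig, n_reg):
    """Exact rational hypergeometric upper tail P(X >= k)."""
    total = Fraction(0)
    for x in range(k, min(n_sig, n_reg) + 1):
        total += Fraction(comb(n_sig, x) * comb(M - n_sig, n_reg - x),
                          comb(M, n_reg))
    return total


class TestExtractRegulons:
    def test_star_network(self):
        net = star({("t", "a"): 1, ("t", "b"): 1, ("t", "c"): 1}, ["t"])
        (reg,) = extract_regulons(net)
        assert reg.tf == "t" and reg.targets == {"a", "b", "c"}

    def test_tf_without_edges_emits_nothing(self):
        net = star({("t", "a"): 1}, ["t", "u"])
        regs = extract_regulons(net)
        assert [r.tf for r in regs] == ["t"]

    def test_tf_tf_edge_mutual_membership(self):
        net = star({("t", "u"): 1, ("t", "a"): 1}, ["t", "u"])
        regs = {r.tf: r.targets for r in extract_regulons(net)}
        assert "u" in regs["t"] and "t" in regs["u"]

    def test_sizes_match_adjacency(self, rng):
        nodes = [f"n{i}" for i in range(20)]
        edges = {}
        for i in range(20):
            for j in range(i + 1, 20):
                if rng.random() < 0.2:
                    edges[(nodes[i], nodes[j])] = 1.0
        net = star(edges, nodes[:5])
        adj = net.adjacency()
        for reg in extract_regulons(net):
            assert reg.targets == adj[reg.tf]


class TestFET:
    def test_worked_example_against_direct_summation(self):
        # universe 100, regulon 10, signature 20, overlap 8
        universe = {f"u{i}" for i in range(100)}
        sig_genes = sorted(universe)[:20]
        reg_genes = sig_genes[:8] + sorted(universe)[90:92]
        res = fet_enrichment(
            Regulon("TF", frozenset(reg_genes)), make_signature(sig_genes),
            universe | {"TF"} - {"TF"},
        )
        expected = float(hypergeom_tail_exact(8, 100, 20, 10))
        assert res.fet_p == pytest.approx(expected, rel=1e-10)
        assert len(res.intersection) == 8

    def test_regulon_inside_signature_boundary_table(self):
        universe = {f"u{i}" for i in range(30)}
        sig = sorted(universe)[:12]
        reg = sig[:5]
        res = fet_enrichment(
            Regulon("TF", frozenset(reg)), make_signature(sig), universe
        )
        assert res.fet_p == pytest.approx(
            float(hypergeom_tail_exact(5, 30, 12, 5)), rel=1e-10
        )

    def test_empty_intersection_returns_one(self):
        universe = {f"u{i}" for i in range(50)}
        res = fet_enrichment(
            Regulon("TF", frozenset(sorted(universe)[:5])),
            make_signature(sorted(universe)[40:45]),
            universe,
        )
        assert res.fet_p == 1.0

    @pytest.mark.parametrize("seed", range(3))
    def test_exhaustive_small_universe_oracle(self, seed):
        rng = np.random.default_rng(seed)
        M = int(rng.integers(5, 26))
        universe = {f"u{i}" for i in range(M)}
        n_sig = int(rng.integers(1, M + 1))
        n_reg = int(rng.integers(1, M + 1))
        sig = list(rng.choice(sorted(universe), n_sig, replace=False))
        reg = list(rng.choice(sorted(universe), n_reg, replace=False))
        k = len(set(sig) & set(reg))
        res = fet_enrichment(
            Regulon("TF", frozenset(reg)), make_signature(sig), universe
        )
        expected = float(hypergeom_tail_exact(k, M, n_sig, n_reg)) if k else 1.0
        assert res.fet_p == pytest.approx(expected, rel=1e-10)

    def test_errors(self):
        with pytest.raises(ValueError, match="universe"):
            fet_enrichment(Regulon("TF", frozenset({"a"})),
                           make_signature(["a"]), set())
        with pytest.raises(ValueError, match="share no gene"):
            fet_enrichment(Regulon("TF", frozenset({"a"})),
                           make_signature(["zz"]), {"a", "b"})


class TestRunMRA:
    def planted_setup(self, seed):
        truth = generate_truth(200, 10, 15, 0.2, 40, 10, seed=seed)
        cohort = simulate_cohort(truth, 100, 100, 0.0, 1.0, seed=seed + 500)
        params = AracneParams(n_null_pairs=300, seed=seed + 900)
        net = apply_dpi(infer_network(cohort.expr, truth.tf_ids, params))
        rng = np.random.default_rng(seed + 1300)
        master_targets = set()
        for tf in truth.master_tfs:
            master_targets |= truth.regulon_map[tf]
        regulated = set().union(*truth.regulon_map.values())
        decoys = rng.choice(
            [g for g in truth.gene_ids
             if g not in regulated and g not in truth.tf_ids],
            20, replace=False,
        )
        signature = make_signature(sorted(master_targets) + list(decoys))
        return truth, net, signature

    def test_masters_rank_top(self):
        truth, net, signature = self.planted_setup(seed=4)
        res = run_mra(net, signature, alpha=0.05)
        top5 = list(res.table["tf"].head(5))
        assert set(truth.master_tfs) <= set(top5)

    def test_ranking_invariant_under_regulon_order(self):
        truth, net, signature = self.planted_setup(seed=5)
        a = run_mra(net, signature, tf_ids=truth.tf_ids)
        b = run_mra(net, signature, tf_ids=truth.tf_ids[::-1])
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_signature_equals_universe_degenerate(self):
        net = star({("t", "a"): 1, ("t", "b"): 1}, ["t"])
        res = run_mra(net, make_signature(net.nodes))
        assert (res.table["fet_p"] == 1.0).all()
        assert not res.table["candidate"].any()

    def test_decoy_regulon_rarely_candidate(self):
        # regulon disjoint from signature must never look enriched
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            universe = {f"u{i}" for i in range(200)}
            sig = list(rng.choice(sorted(universe), 40, replace=False))
            rest = sorted(universe - set(sig))
            reg = list(rng.choice(rest, 15, replace=False))
            net = star({("t", g): 1.0 for g in reg}, ["t"])
            net.nodes = sorted(universe)
            res = run_mra(net, make_signature(sig), alpha=0.05)
            hits += int(res.table["candidate"].any())
        assert hits <= 2


class TestSpecificityAndConsensus:
    def test_normal_network_enriches_nothing(self):
        truth = generate_truth(160, 10, 15, 0.2, 60, 10, seed=9)
        normal = simulate_normal_cohort(truth, 100, 1.0, seed=10)
        params = AracneParams(n_bootstrap=5, n_null_pairs=200, seed=11)
        from cllnet.aracne import bootstrap_consensus

        net = bootstrap_consensus(normal.expr, truth.tf_ids, params)
        master_targets = set()
        for tf in truth.master_tfs:
            master_targets |= truth.regulon_map[tf]
        signature = make_signature(sorted(master_targets))
        if net.n_edges == 0:
            enriched = []
        else:
            enriched = run_mra(net, signature, alpha=0.05).candidates()
        assert enriched == []

    def test_proliferation_regulator_removed(self):
        prolif_genes = [f"p{i}" for i in range(10)]
        sig_genes = [f"s{i}" for i in range(10)]
        edges = {("tSig", g): 1.0 for g in sig_genes}
        edges.update({("tPro", g): 1.0 for g in prolif_genes})
        net = star(edges, ["tSig", "tPro"])
        net.nodes = sorted(set(net.nodes) | {f"x{i}" for i in range(80)})
        disease = run_mra(net, make_signature(sig_genes + prolif_genes),
                          alpha=0.05)
        assert set(disease.candidates()) == {"tSig", "tPro"}
        kept = specificity_controls(
            disease, net_control=None, signature=make_signature(sig_genes),
            proliferation_signature=set(prolif_genes), alpha=0.05,
            net_disease=net,
        )
        assert kept == ["tSig"]

    def test_empty_proliferation_only_control_filtering(self):
        net = star({("t", "a"): 1.0}, ["t"])
        res = run_mra(net, make_signature(["a"]))
        with pytest.warns(UserWarning):
            kept = specificity_controls(
                res, net_control=None, signature=make_signature(["a"]),
                proliferation_signature=set(), alpha=0.05,
            )
        assert isinstance(kept, list)

    def test_cross_network_consensus_threshold_and_union(self):
        def res_for(tfs_targets, network_id):
            rows, regulons = [], {}
            m = len(tfs_targets)
            for tf, targets in tfs_targets.items():
                regulons[tf] = frozenset(targets)
                rows.append(
                    {"tf": tf, "fet_p": 1e-6, "fet_p_bonferroni": 1e-6 * m,
                     "intersection_size": len(targets),
                     "intersection_genes": ";".join(sorted(targets)),
                     "regulon_size": len(targets), "mode": "+",
                     "candidate": True, "network": network_id}
                )
            from cllnet.mra import MRAResults

            return MRAResults(table=pd.DataFrame(rows), regulons=regulons,
                              network_id=network_id)

        nets = [
            res_for({"A": {"x", "y"}, "B": {"z"}}, "n1"),
            res_for({"A": {"y", "w"}}, "n2"),
            res_for({"A": {"x"}}, "n3"),
            res_for({"A": {"v"}, "B": {"z"}}, "n4"),
        ]
        out = cross_network_consensus(nets, min_networks=4)
        assert list(out["tf"]) == ["A"]  # B only in 2 networks
        assert set(out["pooled_targets"].iloc[0].split(";")) == {
            "x", "y", "w", "v"
        }
        with pytest.raises(ValueError):
            cross_network_consensus(nets, min_networks=5)
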