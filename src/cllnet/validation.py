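"""Recovery benchmarks: each function plants known truth, runs the method
and measures agreement, calibration or recovery.

These are the package's own validation experiments — closed-form oracles
for the estimators (Gaussian MI, hypergeometric tails, chi-square
combination), Monte-Carlo calibration of the permutation-based tests, and
planted-truth recovery for the network, regulator and survival stages.
Problem sizes are scaled so the whole battery runs on a laptop; see
docs/methods.md for the chosen sizes.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from cllnet import aracne, metade, mra, survival as surv
from cllnet.aracne import AracneParams, apply_dpi, bootstrap_consensus, canonical, infer_network
from cllnet.metade import Signature
from cllnet.synthetic import (
    generate_truth,
    simulate_cohort,
    simulate_normal_cohort,
)

__all__ = [
    "mi_gaussian_error",
    "threshold_null_exceedance",
    "dpi_oracle_agreement",
    "fet_oracle_max_abs_error",
    "combination_type1_errors",
    "fisher_worked_example_error",
    "network_recovery",
    "mra_recovery",
    "global_test_type1_error",
    "cox_ci_coverage",
    "null_profile_empty_fraction",
    "pipeline_demo_recovery",
]


def _seed31(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0]) % (2**31)


# ---------------------------------------------------------------------------
# MI estimator and threshold


def mi_gaussian_error(seed: int, rho: float = 0.8, n: int = 2000) -> dict:
    """Kernel MI vs the closed form -0.5*ln(1 - rho^2) for a bivariate
    Gaussian; also reports the (exactly zero) symmetry gap."""
    rng = np.random.default_rng(seed)
    xy = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], n)
    est = aracne.estimate_mi(xy[:, 0], xy[:, 1])
    rev = aracne.estimate_mi(xy[:, 1], xy[:, 0])
    truth = -0.5 * np.log(1 - rho**2)
    return {
        "estimate": est,
        "true_mi": truth,
        "abs_error": abs(est - truth),
        "symmetry_gap": abs(est - rev),
        "n": n,
    }


def threshold_null_exceedance(
    seed: int, n_genes: int = 200, n_samples: int = 200, n_pairs: int = 1000,
    threshold_pvalue: float = 0.05,
) -> dict:
    """Calibrate I0 at the given p on independent data, then measure the
    fraction of fresh independent pairs whose MI exceeds it."""
    rng = np.random.default_rng(seed)
    expr = pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
    )
    params = AracneParams(
        threshold_pvalue=threshold_pvalue, n_null_pairs=n_pairs, seed=seed,
    )
    i0 = aracne.calibrate_threshold(expr, params)
    h = aracne.default_kernel_width(n_samples)
    exceed = 0
    block = 200
    for start in range(0, n_pairs, block):
        k = min(block, n_pairs - start)
        A = aracne._copula(rng.normal(size=(k, n_samples)))
        B = aracne._copula(rng.normal(size=(k, n_samples)))
        for a in range(k):
            exceed += aracne._mi_block(A[a:a + 1], B[a:a + 1], h)[0, 0] >= i0
    return {"i0": i0, "fraction": exceed / n_pairs, "n": n_pairs}


# ---------------------------------------------------------------------------
# DPI and FET oracles


def _brute_force_dpi(edges: dict, tol: float) -> dict:
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


def dpi_oracle_agreement(
    seed: int, n_graphs: int = 100, n_nodes: int = 10,
    tolerances: tuple = (0.0, 0.1),
) -> dict:
    """Exact agreement of DPI pruning with exhaustive triangle enumeration
    on random weighted graphs."""
    rng = np.random.default_rng(seed)
    nodes = [f"n{i}" for i in range(n_nodes)]
    agree = total = 0
    for _ in range(n_graphs):
        edges = {
            canonical(a, b): float(rng.uniform(0.05, 1.0))
            for a, b in itertools.combinations(nodes, 2)
            if rng.random() < 0.35
        }
        net = aracne.MINetwork(
            edges=dict(edges), nodes=nodes, tf_ids=nodes, i0=0.0,
            params=AracneParams(),
        )
        for tol in tolerances:
            total += 1
            agree += apply_dpi(net, tol).edges == _brute_force_dpi(edges, tol)
    return {"agreement": agree / total, "n": total}


def fet_oracle_max_abs_error(max_universe: int = 60) -> dict:
    """Maximum |difference| between the FET p-value and a direct
    hypergeometric tail summation over every 2x2 table with universe size
    up to ``max_universe``."""
    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    worst = 0.0
    n_tables = 0
    for M in range(1, max_universe + 1):
        for n_sig in range(0, M + 1):
            n_reg = np.arange(0, M + 1)
            for r in n_reg:
                kmax = min(n_sig, r)
                x = np.arange(0, kmax + 1)
                logpmf = (
                    log_comb(n_sig, x)
                    + log_comb(M - n_sig, r - x)
                    - log_comb(M, r)
                )
                pmf = np.exp(logpmf)
                # upper tails by reverse cumulative sum; P(X >= 0) = 1
                tails = np.concatenate([np.cumsum(pmf[::-1])[::-1], [0.0]])
                ks = np.arange(0, kmax + 1)
                ours = np.where(
                    ks == 0, 1.0, stats.hypergeom.sf(ks - 1, M, n_sig, r)
                )
                expected = np.minimum(1.0, tails[:-1])
                expected[0] = 1.0
                worst = max(worst, np.max(np.abs(ours - expected)))
                n_tables += len(ks)
    return {"max_abs_error": float(worst), "n": n_tables}


# ---------------------------------------------------------------------------
# p-value combination


def combination_type1_errors(
    seed: int, n_genes: int = 2000, K: int = 5, alpha: float = 0.05,
) -> dict:
    """Empirical type-I error of each combination method on uniform nulls."""
    rng = np.random.default_rng(seed)
    P = pd.DataFrame(
        rng.uniform(size=(n_genes, K)),
        index=[f"g{i}" for i in range(n_genes)],
    )
    out = {"n": n_genes}
    for method in ("fisher", "stouffer", "maxp", "rop"):
        res = metade.combine_pvalues(P, method, rop_r=2)
        out[method] = float((res["p"] <= alpha).mean())
    return out


def fisher_worked_example_error() -> dict:
    """|Fisher statistic - chi-square oracle| on p = (0.01, 0.02, 0.03)."""
    p = (0.01, 0.02, 0.03)
    res = metade.combine_pvalues(
        pd.DataFrame([list(p)], index=["g"]), "fisher"
    )
    S = -2 * sum(np.log(p))
    return {
        "S": float(res["S"].iloc[0]),
        "statistic_error": abs(float(res["S"].iloc[0]) - S),
        "pvalue_error": abs(float(res["p"].iloc[0]) - stats.chi2.sf(S, 6)),
        "n": len(p),
    }


# ---------------------------------------------------------------------------
# planted-network and MRA recovery


def network_recovery(
    seed: int, n_seeds: int = 5, n_bootstrap: int = 25,
    n_samples: int = 200, n_null_pairs: int = 300,
) -> dict:
    """Consensus-network recovery of a planted 10 TF x 15 target truth
    (coupling 1, noise SD 1), averaged over seeds."""
    ss = np.random.SeedSequence(seed).spawn(n_seeds)
    recalls, precisions = [], []
    for rep in range(n_seeds):
        child = ss[rep].spawn(3)
        truth = generate_truth(160, 10, 15, 0.0, 0, 0, seed=_seed31(child[0]))
        cohort = simulate_cohort(
            truth, n_samples // 2, n_samples - n_samples // 2, 0.0, 1.0,
            seed=_seed31(child[1]),
        )
        params = AracneParams(
            n_bootstrap=n_bootstrap, n_null_pairs=n_null_pairs,
            seed=_seed31(child[2]),
        )
        net = bootstrap_consensus(cohort.expr, truth.tf_ids, params)
        true = truth.true_edges()
        tp = len(set(net.edges) & true)
        recalls.append(tp / len(true))
        precisions.append(tp / max(1, net.n_edges))
    return {
        "recall": float(np.mean(recalls)),
        "precision": float(np.mean(precisions)),
        "n": n_seeds,
    }


def _truth_signature(truth, rng, n_decoys: int = 20) -> Signature:
    master_targets: set = set()
    for tf in truth.master_tfs:
        master_targets |= truth.regulon_map[tf]
    regulated = set().union(*truth.regulon_map.values())
    free = [g for g in truth.gene_ids
            if g not in regulated and g not in truth.tf_ids]
    decoys = list(rng.choice(free, size=min(n_decoys, len(free)),
                             replace=False))
    genes = sorted(master_targets) + decoys
    return Signature(
        table=pd.DataFrame({"gene": genes, "direction": "Up", "q": 0.01})
    )


def mra_recovery(
    seed: int, n_seeds: int = 10, n_samples: int = 200,
    normal_bootstrap: int = 10, n_null_pairs: int = 300,
) -> dict:
    """Master-TF recovery: signature = 3 planted regulons + decoys; checks
    masters rank in the FET top 5, and that the severed-coupling normal
    control enriches no TF."""
    ss = np.random.SeedSequence(seed).spawn(n_seeds)
    all_in_top5 = 0
    normal_enriched = 0
    for rep in range(n_seeds):
        child = ss[rep].spawn(6)
        truth = generate_truth(200, 10, 15, 0.2, 40, 10, seed=_seed31(child[0]))
        cohort = simulate_cohort(
            truth, n_samples // 2, n_samples - n_samples // 2, 0.0, 1.0,
            seed=_seed31(child[1]),
        )
        params = AracneParams(n_null_pairs=n_null_pairs, seed=_seed31(child[2]))
        net = apply_dpi(infer_network(cohort.expr, truth.tf_ids, params))
        signature = _truth_signature(truth, np.random.default_rng(child[3]))
        res = mra.run_mra(net, signature, alpha=0.05)
        top5 = set(res.table["tf"].head(5))
        all_in_top5 += set(truth.master_tfs) <= top5

        normal = simulate_normal_cohort(
            truth, n_samples, 1.0, seed=_seed31(child[4])
        )
        nparams = AracneParams(
            n_bootstrap=normal_bootstrap, n_null_pairs=n_null_pairs,
            seed=_seed31(child[5]),
        )
        nnet = bootstrap_consensus(normal.expr, truth.tf_ids, nparams)
        if nnet.n_edges > 0:
            nres = mra.run_mra(nnet, signature, alpha=0.05)
            normal_enriched += len(nres.candidates())
    return {
        "masters_in_top5_fraction": all_in_top5 / n_seeds,
        "normal_enriched_tfs": normal_enriched,
        "n": n_seeds,
    }


# ---------------------------------------------------------------------------
# survival calibration and recovery


def global_test_type1_error(
    seed: int, n_sims: int = 400, n_perm: int = 500, n_samples: int = 60,
    n_genes: int = 10, alpha: float = 0.05,
) -> dict:
    """Rejection rate of the permutation global test on null data."""
    ss = np.random.SeedSequence(seed).spawn(n_sims)
    rejections = 0
    for rep in range(n_sims):
        data_ss, perm_ss = ss[rep].spawn(2)
        rng = np.random.default_rng(data_ss)
        X = pd.DataFrame(rng.normal(size=(n_genes, n_samples)))
        t = rng.exponential(10.0, size=n_samples)
        c = rng.exponential(50.0, size=n_samples)
        out = surv.SurvivalOutcome(np.minimum(t, c), (t <= c).astype(float))
        res = surv.global_test(X, out, n_perm=n_perm, seed=_seed31(perm_ss))
        rejections += res.p <= alpha
    return {"type1_error": rejections / n_sims, "n": n_sims}


def cox_ci_coverage(
    seed: int, reps: int = 200, n: int = 300, beta: float = 0.7,
) -> dict:
    """Fraction of per-gene Cox fits whose 95% CI covers the planted
    log-hazard ratio."""
    from lifelines import CoxPHFitter

    ss = np.random.SeedSequence(seed).spawn(reps)
    cover = 0
    for rep in range(reps):
        rng = np.random.default_rng(ss[rep])
        x = rng.normal(size=n)
        z = (x - x.mean()) / x.std(ddof=1)
        t = rng.exponential(1.0 / (0.1 * np.exp(beta * z)))
        c = rng.exponential(1.0 / 0.02, size=n)
        df = pd.DataFrame(
            {"time": np.minimum(t, c), "event": (t <= c).astype(float),
             "x": z}
        )
        cph = CoxPHFitter().fit(df, "time", "event")
        lo, hi = cph.confidence_intervals_.iloc[0]
        cover += lo <= beta <= hi
    return {"coverage": cover / reps, "n": reps}


def null_profile_empty_fraction(
    seed: int, reps: int = 40, n_genes: int = 12, n_samples: int = 100,
    n_perm: int = 500,
) -> dict:
    """Fraction of null datasets on which profile reduction returns the
    empty profile."""
    ss = np.random.SeedSequence(seed).spawn(reps)
    empty = 0
    for rep in range(reps):
        data_ss, perm_ss = ss[rep].spawn(2)
        rng = np.random.default_rng(data_ss)
        X = pd.DataFrame(rng.normal(size=(n_genes, n_samples)),
                         index=[f"g{i}" for i in range(n_genes)])
        t = rng.exponential(10.0, size=n_samples)
        c = rng.exponential(50.0, size=n_samples)
        out = surv.SurvivalOutcome(np.minimum(t, c), (t <= c).astype(float))
        res = surv.reduce_profile(X, out, alpha=0.05, n_perm=n_perm,
                                  seed=_seed31(perm_ss))
        empty += len(res) == 0
    return {"empty_fraction": empty / reps, "n": reps}


# ---------------------------------------------------------------------------
# end-to-end


def pipeline_demo_recovery(seed: int, outdir: str) -> dict:
    """Run the synthetic demo pipeline and score consensus-TF recovery of
    the planted master regulators."""
    import json
    from pathlib import Path

    from cllnet.pipeline import run_pipeline, validate_config

    cfg = validate_config(None, {"seed": seed, "outdir": outdir,
                                 "n_null_pairs": 300})
    manifest = run_pipeline(cfg)
    truth = json.loads((Path(outdir) / "truth.json").read_text())
    masters = set(truth["master_tfs"])
    consensus = set(manifest["stages"]["mra"]["consensus_tfs"])
    errors = manifest["stages"]["survival"].get("svm_errors", {})
    return {
        "masters_recovered_fraction": len(masters & consensus) / len(masters),
        "consensus_size": len(consensus),
        "false_consensus_tfs": len(consensus - set(truth["tf_ids"])),
        "signature_size": manifest["stages"]["metade"]["signature_size"],
        "svm_errors": errors,
        "n": len(masters),
    }
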