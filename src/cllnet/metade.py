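"""Per-study differential expression and cross-study p-value combination.

Each study contributes a pooled-variance two-sample t-test per gene
(unmutated vs mutated IGVH status); per-gene p-values are then combined
across studies with one of the classical meta-analysis statistics —
Fisher, Stouffer, maxP, rOP or the adaptively weighted (AW) statistic —
and corrected with Benjamini-Hochberg FDR to yield a directional
signature.  The poor-prognosis group is the unmutated one throughout:
"Up" means higher expression in unmutated samples.

Genes may be missing from some studies (the >=80%-presence merge); each
gene is combined over its own number of contributing studies K_g, with the
reference distribution adjusted accordingly (e.g. chi-square on 2*K_g
degrees of freedom for Fisher).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from cllnet.synthetic import Cohort

__all__ = [
    "StudyDE",
    "Signature",
    "per_study_de",
    "combine_pvalues",
    "bh_adjust",
    "build_signature",
    "COMBINE_METHODS",
]

COMBINE_METHODS = ("fisher", "stouffer", "maxp", "rop", "aw")

#: smallest p-value admitted into a combination (p = 0 is clamped here)
P_FLOOR = 1e-300


@dataclass
class StudyDE:
    """One study's per-gene two-sample test.

    ``table`` is indexed by gene with columns t, p, direction (sign of
    unmutated-minus-mutated mean difference: +1, -1 or 0), usable (bool) and
    degenerate (bool, zero within-group variance in both groups).
    """

    study_id: str
    table: pd.DataFrame


@dataclass
class Signature:
    """Directional DE signature: genes ordered by combined q-value."""

    table: pd.DataFrame  # columns: gene, direction ("Up"/"Down"), q

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])

    def direction_of(self, gene: str) -> str | None:
        hit = self.table.loc[self.table["gene"] == gene, "direction"]
        return None if hit.empty else str(hit.iloc[0])

    def __len__(self) -> int:
        return len(self.table)


def per_study_de(cohort: Cohort, study_id: str | None = None) -> StudyDE:
    """Pooled-variance two-sample t-test per gene, unmutated vs mutated."""
    groups = cohort.samples["group"]
    if groups.isna().any() or not set(groups) >= {"mutated", "unmutated"}:
        raise ValueError("cohort lacks the two phenotype groups")
    a = cohort.expr.loc[:, cohort.group_mask("unmutated")].to_numpy()
    b = cohort.expr.loc[:, cohort.group_mask("mutated")].to_numpy()
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >= 2 samples per group")

    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    diff = a.mean(axis=1) - b.mean(axis=1)
    direction = np.sign(diff).astype(int)

    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    direction = np.where(degenerate, 0, direction)

    table = pd.DataFrame(
        {
            "t": t,
            "p": np.clip(p, P_FLOOR, 1.0),
            "direction": direction,
            "usable": True,
            "degenerate": degenerate,
        },
        index=cohort.expr.index,
    )
    sid = study_id or str(cohort.samples["cohort"].iloc[0])
    return StudyDE(study_id=sid, table=table)


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    return multipletests(arr, method="fdr_bh")[1]


def _aw_combined(p: np.ndarray, k_pattern: np.ndarray, rng: np.random.Generator,
                 n_perm: int = 1000) -> np.ndarray:
    """Adaptively weighted Fisher: best p over binary study-weight vectors.

    Experimental: the null of the minimum-over-subsets statistic is
    approximated by permutation (uniform p-vectors) per missingness pattern.
    """
    n_genes, K = p.shape
    if K > 10:
        raise ValueError("AW search is exhaustive; supports K <= 10")

    def best_subset_p(mat: np.ndarray, avail: np.ndarray) -> np.ndarray:
        # mat: (n, K) with NaN at missing entries; avail: bool (K,)
        idx = np.flatnonzero(avail)
        best = np.ones(mat.shape[0])
        for r in range(1, len(idx) + 1):
            for subset in itertools.combinations(idx, r):
                s = -2.0 * np.log(mat[:, list(subset)]).sum(axis=1)
                pw = stats.chi2.sf(s, df=2 * r)
                best = np.minimum(best, pw)
        return best

    out = np.ones(n_genes)
    for pattern in np.unique(k_pattern, axis=0):
        rows = np.all(k_pattern == pattern, axis=1)
        avail = pattern.astype(bool)
        obs = best_subset_p(p[rows], avail)
        null_p = rng.uniform(size=(n_perm, K))
        null_p[:, ~avail] = np.nan
        null_best = best_subset_p(null_p, avail)
        # permutation p-value of the minimum-p statistic
        out[rows] = (1 + (null_best[None, :] <= obs[:, None]).sum(axis=1)) / (
            n_perm + 1
        )
    return out


def combine_pvalues(
    p_matrix: pd.DataFrame,
    method: str = "fisher",
    rop_r: int = 2,
    direction_matrix: pd.DataFrame | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Combine per-study p-values gene-wise into a meta-analysis result.

    Parameters
    ----------
    p_matrix : DataFrame
        Genes x studies, NaN where a gene is absent from a study.
    method : {"fisher", "stouffer", "maxp", "rop", "aw"}
    rop_r : int
        Order r of the rOP statistic; clipped per gene to its K_g.
    direction_matrix : DataFrame, optional
        Same shape, per-study direction signs; the consensus direction is
        the sign of their sum.
    seed : int
        Only used by the permutation reference of the AW method.

    Returns
    -------
    DataFrame indexed by gene with columns S (combined statistic), p, q
    (BH-adjusted), K (contributing studies), direction.
    """
    if method not in COMBINE_METHODS:
        raise ValueError(f"unknown method {method!r}")
    P = p_matrix.to_numpy(dtype=float)
    if np.any(P == 0):
        warnings.warn("p-values of 0 clamped to the floor")
        P = np.where(P == 0, P_FLOOR, P)
    observed = np.isfinite(P)
    K = observed.sum(axis=1)
    keep = K >= 1
    if not np.all(keep):
        P, observed, K = P[keep], observed[keep], K[keep]
    genes = p_matrix.index[keep]

    with np.errstate(invalid="ignore"):
        if method == "fisher":
            S = -2.0 * np.nansum(np.log(np.where(observed, P, 1.0)), axis=1)
            p = stats.chi2.sf(S, df=2 * K)
        elif method == "stouffer":
            z = stats.norm.isf(np.where(observed, P, np.nan))
            S = np.nansum(z, axis=1) / np.sqrt(K)
            p = stats.norm.sf(S)
        elif method == "maxp":
            S = np.nanmax(np.where(observed, P, -np.inf), axis=1)
            p = S**K
        elif method == "rop":
            r = np.minimum(rop_r, K)
            Psort = np.sort(np.where(observed, P, np.inf), axis=1)
            S = Psort[np.arange(len(K)), r - 1]
            p = stats.beta.cdf(S, r, K - r + 1)
        else:  # aw
            rng = np.random.default_rng(seed)
            p = _aw_combined(np.where(observed, P, np.nan), observed, rng)
            S = -np.log(p)

    p = np.clip(p, P_FLOOR, 1.0)
    if direction_matrix is not None:
        D = direction_matrix.reindex(p_matrix.index).to_numpy(dtype=float)[keep]
        direction = np.sign(np.nansum(np.where(observed, D, np.nan), axis=1))
    else:
        direction = np.zeros(len(K))

    return pd.DataFrame(
        {"S": S, "p": p, "q": bh_adjust(p), "K": K, "direction": direction.astype(int)},
        index=pd.Index(genes, name="gene"),
    )


def build_signature(meta: pd.DataFrame, q_threshold: float = 0.05) -> Signature:
    """Directional signature of genes with combined q below the threshold.

    Direction is reported relative to poor prognosis: "Up" = higher in the
    unmutated group.  Sorted by q then gene id; genes with no consensus
    direction (sign 0) are dropped with a warning.
    """
    if meta.empty:
        raise ValueError("empty meta-analysis result")
    hits = meta[meta["q"] < q_threshold].copy()
    no_dir = hits["direction"] == 0
    if no_dir.any():
        warnings.warn(f"{int(no_dir.sum())} significant genes lack a consensus "
                      "direction and were dropped")
        hits = hits[~no_dir]
    if hits.empty:
        warnings.warn("no gene passes the signature threshold")
    table = pd.DataFrame(
        {
            "gene": hits.index,
            "direction": np.where(hits["direction"] > 0, "Up", "Down"),
            "q": hits["q"].to_numpy(),
        }
    ).sort_values(["q", "gene"], kind="stable", ignore_index=True)
    return Signature(table=table)
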