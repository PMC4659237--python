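"""Gene filtering, probe summarization and cross-cohort merging.

Implements the preprocessing rules of the meta-analysis workflow: a
two-step mean/variance filter per study, IQR-based probe summarization,
merging cohorts on genes present in at least a configured fraction of
studies, and the shorth-based SD filter applied before network inference.

Matrices are dense pandas DataFrames with genes as rows.  Missing cells
occur only in merged matrices, for (gene, cohort) pairs where the gene was
absent from the study; they are excluded from downstream statistics, never
imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MergedExpression",
    "filter_expression",
    "summarize_probes_iqr",
    "merge_cohorts",
    "shorth_sd_filter",
    "shorth",
    "log2_transform",
    "read_probe_map",
]


def log2_transform(expr: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1) for raw-scale intensities.

    Inputs are otherwise assumed to be already variance-stabilized /
    log-scale; negative values indicate the data is not raw-scale.
    """
    if (expr < 0).any().any():
        raise ValueError("negative intensities: input does not look raw-scale")
    return np.log2(expr + 1.0)


@dataclass
class MergedExpression:
    """Multi-cohort expression matrix with per-cohort presence tracking.

    ``expr`` spans all cohorts' samples; cells are NaN where a gene was
    absent from the sample's cohort.  ``cohort_of`` maps each sample to its
    cohort, and ``presence`` is a gene x cohort boolean mask.
    """

    expr: pd.DataFrame
    cohort_of: pd.Series
    presence: pd.DataFrame

    def cohort_matrix(self, cohort: str) -> pd.DataFrame:
        """The merged matrix restricted to one cohort, absent genes dropped."""
        cols = self.cohort_of.index[self.cohort_of == cohort]
        sub = self.expr[cols]
        return sub.loc[self.presence[cohort]]


def _drop_lowest(values: np.ndarray, fraction: float) -> np.ndarray:
    """Boolean keep-mask dropping the floor(fraction*n) lowest values.

    Ties resolved by stable position order, so the result is independent of
    how equal values are interleaved.
    """
    n = len(values)
    k = int(np.floor(fraction * n))
    if k == 0:
        return np.ones(n, dtype=bool)
    order = np.argsort(values, kind="stable")
    keep = np.ones(n, dtype=bool)
    keep[order[:k]] = False
    return keep


def filter_expression(
    expr: pd.DataFrame, mean_drop: float = 0.30, var_drop: float = 0.30
) -> pd.DataFrame:
    """Two-step unsupervised gene filter.

    First drops the ``mean_drop`` fraction of genes with the lowest mean
    intensity (non-expressed genes), then drops the ``var_drop`` fraction of
    the *remainder* with the lowest variance (non-informative genes).  Row
    order of surviving genes is preserved.
    """
    if not (0.0 <= mean_drop < 1.0 and 0.0 <= var_drop < 1.0):
        raise ValueError("drop fractions must be in [0, 1)")
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples")

    means = expr.mean(axis=1, skipna=True).to_numpy()
    step1 = expr.loc[_drop_lowest(means, mean_drop)]
    variances = step1.var(axis=1, ddof=1, skipna=True).to_numpy()
    return step1.loc[_drop_lowest(variances, var_drop)]


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Load a two-column TSV (probe_id, gene_id) into a probe -> gene dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["probe_id", "gene_id"],
                     dtype=str, comment="#")
    if df["probe_id"].duplicated().any():
        raise ValueError("probe map assigns a probe to more than one gene")
    return dict(zip(df["probe_id"], df["gene_id"]))


def summarize_probes_iqr(
    expr: pd.DataFrame, probe_map: dict[str, str]
) -> pd.DataFrame:
    """Collapse probe-level rows to one row per gene by maximal IQR.

    For each gene the representative probe is the one whose expression
    values have the largest interquartile range; IQR ties are broken by the
    lexicographically smallest probe id, so the output does not depend on
    input row order.
    """
    unknown = [p for p in expr.index if p not in probe_map]
    if unknown:
        raise ValueError(f"probes missing from map: {unknown[:5]}...")
    if expr.empty:
        raise ValueError("no probes shared between matrix and map")

    q75 = expr.quantile(0.75, axis=1)
    q25 = expr.quantile(0.25, axis=1)
    iqr = (q75 - q25).to_numpy()

    best: dict[str, tuple[float, str]] = {}
    for probe, gene_iqr in zip(expr.index, iqr):
        gene = probe_map[probe]
        cand = (-gene_iqr, probe)  # max IQR, then min probe id
        if gene not in best or cand < best[gene]:
            best[gene] = cand
    chosen = {gene: probe for gene, (_, probe) in best.items()}
    genes = sorted(chosen)
    out = expr.loc[[chosen[g] for g in genes]].copy()
    out.index = pd.Index(genes, name="gene")
    return out


def merge_cohorts(
    cohorts: dict[str, pd.DataFrame], min_presence: float = 0.80
) -> MergedExpression:
    """Merge gene x sample matrices across cohorts on mostly-shared genes.

    Retains genes present in at least ``min_presence`` of the cohorts;
    samples are concatenated with cohort provenance and absent
    (gene, cohort) cells are NaN.
    """
    if len(cohorts) < 2:
        raise ValueError("need at least 2 cohorts to merge")
    names = list(cohorts)
    all_genes: list[str] = []
    seen: set[str] = set()
    for m in cohorts.values():
        for g in m.index:
            if g not in seen:
                seen.add(g)
                all_genes.append(g)

    presence = pd.DataFrame(
        {name: pd.Index(all_genes).isin(m.index) for name, m in cohorts.items()},
        index=pd.Index(all_genes, name="gene"),
    )
    frac = presence.sum(axis=1) / len(names)
    retained = presence.index[frac >= min_presence]
    if len(retained) == 0:
        raise ValueError("no gene present in enough cohorts; nothing to merge")

    blocks = []
    cohort_of = {}
    for name, m in cohorts.items():
        block = m.reindex(retained)
        blocks.append(block)
        for s in m.columns:
            cohort_of[s] = name
    expr = pd.concat(blocks, axis=1)
    if expr.columns.has_duplicates:
        raise ValueError("duplicated sample IDs across cohorts")
    return MergedExpression(
        expr=expr,
        cohort_of=pd.Series(cohort_of, name="cohort"),
        presence=presence.loc[retained],
    )


def shorth(values: np.ndarray) -> float:
    """Mean of the shortest contiguous half-sample (the "shorth").

    The half-sample is a window of floor(n/2)+1 consecutive order
    statistics; among equal-width windows the leftmost is taken.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("empty sample")
    m = n // 2 + 1
    if m >= n:
        return float(x.mean())
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))  # argmin takes the first = leftmost window
    return float(x[i : i + m].mean())


def shorth_sd_filter(expr: pd.DataFrame) -> pd.DataFrame:
    """Drop low-variability genes before network inference.

    Each gene's standard deviation is computed; genes whose SD falls below
    the shorth of the SD distribution are discarded (comparison is >=, so a
    degenerate all-equal-SD matrix is fully retained).
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples per gene")
    if expr.shape[0] < 2:
        warnings.warn("fewer than 2 genes; shorth SD filter skipped")
        return expr
    sds = expr.std(axis=1, ddof=1, skipna=True).to_numpy()
    threshold = shorth(sds)
    # tiny slack so exact SD ties (equal up to float rounding) are retained
    return expr.loc[sds >= threshold * (1.0 - 1e-12)]
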