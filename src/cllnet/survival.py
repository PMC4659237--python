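"""Censored-survival evaluation of candidate regulons.

Covers the clinical stage of the workflow: a gene-set global test of
association between expression profiles and a censored outcome (overall
survival or time to treatment), univariate Cox screening per gene,
dendrogram-based reduction of a profile to its prognostic core, SVM
classification-error comparison of feature sets, and group-wise relative
expression contrasts.

The global test statistic is the mean squared covariance between each
(standardized) gene and the martingale residuals of the covariate-free Cox
null model; its p-value comes from permuting the residuals, which makes
the test exact under the null irrespective of censoring pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.svm import SVC

from cllnet.metade import bh_adjust

__all__ = [
    "SurvivalOutcome",
    "GlobalTestResult",
    "ReducedProfile",
    "global_test",
    "cox_per_gene",
    "reduce_profile",
    "classification_error",
    "group_contrast",
    "martingale_residuals",
]


@dataclass
class SurvivalOutcome:
    """Per-sample censored outcome for one endpoint (OS or TTT)."""

    time: np.ndarray
    event: np.ndarray
    endpoint: str = "OS"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=float)
        if np.any(self.time <= 0):
            raise ValueError("survival times must be positive")
        if self.event.sum() < 2:
            raise ValueError("need at least 2 events")

    @classmethod
    def from_samples(cls, samples: pd.DataFrame, endpoint: str = "OS"
                     ) -> "SurvivalOutcome":
        tag = endpoint.lower()
        return cls(
            time=samples[f"{tag}_time"].to_numpy(),
            event=samples[f"{tag}_event"].to_numpy(),
            endpoint=endpoint,
        )

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class GlobalTestResult:
    set_id: str
    statistic: float
    p: float
    n_permutations: int
    n_genes: int


@dataclass
class ReducedProfile:
    """Prognostic core of a profile after dendrogram branch testing.

    ``table`` has one row per retained gene with its association sign
    (POS = higher expression associated with longer survival, i.e. a
    negative Cox log-hazard; NEG the opposite) and BH-adjusted Cox p.
    """

    table: pd.DataFrame  # columns: gene, sign, p_adj
    linkage_matrix: np.ndarray | None
    tested_branches: int

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])

    def __len__(self) -> int:
        return len(self.table)


def martingale_residuals(outcome: SurvivalOutcome) -> np.ndarray:
    """Null-model martingale residuals: event - Nelson-Aalen H(t)."""
    t, d = outcome.time, outcome.event
    order = np.argsort(t, kind="stable")
    ts, ds = t[order], d[order]
    n = len(ts)
    # Nelson-Aalen increments at each ordered time (ties share the risk set)
    uniq, first = np.unique(ts, return_index=True)
    H = np.zeros(n)
    cum = 0.0
    for u, i0 in zip(uniq, first):
        at_risk = n - i0
        in_tie = ts == u
        cum += ds[in_tie].sum() / at_risk
        H[in_tie] = cum
    resid = np.empty(n)
    resid[order] = ds - H
    return resid


def _standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    keep = (sd[:, 0] > 0)
    Z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return Z, keep


def global_test(
    expr_subset: pd.DataFrame,
    outcome: SurvivalOutcome,
    n_perm: int = 500,
    seed: int = 0,
    set_id: str = "",
) -> GlobalTestResult:
    """Permutation global test of a gene set against a censored outcome.

    Q = mean over genes of (standardized gene . null martingale residuals)^2;
    the p-value is the permutation tail probability of Q under residual
    relabeling, with the +1 correction so p >= 1/(n_perm + 1).
    """
    if expr_subset.shape[1] != len(outcome):
        raise ValueError("expression and outcome sample counts differ")
    if expr_subset.shape[1] < 10:
        raise ValueError("need at least 10 samples")
    X = expr_subset.to_numpy(dtype=float)
    Z, keep = _standardize_rows(X)
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} constant gene rows dropped")
        Z = Z[keep]
    if Z.shape[0] == 0:
        raise ValueError("no non-constant gene rows")

    r = martingale_residuals(outcome)
    n = len(r)
    G = Z.shape[0]
    q_obs = float(np.mean((Z @ r) ** 2))

    rng = np.random.default_rng(seed)
    # permutation matrix of residuals: (n, n_perm)
    perm = np.argsort(rng.random((n_perm, n)), axis=1)
    R = r[perm].T
    q_perm = np.mean((Z @ R) ** 2, axis=0)
    p = (1.0 + np.sum(q_perm >= q_obs)) / (n_perm + 1.0)
    return GlobalTestResult(
        set_id=set_id, statistic=q_obs, p=float(p),
        n_permutations=n_perm, n_genes=G,
    )


def cox_per_gene(
    expr_subset: pd.DataFrame, outcome: SurvivalOutcome
) -> pd.DataFrame:
    """Univariate Cox fit per standardized gene (Efron ties, Wald p, BH q).

    Non-converging genes are flagged and excluded from downstream
    reduction; their p is NaN.
    """
    if expr_subset.shape[1] != len(outcome):
        raise ValueError("expression and outcome sample counts differ")
    rows = []
    base = pd.DataFrame({"time": outcome.time, "event": outcome.event})
    for gene, row in expr_subset.iterrows():
        x = row.to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            rows.append({"gene": gene, "coef": np.nan, "p": np.nan,
                         "sign": 0, "converged": False})
            continue
        df = base.copy()
        df["x"] = (x - x.mean()) / sd
        try:
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time", event_col="event")
            coef = float(cph.params_["x"])
            p = float(cph.summary.loc["x", "p"])
            rows.append({"gene": gene, "coef": coef, "p": p,
                         "sign": int(np.sign(coef)), "converged": True})
        except Exception:
            rows.append({"gene": gene, "coef": np.nan, "p": np.nan,
                         "sign": 0, "converged": False})
    out = pd.DataFrame(rows).set_index("gene")
    ok = out["converged"] & out["p"].notna()
    q = np.full(len(out), np.nan)
    if ok.any():
        q[ok.to_numpy()] = bh_adjust(out.loc[ok, "p"])
    out["q"] = q
    return out


def _cluster_tree(expr: pd.DataFrame) -> tuple[np.ndarray, list[list[int]]]:
    """Average-linkage tree on 1 - |Pearson correlation| distances.

    Returns the linkage matrix and, for every internal node (in linkage
    order), the list of leaf indices under it.
    """
    X = expr.to_numpy(dtype=float)
    C = np.corrcoef(X)
    D = 1.0 - np.abs(C)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    Z = linkage(squareform(np.clip(D, 0.0, None), checks=False), method="average")
    g = X.shape[0]
    members: list[list[int]] = [[i] for i in range(g)]
    for a, b in Z[:, :2].astype(int):
        members.append(members[a] + members[b])
    return Z, members


def reduce_profile(
    expr_subset: pd.DataFrame,
    outcome: SurvivalOutcome,
    alpha: float = 0.05,
    n_perm: int = 2000,
    seed: int = 0,
) -> ReducedProfile:
    """Dendrogram "zoom": discard non-significant branches, keep the core.

    Genes are clustered with distance 1 - |correlation| and average linkage;
    branches are tested top-down with the global test under an inheritance
    rule — a child is tested only if its parent was significant, and the
    parent's alpha is split between children proportionally to their leaf
    counts.  Retained genes are leaves whose whole ancestor chain (their
    own single-gene test included) was significant; each is reported with
    its Cox coefficient sign (POS = protective) and BH-adjusted Cox p.
    """
    if expr_subset.shape[0] < 3:
        raise ValueError("need at least 3 genes to reduce")
    genes = list(expr_subset.index)
    Z, members = _cluster_tree(expr_subset)
    g = len(genes)
    root = g + len(Z) - 1

    ss = np.random.SeedSequence(seed)
    child_seeds = iter(ss.generate_state(4 * g + 16))

    tested = 0
    retained: list[int] = []
    stack: list[tuple[int, float]] = [(root, alpha)]
    while stack:
        node, a_node = stack.pop()
        leaves = members[node]
        res = global_test(
            expr_subset.iloc[leaves],
            outcome,
            n_perm=n_perm,
            seed=int(next(child_seeds)) % (2**31),
            set_id=f"branch{node}",
        )
        tested += 1
        if res.p > a_node:
            continue
        if node < g:
            retained.append(node)
            continue
        left, right = Z[node - g, :2].astype(int)
        n_leaves = len(leaves)
        for child in (left, right):
            frac = len(members[child]) / n_leaves
            stack.append((child, a_node * frac))

    if not retained:
        return ReducedProfile(
            table=pd.DataFrame(columns=["gene", "sign", "p_adj"]),
            linkage_matrix=Z, tested_branches=tested,
        )

    kept_genes = [genes[i] for i in sorted(retained)]
    cox = cox_per_gene(expr_subset.loc[kept_genes], outcome)
    table = pd.DataFrame(
        {
            "gene": kept_genes,
            # POS: higher expression -> lower hazard -> longer survival
            "sign": ["POS" if cox.loc[gn, "coef"] < 0 else "NEG"
                     for gn in kept_genes],
            "p_adj": [cox.loc[gn, "q"] for gn in kept_genes],
        }
    ).sort_values("p_adj", kind="stable", ignore_index=True)
    return ReducedProfile(table=table, linkage_matrix=Z, tested_branches=tested)


def classification_error(
    expr: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    feature_sets: dict[str, list[str]],
    train_n: int,
    test_n: int,
    seed: int = 0,
) -> dict[str, float]:
    """Linear-SVM misclassification rate per feature set on one shared split.

    The split is drawn once, stratified by class so both labels occur on
    both sides, and reused for every feature set so their errors are
    directly comparable.  The SVM is a linear-kernel SVC with C = 1.
    """
    y = np.asarray(labels)
    n = len(y)
    if train_n + test_n > n:
        raise ValueError("train_n + test_n exceeds the number of samples")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")

    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        k_train = int(round(train_n * len(idx) / n))
        k_test = int(round(test_n * len(idx) / n))
        k_train = max(1, min(k_train, len(idx) - 1))
        train_idx.extend(idx[:k_train])
        test_idx.extend(idx[k_train : k_train + k_test])
    train_idx = np.sort(np.array(train_idx))
    test_idx = np.sort(np.array(test_idx))

    errors = {}
    for name, genes in feature_sets.items():
        present = [gn for gn in genes if gn in expr.index]
        if not present:
            raise ValueError(f"feature set {name!r} has no gene in the matrix")
        X = expr.loc[present].to_numpy(dtype=float).T
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(X[train_idx], y[train_idx])
        pred = clf.predict(X[test_idx])
        errors[name] = float(np.mean(pred != y[test_idx]))
    return errors


def group_contrast(
    expr_subset: pd.DataFrame, groups: pd.Series | np.ndarray
) -> pd.DataFrame:
    """Relative-expression group comparison with Bonferroni-corrected t-tests.

    Expression is scaled per gene by its grand mean across all samples (so a
    relative mean of 1 is "average"); each gene gets a two-sided pooled t
    test between the two groups, Bonferroni-corrected over the genes tested.
    Genes with a zero grand mean are skipped with a warning.
    """
    gvec = np.asarray(groups)
    names = [x for x in pd.unique(gvec) if not pd.isna(x)]
    if len(names) != 2:
        raise ValueError("need exactly two groups")
    m1, m2 = gvec == names[0], gvec == names[1]
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("need >= 2 samples per group")

    grand = expr_subset.mean(axis=1)
    zero = grand == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} genes with zero grand mean skipped")
    sub = expr_subset.loc[~zero]
    rel = sub.div(sub.mean(axis=1), axis=0)

    a = rel.loc[:, m1].to_numpy()
    b = rel.loc[:, m2].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    p = np.where(np.isfinite(p), p, 1.0)
    m = len(sub)
    return pd.DataFrame(
        {
            f"rel_mean_{names[0]}": a.mean(axis=1),
            f"rel_mean_{names[1]}": b.mean(axis=1),
            "t": t,
            "p": p,
            "p_bonferroni": np.minimum(1.0, m * p),
        },
        index=sub.index,
    )
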