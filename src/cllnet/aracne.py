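"""TF-centered mutual-information network inference.

The reconstruction follows the classical information-theoretic recipe:

1. pairwise mutual information (MI) between each transcription factor and
   every other gene, estimated with a Gaussian kernel density estimator on
   copula(rank)-transformed data;
2. a minimum MI threshold I0 calibrated from a permutation null at a chosen
   significance level (default p = 0.05), with the null tail extrapolated
   by an exponential fit ln P(MI > m) = alpha - beta * m;
3. data processing inequality (DPI) pruning of the weakest edge in every
   triangle (tolerance 0 by default);
4. bootstrap resampling of samples (default 100 replicates) and a consensus
   network keeping edges supported by significantly many replicates under a
   Poisson null.

Edges are stored undirected with at least one TF endpoint; downstream
regulon extraction treats the TF endpoint as the regulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AracneParams",
    "MINetwork",
    "estimate_mi",
    "calibrate_threshold",
    "infer_network",
    "apply_dpi",
    "bootstrap_consensus",
    "default_kernel_width",
]

Edge = tuple[str, str]


def canonical(a: str, b: str) -> Edge:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class AracneParams:
    """Tuning knobs of the network reconstruction.

    threshold_pvalue : significance level of the MI threshold (default 0.05).
    dpi_tolerance    : DPI tolerance epsilon in [0, 1); 0 removes the weakest
                       edge of every triangle with a strict comparison.
    n_bootstrap      : number of bootstrap replicates for the consensus.
    kernel_width     : Gaussian kernel width on the copula-transformed unit
                       square, or "auto" for 0.25 * n^(-1/6).
    n_null_pairs     : permuted gene pairs used to calibrate I0.
    consensus_alpha  : significance for bootstrap edge retention (Bonferroni
                       over tested edges).
    seed             : master seed; per-replicate seeds are derived from it.
    """

    threshold_pvalue: float = 0.05
    dpi_tolerance: float = 0.0
    n_bootstrap: int = 100
    kernel_width: float | str = "auto"
    n_null_pairs: int = 1000
    consensus_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold_pvalue < 1.0):
            raise ValueError("threshold_pvalue must be in (0, 1)")
        if not (0.0 <= self.dpi_tolerance < 1.0):
            raise ValueError("dpi_tolerance must be in [0, 1)")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")


@dataclass
class MINetwork:
    """Undirected TF-centered network with MI-weighted edges.

    ``edges`` maps a canonically sorted gene pair to its MI; ``support`` and
    ``consensus_p`` are populated by :func:`bootstrap_consensus`.
    """

    edges: dict[Edge, float]
    nodes: list[str]
    tf_ids: list[str]
    i0: float
    params: AracneParams
    support: dict[Edge, int] = field(default_factory=dict)
    consensus_p: dict[Edge, float] = field(default_factory=dict)
    network_id: str = ""

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, gene: str) -> set[str]:
        out = set()
        for a, b in self.edges:
            if a == gene:
                out.add(b)
            elif b == gene:
                out.add(a)
        return out

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {}
        for a, b in self.edges:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        return adj

    def to_frame(self) -> pd.DataFrame:
        """Edge list with the TF endpoint first (SIF-like)."""
        tfs = set(self.tf_ids)
        rows = []
        for (a, b), mi in sorted(self.edges.items()):
            tf, target = (a, b) if a in tfs else (b, a)
            rows.append(
                {
                    "tf": tf,
                    "target": target,
                    "mi": mi,
                    "support": self.support.get((a, b), np.nan),
                    "consensus_p": self.consensus_p.get((a, b), np.nan),
                }
            )
        return pd.DataFrame(rows, columns=["tf", "target", "mi", "support",
                                           "consensus_p"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def default_kernel_width(n: int) -> float:
    """Default bandwidth 0.25 * n^(-1/6) on the copula unit square."""
    return 0.25 * n ** (-1.0 / 6.0)


def _copula(X: np.ndarray) -> np.ndarray:
    """Row-wise rank transform to (0, 1): ranks / (n + 1), average ties."""
    n = X.shape[-1]
    return stats.rankdata(X, axis=-1) / (n + 1)


def _mi_block(U: np.ndarray, V: np.ndarray, h: float) -> np.ndarray:
    """MI between every row of U (p, n) and every row of V (q, n), in nats.

    Plug-in Gaussian-kernel estimator on copula scale, evaluated at the
    sample points: mean_i log[ f2(u_i, v_i) / (f1(u_i) f1(v_i)) ], clamped
    at 0.  Normalization constants cancel in the ratio except for the n vs
    n^2 factor, which is kept explicit.
    """
    p, n = U.shape
    q = V.shape[0]
    inv = -1.0 / (2.0 * h * h)
    # per-row kernel matrices
    KU = np.exp(inv * (U[:, :, None] - U[:, None, :]) ** 2)  # (p, n, n)
    KV = np.exp(inv * (V[:, :, None] - V[:, None, :]) ** 2)  # (q, n, n)
    su = KU.sum(axis=2)  # (p, n) ~ n * sqrt(2 pi) h * f1(u_i)
    sv = KV.sum(axis=2)  # (q, n)
    out = np.empty((p, q))
    for a in range(p):
        j2 = np.einsum("ij,qij->qi", KU[a], KV)  # (q, n) joint kernel sums
        ratio = n * j2 / (su[a][None, :] * sv)
        out[a] = np.mean(np.log(ratio), axis=1)
    return np.maximum(out, 0.0)


def estimate_mi(x: np.ndarray, y: np.ndarray, width: float | str = "auto") -> float:
    """Kernel MI (nats) between two sample vectors after copula transform.

    Symmetric by construction; constant vectors yield 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    n = len(x)
    if n < 20:
        raise ValueError("need at least 20 samples for the kernel estimator")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: MI defined as 0")
        return 0.0
    h = default_kernel_width(n) if width == "auto" else float(width)
    U = _copula(x[None, :])
    V = _copula(y[None, :])
    return float(_mi_block(U, V, h)[0, 0])


def _null_mis(
    X: np.ndarray, n_pairs: int, h: float, rng: np.random.Generator,
    block: int = 250,
) -> np.ndarray:
    """MI of random gene pairs with one member independently permuted."""
    g, n = X.shape
    U = _copula(X)
    i_idx = rng.integers(0, g, size=n_pairs)
    j_idx = rng.integers(0, g, size=n_pairs)
    out = np.empty(n_pairs)
    for start in range(0, n_pairs, block):
        sl = slice(start, min(start + block, n_pairs))
        A = U[i_idx[sl]]
        B = U[j_idx[sl]]
        # destroy dependence by permuting each pair's second member
        B = np.take_along_axis(
            B, np.argsort(rng.random(B.shape), axis=1), axis=1
        )
        p = A.shape[0]
        inv = -1.0 / (2.0 * h * h)
        KA = np.exp(inv * (A[:, :, None] - A[:, None, :]) ** 2)
        KB = np.exp(inv * (B[:, :, None] - B[:, None, :]) ** 2)
        sa = KA.sum(axis=2)
        sb = KB.sum(axis=2)
        j2 = np.einsum("pij,pij->pi", KA, KB)
        ratio = n * j2 / (sa * sb)
        out[sl] = np.maximum(np.mean(np.log(ratio), axis=1), 0.0)
    return out


def calibrate_threshold(
    expr: pd.DataFrame | np.ndarray,
    params: AracneParams,
    rng: np.random.Generator | None = None,
) -> float:
    """MI threshold I0 from a permutation null at ``params.threshold_pvalue``.

    Null MI values are generated by permuting one member of random gene
    pairs; the upper tail is fitted as ln P(MI > m) = alpha - beta * m and
    I0 solves the fit at the requested p.  If the fit degenerates
    (beta <= 0) the empirical (1 - p) quantile is returned with a warning.
    """
    if params.n_null_pairs < 100:
        raise ValueError("n_null_pairs must be >= 100")
    X = expr.to_numpy(dtype=float) if isinstance(expr, pd.DataFrame) else expr
    n = X.shape[1]
    h = (
        default_kernel_width(n)
        if params.kernel_width == "auto"
        else float(params.kernel_width)
    )
    if rng is None:
        rng = np.random.default_rng(params.seed)
    null = np.sort(_null_mis(X, params.n_null_pairs, h, rng))
    m = len(null)

    if params.threshold_pvalue >= 1.0:
        return float(null[0])

    # upper-tail survival: P(MI > null[k]) ~ (m - 1 - k) / m; fit the top 25%
    k0 = int(0.75 * m)
    tail = np.arange(k0, m - 1)
    surv = (m - 1 - tail) / m
    x_fit = null[tail]
    y_fit = np.log(surv)
    if np.ptp(x_fit) == 0:
        beta = -1.0
    else:
        beta_slope, alpha = np.polyfit(x_fit, y_fit, 1)
        beta = -beta_slope
    if beta <= 0:
        warnings.warn("degenerate tail fit; falling back to empirical quantile")
        return float(np.quantile(null, 1.0 - params.threshold_pvalue))
    return float((alpha - np.log(params.threshold_pvalue)) / beta)


def infer_network(
    expr: pd.DataFrame,
    tf_ids: list[str],
    params: AracneParams,
    i0: float | None = None,
    network_id: str = "",
) -> MINetwork:
    """Single-run network: all (TF, gene) MI values thresholded at I0.

    TF-TF pairs are allowed; edges are stored once, undirected.  ``i0`` may
    be passed to reuse a threshold calibrated on the full data (as done for
    bootstrap replicates); otherwise it is calibrated here.
    """
    genes = list(expr.index)
    tfs = [t for t in tf_ids if t in set(genes)]
    if not tfs:
        raise ValueError("no TF present in the expression matrix")
    n = expr.shape[1]
    if n < 20:
        raise ValueError("need at least 20 samples for the MI estimator")

    if i0 is None:
        i0 = calibrate_threshold(expr, params)
    h = (
        default_kernel_width(n)
        if params.kernel_width == "auto"
        else float(params.kernel_width)
    )

    X = expr.to_numpy(dtype=float)
    U = _copula(X)
    pos = {g: i for i, g in enumerate(genes)}
    tf_rows = np.array([pos[t] for t in tfs])
    mi = _mi_block(U[tf_rows], U, h)  # (n_tfs, n_genes)

    tf_set = set(tfs)
    edges: dict[Edge, float] = {}
    for a, tf in enumerate(tfs):
        hits = np.flatnonzero(mi[a] >= i0)
        for j in hits:
            g = genes[j]
            if g == tf:
                continue
            key = canonical(tf, g)
            # a TF-TF pair is computed twice; keep the mean (they are equal
            # up to symmetry of the estimator)
            if key not in edges:
                edges[key] = float(mi[a, j])
    return MINetwork(
        edges=edges, nodes=genes, tf_ids=tfs, i0=float(i0), params=params,
        network_id=network_id,
    )


def apply_dpi(net: MINetwork, tolerance: float | None = None) -> MINetwork:
    """Remove the weakest edge of every triangle (data processing inequality).

    Edge (i, j) is removed when MI(i, j) < (1 - tolerance) * min(MI(i, k),
    MI(j, k)) for some common neighbor k **of the input network**; all
    checks use input MI values and removals are applied once at the end.
    The comparison is strict, so exact ties keep all three edges at
    tolerance 0.
    """
    tol = net.params.dpi_tolerance if tolerance is None else tolerance
    if not (0.0 <= tol < 1.0):
        raise ValueError("tolerance must be in [0, 1)")
    adj = net.adjacency()
    doomed: set[Edge] = set()
    for (a, b), mi_ab in net.edges.items():
        common = adj[a] & adj[b]
        for k in common:
            mi_ak = net.edges[canonical(a, k)]
            mi_bk = net.edges[canonical(b, k)]
            if mi_ab < (1.0 - tol) * min(mi_ak, mi_bk):
                doomed.add((a, b))
                break
    kept = {e: v for e, v in net.edges.items() if e not in doomed}
    return replace(net, edges=kept,
                   support={e: s for e, s in net.support.items() if e in kept},
                   consensus_p={e: p for e, p in net.consensus_p.items() if e in kept})


def consensus_support_threshold(
    supports: dict[Edge, int], n_bootstrap: int, alpha: float
) -> tuple[int, float]:
    """Minimal significant support count under the Poisson edge null.

    The null rate is the mean support over all edges ever observed; the
    threshold is the smallest s with P(Poisson(mu) >= s) <= alpha / n_edges
    (Bonferroni over tested edges).
    """
    counts = np.array(list(supports.values()))
    n_edges = len(counts)
    mu = counts.sum() / n_edges
    bonf = alpha / n_edges
    # P(X >= s) = poisson.sf(s - 1, mu); an edge present in every replicate
    # is always retained, so the threshold is capped at n_bootstrap (the
    # Poisson null degenerates when persistent edges dominate the mean)
    for s in range(1, n_bootstrap + 1):
        if stats.poisson.sf(s - 1, mu) <= bonf:
            return s, mu
    return n_bootstrap, mu


def bootstrap_consensus(
    expr: pd.DataFrame,
    tf_ids: list[str],
    params: AracneParams,
    network_id: str = "",
) -> MINetwork:
    """Consensus network over bootstrap-resampled reconstructions.

    Samples are resampled with replacement ``params.n_bootstrap`` times;
    each replicate runs :func:`infer_network` with the MI threshold
    recalibrated on the resampled data (resampling duplicates samples,
    which inflates kernel MI estimates; a threshold calibrated on the
    original data would be systematically too low) followed by DPI
    pruning.  Edges
    are retained when their support count is significant under a Poisson
    null whose mean is the average support over all observed edges, at
    ``params.consensus_alpha`` with Bonferroni correction.  The consensus
    MI of an edge is its mean over supporting replicates; ``consensus_p``
    records the Bonferroni-adjusted Poisson tail probability.
    """
    if params.n_bootstrap < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    n = expr.shape[1]
    if params.n_bootstrap * n < 100:
        warnings.warn("few resampled observations; consensus may be unstable")

    i0 = calibrate_threshold(expr, params)
    seeds = np.random.SeedSequence(params.seed).spawn(params.n_bootstrap)

    support: dict[Edge, int] = {}
    mi_sum: dict[Edge, float] = {}
    for b in range(params.n_bootstrap):
        rng = np.random.default_rng(seeds[b])
        cols = rng.integers(0, n, size=n)
        boot = pd.DataFrame(
            expr.to_numpy()[:, cols],
            index=expr.index,
            columns=[f"b{b}_{i}" for i in range(n)],
        )
        i0_b = calibrate_threshold(boot, params, rng=rng)
        net_b = apply_dpi(infer_network(boot, tf_ids, params, i0=i0_b))
        for e, v in net_b.edges.items():
            support[e] = support.get(e, 0) + 1
            mi_sum[e] = mi_sum.get(e, 0.0) + v

    if not support:
        return MINetwork(edges={}, nodes=list(expr.index), tf_ids=list(tf_ids),
                         i0=i0, params=params, network_id=network_id)

    s_min, mu = consensus_support_threshold(
        support, params.n_bootstrap, params.consensus_alpha
    )
    n_edges = len(support)
    kept = {e for e, s in support.items() if s >= s_min}
    edges = {e: mi_sum[e] / support[e] for e in kept}
    consensus_p = {
        e: min(1.0, n_edges * stats.poisson.sf(support[e] - 1, mu)) for e in kept
    }
    return MINetwork(
        edges=edges,
        nodes=list(expr.index),
        tf_ids=[t for t in tf_ids if t in set(expr.index)],
        i0=i0,
        params=params,
        support={e: support[e] for e in kept},
        consensus_p=consensus_p,
        network_id=network_id,
    )


def read_network(path, tf_ids: list[str], params: AracneParams | None = None) -> MINetwork:
    """Load a 5-column TSV edge list written by :meth:`MINetwork.write`."""
    df = pd.read_csv(path, sep="\t")
    edges, support, consensus_p = {}, {}, {}
    for row in df.itertuples(index=False):
        key = canonical(row.tf, row.target)
        edges[key] = float(row.mi)
        if not pd.isna(row.support):
            support[key] = int(row.support)
        if not pd.isna(row.consensus_p):
            consensus_p[key] = float(row.consensus_p)
    nodes = sorted({g for e in edges for g in e})
    return MINetwork(
        edges=edges, nodes=nodes, tf_ids=[t for t in tf_ids],
        i0=float("nan"), params=params or AracneParams(),
        support=support, consensus_p=consensus_p,
    )
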