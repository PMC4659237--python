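"""Synthetic multi-cohort expression data with planted regulatory structure.

The generator emulates the statistical features the downstream analysis
relies on: several expression cohorts sharing one gene universe, a planted
TF -> target network with a linear-Gaussian coupling model, a two-group
differential-expression contrast between IGVH mutational statuses
("mutated" vs "unmutated", where unmutated carries the poorer prognosis),
exponential proportional-hazards survival outcomes driven by a subset of
the planted DE genes, and a "normal" control cohort in which the disease
couplings are severed.

All generators are pure functions of their arguments, including the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticTruth",
    "Cohort",
    "generate_truth",
    "simulate_cohort",
    "simulate_survival",
    "simulate_normal_cohort",
    "write_cohort",
    "read_cohort",
    "write_truth",
    "read_truth",
]

#: baseline log-scale intensity added to every gene
BASELINE = 8.0

#: magnitude of the planted per-gene log-hazard coefficients
DEFAULT_LOG_HR = 0.7

ANNOT_COLUMNS = ["cohort", "group", "os_time", "os_event", "ttt_time", "ttt_event"]


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth against which recovery is scored.

    Attributes
    ----------
    gene_ids : list of str
        The full gene universe, TFs included.
    tf_ids : list of str
        Genes designated as transcription factors (regulators).
    master_tfs : list of str
        The subset of TFs whose targets seed the differential-expression
        signature; these are the regulators the analysis should recover.
    regulon_map : dict
        TF id -> set of target gene ids.  Regulons may overlap through a
        shared target pool.
    regulon_strength : dict
        TF id -> linear coupling coefficient of its targets.
    de_genes : dict
        gene id -> direction ("Up"/"Down") of regulation in the poor-prognosis
        (unmutated) group.
    survival_genes : dict
        gene id -> log-hazard coefficient per standard deviation of
        expression; a subset of ``de_genes``.
    seed : int
    """

    gene_ids: list[str]
    tf_ids: list[str]
    master_tfs: list[str]
    regulon_map: dict[str, set[str]]
    regulon_strength: dict[str, float]
    de_genes: dict[str, str]
    survival_genes: dict[str, float]
    seed: int

    @property
    def target_of(self) -> dict[str, list[str]]:
        """Map target gene -> list of TFs regulating it (sorted)."""
        owners: dict[str, list[str]] = {}
        for tf in self.tf_ids:
            for g in self.regulon_map.get(tf, ()):
                owners.setdefault(g, []).append(tf)
        return {g: sorted(v) for g, v in owners.items()}

    def true_edges(self) -> set[tuple[str, str]]:
        """All planted TF-target edges as canonically sorted pairs."""
        return {
            tuple(sorted((tf, g)))
            for tf, targets in self.regulon_map.items()
            for g in targets
        }


@dataclass
class Cohort:
    """One study: expression matrix plus per-sample annotations.

    ``expr`` is genes x samples (log-scale intensities); ``samples`` is
    indexed by sample id with columns cohort, group, os_time, os_event,
    ttt_time, ttt_event (outcome columns NaN until survival is simulated,
    or for cohorts used only for network inference).
    """

    expr: pd.DataFrame
    samples: pd.DataFrame
    platform: str = "synthetic"

    def __post_init__(self) -> None:
        if self.expr.index.has_duplicates:
            raise ValueError("duplicated gene IDs in cohort")
        if self.expr.columns.has_duplicates:
            raise ValueError("duplicated sample IDs in cohort")
        if not self.expr.columns.equals(self.samples.index):
            raise ValueError("expression columns and sample annotations disagree")

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]

    def group_mask(self, group: str) -> np.ndarray:
        return (self.samples["group"] == group).to_numpy()


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_truth(
    n_genes: int,
    n_tfs: int,
    targets_per_tf: int,
    overlap_fraction: float,
    n_de: int,
    n_survival: int,
    seed: int,
    n_masters: int | None = None,
    coupling: float = 1.0,
    log_hr: float = DEFAULT_LOG_HR,
) -> SyntheticTruth:
    """Plant a TF->target map, DE genes and survival coefficients.

    Each regulon has ``round(overlap_fraction * targets_per_tf)`` targets
    drawn from a shared pool (producing regulon overlap) and the rest
    exclusive, which keeps every planted regulator identifiable.  DE genes
    are the union of the master TFs' targets (up to ``n_de``) topped up with
    independent genes; survival genes are a subset of the DE genes with
    log-hazard coefficient ``+log_hr`` for Up genes and ``-log_hr`` for
    Down genes (Up in the poor-prognosis group drives hazard up).
    """
    if n_tfs < 1:
        raise ValueError("need at least one TF")
    if not (0.0 <= overlap_fraction < 1.0):
        raise ValueError("overlap_fraction must be in [0, 1)")
    if n_tfs + n_tfs * targets_per_tf > n_genes:
        raise ValueError(
            f"{n_tfs} TFs with {targets_per_tf} targets each do not fit in "
            f"{n_genes} genes"
        )
    if n_de > n_genes - n_tfs:
        raise ValueError("n_de exceeds the number of non-TF genes")
    if n_survival > n_de:
        raise ValueError("n_survival exceeds n_de")

    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    tf_ids = genes[:n_tfs]
    non_tf = genes[n_tfs:]

    n_shared = int(round(overlap_fraction * targets_per_tf))
    pool_size = targets_per_tf if n_shared > 0 else 0
    pool = list(non_tf[:pool_size])
    exclusive_stock = list(non_tf[pool_size:])
    n_excl = targets_per_tf - n_shared
    if n_tfs * n_excl > len(exclusive_stock):
        raise ValueError("not enough genes for exclusive targets")

    regulon_map: dict[str, set[str]] = {}
    regulon_strength: dict[str, float] = {}
    for i, tf in enumerate(tf_ids):
        shared = (
            list(rng.choice(pool, size=n_shared, replace=False)) if n_shared else []
        )
        excl = exclusive_stock[i * n_excl : (i + 1) * n_excl]
        regulon_map[tf] = set(shared) | set(excl)
        regulon_strength[tf] = coupling

    if n_masters is None:
        n_masters = min(3, n_tfs)
    masters = tf_ids[:n_masters]

    master_targets: list[str] = []
    seen: set[str] = set()
    for tf in masters:
        for g in sorted(regulon_map[tf]):
            if g not in seen:
                seen.add(g)
                master_targets.append(g)
    de_pool = master_targets[:n_de]
    if len(de_pool) < n_de:
        regulated = set().union(*regulon_map.values()) if regulon_map else set()
        free = [g for g in non_tf if g not in regulated]
        extra = n_de - len(de_pool)
        if extra > len(free):
            raise ValueError("not enough independent genes for n_de")
        de_pool = de_pool + list(rng.choice(free, size=extra, replace=False))

    directions = rng.choice(["Up", "Down"], size=n_de)
    de_genes = dict(zip(de_pool, directions))

    surv_pick = rng.choice(de_pool, size=n_survival, replace=False) if n_survival else []
    survival_genes = {
        g: (log_hr if de_genes[g] == "Up" else -log_hr) for g in surv_pick
    }

    return SyntheticTruth(
        gene_ids=genes,
        tf_ids=list(tf_ids),
        master_tfs=list(masters),
        regulon_map=regulon_map,
        regulon_strength=regulon_strength,
        de_genes=de_genes,
        survival_genes=survival_genes,
        seed=seed,
    )


def _gene_properties(
    truth: SyntheticTruth, noise_sd: float, sd_jitter: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene baselines and noise SDs, deterministic from the truth seed.

    Gene identity is a property of the universe, not of one cohort, so
    baselines and variability multipliers are shared by every cohort drawn
    from the same truth.  Genes involved in the planted regulation (TFs,
    targets, DE genes) are "expressed": their baseline sits in the upper
    intensity range, while background genes spread lower — emulating the
    non-expressed fraction that mean-intensity filters remove.  With
    ``sd_jitter > 0`` background variability is log-normally heterogeneous,
    giving the continuous SD distribution that shorth-based filters assume.
    """
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 0x5EED]))
    genes = truth.gene_ids
    planted = set(truth.tf_ids) | set(truth.de_genes)
    for targets in truth.regulon_map.values():
        planted |= targets
    is_planted = np.array([g in planted for g in genes])
    baseline = np.where(
        is_planted,
        rng.normal(BASELINE + 1.5, 0.5, size=len(genes)),
        rng.normal(BASELINE - 1.0, 1.5, size=len(genes)),
    )
    sds = np.full(len(genes), noise_sd)
    if sd_jitter > 0:
        jitter = np.exp(rng.normal(0.0, sd_jitter, size=len(genes)))
        sds = np.where(is_planted, sds, sds * jitter)
    return baseline, sds


def _base_expression(
    truth: SyntheticTruth,
    n: int,
    noise_sd: float,
    rng: np.random.Generator,
    sd_jitter: float = 0.0,
) -> np.ndarray:
    """Linear-Gaussian expression: TFs iid, targets = sum(coupling*TF) + noise.

    A TF's marginal variance is noise_sd^2 + coupling^2: intrinsic noise
    plus a unit-variance regulatory drive scaled by the coupling, so that
    regulators are as variable as the targets they drive (in real tissue
    regulators are themselves regulated).  At coupling 0 every gene is
    plain noise; as noise_sd -> 0 targets become deterministic functions of
    their TFs.
    """
    genes = truth.gene_ids
    gene_pos = {g: i for i, g in enumerate(genes)}
    baseline, sds = _gene_properties(truth, noise_sd, sd_jitter)
    X = rng.normal(0.0, 1.0, size=(len(genes), n)) * sds[:, None]
    for tf in truth.tf_ids:
        c = truth.regulon_strength[tf]
        i_tf = gene_pos[tf]
        X[i_tf] *= np.sqrt(noise_sd**2 + c * c) / noise_sd
        for g in truth.regulon_map[tf]:
            X[gene_pos[g]] += c * X[i_tf]
    return X + baseline[:, None]


def simulate_cohort(
    truth: SyntheticTruth,
    n_mut: int,
    n_unmut: int,
    group_shift: float,
    noise_sd: float,
    seed: int,
    cohort_id: str = "C1",
    platform: str = "synthetic",
    sd_jitter: float = 0.0,
) -> Cohort:
    """Simulate one disease cohort with the planted couplings and DE contrast.

    Up-regulated DE genes receive ``+group_shift`` in the unmutated
    (poor-prognosis) group, Down genes ``-group_shift``; the mutated group is
    the reference.  ``sd_jitter`` adds per-gene log-normal noise-SD
    heterogeneity (a gene property shared across cohorts).  Survival columns
    are left NaN until :func:`simulate_survival` fills them.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if n_mut + n_unmut < 4:
        raise ValueError("need at least 4 samples for downstream tests")

    rng = np.random.default_rng(seed)
    n = n_mut + n_unmut
    X = _base_expression(truth, n, noise_sd, rng, sd_jitter=sd_jitter)

    genes = truth.gene_ids
    gene_pos = {g: i for i, g in enumerate(genes)}
    unmut = np.zeros(n, dtype=bool)
    unmut[n_mut:] = True
    for g, direction in truth.de_genes.items():
        shift = group_shift if direction == "Up" else -group_shift
        X[gene_pos[g], unmut] += shift

    sample_ids = [f"{cohort_id}_S{i:04d}" for i in range(1, n + 1)]
    samples = pd.DataFrame(
        {
            "cohort": cohort_id,
            "group": np.where(unmut, "unmutated", "mutated"),
            "os_time": np.nan,
            "os_event": np.nan,
            "ttt_time": np.nan,
            "ttt_event": np.nan,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    expr = pd.DataFrame(X, index=pd.Index(genes, name="gene"), columns=sample_ids)
    return Cohort(expr=expr, samples=samples, platform=platform)


def simulate_survival(
    cohort: Cohort,
    truth: SyntheticTruth,
    baseline_rate: float,
    censor_rate: float,
    seed: int,
    ttt_rate_factor: float = 3.0,
) -> Cohort:
    """Attach OS and TTT outcomes from an exponential proportional-hazards model.

    The linear predictor is sum(coefficient * standardized expression) over
    the planted survival genes; censoring is independent exponential with
    rate ``censor_rate`` (0 means no censoring).  Time to treatment uses a
    ``ttt_rate_factor`` times larger baseline rate (treatment precedes death).
    """
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    if censor_rate < 0:
        raise ValueError("censor_rate must be nonnegative")
    missing = [g for g in truth.survival_genes if g not in cohort.expr.index]
    if missing:
        raise ValueError(f"cohort lacks expression for survival genes: {missing}")

    rng = np.random.default_rng(seed)
    n = cohort.n_samples
    lp = np.zeros(n)
    for g, beta in truth.survival_genes.items():
        row = cohort.expr.loc[g].to_numpy()
        sd = row.std()
        if sd > 0:
            lp += beta * (row - row.mean()) / sd

    samples = cohort.samples.copy()
    for tag, rate in (("os", baseline_rate), ("ttt", baseline_rate * ttt_rate_factor)):
        event_t = rng.exponential(1.0 / (rate * np.exp(lp)))
        if censor_rate > 0:
            censor_t = rng.exponential(1.0 / censor_rate, size=n)
        else:
            censor_t = np.full(n, np.inf)
        samples[f"{tag}_time"] = np.minimum(event_t, censor_t)
        samples[f"{tag}_event"] = (event_t <= censor_t).astype(float)
    return Cohort(expr=cohort.expr.copy(), samples=samples, platform=cohort.platform)


def simulate_normal_cohort(
    truth: SyntheticTruth,
    n: int,
    noise_sd: float,
    seed: int,
    cohort_id: str = "NORMAL",
    platform: str = "synthetic-normal",
    sd_jitter: float = 0.0,
) -> Cohort:
    """Healthy-tissue control: same gene universe, disease couplings severed.

    Every gene is independent Gaussian noise around its baseline, the group
    label is "normal" and no outcomes are attached, emulating a control
    cohort used only to check regulator specificity.
    """
    if n < 4:
        raise ValueError("need at least 4 samples")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    genes = truth.gene_ids
    baseline, sds = _gene_properties(truth, noise_sd, sd_jitter)
    X = rng.normal(0.0, 1.0, size=(len(genes), n)) * sds[:, None] + baseline[:, None]
    sample_ids = [f"{cohort_id}_S{i:04d}" for i in range(1, n + 1)]
    samples = pd.DataFrame(
        {
            "cohort": cohort_id,
            "group": "normal",
            "os_time": np.nan,
            "os_event": np.nan,
            "ttt_time": np.nan,
            "ttt_event": np.nan,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    expr = pd.DataFrame(X, index=pd.Index(genes, name="gene"), columns=sample_ids)
    return Cohort(expr=expr, samples=samples, platform=platform)


# ---------------------------------------------------------------------------
# TSV / JSON round-trip


def write_cohort(cohort: Cohort, expr_path: str | Path, annot_path: str | Path) -> None:
    cohort.expr.to_csv(expr_path, sep="\t")
    cohort.samples.to_csv(annot_path, sep="\t")


def read_cohort(
    expr_path: str | Path, annot_path: str | Path | None = None, platform: str = ""
) -> Cohort:
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    expr.index.name = "gene"
    if annot_path is not None:
        samples = pd.read_csv(annot_path, sep="\t", index_col=0)
        samples.index.name = "sample_id"
    else:
        samples = pd.DataFrame(
            {c: np.nan for c in ANNOT_COLUMNS},
            index=pd.Index(expr.columns, name="sample_id"),
        )
        samples["cohort"] = "unknown"
    return Cohort(expr=expr, samples=samples, platform=platform)


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    doc = {
        "gene_ids": truth.gene_ids,
        "tf_ids": truth.tf_ids,
        "master_tfs": truth.master_tfs,
        "regulon_map": {tf: sorted(t) for tf, t in truth.regulon_map.items()},
        "regulon_strength": truth.regulon_strength,
        "de_genes": truth.de_genes,
        "survival_genes": truth.survival_genes,
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_truth(path: str | Path) -> SyntheticTruth:
    doc = json.loads(Path(path).read_text())
    return SyntheticTruth(
        gene_ids=doc["gene_ids"],
        tf_ids=doc["tf_ids"],
        master_tfs=doc["master_tfs"],
        regulon_map={tf: set(t) for tf, t in doc["regulon_map"].items()},
        regulon_strength=doc["regulon_strength"],
        de_genes=doc["de_genes"],
        survival_genes=doc["survival_genes"],
        seed=doc["seed"],
    )
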