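"""End-to-end orchestration of the regulator-inference workflow.

Two data paths feed the analysis, as in the original workflow: the
differential-expression path (per-cohort mean/variance filtering, probe
summarization when a probe map is given, >=80%-presence merging, per-study
tests, p-value combination, signature) and the network path (per-cohort
shorth SD filtering, MI network reconstruction with bootstrap consensus).
Master regulator analysis joins the two, followed by specificity controls,
cross-network consensus and survival evaluation.

All randomness flows from one master seed through named substreams, so a
run is a pure function of its configuration.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cllnet import aracne, metade, mra, preprocess, survival as surv
from cllnet.synthetic import (
    Cohort,
    generate_truth,
    read_cohort,
    simulate_cohort,
    simulate_normal_cohort,
    simulate_survival,
    write_cohort,
    write_truth,
)

log = logging.getLogger("cllnet")

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "simulate_cohorts"]


@dataclass
class PipelineConfig:
    """Validated parameters of a full run.  Defaults follow the reference
    workflow: MI threshold p 0.05, DPI tolerance 0, 100 bootstraps, 80%
    merge presence, 30%/30% expression filters."""

    # data
    cohort_expr: list[str] = field(default_factory=list)
    cohort_annot: list[str] = field(default_factory=list)
    tf_list: str | None = None
    normal_expr: str | None = None
    # synthetic generation (used when cohort_expr is empty)
    synthetic: bool = True
    n_genes: int = 600
    n_tfs: int = 10
    targets_per_tf: int = 15
    overlap_fraction: float = 0.2
    n_de: int = 60
    n_survival: int = 20
    n_cohorts: int = 5
    n_mut: int = 60
    n_unmut: int = 60
    group_shift: float = 1.5
    noise_sd: float = 1.0
    sd_jitter: float = 0.3
    n_normal: int = 60
    baseline_rate: float = 0.1
    censor_rate: float = 0.05
    # preprocessing
    mean_drop: float = 0.30
    var_drop: float = 0.30
    min_presence: float = 0.80
    # meta-analysis
    combine_method: str = "fisher"
    rop_r: int = 2
    q_threshold: float = 0.05
    # network
    threshold_pvalue: float = 0.05
    dpi_tolerance: float = 0.0
    n_bootstrap: int = 25
    n_null_pairs: int = 500
    consensus_alpha: float = 0.05
    # mra
    mra_alpha: float = 0.05
    min_networks: int = 4
    # survival
    survival_alpha: float = 0.05
    n_perm: int = 500
    train_fraction: float = 0.5
    # bookkeeping
    seed: int = 0
    outdir: str = "cllnet_run"

    def aracne_params(self, seed: int) -> aracne.AracneParams:
        return aracne.AracneParams(
            threshold_pvalue=self.threshold_pvalue,
            dpi_tolerance=self.dpi_tolerance,
            n_bootstrap=self.n_bootstrap,
            n_null_pairs=self.n_null_pairs,
            consensus_alpha=self.consensus_alpha,
            seed=seed,
        )


_RANGES = {
    "overlap_fraction": (0.0, 1.0),
    "mean_drop": (0.0, 1.0),
    "var_drop": (0.0, 1.0),
    "min_presence": (0.0, 1.0),
    "q_threshold": (0.0, 1.0),
    "threshold_pvalue": (0.0, 1.0),
    "dpi_tolerance": (0.0, 1.0),
    "consensus_alpha": (0.0, 1.0),
    "mra_alpha": (0.0, 1.0),
    "survival_alpha": (0.0, 1.0),
    "train_fraction": (0.0, 1.0),
}


def validate_config(path: str | Path | None = None,
                    overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML config, inject defaults and check ranges.

    Unknown keys are rejected; an empty (or absent) file yields all
    defaults.
    """
    doc: dict = {}
    if path is not None:
        try:
            loaded = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ValueError(f"malformed config {path}: {exc}") from exc
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"config {path} must be a mapping")
            doc = loaded
    if overrides:
        doc.update(overrides)

    valid = set(PipelineConfig.__dataclass_fields__)
    unknown = set(doc) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**doc)

    for key, (lo, hi) in _RANGES.items():
        v = getattr(cfg, key)
        if not (lo <= v < hi or (key == "min_presence" and v == hi)):
            raise ValueError(f"{key}={v} outside [{lo}, {hi})")
    if cfg.combine_method not in metade.COMBINE_METHODS:
        raise ValueError(f"unknown combine_method {cfg.combine_method!r}")
    if cfg.synthetic and cfg.min_networks > cfg.n_cohorts:
        raise ValueError("min_networks exceeds the number of cohorts")
    if not cfg.synthetic:
        if len(cfg.cohort_expr) < 2:
            raise ValueError("need at least 2 cohort expression files")
        for p in [*cfg.cohort_expr, *cfg.cohort_annot,
                  *( [cfg.tf_list] if cfg.tf_list else []),
                  *( [cfg.normal_expr] if cfg.normal_expr else [])]:
            if p and not Path(p).exists():
                raise ValueError(f"missing input file: {p}")
        if cfg.min_networks > len(cfg.cohort_expr):
            raise ValueError("min_networks exceeds the number of cohorts")
    return cfg


def _substreams(master_seed: int, names: list[str]) -> dict[str, int]:
    """Named 31-bit seeds derived deterministically from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    states = ss.generate_state(len(names))
    return {name: int(s) % (2**31) for name, s in zip(names, states)}


def simulate_cohorts(cfg: PipelineConfig, seeds: dict[str, int]):
    """Generate the demo data: truth, disease cohorts (the last two with
    survival outcomes), and a severed-coupling normal control."""
    truth = generate_truth(
        n_genes=cfg.n_genes,
        n_tfs=cfg.n_tfs,
        targets_per_tf=cfg.targets_per_tf,
        overlap_fraction=cfg.overlap_fraction,
        n_de=cfg.n_de,
        n_survival=cfg.n_survival,
        seed=seeds["truth"],
    )
    cohorts: dict[str, Cohort] = {}
    for i in range(cfg.n_cohorts):
        cid = f"SYN{i + 1}"
        c = simulate_cohort(
            truth, cfg.n_mut, cfg.n_unmut, cfg.group_shift, cfg.noise_sd,
            seed=seeds[f"cohort{i}"], cohort_id=cid, sd_jitter=cfg.sd_jitter,
        )
        if i >= cfg.n_cohorts - 2:  # the two survival-annotated cohorts
            c = simulate_survival(
                c, truth, cfg.baseline_rate, cfg.censor_rate,
                seed=seeds[f"survival{i}"],
            )
        cohorts[cid] = c
    normal = simulate_normal_cohort(
        truth, cfg.n_normal, cfg.noise_sd, seed=seeds["normal"],
        sd_jitter=cfg.sd_jitter,
    )
    return truth, cohorts, normal


def _load_cohorts(cfg: PipelineConfig):
    cohorts: dict[str, Cohort] = {}
    for i, path in enumerate(cfg.cohort_expr):
        annot = cfg.cohort_annot[i] if i < len(cfg.cohort_annot) else None
        c = read_cohort(path, annot)
        cid = str(c.samples["cohort"].iloc[0])
        if cid in ("unknown", "nan") or cid in cohorts:
            cid = Path(path).stem
        cohorts[cid] = c
    normal = read_cohort(cfg.normal_expr) if cfg.normal_expr else None
    tf_ids = [
        line.strip()
        for line in Path(cfg.tf_list).read_text().splitlines()
        if line.strip()
    ]
    return cohorts, normal, tf_ids


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest.

    The manifest records parameters, derived seeds, per-stage record counts
    and the paths of every artifact written under ``cfg.outdir``.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "stages": {}, "artifacts": {}}
    seeds = _substreams(
        cfg.seed,
        ["truth", "normal", "aracne", "mra", "survival_eval", "split"]
        + [f"cohort{i}" for i in range(max(cfg.n_cohorts, 1))]
        + [f"survival{i}" for i in range(max(cfg.n_cohorts, 1))],
    )
    manifest["seeds"] = seeds

    def stage(name):
        log.info("stage %s", name)
        return time.perf_counter()

    def done(name, t0, **counts):
        manifest["stages"][name] = {
            "seconds": round(time.perf_counter() - t0, 3), **counts
        }

    # -- ingest -------------------------------------------------------------
    t0 = stage("ingest")
    truth = None
    if cfg.synthetic:
        truth, cohorts, normal = simulate_cohorts(cfg, seeds)
        tf_ids = list(truth.tf_ids)
        write_truth(truth, out / "truth.json")
        manifest["artifacts"]["truth"] = str(out / "truth.json")
        for cid, c in cohorts.items():
            write_cohort(c, out / f"{cid}_expr.tsv", out / f"{cid}_annot.tsv")
        write_cohort(normal, out / "NORMAL_expr.tsv", out / "NORMAL_annot.tsv")
    else:
        cohorts, normal, tf_ids = _load_cohorts(cfg)
    done("ingest", t0, n_cohorts=len(cohorts),
         n_genes={cid: c.expr.shape[0] for cid, c in cohorts.items()},
         n_samples={cid: c.n_samples for cid, c in cohorts.items()})

    # -- preprocess: DE path ------------------------------------------------
    t0 = stage("preprocess")
    filtered = {
        cid: preprocess.filter_expression(c.expr, cfg.mean_drop, cfg.var_drop)
        for cid, c in cohorts.items()
    }
    merged = preprocess.merge_cohorts(filtered, cfg.min_presence)
    merged.expr.to_csv(out / "merged_expr.tsv", sep="\t")
    # network path: shorth SD filter on the unfiltered cohort matrices
    network_input = {
        cid: preprocess.shorth_sd_filter(c.expr) for cid, c in cohorts.items()
    }
    done("preprocess", t0,
         merged_genes=merged.expr.shape[0], merged_samples=merged.expr.shape[1],
         network_genes={cid: m.shape[0] for cid, m in network_input.items()})

    # -- meta-analysis DE ---------------------------------------------------
    t0 = stage("metade")
    p_cols, d_cols = {}, {}
    for cid, c in cohorts.items():
        sub = Cohort(
            expr=merged.cohort_matrix(cid),
            samples=c.samples.loc[merged.cohort_of.index[
                merged.cohort_of == cid]],
            platform=c.platform,
        )
        de = metade.per_study_de(sub, study_id=cid)
        p_cols[cid] = de.table["p"]
        d_cols[cid] = de.table["direction"]
    p_matrix = pd.DataFrame(p_cols)
    d_matrix = pd.DataFrame(d_cols)
    meta = metade.combine_pvalues(
        p_matrix, method=cfg.combine_method, rop_r=cfg.rop_r,
        direction_matrix=d_matrix,
    )
    meta.to_csv(out / "meta_de.tsv", sep="\t")
    signature = metade.build_signature(meta, cfg.q_threshold)
    if len(signature) == 0:
        raise RuntimeError("stage metade: empty signature, cannot run MRA")
    signature.table.to_csv(out / "signature.tsv", sep="\t", index=False)
    manifest["artifacts"]["signature"] = str(out / "signature.tsv")
    done("metade", t0, genes_tested=len(meta), signature_size=len(signature))

    # -- networks -----------------------------------------------------------
    t0 = stage("network")
    net_seeds = _substreams(seeds["aracne"], list(cohorts) + ["normal"])
    networks: dict[str, aracne.MINetwork] = {}
    for cid in cohorts:
        params = cfg.aracne_params(net_seeds[cid])
        net = aracne.bootstrap_consensus(
            network_input[cid], tf_ids, params, network_id=cid
        )
        net.write(out / f"network_{cid}.tsv")
        networks[cid] = net
    normal_net = None
    if normal is not None:
        params = cfg.aracne_params(net_seeds["normal"])
        normal_net = aracne.bootstrap_consensus(
            preprocess.shorth_sd_filter(normal.expr), tf_ids, params,
            network_id="NORMAL",
        )
        normal_net.write(out / "network_NORMAL.tsv")
    done("network", t0,
         edges={cid: n.n_edges for cid, n in networks.items()},
         normal_edges=normal_net.n_edges if normal_net is not None else None)

    # -- MRA ----------------------------------------------------------------
    t0 = stage("mra")
    results = []
    for cid, net in networks.items():
        if net.n_edges == 0:
            log.warning("network %s is empty; skipped in MRA", cid)
            continue
        res = mra.run_mra(net, signature, alpha=cfg.mra_alpha, meta=meta)
        res.table.to_csv(out / f"mra_{cid}.tsv", sep="\t", index=False)
        results.append(res)
    if not results:
        raise RuntimeError("stage mra: no non-empty network")

    # specificity: healthy-network check (no proliferation set in the demo)
    surviving = {}
    for res in results:
        kept = mra.specificity_controls(
            res, normal_net, signature, proliferation_signature=None,
            alpha=cfg.mra_alpha,
            net_disease=networks[res.network_id],
        )
        surviving[res.network_id] = kept
    consensus = mra.cross_network_consensus(
        results, min_networks=min(cfg.min_networks, len(results))
    )
    # drop TFs removed by the specificity controls in any network
    removed = {
        tf
        for res in results
        for tf in set(res.candidates()) - set(surviving[res.network_id])
    }
    consensus = consensus[~consensus["tf"].isin(removed)].reset_index(drop=True)
    consensus.to_csv(out / "consensus_tfs.tsv", sep="\t", index=False)
    manifest["artifacts"]["consensus"] = str(out / "consensus_tfs.tsv")
    done("mra", t0, candidates={r.network_id: len(r.candidates())
                                for r in results},
         consensus_tfs=list(consensus["tf"]))

    # -- survival -----------------------------------------------------------
    t0 = stage("survival")
    surv_counts = {}
    surv_cohorts = {
        cid: c for cid, c in cohorts.items()
        if c.samples["os_event"].notna().any()
    }
    if len(consensus) and surv_cohorts:
        pooled: set[str] = set()
        for targets in consensus["pooled_targets"]:
            pooled |= set(targets.split(";"))
        gt_rows = []
        for cid, c in surv_cohorts.items():
            genes = sorted(pooled & set(c.expr.index))
            for endpoint in ("OS", "TTT"):
                outcome = surv.SurvivalOutcome.from_samples(c.samples, endpoint)
                for tf in consensus["tf"]:
                    tf_targets = sorted(
                        set(consensus.loc[consensus["tf"] == tf,
                                          "pooled_targets"].iloc[0].split(";"))
                        & set(c.expr.index)
                    )
                    if len(tf_targets) < 2:
                        continue
                    res = surv.global_test(
                        c.expr.loc[tf_targets], outcome, n_perm=cfg.n_perm,
                        seed=seeds["survival_eval"], set_id=f"{tf}:{cid}",
                    )
                    gt_rows.append(
                        {"cohort": cid, "endpoint": endpoint, "set": tf,
                         "Q": res.statistic, "p": res.p}
                    )
            # profile reduction on the pooled target union, OS endpoint
            outcome = surv.SurvivalOutcome.from_samples(c.samples, "OS")
            cox = surv.cox_per_gene(c.expr.loc[genes], outcome)
            cox.to_csv(out / f"cox_{cid}.tsv", sep="\t")
            reduced = surv.reduce_profile(
                c.expr.loc[genes], outcome, alpha=cfg.survival_alpha,
                n_perm=cfg.n_perm * 4, seed=seeds["survival_eval"],
            )
            reduced.table.to_csv(out / f"reduced_profile_{cid}.tsv",
                                 sep="\t", index=False)
            surv_counts[cid] = {"pooled_targets": len(genes),
                                "reduced_profile": len(reduced)}
        pd.DataFrame(gt_rows).to_csv(out / "global_tests.tsv", sep="\t",
                                     index=False)

        # SVM comparison on the merged DE data: regulators+targets vs top-50
        merged_groups = pd.Series(
            {s: cohorts[merged.cohort_of[s]].samples.loc[s, "group"]
             for s in merged.expr.columns}
        )
        usable = merged_groups.isin(["mutated", "unmutated"])
        X = merged.expr.loc[:, usable.index[usable]].dropna(axis=0)
        y = merged_groups[usable]
        feature_sets = {
            "regulators_and_targets": sorted(
                (pooled | set(consensus["tf"])) & set(X.index)
            ),
            "top50_signature": [g for g in signature.genes
                                if g in set(X.index)][:50],
        }
        half = int(cfg.train_fraction * len(y))
        errors = surv.classification_error(
            X, y, feature_sets, train_n=half, test_n=len(y) - half,
            seed=seeds["split"],
        )
        Path(out / "svm_errors.json").write_text(json.dumps(errors, indent=1))
        surv_counts["svm_errors"] = errors
    done("survival", t0, **surv_counts)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
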