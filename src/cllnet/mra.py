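"""Master regulator analysis (MRA).

Each transcription factor's regulon — its neighbors in the reconstructed
network — is tested for over-representation of the differential-expression
signature with a one-sided Fisher's exact test over a gene universe
(default: the nodes of the network under test).  Specificity controls
remove TFs that are also enriched in a healthy-tissue control network or
for a proliferation signature, and a cross-network consensus keeps TFs
recurring as significant regulators in several independent cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from cllnet.aracne import MINetwork
from cllnet.metade import Signature

__all__ = [
    "Regulon",
    "MRAResult",
    "MRAResults",
    "extract_regulons",
    "fet_enrichment",
    "run_mra",
    "specificity_controls",
    "cross_network_consensus",
]


@dataclass(frozen=True)
class Regulon:
    """One TF's inferred target set (network neighbors, TF excluded)."""

    tf: str
    targets: frozenset[str]

    def __post_init__(self) -> None:
        if self.tf in self.targets:
            raise ValueError("a TF cannot be its own target")

    def __len__(self) -> int:
        return len(self.targets)


@dataclass
class MRAResult:
    """Enrichment of one regulon in the signature."""

    tf: str
    fet_p: float
    intersection: frozenset[str]
    mode: str  # "+" (TF up in poor prognosis), "-" or "" when unknown
    regulon_size: int
    signature_in_universe: int
    universe_size: int
    network_id: str = ""


@dataclass
class MRAResults:
    """Ranked MRA over one network: result table plus the regulons tested."""

    table: pd.DataFrame
    regulons: dict[str, frozenset[str]]
    network_id: str = ""

    def candidates(self) -> list[str]:
        return list(self.table.loc[self.table["candidate"], "tf"])


def extract_regulons(net: MINetwork, tf_ids: list[str] | None = None) -> list[Regulon]:
    """Regulons from undirected edges; a TF-TF edge puts each TF in the
    other's regulon.  TFs without retained edges yield no regulon."""
    if net.n_edges == 0:
        raise ValueError("empty network")
    tfs = list(tf_ids) if tf_ids is not None else list(net.tf_ids)
    adj = net.adjacency()
    out = []
    for tf in tfs:
        neigh = adj.get(tf, set())
        if neigh:
            out.append(Regulon(tf=tf, targets=frozenset(neigh)))
    return out


def _tf_mode(tf: str, signature: Signature | None,
             meta: pd.DataFrame | None) -> str:
    """Mode from the TF's own DE direction: "+" = up in unmutated (poor
    prognosis).  Signature direction wins; else the meta-analysis consensus
    sign; else unknown."""
    if signature is not None:
        d = signature.direction_of(tf)
        if d is not None:
            return "+" if d == "Up" else "-"
    if meta is not None and tf in meta.index:
        sgn = int(meta.loc[tf, "direction"])
        if sgn:
            return "+" if sgn > 0 else "-"
    return ""


def fet_enrichment(
    regulon: Regulon,
    signature: Signature,
    universe: set[str],
    meta: pd.DataFrame | None = None,
    network_id: str = "",
) -> MRAResult:
    """One-sided Fisher's exact test of regulon-signature over-representation.

    The 2x2 table classifies the universe genes by regulon membership and
    signature membership; the p-value is the hypergeometric upper tail
    P(X >= |intersection|).
    """
    if not universe:
        raise ValueError("empty universe")
    if not regulon.targets <= universe:
        raise ValueError("regulon targets outside the universe")
    sig_in = set(signature.genes) & universe
    if not sig_in:
        raise ValueError("signature and universe share no gene")

    inter = regulon.targets & sig_in
    M, n_reg, n_sig, k = len(universe), len(regulon.targets), len(sig_in), len(inter)
    p = float(stats.hypergeom.sf(k - 1, M, n_sig, n_reg)) if k > 0 else 1.0
    return MRAResult(
        tf=regulon.tf,
        fet_p=min(1.0, p),
        intersection=frozenset(inter),
        mode=_tf_mode(regulon.tf, signature, meta),
        regulon_size=n_reg,
        signature_in_universe=n_sig,
        universe_size=M,
        network_id=network_id,
    )


def run_mra(
    net: MINetwork,
    signature: Signature,
    alpha: float = 0.05,
    universe: set[str] | None = None,
    meta: pd.DataFrame | None = None,
    tf_ids: list[str] | None = None,
) -> MRAResults:
    """Test every regulon of the network, ranked by FET p-value.

    The default universe is the network's node set (the genes that survived
    that cohort's filtering); pass ``universe`` for the all-merged-genes
    sensitivity analysis.  Candidates are flagged by Bonferroni-corrected
    p <= alpha over the number of regulons tested; raw p-values are kept
    alongside.
    """
    uni = set(net.nodes) if universe is None else set(universe)
    regulons = extract_regulons(net, tf_ids)
    results = [
        fet_enrichment(
            Regulon(r.tf, frozenset(r.targets & uni)), signature, uni,
            meta=meta, network_id=net.network_id,
        )
        for r in regulons
        if r.targets & uni
    ]
    m = len(results)
    rows = []
    for r in results:
        p_bonf = min(1.0, r.fet_p * m)
        rows.append(
            {
                "tf": r.tf,
                "fet_p": r.fet_p,
                "fet_p_bonferroni": p_bonf,
                "intersection_size": len(r.intersection),
                "intersection_genes": ";".join(sorted(r.intersection)),
                "regulon_size": r.regulon_size,
                "mode": r.mode,
                "candidate": p_bonf <= alpha,
                "network": r.network_id,
            }
        )
    table = (
        pd.DataFrame(rows)
        .sort_values(["fet_p", "tf"], kind="stable", ignore_index=True)
    )
    return MRAResults(
        table=table,
        regulons={r.tf: frozenset(r.targets) for r in regulons},
        network_id=net.network_id,
    )


def specificity_controls(
    mra_disease: MRAResults,
    net_control: MINetwork | None,
    signature: Signature,
    proliferation_signature: set[str] | None,
    alpha: float = 0.05,
    net_disease: MINetwork | None = None,
) -> list[str]:
    """Filter candidates by the two specificity checks.

    Removes a candidate TF that (a) is enriched for the disease signature in
    the healthy-tissue control network, or (b) is enriched for the
    proliferation signature within the disease network.  Either control may
    be absent, in which case that check is skipped with a warning.
    """
    candidates = mra_disease.candidates()
    dropped: set[str] = set()

    if net_control is not None and net_control.n_edges > 0:
        uni = set(net_control.nodes)
        if set(signature.genes) & uni:
            control = run_mra(net_control, signature, alpha=alpha)
            enriched = set(control.candidates())
            dropped |= {tf for tf in candidates if tf in enriched}
    elif net_control is None:
        warnings.warn("no control network supplied; healthy-network check skipped")

    if proliferation_signature:
        if net_disease is None:
            warnings.warn("disease network not supplied; proliferation check skipped")
        else:
            prolif = Signature(
                table=pd.DataFrame(
                    {
                        "gene": sorted(proliferation_signature),
                        "direction": "Up",
                        "q": 0.0,
                    }
                )
            )
            uni = set(net_disease.nodes)
            if set(prolif.genes) & uni:
                pro = run_mra(net_disease, prolif, alpha=alpha)
                enriched = set(pro.candidates())
                dropped |= {tf for tf in candidates if tf in enriched}
    elif proliferation_signature is None:
        warnings.warn("no proliferation signature supplied; check skipped")

    return [tf for tf in candidates if tf not in dropped]


def cross_network_consensus(
    results_per_network: list[MRAResults],
    min_networks: int = 4,
) -> pd.DataFrame:
    """TFs significant in at least ``min_networks`` networks.

    Returns one row per consensus TF with the number of supporting networks,
    per-network FET p-values and the pooled union of its regulon targets
    over the supporting networks.
    """
    if min_networks > len(results_per_network):
        raise ValueError("min_networks exceeds the number of networks supplied")
    hits: dict[str, list[MRAResults]] = {}
    for res in results_per_network:
        for tf in res.candidates():
            hits.setdefault(tf, []).append(res)

    rows = []
    for tf, supporting in sorted(hits.items()):
        if len(supporting) < min_networks:
            continue
        pooled: set[str] = set()
        pvals = {}
        for res in supporting:
            pooled |= set(res.regulons[tf])
            row = res.table.loc[res.table["tf"] == tf].iloc[0]
            pvals[res.network_id or "?"] = float(row["fet_p"])
        rows.append(
            {
                "tf": tf,
                "n_networks": len(supporting),
                "pooled_targets": ";".join(sorted(pooled)),
                "n_pooled_targets": len(pooled),
                "fet_p_per_network": ";".join(
                    f"{k}={v:.3g}" for k, v in sorted(pvals.items())
                ),
                "best_fet_p": min(pvals.values()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["tf", "n_networks", "pooled_targets", "n_pooled_targets",
                 "fet_p_per_network", "best_fet_p"],
    ).sort_values(["best_fet_p", "tf"], kind="stable", ignore_index=True)
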