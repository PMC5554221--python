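"""TF-TF cooperativity network ("heterarchy") construction.

Two TFs are linked when they appear on the same side (co-activation or
co-inhibition) of sufficiently many selected gene models and the shared
count is hypergeometrically significant; edges backed by PPI evidence are
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd
from scipy.stats import hypergeom

from .data import EvidenceSet
from .licorn import GRN

__all__ = ["CoopEdge", "CoopNetwork", "build_coop_network", "attach_influence"]


@dataclass
class CoopEdge:
    pair: tuple[str, str]
    shared_gene_count: int
    p_value: float
    evidence_flag: bool


@dataclass
class CoopNetwork:
    nodes: list[str]
    node_attrs: dict[str, dict] = field(default_factory=dict)
    edges: list[CoopEdge] = field(default_factory=list)

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {e.pair for e in self.edges}


def build_coop_network(
    grn: GRN,
    evidence: EvidenceSet | None = None,
    min_common_genes: int = 5,
    alpha: float = 0.01,
) -> CoopNetwork:
    """Build the cooperativity network from a GRN.

    For each TF pair, ``shared_gene_count`` counts genes whose selected
    model carries both TFs on the same side. An edge is kept when the count
    reaches ``min_common_genes`` and the one-sided hypergeometric tail
    (universe: genes with models; successes: genes whose model contains the
    first TF; draws: genes containing the second) is at most ``alpha``.
    """
    if not grn.models:
        raise ValueError("cannot build a cooperativity network from an empty GRN")
    n_genes = len(grn.models)
    gene_count: dict[str, int] = {}       # genes whose model contains the TF
    shared: dict[tuple[str, str], int] = {}
    for gene in sorted(grn.models):
        m = grn.models[gene]
        for tf in set(m.activators) | set(m.inhibitors):
            gene_count[tf] = gene_count.get(tf, 0) + 1
        for side in (m.activators, m.inhibitors):
            for pair in combinations(sorted(side), 2):
                shared[pair] = shared.get(pair, 0) + 1

    edges = []
    for pair in sorted(shared):
        cnt = shared[pair]
        if cnt < min_common_genes:
            continue
        k1, k2 = gene_count[pair[0]], gene_count[pair[1]]
        p = float(hypergeom.sf(cnt - 1, n_genes, k1, k2))
        if p > alpha:
            continue
        flag = evidence is not None and pair in evidence
        edges.append(CoopEdge(pair=pair, shared_gene_count=cnt, p_value=p, evidence_flag=flag))

    nodes = sorted(grn.regulons)
    attrs = {
        tf: {
            "n_activated": len(grn.regulons[tf][0]),
            "n_repressed": len(grn.regulons[tf][1]),
        }
        for tf in nodes
    }
    return CoopNetwork(nodes=nodes, node_attrs=attrs, edges=edges)


def attach_influence(
    coop: CoopNetwork, influence: pd.DataFrame, labels: list[int] | None = None
) -> None:
    """Annotate nodes with mean influence, optionally per phase.

    ``influence`` is a TF x sample frame (NaN = undefined); ``labels`` gives
    a phase id per sample column. Adds ``influence_mean`` and, with labels,
    ``influence_phase<p>`` attributes in place.
    """
    for tf in coop.nodes:
        if tf not in influence.index:
            continue
        row = influence.loc[tf]
        coop.node_attrs[tf]["influence_mean"] = float(row.mean())
        if labels is not None:
            for p in sorted(set(labels)):
                cols = [c for c, l in zip(influence.columns, labels) if l == p]
                coop.node_attrs[tf][f"influence_phase{p}"] = float(row[cols].mean())
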