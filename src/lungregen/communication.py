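"""Receptor-ligand cell-cell communication networks.

An edge is drawn between two cell types when they share a catalog
receptor-ligand pair between their marker genes: the ligand a marker of
the source type, the receptor a marker of the target.  Edge weight is
the number of supporting pairs.  The directed ligand->receptor view is
kept internally; the undirected summary (union of both directions) is
the default export.  Injury-time dynamics annotate each edge with the
fraction of supporting pairs whose ligand (in the source) or receptor
(in the target) is injury-regulated in the temporal differential
detection results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core import ValidationError

__all__ = [
    "marker_sets",
    "build_network",
    "focal_connectome",
    "dynamic_edges",
    "connectome_fold_changes",
    "CommNetwork",
]


def marker_sets(
    markers: pd.DataFrame, max_padj: float = 0.1, positive_only: bool = True
) -> dict:
    """Positive marker gene sets per cell type from a MarkerTable."""
    sel = markers
    if positive_only:
        sel = sel[sel["avg_logFC"] > 0]
    if max_padj is not None:
        sel = sel[sel["p_adj"] < max_padj]
    return {
        str(ct): set(map(str, grp["gene"]))
        for ct, grp in sel.groupby("cell_type")
    }


@dataclass
class CommNetwork:
    """Weighted directed graph over cell types with per-edge pair lists."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def weight(self, source: str, target: str) -> int:
        if self.graph.has_edge(source, target):
            return self.graph[source][target]["weight"]
        return 0

    def pairs(self, source: str, target: str) -> list:
        if self.graph.has_edge(source, target):
            return list(self.graph[source][target]["pairs"])
        return []

    def edges(self) -> pd.DataFrame:
        rows = [
            {
                "source": u,
                "target": v,
                "weight": d["weight"],
                "pairs": ";".join(f"{l}-{r}" for l, r in d["pairs"]),
                **(
                    {"altered_fraction": d["altered_fraction"]}
                    if "altered_fraction" in d
                    else {}
                ),
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows)

    def undirected_summary(self) -> pd.DataFrame:
        """Union of both directions per unordered type pair (the default
        network view): weight = total supporting pairs either way."""
        agg = {}
        for u, v, d in self.graph.edges(data=True):
            key = tuple(sorted((u, v)))
            agg.setdefault(key, 0)
            agg[key] += d["weight"]
        return pd.DataFrame(
            [{"type_a": a, "type_b": b, "weight": w} for (a, b), w in sorted(agg.items())]
        )

    def to_graphml(self, path):
        g = nx.DiGraph()
        for u, v, d in self.graph.edges(data=True):
            attrs = {"weight": d["weight"],
                     "pairs": ";".join(f"{l}-{r}" for l, r in d["pairs"])}
            if "altered_fraction" in d:
                attrs["altered_fraction"] = float(d["altered_fraction"])
            g.add_edge(u, v, **attrs)
        nx.write_graphml(g, path)


def build_network(markers, catalog: pd.DataFrame, max_padj: float = 0.1) -> CommNetwork:
    """Build the ligand->receptor communication network.

    ``markers`` is a MarkerTable DataFrame or a precomputed dict of marker
    sets per cell type.  For every ordered type pair (A, B) the supporting
    pairs are the catalog rows whose ligand is a marker of A and receptor a
    marker of B; an edge exists iff the set is nonempty.  Self-edges are
    permitted.  An empty catalog yields an empty network.
    """
    sets = markers if isinstance(markers, dict) else marker_sets(markers, max_padj)
    sets = {str(ct): {str(g) for g in gs} for ct, gs in sets.items()}
    net = CommNetwork()
    net.graph.add_nodes_from(sets)
    cat = catalog[["ligand", "receptor"]].astype(str).drop_duplicates()
    for a, a_genes in sets.items():
        lig_hits = cat[cat["ligand"].isin(a_genes)]
        for b, b_genes in sets.items():
            pairs = [
                (l, r)
                for l, r in zip(lig_hits["ligand"], lig_hits["receptor"])
                if r in b_genes
            ]
            if pairs:
                net.graph.add_edge(a, b, weight=len(pairs), pairs=sorted(pairs))
    return net


def focal_connectome(focal_type: str, markers, catalog: pd.DataFrame,
                     max_padj: float = 0.1) -> pd.Series:
    """Pair counts between one focal state's markers and every other type.

    Per partner type: number of catalog pairs with one side a focal marker
    and the other a partner marker, both directions summed.
    """
    sets = markers if isinstance(markers, dict) else marker_sets(markers, max_padj)
    sets = {str(ct): {str(g) for g in gs} for ct, gs in sets.items()}
    if focal_type not in sets:
        raise ValidationError(f"unknown focal type '{focal_type}'")
    net = build_network(sets, catalog)
    weights = {
        ct: net.weight(focal_type, ct) + net.weight(ct, focal_type)
        for ct in sets
        if ct != focal_type
    }
    return pd.Series(weights, name=focal_type).sort_index()


def dynamic_edges(
    network: CommNetwork,
    temporal_results: pd.DataFrame,
    fdr_threshold: float = 0.1,
) -> CommNetwork:
    """Annotate each edge with the fraction of supporting pairs altered
    after injury: ligand injury-regulated in the source type or receptor
    injury-regulated in the target type (temporal FDR below threshold).
    Genes missing from the temporal results count as unaltered."""
    reg = set(
        zip(
            temporal_results.loc[temporal_results["fdr"] < fdr_threshold, "cell_type"]
            .astype(str),
            temporal_results.loc[temporal_results["fdr"] < fdr_threshold, "gene"]
            .astype(str),
        )
    )
    covered = set(
        zip(temporal_results["cell_type"].astype(str), temporal_results["gene"].astype(str))
    )
    out = CommNetwork(graph=network.graph.copy())
    for u, v, d in out.graph.edges(data=True):
        altered = 0
        for lig, rec in d["pairs"]:
            if (u, lig) not in covered and (v, rec) not in covered:
                warnings.warn(
                    f"pair ({lig}, {rec}) on edge {u}->{v} not covered by temporal results"
                )
            if (u, lig) in reg or (v, rec) in reg:
                altered += 1
        d["altered_fraction"] = altered / d["weight"]
    return out


def connectome_fold_changes(
    type_a: str,
    type_b: str,
    role: str,
    fold_changes: pd.DataFrame,
    network: CommNetwork,
) -> list:
    """Genes of one role (receptor or ligand) on the edges between two
    types, each with its average log2 fold change in the expressing type,
    deduplicated and sorted by fold change descending.

    ``fold_changes`` is a genes x cell-types DataFrame of log2 fold
    changes (injury vs control).  Ligands are attributed to the edge
    source, receptors to the target.  Returns a list of (gene, fc).
    """
    if role not in ("receptor", "ligand"):
        raise ValidationError("role must be 'receptor' or 'ligand'")
    hits = {}
    for u, v in ((type_a, type_b), (type_b, type_a)):
        for lig, rec in network.pairs(u, v):
            gene, expressing = (lig, u) if role == "ligand" else (rec, v)
            if gene in hits:
                continue
            try:
                fc = float(fold_changes.loc[gene, expressing])
            except KeyError:
                warnings.warn(f"no fold change for {role} '{gene}' in '{expressing}'")
                continue
            hits[gene] = fc
    return sorted(hits.items(), key=lambda kv: -kv[1])
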