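"""Term enrichment, co-expression edges and multi-layer network assembly.

The network joins four node layers — lncRNAs, protein-coding genes (PCgenes,
re-typed TF when a transcription-factor family table lists them), and
miRNAs — through typed edges: ``cis`` and ``trans`` lncRNA-target edges,
``mimic`` lncRNA-miRNA edges, ``mirna_target`` miRNA-gene edges and
``coexpression`` edges from Pearson correlation of log-transformed FPKM.

Enrichment uses the plain upper-tail hypergeometric test with significance
called on the raw p-value (default cutoff 0.05); Benjamini-Hochberg FDRs
are reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .expression import DEResult, bh_adjust
from .models import ExpressionMatrix, ValidationError
from .targeting import CisPair, MimicHit, TransPair

NODE_TYPES = ("lncRNA", "PCgene", "miRNA", "TF")
EDGE_TYPES = ("cis", "trans", "mimic", "mirna_target", "coexpression")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # selected genes carrying the term
    K: int  # universe genes carrying the term
    n: int  # selected set size
    N: int  # universe size
    pvalue: float
    fdr: float
    significant: bool


@dataclass(frozen=True)
class InteractionEdge:
    source_id: str
    target_id: str
    source_type: str
    target_type: str
    edge_type: str
    weight: float

    def __post_init__(self) -> None:
        if self.source_id == self.target_id:
            raise ValidationError("self-edges are not allowed")
        if self.source_type not in NODE_TYPES or self.target_type not in NODE_TYPES:
            raise ValidationError("unknown node type")
        if self.edge_type not in EDGE_TYPES:
            raise ValidationError(f"unknown edge type {self.edge_type!r}")


def hypergeom_enrich(
    selected: set[str],
    universe: set[str],
    term_map: Mapping[str, set[str]],
    p_max: float = 0.05,
    term_names: Mapping[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of ``selected`` within ``universe``.

    For each term with ``K`` universe genes and ``k`` of them selected,
    ``p = P(X >= k)`` for ``X ~ Hypergeom(N, K, n)``.  Terms absent from the
    universe (K = 0) are skipped.  Results carry BH FDRs but significance
    follows the raw p-value cutoff.  Sorted by (p, term_id).
    """
    offenders = selected - universe
    if offenders:
        raise ValidationError(f"selected genes outside universe: {sorted(offenders)[:5]}")
    N, n = len(universe), len(selected)
    rows = []
    for term in sorted(term_map):
        genes = term_map[term] & universe
        K = len(genes)
        if K == 0:
            continue
        k = len(genes & selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, p))
    if not rows:
        return []
    fdrs = bh_adjust([r[3] for r in rows])
    out = [
        EnrichmentResult(
            term_id=term,
            term_name=(term_names or {}).get(term, term),
            k=k, K=K, n=n, N=N,
            pvalue=p, fdr=float(f), significant=p < p_max,
        )
        for (term, k, K, p), f in zip(rows, fdrs)
    ]
    out.sort(key=lambda r: (r.pvalue, r.term_id))
    return out


def coexpression_edges(
    expr: ExpressionMatrix,
    candidate_pairs: Sequence[tuple[str, str]],
    r_min: float = 0.8,
    node_types: Mapping[str, str] | None = None,
) -> list[InteractionEdge]:
    """Pearson co-expression edges over log2(FPKM + 1) across all samples.

    A pair becomes an edge iff ``|r| >= r_min``; the edge weight is r
    itself.  Pairs with a zero-variance vector are skipped with a warning.
    """
    if expr.fpkm.shape[1] < 3:
        raise ValidationError("co-expression needs >= 3 samples")
    log = np.log2(expr.fpkm + 1.0)
    out = []
    types = node_types or {}
    for a, b in candidate_pairs:
        for x in (a, b):
            if x not in log.index:
                raise ValidationError(f"{x!r} not in expression matrix")
        va = log.loc[a].to_numpy()
        vb = log.loc[b].to_numpy()
        if va.std() == 0 or vb.std() == 0:
            warnings.warn(f"zero-variance expression for pair ({a}, {b}); skipped")
            continue
        r = float(np.corrcoef(va, vb)[0, 1])
        if abs(r) >= r_min:
            out.append(
                InteractionEdge(a, b, types.get(a, "PCgene"),
                                types.get(b, "PCgene"), "coexpression", r)
            )
    return out


def assemble_network(
    cis: Sequence[CisPair] = (),
    trans: Sequence[TransPair] = (),
    mimics: Sequence[MimicHit] = (),
    mirna_targets: Sequence[tuple[str, str]] = (),
    de_results: Sequence[DEResult] = (),
    tf_table: Mapping[str, str] | None = None,
    coexpr: Sequence[InteractionEdge] = (),
    de_only: bool = False,
) -> nx.MultiDiGraph:
    """Assemble the typed lncRNA-PCgene-miRNA-TF interaction graph.

    Gene nodes present in ``tf_table`` are re-typed ``TF`` (family stored as
    a node attribute).  Duplicate (source, target, type) edges collapse to
    one.  With ``de_only``, only lncRNAs flagged DE in ``de_results`` (and
    their partners) contribute lncRNA-anchored edges.

    Node attributes: ``node_type``, optionally ``tf_family`` and ``is_de``.
    Graph attributes carry a degree/component report.
    """
    tf_table = dict(tf_table or {})
    de_lnc = {r.transcript_id for r in de_results if r.is_DE}

    def gene_type(gid: str) -> str:
        return "TF" if gid in tf_table else "PCgene"

    g = nx.MultiDiGraph()

    def add_node(nid: str, ntype: str) -> None:
        if nid in g:
            if g.nodes[nid]["node_type"] != ntype:
                raise ValidationError(
                    f"node {nid!r} used with conflicting types "
                    f"{g.nodes[nid]['node_type']}/{ntype}"
                )
            return
        attrs = {"node_type": ntype}
        if ntype == "TF":
            attrs["tf_family"] = tf_table[nid]
        if ntype == "lncRNA":
            attrs["is_de"] = nid in de_lnc
        g.add_node(nid, **attrs)

    def add_edge(src: str, stype: str, dst: str, dtype: str,
                 etype: str, weight: float) -> None:
        if src == dst:
            raise ValidationError("self-edges are not allowed")
        add_node(src, stype)
        add_node(dst, dtype)
        if not g.has_edge(src, dst, key=etype):
            g.add_edge(src, dst, key=etype, edge_type=etype, weight=weight)

    def lnc_ok(lid: str) -> bool:
        return (not de_only) or lid in de_lnc

    for p in cis:
        if lnc_ok(p.lncrna_id):
            add_edge(p.lncrna_id, "lncRNA", p.gene_id, gene_type(p.gene_id),
                     "cis", float(p.gap_nt))
    for p in trans:
        if lnc_ok(p.lncrna_id):
            add_edge(p.lncrna_id, "lncRNA", p.mrna_id, gene_type(p.mrna_id),
                     "trans", p.ndG)
    for h in mimics:
        if lnc_ok(h.lncrna_id):
            add_edge(h.lncrna_id, "lncRNA", h.mirna_id, "miRNA",
                     "mimic", h.score)
    for mid, gid in mirna_targets:
        add_edge(mid, "miRNA", gid, gene_type(gid), "mirna_target", 1.0)
    for e in coexpr:
        src_t = "TF" if gene_type(e.source_id) == "TF" and e.source_type == "PCgene" else e.source_type
        dst_t = "TF" if gene_type(e.target_id) == "TF" and e.target_type == "PCgene" else e.target_type
        if e.source_type == "lncRNA" and not lnc_ok(e.source_id):
            continue
        add_edge(e.source_id, src_t, e.target_id, dst_t, "coexpression", e.weight)

    comps = list(nx.connected_components(g.to_undirected(as_view=True)))
    g.graph["n_components"] = len(comps)
    g.graph["n_nodes"] = g.number_of_nodes()
    g.graph["n_edges"] = g.number_of_edges()
    g.graph["max_degree"] = max((d for _, d in g.degree()), default=0)
    return g


def degree_report(g: nx.MultiDiGraph) -> pd.DataFrame:
    rows = [
        {"node_id": n, "node_type": g.nodes[n]["node_type"],
         "degree": d}
        for n, d in g.degree()
    ]
    df = pd.DataFrame(rows, columns=["node_id", "node_type", "degree"])
    return df.sort_values(["node_id"]).reset_index(drop=True)


def _sorted_copy(g: nx.MultiDiGraph) -> nx.MultiDiGraph:
    out = nx.MultiDiGraph(**g.graph)
    for n in sorted(g.nodes):
        out.add_node(n, **g.nodes[n])
    for u, v, k in sorted(g.edges(keys=True)):
        out.add_edge(u, v, key=k, **g.edges[u, v, k])
    return out


def export_network(g: nx.MultiDiGraph, fmt: str, path: str) -> None:
    """Write the graph as SIF, GraphML or an edge TSV (deterministic order).

    SIF uses the edge type as the relation token.  GraphML preserves node
    and edge attributes and can be re-imported losslessly.
    """
    gs = _sorted_copy(g)
    if fmt == "sif":
        with open(path, "w") as fh:
            for u, v, k in gs.edges(keys=True):
                fh.write(f"{u}\t{k}\t{v}\n")
    elif fmt == "graphml":
        nx.write_graphml(gs, path, named_key_ids=True)
    elif fmt == "tsv":
        rows = [
            {
                "source_id": u,
                "target_id": v,
                "source_type": gs.nodes[u]["node_type"],
                "target_type": gs.nodes[v]["node_type"],
                "edge_type": k,
                "weight": gs.edges[u, v, k]["weight"],
            }
            for u, v, k in gs.edges(keys=True)
        ]
        pd.DataFrame(
            rows,
            columns=["source_id", "target_id", "source_type", "target_type",
                     "edge_type", "weight"],
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValidationError(f"unknown export format {fmt!r}")
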