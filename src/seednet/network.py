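"""Bipartite miRNA-enrichment-term networks.

Connects differentially expressed miRNAs of one direction to the
significant enrichment terms of one annotation domain.  The integer edge
score is the number of the miRNA's filtered (anti-correlated) target genes
inside the term's gene set and the enrichment foreground — the quantity a
Cytoscape rendering encodes as edge width.  Term nodes carry both
fold_enrichment and -log2 p as attributes so either can drive node color.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .enrichment import TermAnnotation

EXPORT_FORMATS = ("graphml", "sif", "tsv")


def edge_score(
    targets: Iterable[str], term_genes: Iterable[str], foreground: Iterable[str]
) -> int:
    """Number of one miRNA's filtered target genes inside a term (restricted
    to the enrichment foreground)."""
    return len(set(targets) & set(term_genes) & set(foreground))


def build_network(
    direction: str,
    mirna_de: pd.DataFrame,
    filtered_targets: Mapping[str, frozenset[str]],
    enrichment_results: pd.DataFrame,
    annotation: Iterable[TermAnnotation],
    domain: str,
) -> nx.Graph:
    """miRNA-term network for one (direction, domain) pair.

    ``enrichment_results`` must already be gated to significant terms (the
    foreground is reconstructed as the union of the direction's filtered
    targets).  Nodes with no positive-score edge are excluded; a direction
    with no significant miRNAs yields an empty graph.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    term_genes = {t.term_id: t.genes for t in annotation}

    sig = mirna_de[(mirna_de["significant"]) & (mirna_de["direction"] == direction)]
    mirnas = [m for m in sig.index if m in filtered_targets]
    foreground: set[str] = set()
    for m in mirnas:
        foreground |= filtered_targets[m]

    g = nx.Graph(direction=direction, domain=domain)
    dom_terms = enrichment_results[enrichment_results["domain"] == domain]
    for m in mirnas:
        for row in dom_terms.itertuples():
            if row.term_id not in term_genes:
                raise ValueError(f"enriched term {row.term_id} missing from annotation")
            s = edge_score(filtered_targets[m], term_genes[row.term_id], foreground)
            if s < 1:
                continue
            if m not in g:
                g.add_node(
                    m,
                    kind="mirna",
                    bipartite=0,
                    direction=direction,
                    fc=float(sig.loc[m, "fc"]),
                    log2fc=float(sig.loc[m, "log2fc"]),
                )
            if row.term_id not in g:
                g.add_node(
                    row.term_id,
                    kind="term",
                    bipartite=1,
                    domain=domain,
                    label=str(row.label),
                    neg_log2_p=float(row.neg_log2_p),
                    fold_enrichment=float(row.fold_enrichment),
                )
            g.add_edge(m, row.term_id, score=int(s))
    return g


def export_network(network: nx.Graph, path: str | Path, fmt: str = "graphml") -> Path:
    """Serialize to a Cytoscape-readable format: graphml (all attributes),
    sif ("mirna targets term"), or a TSV edge list."""
    path = Path(path)
    if fmt not in EXPORT_FORMATS:
        raise ValueError(f"format must be one of {EXPORT_FORMATS}")
    if fmt == "graphml":
        nx.write_graphml(network, path, named_key_ids=True)
    elif fmt == "sif":
        lines = [
            f"{m}\ttargets\t{t}"
            for m, t in sorted(_oriented_edges(network))
        ]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    else:
        rows = [
            {
                "mirna_id": m,
                "term_id": t,
                "score": network.edges[m, t]["score"],
                "direction": network.graph.get("direction", ""),
                "domain": network.graph.get("domain", ""),
            }
            for m, t in sorted(_oriented_edges(network))
        ]
        pd.DataFrame(rows, columns=["mirna_id", "term_id", "score", "direction", "domain"]).to_csv(
            path, sep="\t", index=False
        )
    return path


def _oriented_edges(network: nx.Graph) -> list[tuple[str, str]]:
    out = []
    for u, v in network.edges:
        if network.nodes[u].get("kind") == "mirna":
            out.append((u, v))
        else:
            out.append((v, u))
    return out


def read_graphml(path: str | Path) -> nx.Graph:
    """Read a network written by :func:`export_network` (graphml)."""
    return nx.read_graphml(path)
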