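"""Gene-term association networks over selected functional terms.

A GTAN is a bipartite graph linking the genes of a deregulated list to a
small, hand-picked set of functional terms; genes reached by two or more
terms mark cross-pathway candidates.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .enrichment import GeneSetCollection
from .types import GeneList

GENE_ROLE = "gene"
TERM_ROLE = "term"


def build_gtan(
    gene_list: GeneList | set[str],
    sets: GeneSetCollection,
    selected_terms: list[str],
) -> nx.Graph:
    """Bipartite (gene, term) network restricted to the selected terms.

    An edge (g, t) exists iff g is in the gene list and annotated to
    term t. Gene nodes carry the collapsed fold change when the input is
    a :class:`GeneList`; term nodes carry their member count.
    """
    unknown = [t for t in selected_terms if t not in sets.sets]
    if unknown:
        raise KeyError(f"unknown term id(s): {unknown}")

    if isinstance(gene_list, GeneList):
        from .list_comparison import collapse_gene_list

        fc = collapse_gene_list(gene_list)
        genes = set(fc.index)
    else:
        fc = pd.Series(dtype=float)
        genes = set(gene_list)

    net = nx.Graph()
    for term in selected_terms:
        members = sets.members(term)
        net.add_node(term, role=TERM_ROLE, bipartite=1, size=len(members))
        for gene in sorted(genes.intersection(members)):
            if gene not in net:
                attrs = {"role": GENE_ROLE, "bipartite": 0}
                if gene in fc.index:
                    attrs["fold_change"] = float(fc[gene])
                net.add_node(gene, **attrs)
            net.add_edge(gene, term)
    return net


def select_multiterm_genes(net: nx.Graph, min_terms: int = 2) -> list[str]:
    """Genes associated with at least ``min_terms`` terms, sorted."""
    if min_terms < 1:
        raise ValueError("min_terms must be >= 1")
    return sorted(
        n for n, data in net.nodes(data=True)
        if data.get("role") == GENE_ROLE and net.degree(n) >= min_terms
    )


def edge_table(net: nx.Graph) -> pd.DataFrame:
    """Flat (gene, term) edge list in deterministic order."""
    rows = sorted(
        (u, v) if net.nodes[u].get("role") == GENE_ROLE else (v, u)
        for u, v in net.edges
    )
    return pd.DataFrame(rows, columns=["gene", "term"])


def write_gtan(net: nx.Graph, graphml_path: str | Path,
               edges_path: str | Path | None = None) -> None:
    """Export the network as GraphML and optionally a TSV edge list."""
    nx.write_graphml(net, str(graphml_path))
    if edges_path is not None:
        edge_table(net).to_csv(edges_path, sep="\t", index=False)
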