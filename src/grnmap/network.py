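"""Hub-centred layered gene-gene interaction networks.

Significant SNP x SNP epistasis pairs are collapsed to undirected gene-level
edges, and genes are layered by breadth-first distance from the hub TF:
layer 1 is the hub alone, layer 2 its direct interactors, layer 3 everything
else reachable (distance capped at the configured maximum).  Genes
unreachable from the hub are excluded and reported separately.  Edge classes
are a function of endpoint layers only (L1-L2, within-L2, L2-L3, within-L3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "GeneEdge",
    "LayeredNetwork",
    "ConnectivitySummary",
    "collapse_to_gene_edges",
    "build_layers",
    "connectivity_fraction",
    "export_network",
]


@dataclass
class GeneEdge:
    """Undirected gene-gene edge with its supporting SNP-pair records."""

    gene_a: str
    gene_b: str
    support: list[tuple[str, str]] = field(default_factory=list)
    traits: set[str] = field(default_factory=set)
    edge_class: str = ""

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.gene_a, self.gene_b)))


@dataclass
class LayeredNetwork:
    hub_gene: str
    layer_of: dict[str, int]
    edges: list[GeneEdge]
    unconnected: list[str] = field(default_factory=list)

    def genes_in_layer(self, layer: int) -> list[str]:
        return sorted(g for g, l in self.layer_of.items() if l == layer)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for gene, layer in sorted(self.layer_of.items()):
            g.add_node(gene, layer=layer)
        for e in sorted(self.edges, key=lambda e: e.key):
            g.add_edge(
                e.gene_a, e.gene_b,
                edge_class=e.edge_class,
                support=len(e.support),
                traits=",".join(sorted(e.traits)),
            )
        return g


@dataclass
class ConnectivitySummary:
    n_genes_in_network: int
    n_universe: int

    @property
    def fraction_connected(self) -> float:
        return self.n_genes_in_network / self.n_universe


def collapse_to_gene_edges(significant_pairs: pd.DataFrame) -> list[GeneEdge]:
    """Collapse significant SNP pairs to undirected gene-level edges.

    Expects the long-format epistasis scan table filtered to significant
    rows (columns snp1, gene1, snp2, gene2, trait).  Within-gene SNP pairs
    are dropped (no self-loops); records lacking a gene annotation are
    skipped.  Deterministic output order (sorted by gene pair).
    """
    edges: dict[tuple[str, str], GeneEdge] = {}
    for row in significant_pairs.itertuples(index=False):
        ga, gb = str(row.gene1), str(row.gene2)
        if not ga or not gb or ga == "nan" or gb == "nan":
            continue
        if ga == gb:
            continue
        key = tuple(sorted((ga, gb)))
        edge = edges.setdefault(key, GeneEdge(key[0], key[1]))
        edge.support.append((str(row.snp1), str(row.snp2)))
        if hasattr(row, "trait"):
            edge.traits.add(str(row.trait))
    return [edges[k] for k in sorted(edges)]


_EDGE_CLASS = {
    (1, 2): "L1-L2",
    (2, 2): "within-L2",
    (2, 3): "L2-L3",
    (3, 3): "within-L3",
}


def build_layers(
    gene_edges: list[GeneEdge],
    hub_gene: str,
    max_layer: int = 3,
    declare_hub: bool = True,
) -> LayeredNetwork:
    """Assign layers by BFS distance from the hub and classify edges.

    Layer = min(BFS distance + 1, max_layer): the hub is layer 1, direct
    interactors layer 2, and all other reachable genes collapse into the
    deepest layer.  Unreachable genes are excluded and listed separately.
    Output is independent of edge-list order (lexicographic tie-breaks).
    With ``declare_hub=False`` a hub absent from the edge list is an error
    instead of an isolated layer-1 node.
    """
    g = nx.Graph()
    for e in gene_edges:
        g.add_edge(*e.key)
    if hub_gene not in g:
        if not declare_hub:
            raise ValueError(f"hub gene {hub_gene!r} absent from edge list")
        g.add_node(hub_gene)
    dist = nx.single_source_shortest_path_length(g, hub_gene)
    layer_of = {gene: min(d + 1, max_layer) for gene, d in dist.items()}
    unconnected = sorted(set(g.nodes) - set(dist))
    kept = []
    for e in sorted(gene_edges, key=lambda e: e.key):
        la = layer_of.get(e.gene_a)
        lb = layer_of.get(e.gene_b)
        if la is None or lb is None:
            continue
        e.edge_class = _EDGE_CLASS.get(tuple(sorted((la, lb))), f"L{min(la, lb)}-L{max(la, lb)}")
        kept.append(e)
    return LayeredNetwork(hub_gene, layer_of, kept, unconnected)


def connectivity_fraction(
    network: LayeredNetwork, gene_universe: list[str]
) -> ConnectivitySummary:
    """Share of universe genes (hub excluded) placed in layer 2 or deeper."""
    universe = [g for g in gene_universe if g != network.hub_gene]
    if not universe:
        raise ValueError("empty gene universe")
    connected = sum(
        1 for g in universe if network.layer_of.get(g, 0) >= 2
    )
    return ConnectivitySummary(connected, len(universe))


def trait_networks(
    significant_pairs: pd.DataFrame, hub_gene: str, max_layer: int = 3
) -> dict[str, LayeredNetwork]:
    """One layered network per trait from a significant-pair table."""
    out = {}
    for trait in sorted(significant_pairs["trait"].unique()):
        sub = significant_pairs[significant_pairs["trait"] == trait]
        out[str(trait)] = build_layers(
            collapse_to_gene_edges(sub), hub_gene, max_layer=max_layer
        )
    return out


def network_overlap(networks: dict[str, LayeredNetwork]) -> pd.DataFrame:
    """Pairwise counts of genes (hub excluded) shared between trait networks."""
    names = sorted(networks)
    gene_sets = {
        t: {g for g, l in networks[t].layer_of.items() if l >= 2} for t in names
    }
    data = [
        [len(gene_sets[a] & gene_sets[b]) for b in names] for a in names
    ]
    return pd.DataFrame(data, index=names, columns=names)


def export_network(
    network: LayeredNetwork, path: str | Path, fmt: str = "sif"
) -> None:
    """Write the network as SIF, GraphML or a TSV edge list (deterministic)."""
    path = Path(path)
    graph = network.to_graph()
    if fmt == "sif":
        lines = [
            f"{e.gene_a}\tinteracts\t{e.gene_b}"
            for e in sorted(network.edges, key=lambda e: e.key)
        ]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "tsv":
        rows = [
            dict(
                gene_a=e.gene_a,
                gene_b=e.gene_b,
                edge_class=e.edge_class,
                support=len(e.support),
                traits=",".join(sorted(e.traits)),
            )
            for e in sorted(network.edges, key=lambda e: e.key)
        ]
        pd.DataFrame(
            rows, columns=["gene_a", "gene_b", "edge_class", "support", "traits"]
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {fmt!r}")
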