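"""Network topology: tissue sub-networks, bridging genes, core network.

The full co-expression network of a multi-tissue design splits into
tissue-specific sub-networks once each gene is assigned to the tissue
where it changes most.  Genes whose direct neighbours span at least two
different tissue labels are *bridging genes*; the subgraph they induce is
the *core network* linking the tissue sub-networks together.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .expression_io import ProfileMatrix

__all__ = [
    "TissueAssignment",
    "SubnetworkPartition",
    "assign_tissue",
    "extract_tissue_subnetworks",
    "find_bridging_genes",
    "build_core_network",
    "network_summary",
    "export_graph",
    "import_graph",
]

UNASSIGNED = "unassigned"


@dataclass
class TissueAssignment:
    """Per-gene tissue call: the tissue and day of the maximum |log2FC|.

    ``table`` columns: ``tissue`` (or ``unassigned`` for all-zero
    profiles), ``max_abs_log2fc``, ``peak_day``, ``tied`` (True when the
    maximum was shared between conditions and broken by declared tissue
    order, then earliest day).  Indexed by gene.
    """

    table: pd.DataFrame
    tissue_order: tuple[str, ...]

    def tissue_of(self, gene: str) -> str:
        return self.table.at[gene, "tissue"]

    @property
    def unassigned(self) -> set[str]:
        t = self.table
        return set(t.index[t["tissue"] == UNASSIGNED])

    def label_map(self) -> dict[str, str]:
        return dict(self.table["tissue"])


def assign_tissue(profiles: ProfileMatrix) -> TissueAssignment:
    """Assign each gene to the tissue/day of its maximum |log2FC|.

    Ties are broken by the declared tissue order, then by earliest day
    (the condition column order encodes exactly that precedence).
    All-zero profiles are flagged ``unassigned``.
    """
    if len(profiles.genes) == 0:
        raise ValueError("profile matrix has no genes")
    conds = profiles.conditions
    values = np.abs(profiles.data.to_numpy(dtype=float))
    best = values.argmax(axis=1)  # argmax returns the first maximum: the
    # condition order (declared tissue order x ascending days) is the tie-break
    max_abs = values[np.arange(len(best)), best]
    n_at_max = (values == max_abs[:, None]).sum(axis=1)
    rows = []
    for gene, b, m, ties in zip(profiles.genes, best, max_abs, n_at_max):
        if m == 0:
            rows.append((gene, UNASSIGNED, 0.0, -1, False))
        else:
            tissue, day = conds[b]
            rows.append((gene, tissue, float(m), day, bool(ties > 1)))
    table = pd.DataFrame(
        rows, columns=["gene", "tissue", "max_abs_log2fc", "peak_day", "tied"]
    ).set_index("gene")
    return TissueAssignment(table, tuple(profiles.tissues))


@dataclass
class SubnetworkPartition:
    """Tissue sub-networks plus bridging/core structure.

    ``subnetworks``: tissue -> induced subgraph on genes assigned to the
    tissue, after dropping genes with no intra-tissue edge (listed in
    ``excluded``).  ``bridging``: genes whose neighbours span >= 2 tissue
    labels.  ``core``: subgraph induced on the bridging genes.
    ``bridge_connectivity``: number of distinct full-network edges with at
    least one bridging endpoint.
    """

    subnetworks: dict[str, nx.Graph]
    excluded: dict[str, list[str]]
    unassigned: list[str]
    bridging: set[str] = field(default_factory=set)
    core: nx.Graph | None = None
    bridge_connectivity: int = 0


def extract_tissue_subnetworks(
    net: nx.Graph, assignment: TissueAssignment
) -> SubnetworkPartition:
    """Induced per-tissue subgraphs; nodes without an intra-tissue edge
    are removed from their sub-network and reported as excluded."""
    labels = assignment.label_map()
    missing = [n for n in net.nodes if n not in labels]
    if missing:
        raise ValueError(f"network node(s) without tissue assignment: {missing[:5]}")
    subnetworks: dict[str, nx.Graph] = {}
    excluded: dict[str, list[str]] = {}
    for tissue in assignment.tissue_order:
        members = [n for n in net.nodes if labels[n] == tissue]
        sub = net.subgraph(members).copy()
        isolated = [n for n in sub.nodes if sub.degree(n) == 0]
        sub.remove_nodes_from(isolated)
        subnetworks[tissue] = sub
        excluded[tissue] = sorted(isolated)
    unassigned = sorted(n for n in net.nodes if labels[n] == UNASSIGNED)
    return SubnetworkPartition(subnetworks, excluded, unassigned)


def find_bridging_genes(net: nx.Graph, assignment: TissueAssignment) -> set[str]:
    """Genes whose neighbour set carries >= 2 distinct tissue labels
    (the gene's own label does not matter; unassigned neighbours are
    ignored)."""
    labels = assignment.label_map()
    bridging = set()
    for node in net.nodes:
        seen = {
            labels.get(nb, UNASSIGNED)
            for nb in net.neighbors(node)
            if labels.get(nb, UNASSIGNED) != UNASSIGNED
        }
        if len(seen) >= 2:
            bridging.add(node)
    return bridging


def build_core_network(net: nx.Graph, bridging: set[str]) -> tuple[nx.Graph, int]:
    """Subgraph induced on the bridging genes, plus the number of distinct
    full-network edges incident to at least one bridging gene."""
    unknown = bridging - set(net.nodes)
    if unknown:
        raise ValueError(f"bridging gene(s) not in network: {sorted(unknown)[:5]}")
    core = net.subgraph(sorted(bridging)).copy()
    connectivity = sum(1 for u, v in net.edges if u in bridging or v in bridging)
    return core, connectivity


def partition_network(
    net: nx.Graph, assignment: TissueAssignment
) -> SubnetworkPartition:
    """Full partition: tissue sub-networks + bridging genes + core network."""
    part = extract_tissue_subnetworks(net, assignment)
    part.bridging = find_bridging_genes(net, assignment)
    part.core, part.bridge_connectivity = build_core_network(net, part.bridging)
    return part


def network_summary(graph: nx.Graph) -> dict[str, float]:
    """Node/edge counts, degree min/median/max, connected components."""
    n = graph.number_of_nodes()
    degrees = [d for _, d in graph.degree()]
    return {
        "n_nodes": n,
        "n_edges": graph.number_of_edges(),
        "degree_min": int(min(degrees)) if degrees else 0,
        "degree_median": float(np.median(degrees)) if degrees else 0.0,
        "degree_max": int(max(degrees)) if degrees else 0,
        "n_components": nx.number_connected_components(graph) if n else 0,
    }


# ---------------------------------------------------------------------------
# interchange formats


def export_graph(
    graph: nx.Graph,
    fmt: str,
    path: str | Path,
    node_attr_path: str | Path | None = None,
    edge_attr_path: str | Path | None = None,
    interaction: str = "co",
) -> None:
    """Write a graph as GraphML or SIF (plus optional attribute TSVs).

    GraphML carries node and edge attributes inline and round-trips
    exactly through :func:`import_graph`.  SIF lines read
    ``geneA <interaction> geneB``, one per edge, with isolated nodes on
    their own line; attributes go to the side tables.
    """
    path = Path(path)
    fmt = fmt.lower()
    if fmt == "graphml":
        nx.write_graphml(graph, path, named_key_ids=True)
    elif fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            written = set()
            for u, v in sorted(graph.edges):
                fh.write(f"{u}\t{interaction}\t{v}\n")
                written.update((u, v))
            for node in sorted(graph.nodes):
                if node not in written:
                    fh.write(f"{node}\n")
    else:
        raise ValueError(f"unknown graph format {fmt!r} (expected 'sif' or 'graphml')")
    if node_attr_path is not None:
        rows = [{"gene": n, **graph.nodes[n]} for n in sorted(graph.nodes)]
        pd.DataFrame(rows).to_csv(node_attr_path, sep="\t", index=False)
    if edge_attr_path is not None:
        rows = [
            {"gene_a": u, "gene_b": v, **graph.edges[u, v]}
            for u, v in sorted(graph.edges)
        ]
        pd.DataFrame(rows).to_csv(edge_attr_path, sep="\t", index=False)


def import_graph(path: str | Path, fmt: str | None = None) -> nx.Graph:
    """Read a graph written by :func:`export_graph`."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt == "graphml":
        graph = nx.read_graphml(path)
        graph.graph.pop("node_default", None)
        graph.graph.pop("edge_default", None)
        return graph
    if fmt == "sif":
        graph = nx.Graph()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) == 1 and parts[0]:
                    graph.add_node(parts[0])
                elif len(parts) == 3:
                    graph.add_edge(parts[0], parts[2])
                elif parts != [""]:
                    raise ValueError(f"malformed SIF line: {line!r}")
        return graph
    raise ValueError(f"unknown graph format {fmt!r} (expected 'sif' or 'graphml')")
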