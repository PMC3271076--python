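"""TF-centered regulatory network assembly and feedback-loop detection.

Nodes are typed (TF, miRNA, gene); edges are typed directed repressions:
``transcriptional_repression`` (TF -> miRNA, from the promoter-site scan)
and ``posttranscriptional_repression`` (miRNA -> gene, from seed matching
or user-supplied literature edges). A feedback loop is a 2-cycle through
the TF: TF -| miRNA and miRNA -| TF.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import networkx as nx

from .formats import write_sif

TRANSCRIPTIONAL = "transcriptional_repression"
POSTTRANSCRIPTIONAL = "posttranscriptional_repression"

# short relation labels used in SIF lines
_SIF_RELATION = {TRANSCRIPTIONAL: "represses-tx", POSTTRANSCRIPTIONAL: "represses-pt"}
_SIF_RELATION_INV = {v: k for k, v in _SIF_RELATION.items()}

NODE_TYPES = ("TF", "miRNA", "gene")


class RegulatoryNetwork:
    """A typed directed repression network backed by a networkx DiGraph."""

    def __init__(self) -> None:
        self.graph = nx.DiGraph()

    # -- construction -------------------------------------------------------
    def add_node(self, name: str, node_type: str) -> None:
        if node_type not in NODE_TYPES:
            raise ValueError(f"unknown node type {node_type!r}")
        existing = self.graph.nodes.get(name)
        if existing is not None:
            # a gene that is also the TF collapses onto the TF node
            if existing["node_type"] != node_type and "TF" in (existing["node_type"], node_type):
                self.graph.nodes[name]["node_type"] = "TF"
            return
        self.graph.add_node(name, node_type=node_type)

    def add_edge(self, source: str, target: str, edge_type: str, provenance: str = "pipeline") -> None:
        if source == target:
            raise ValueError(f"self-edge on {source!r} not allowed")
        if edge_type == TRANSCRIPTIONAL and self.node_type(source) != "TF":
            raise ValueError(f"transcriptional edge must originate at a TF, not {source!r}")
        if edge_type == POSTTRANSCRIPTIONAL and self.node_type(source) != "miRNA":
            raise ValueError(f"post-transcriptional edge must originate at a miRNA, not {source!r}")
        if self.graph.has_edge(source, target) and self.graph[source][target]["edge_type"] == edge_type:
            prov = self.graph[source][target]["provenance"]
            merged = sorted(set(prov.split(";")) | {provenance})
            self.graph[source][target]["provenance"] = ";".join(merged)
            return
        self.graph.add_edge(source, target, edge_type=edge_type, provenance=provenance)

    # -- queries ------------------------------------------------------------
    def node_type(self, name: str) -> str:
        try:
            return self.graph.nodes[name]["node_type"]
        except KeyError:
            raise KeyError(f"unknown node {name!r}") from None

    @property
    def nodes(self) -> list:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list:
        return sorted(
            (s, t, d["edge_type"], d["provenance"]) for s, t, d in self.graph.edges(data=True)
        )

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def build_network(
    tf_id: str,
    repressed_mirnas: Iterable[str],
    mirna_targets: Mapping[str, Iterable[str]],
    provenance: str = "pipeline",
) -> RegulatoryNetwork:
    """Assemble the TF-centered network.

    One TF node; an edge TF -| m for every repressed miRNA; an edge m -| g
    for every target gene of m. A target gene named like the TF collapses
    onto the TF node, which is what makes feedback loops representable.
    """
    net = RegulatoryNetwork()
    net.add_node(tf_id, "TF")
    for m in repressed_mirnas:
        net.add_node(m, "miRNA")
        net.add_edge(tf_id, m, TRANSCRIPTIONAL, provenance)
    for m, genes in mirna_targets.items():
        net.add_node(m, "miRNA")
        for g in genes:
            net.add_node(g, "TF" if g == tf_id else "gene")
            net.add_edge(m, g, POSTTRANSCRIPTIONAL, provenance)
    return net


def add_edge_table(net: RegulatoryNetwork, path) -> None:
    """Import extra edges (e.g. literature-validated targets) from a TSV.

    Columns: source, relation (SIF short labels or full type names), target,
    provenance.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    for row in df.itertuples(index=False):
        edge_type = _SIF_RELATION_INV.get(row.relation, row.relation)
        if edge_type not in (TRANSCRIPTIONAL, POSTTRANSCRIPTIONAL):
            raise ValueError(f"unknown relation {row.relation!r}")
        src_type = "TF" if edge_type == TRANSCRIPTIONAL else "miRNA"
        tgt_type = "miRNA" if edge_type == TRANSCRIPTIONAL else "gene"
        net.add_node(str(row.source), src_type)
        net.add_node(str(row.target), tgt_type)
        net.add_edge(str(row.source), str(row.target), edge_type, str(getattr(row, "provenance", "literature")))


def find_feedback_loops(net: RegulatoryNetwork, tf_id: str) -> list:
    """miRNAs m with both TF -| m (transcriptional) and m -| TF (post-transcriptional)."""
    if tf_id not in net.graph:
        raise KeyError(f"unknown TF {tf_id!r}")
    loops = []
    for _, m, d in net.graph.out_edges(tf_id, data=True):
        if d["edge_type"] != TRANSCRIPTIONAL:
            continue
        back = net.graph.get_edge_data(m, tf_id)
        if back and back["edge_type"] == POSTTRANSCRIPTIONAL:
            loops.append(m)
    return sorted(loops)


def export_network(net: RegulatoryNetwork, path, fmt: str = "SIF") -> None:
    """Write the network as SIF or GraphML with deterministic ordering."""
    fmt = fmt.upper()
    if fmt == "SIF":
        edges = [(s, _SIF_RELATION[etype], t) for s, t, etype, _ in net.edges]
        write_sif(edges, path)
    elif fmt == "GRAPHML":
        # rebuild in sorted order so the serialization is deterministic
        g = nx.DiGraph()
        for n in net.nodes:
            g.add_node(n, node_type=net.node_type(n))
        for s, t, etype, prov in net.edges:
            g.add_edge(s, t, edge_type=etype, provenance=prov)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {fmt!r} (use SIF or GraphML)")


def read_network_sif(path) -> RegulatoryNetwork:
    """Parse a SIF file written by :func:`export_network` back into a network."""
    from .formats import read_sif

    net = RegulatoryNetwork()
    for s, rel, t in read_sif(path):
        edge_type = _SIF_RELATION_INV.get(rel)
        if edge_type is None:
            raise ValueError(f"unknown SIF relation {rel!r}")
        if edge_type == TRANSCRIPTIONAL:
            net.add_node(s, "TF")
            net.add_node(t, "miRNA")
        else:
            net.add_node(s, "miRNA")
            net.add_node(t, "gene")
        net.add_edge(s, t, edge_type)
    return net
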