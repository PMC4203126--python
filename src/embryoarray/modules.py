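"""Transcriptional-module graphs: TF -> enriched motif -> target genes,
with GO-term annotation nodes, exported as Cytoscape SIF + attribute files.

A module is built from one analyzed gene set: every motif enriched in that
set (p < 0.001) becomes a diamond node; transcription factors mapped to the
motif and themselves members of the gene set become octagon nodes with a
``binds`` edge to the motif; every set gene whose promoter carries >= 1
match becomes a circle node targeted by the motif; GO terms enriched in the
set annotate their member genes.  The graph is tripartite plus annotation:
no TF -> gene or motif -> motif edges exist.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

NODE_ROLES = {"TF": "octagon", "motif": "diamond", "GO_term": "circle",
              "gene": "circle"}
RELATIONS = {("TF", "motif"): "binds", ("motif", "gene"): "targets",
             ("GO_term", "gene"): "annotates"}


def build_module(
    gene_set,
    motif_results: pd.DataFrame,
    tf_map: dict[str, str],
    hit_table: pd.DataFrame,
    go_results: pd.DataFrame | None = None,
    gmt: dict[str, dict] | None = None,
    require_tf_in_set: bool = True,
) -> nx.DiGraph:
    """Assemble the module graph for one gene set.

    ``motif_results`` / ``go_results`` are enrichment tables computed on
    this same gene set; ``hit_table`` is the genes x motifs promoter match
    count table.  An enriched motif with no mapped TF is retained and
    flagged ``orphan``.  ``require_tf_in_set=False`` admits mapped TFs that
    are not members of the analyzed set.
    """
    gene_set = set(gene_set)
    graph = nx.DiGraph()
    enriched_motifs = list(
        motif_results.loc[motif_results["enriched"], "term"]
    )
    for motif_id in enriched_motifs:
        p = float(
            motif_results.loc[motif_results["term"] == motif_id, "p"].iloc[0]
        )
        graph.add_node(motif_id, node_type="motif",
                       display_role=NODE_ROLES["motif"], p=p, orphan=False)
        tfs = sorted(
            tf for tf, m in tf_map.items()
            if m == motif_id and (tf in gene_set or not require_tf_in_set)
        )
        if not tfs:
            graph.nodes[motif_id]["orphan"] = True
        for tf in tfs:
            graph.add_node(tf, node_type="TF", display_role=NODE_ROLES["TF"])
            graph.add_edge(tf, motif_id, relation="binds")
        targets = sorted(
            g for g in gene_set
            if g in hit_table.index and hit_table.loc[g, motif_id] > 0
        )
        for g in targets:
            if g not in graph or graph.nodes[g].get("node_type") != "TF":
                graph.add_node(g, node_type="gene",
                               display_role=NODE_ROLES["gene"])
            graph.add_edge(motif_id, g, relation="targets")

    if go_results is not None and gmt is not None:
        target_genes = {
            n for n, d in graph.nodes(data=True)
            if d["node_type"] in ("gene", "TF")
        }
        for term_id in go_results.loc[go_results["enriched"], "term"]:
            members = set(gmt[term_id]["genes"]) & target_genes
            if not members:
                continue
            graph.add_node(term_id, node_type="GO_term",
                           display_role=NODE_ROLES["GO_term"])
            for g in sorted(members):
                graph.add_edge(term_id, g, relation="annotates")
    _validate(graph)
    return graph


def _validate(graph: nx.DiGraph) -> None:
    for a, b, data in graph.edges(data=True):
        ta = graph.nodes[a]["node_type"]
        tb = graph.nodes[b]["node_type"]
        tb_eff = "gene" if tb == "TF" and ta != "TF" else tb
        if (ta, tb_eff) not in RELATIONS:
            raise ValueError(f"illegal edge {ta} -> {tb}")
        expected = RELATIONS[(ta, tb_eff)]
        if data.get("relation") != expected:
            raise ValueError(f"edge {a}->{b} relation {data.get('relation')}")


# ---------------------------------------------------------------------------
# Cytoscape export
# ---------------------------------------------------------------------------

def export_cytoscape(graph: nx.DiGraph, prefix) -> dict[str, Path]:
    """Write SIF + node-attribute + edge-attribute files.

    SIF lines are ``source <relation> target`` (tab-separated, one
    interaction per line); nodes are sorted so a rebuild is byte-identical.
    Node ids containing tabs or newlines are rejected.
    """
    prefix = Path(prefix)
    for node in graph.nodes:
        if any(c in str(node) for c in "\t\n"):
            raise ValueError(f"node id {node!r} contains tab/newline")
    sif_path = prefix.with_suffix(".sif")
    noa_path = prefix.with_name(prefix.name + "_nodes.tsv")
    eda_path = prefix.with_name(prefix.name + "_edges.tsv")

    edges = sorted(
        (str(a), graph.edges[a, b]["relation"], str(b)) for a, b in graph.edges
    )
    with open(sif_path, "w") as fh:
        for a, rel, b in edges:
            fh.write(f"{a}\t{rel}\t{b}\n")
    with open(noa_path, "w") as fh:
        fh.write("node\tnode_type\tdisplay_role\n")
        for node in sorted(graph.nodes, key=str):
            d = graph.nodes[node]
            fh.write(f"{node}\t{d['node_type']}\t{d['display_role']}\n")
    with open(eda_path, "w") as fh:
        fh.write("source\trelation\ttarget\n")
        for a, rel, b in edges:
            fh.write(f"{a}\t{rel}\t{b}\n")
    return {"sif": sif_path, "nodes": noa_path, "edges": eda_path}


def read_sif(path) -> list[tuple[str, str, str]]:
    """Parse a SIF file back to its (source, relation, target) edge list."""
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"malformed SIF line: {line!r}")
            edges.append((parts[0], parts[1], parts[2]))
    return edges


def graph_from_sif(path, node_attributes_path=None) -> nx.DiGraph:
    """Rebuild a module graph from SIF (+ optional node attribute file)."""
    graph = nx.DiGraph()
    rel_to_types = {rel: pair for pair, rel in RELATIONS.items()}
    for a, rel, b in read_sif(path):
        if rel not in rel_to_types:
            raise ValueError(f"unknown relation {rel!r}")
        ta, tb = rel_to_types[rel]
        for node, t in ((a, ta), (b, tb)):
            if node not in graph:
                graph.add_node(node, node_type=t, display_role=NODE_ROLES[t])
        graph.add_edge(a, b, relation=rel)
    if node_attributes_path is not None:
        attrs = pd.read_csv(node_attributes_path, sep="\t").set_index("node")
        for node, row in attrs.iterrows():
            if node in graph:
                graph.nodes[node].update(row.to_dict())
    return graph


def graph_to_json(graph: nx.DiGraph) -> dict:
    """JSON-serializable description of the full graph."""
    return {
        "nodes": [
            {"id": str(n), **{k: v for k, v in d.items()}}
            for n, d in sorted(graph.nodes(data=True), key=lambda x: str(x[0]))
        ],
        "edges": [
            {"source": str(a), "target": str(b), **d}
            for a, b, d in sorted(graph.edges(data=True), key=lambda x: (str(x[0]), str(x[1])))
        ],
    }
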