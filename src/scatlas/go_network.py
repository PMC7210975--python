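"""Gene-gene functional-association network from GO Biological Process terms.

Edges connect marker genes whose BP term sets have a Jaccard similarity
(intersection over union) strictly above a threshold; genes left isolated
are dropped from the network.
"""

from __future__ import annotations

from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from scatlas._errors import FormatError, ValidationError

GoAnnotation = Mapping[str, frozenset]


def jaccard(a: frozenset | set, b: frozenset | set) -> float:
    """Intersection over union of two non-empty term sets."""
    if not a or not b:
        raise ValidationError("jaccard undefined for empty term sets")
    return len(a & b) / len(a | b)


def load_go_annotation(path: str | Path, namespace: str = "BP") -> dict[str, frozenset]:
    """Load gene -> BP term-set mapping from a TSV or a GAF 2.x file.

    TSV columns: ``gene_id, go_id[, namespace]``. GAF rows are used when the
    aspect column is ``P`` (Biological Process).
    """
    path = Path(path)
    terms: dict[str, set] = {}
    with open(path) as handle:
        first = handle.readline()
    if first.startswith("!gaf") or first.startswith("!"):
        with open(path) as handle:
            for line in handle:
                if line.startswith("!"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9:
                    raise FormatError("malformed GAF row")
                gene, go_id, aspect = fields[2], fields[4], fields[8]
                if aspect == "P":
                    terms.setdefault(gene, set()).add(go_id)
    else:
        frame = pd.read_csv(path, sep="\t", dtype=str)
        if "gene_id" not in frame.columns or "go_id" not in frame.columns:
            raise FormatError("GO TSV must have gene_id and go_id columns")
        if "namespace" in frame.columns:
            frame = frame[frame["namespace"] == namespace]
        for gene, go_id in zip(frame["gene_id"], frame["go_id"]):
            terms.setdefault(gene, set()).add(go_id)
    return {g: frozenset(t) for g, t in terms.items()}


def build_network(
    genes: Mapping[str, str] | Sequence[str],
    go: GoAnnotation,
    threshold: float = 0.05,
) -> nx.Graph:
    """Score all unordered marker-gene pairs; keep edges with jaccard > threshold.

    ``genes`` is either a mapping gene -> regulation tag ("up"/"down") or a
    plain sequence. Genes with no BP terms are excluded before pairing, and
    nodes without any surviving edge are dropped.
    """
    if not isinstance(genes, Mapping):
        genes = {g: "" for g in genes}
    annotated = {g: tag for g, tag in genes.items() if go.get(g)}
    if not annotated:
        raise ValidationError("no marker gene has GO BP terms")

    graph = nx.Graph()
    for g, tag in annotated.items():
        graph.add_node(g, direction=tag)
    for g1, g2 in combinations(sorted(annotated), 2):
        j = jaccard(go[g1], go[g2])
        if j > threshold:
            graph.add_edge(g1, g2, jaccard=j)
    graph.remove_nodes_from(list(nx.isolates(graph)))
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    rows = [
        {"gene_a": a, "gene_b": b, "jaccard": data["jaccard"]}
        for a, b, data in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "jaccard"]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_list(path: str | Path) -> nx.Graph:
    frame = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    graph = nx.Graph()
    for _, row in frame.iterrows():
        graph.add_edge(row["gene_a"], row["gene_b"], jaccard=float(row["jaccard"]))
    return graph


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, path)
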