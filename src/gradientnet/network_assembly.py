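"""Assembly and export of the signed seed-germination gene network.

Edges come from two rule families: (1) the AFB-group gradient rule, which
connects the two auxin co-receptor group nodes to each classified gene
with a sign determined by the gene's response direction and gradient; and
(2) hormone-regulon membership, which connects configured upstream
pathway nodes (e.g. BES1/BZR1 for brassinosteroid, ABI3/4/5 for ABA) to
genes found in the corresponding regulon lists. Germination-role labels
are consumed from an annotation table, never inferred.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from gradientnet.errors import ConfigError, ValidationError
from gradientnet.expression_io import RegulonTable
from gradientnet.gradient_grouping import AfbGroupAssignment, GradientGroup

__all__ = [
    "NetworkNode",
    "RegulatoryEdge",
    "AFB1_GROUP_NODE",
    "AFB5_GROUP_NODE",
    "DEFAULT_PATHWAY_MAP",
    "infer_afb_edges",
    "merge_hormone_edges",
    "collapse_edges",
    "export_network",
    "load_node_annotations",
    "packaged_annotation_path",
]

AFB1_GROUP_NODE = "AFB1-group"
AFB5_GROUP_NODE = "AFB5-group"

#: hormone -> upstream pathway node(s) credited with the regulation.
DEFAULT_PATHWAY_MAP: dict[str, tuple[str, ...]] = {
    "auxin": (AFB1_GROUP_NODE, AFB5_GROUP_NODE),
    "ABA": ("ABI3", "ABI4", "ABI5"),
    "brassinosteroid": ("BES1", "BZR1"),
}

_ROLES = ("positive", "negative", "unknown")
_SIGNS = ("activation", "repression")


@dataclass(frozen=True)
class NetworkNode:
    node_id: str
    germination_role: str = "unknown"
    source_table: str = ""

    def __post_init__(self) -> None:
        if self.germination_role not in _ROLES:
            raise ValidationError(
                f"node {self.node_id}: unknown germination_role "
                f"{self.germination_role!r}"
            )


@dataclass(frozen=True)
class RegulatoryEdge:
    source: str
    target: str
    sign: str
    evidence: str

    def __post_init__(self) -> None:
        if self.sign not in _SIGNS:
            raise ValidationError(f"unknown edge sign {self.sign!r}")
        if self.source == self.target:
            raise ValidationError(f"self-edge on {self.source!r} not allowed")

    @property
    def sif_interaction(self) -> str:
        return "activates" if self.sign == "activation" else "represses"


def infer_afb_edges(
    groups: Sequence[GradientGroup],
    afb: AfbGroupAssignment,
) -> list[RegulatoryEdge]:
    """Emit one signed AFB-group edge per classified gene.

    An auxin-downregulated gene is repressed by the AFB group whose
    gradient is opposite to the gene's; an auxin-upregulated gene is
    activated by the AFB group whose gradient matches the gene's. The
    ``afb`` assignment is accepted so callers can record whether the AFB
    partition was data-derived, but the group nodes themselves are fixed:
    the AFB1 group carries the down gradient and the AFB5 group the up
    gradient.
    """
    edges: list[RegulatoryEdge] = []
    node_by_gradient = {"down": AFB1_GROUP_NODE, "up": AFB5_GROUP_NODE}
    opposite = {"down": "up", "up": "down"}
    for group in groups:
        if group.auxin_response == "down":
            source = node_by_gradient[opposite[group.gradient]]
            sign = "repression"
        else:
            source = node_by_gradient[group.gradient]
            sign = "activation"
        for gene in group.genes:
            edges.append(
                RegulatoryEdge(
                    source=source,
                    target=gene,
                    sign=sign,
                    evidence=f"afb-gradient-rule:{group.group_id}",
                )
            )
    return _dedupe(edges)


def merge_hormone_edges(
    nodes: Iterable[str],
    regulons: Sequence[RegulonTable],
    pathway_map: Mapping[str, Sequence[str]] = DEFAULT_PATHWAY_MAP,
) -> list[RegulatoryEdge]:
    """Connect pathway nodes to network genes found in hormone regulons.

    For each gene in ``nodes`` present in a regulon, one edge per mapped
    pathway node is emitted with sign up -> activation, down -> repression
    and the regulon identifier as evidence. Genes in no regulon get no
    edge.
    """
    node_set = set(nodes)
    missing = sorted({r.hormone for r in regulons} - set(pathway_map))
    if missing:
        raise ConfigError(
            "pathway_map has no entry for hormone(s): " + ", ".join(missing)
        )
    edges: list[RegulatoryEdge] = []
    for regulon in regulons:
        sign = "activation" if regulon.direction == "up" else "repression"
        for gene in sorted(regulon.genes & node_set):
            for pathway_node in pathway_map[regulon.hormone]:
                if pathway_node == gene:
                    continue
                edges.append(
                    RegulatoryEdge(
                        source=pathway_node,
                        target=gene,
                        sign=sign,
                        evidence=regulon.name,
                    )
                )
    return _dedupe(edges)


def collapse_edges(
    edges: Sequence[RegulatoryEdge],
    gene_to_subgroup: Mapping[str, str],
) -> list[RegulatoryEdge]:
    """Collapse per-gene edges onto subgroup nodes (presentation view).

    Targets found in the mapping are replaced by their subgroup ID;
    duplicate collapsed edges merge.
    """
    collapsed = [
        RegulatoryEdge(
            source=e.source,
            target=gene_to_subgroup.get(e.target, e.target),
            sign=e.sign,
            evidence=e.evidence,
        )
        for e in edges
    ]
    return _dedupe(collapsed)


def _dedupe(edges: Iterable[RegulatoryEdge]) -> list[RegulatoryEdge]:
    return sorted(
        set(edges), key=lambda e: (e.source, e.target, e.sign, e.evidence)
    )


def _validate(nodes: Sequence[NetworkNode], edges: Sequence[RegulatoryEdge]) -> None:
    ids = [n.node_id for n in nodes]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate node IDs in network")
    id_set = set(ids)
    for e in edges:
        for endpoint in (e.source, e.target):
            if endpoint not in id_set:
                raise ValidationError(
                    f"edge {e.source}->{e.target}: endpoint {endpoint!r} "
                    "is not a declared node"
                )


def export_network(
    nodes: Sequence[NetworkNode],
    edges: Sequence[RegulatoryEdge],
    format: str,
    path: str | Path,
) -> Path:
    """Write the network to ``path`` in SIF, GraphML or TSV form.

    Output is byte-stable across runs: nodes and edges are sorted before
    writing. The TSV format writes two files, ``<stem>.nodes.tsv`` and
    ``<stem>.edges.tsv``, and returns the node-table path.
    """
    _validate(nodes, edges)
    path = Path(path)
    nodes = sorted(nodes, key=lambda n: n.node_id)
    edges = _dedupe(edges)

    if format == "sif":
        lines = [f"{e.source} {e.sif_interaction} {e.target}" for e in edges]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        return path
    if format == "graphml":
        graph = nx.MultiDiGraph()
        for n in nodes:
            graph.add_node(
                n.node_id,
                germination_role=n.germination_role,
                source_table=n.source_table,
            )
        for e in edges:
            graph.add_edge(e.source, e.target, sign=e.sign, evidence=e.evidence)
        nx.write_graphml(graph, path, named_key_ids=True)
        return path
    if format == "tsv":
        node_path = path.with_suffix(".nodes.tsv")
        edge_path = path.with_suffix(".edges.tsv")
        node_lines = ["node_id\tgermination_role\tsource_table"] + [
            f"{n.node_id}\t{n.germination_role}\t{n.source_table}" for n in nodes
        ]
        edge_lines = ["source\ttarget\tsign\tevidence"] + [
            f"{e.source}\t{e.target}\t{e.sign}\t{e.evidence}" for e in edges
        ]
        node_path.write_text("\n".join(node_lines) + "\n")
        edge_path.write_text("\n".join(edge_lines) + "\n")
        return node_path
    raise ConfigError(f"unknown network format {format!r}")


def packaged_annotation_path() -> Path:
    """Path of the bundled gene-annotation table (subgroups 1A/1B/4A)."""
    return Path(resources.files("gradientnet").joinpath("data/table_annotations.tsv"))


def load_node_annotations(path: str | Path | None = None) -> list[NetworkNode]:
    """Read node annotations (gene_id, subgroup, role) into network nodes.

    Defaults to the packaged table transcribing the published
    seed-germination subgroup gene lists and their role classes.
    """
    import pandas as pd

    table_path = Path(path) if path is not None else packaged_annotation_path()
    frame = pd.read_csv(table_path, sep="\t", dtype=str, keep_default_na=False)
    for column in ("gene_id", "subgroup", "germination_role"):
        if column not in frame.columns:
            raise ValidationError(
                f"{table_path.name}: missing required column {column!r}"
            )
    return [
        NetworkNode(
            node_id=row.gene_id,
            germination_role=row.germination_role,
            source_table=row.subgroup,
        )
        for row in frame.itertuples(index=False)
    ]
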