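"""End-to-end orchestration: load -> normalize -> filter -> group ->
subgroup -> leave-one-out validation -> network, with a run manifest.

All stage outputs are deterministic: the same config and inputs produce
byte-identical tables and network files (the manifest's timestamp field
is the only exception, recorded for provenance).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import yaml

import gradientnet
from gradientnet.errors import ConfigError, GradientNetError
from gradientnet.expression_io import (
    RegulonTable,
    format_float,
    load_expression_table,
    load_regulon,
    resolve_regulon_conflicts,
)
from gradientnet.gradient_grouping import (
    AFB_LOCI,
    CANONICAL_AFB1_GROUP,
    CANONICAL_AFB5_GROUP,
    AfbGroupAssignment,
    assign_afb_groups,
    assign_groups,
)
from gradientnet.network_assembly import (
    AFB1_GROUP_NODE,
    AFB5_GROUP_NODE,
    DEFAULT_PATHWAY_MAP,
    NetworkNode,
    export_network,
    infer_afb_edges,
    load_node_annotations,
    merge_hormone_edges,
)
from gradientnet.normalization import (
    NormalizationConfig,
    filter_low_signal,
    normalize_dsc,
)
from gradientnet.subgrouping import (
    cluster_subgroups,
    loo_group_sum_r2,
    pairwise_r2,
    profiles_to_3point,
    split_degenerate,
)

__all__ = ["PipelineError", "RunManifest", "load_config", "run_pipeline"]

logger = logging.getLogger("gradientnet")

_HORMONE_KEYS = {
    "auxin_up": ("auxin", "up"),
    "auxin_down": ("auxin", "down"),
    "aba_up": ("ABA", "up"),
    "aba_down": ("ABA", "down"),
    "br_up": ("brassinosteroid", "up"),
    "br_down": ("brassinosteroid", "down"),
}


class PipelineError(GradientNetError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunManifest:
    config: dict[str, Any]
    input_checksums: dict[str, str]
    tool_version: str
    counts: dict[str, int]
    timestamp: str

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as handle:
        config = yaml.safe_load(handle)
    if not isinstance(config, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    if "expression_table" not in config:
        raise ConfigError(f"{path}: missing required key 'expression_table'")
    regulons = config.get("regulons", {})
    if "auxin_up" not in regulons or "auxin_down" not in regulons:
        raise ConfigError(
            f"{path}: regulons.auxin_up and regulons.auxin_down are required"
        )
    return config


def run_pipeline(
    config: Mapping[str, Any] | str | Path, out_dir: str | Path | None = None
) -> RunManifest:
    """Execute every stage and write the full output set to ``out_dir``.

    ``config`` is a mapping or a YAML path. On any stage failure, partial
    outputs are removed and a :class:`PipelineError` naming the stage is
    raised.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    config = dict(config)
    out_dir = Path(out_dir or config.get("out_dir", "gradientnet_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, text: str) -> Path:
        path = out_dir / name
        path.write_text(text)
        written.append(path)
        return path

    try:
        return _run(config, out_dir, emit)
    except Exception:
        for name in ("net.sif", "net.graphml", "net.nodes.tsv", "net.edges.tsv", "manifest.json"):
            written.append(out_dir / name)
        for path in written:
            path.unlink(missing_ok=True)
        raise


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc

        return inner

    return wrap


def _run(config: dict[str, Any], out_dir: Path, emit) -> RunManifest:
    norm_config = NormalizationConfig(
        area_ratio=float(config.get("area_ratio", 26.8)),
        low_signal_threshold=float(config.get("low_signal_threshold", 10.0)),
    )
    tie_epsilon = float(config.get("tie_epsilon", 0.0))
    r2_min = float(config.get("r2_min", 0.90))
    linkage = config.get("linkage", "complete")
    sign_constraint = config.get("sign_constraint", "any")

    expr_path = Path(config["expression_table"])
    regulon_paths = {k: Path(v) for k, v in config.get("regulons", {}).items()}
    checksums: dict[str, str] = {}

    # --- load ---------------------------------------------------------
    @_stage("load")
    def stage_load():
        if not expr_path.exists():
            raise FileNotFoundError(f"expression table not found: {expr_path}")
        checksums[str(expr_path)] = _sha256(expr_path)
        profiles = load_expression_table(expr_path)
        regulons: dict[str, RegulonTable] = {}
        for key, path in regulon_paths.items():
            if key not in _HORMONE_KEYS:
                raise ConfigError(f"unknown regulon key {key!r}")
            if not path.exists():
                raise FileNotFoundError(f"regulon file not found: {path}")
            checksums[str(path)] = _sha256(path)
            hormone, direction = _HORMONE_KEYS[key]
            regulons[key] = load_regulon(path, hormone, direction)
        auxin_up, auxin_down, conflicts = resolve_regulon_conflicts(
            regulons["auxin_up"], regulons["auxin_down"]
        )
        regulons["auxin_up"], regulons["auxin_down"] = auxin_up, auxin_down
        return profiles, regulons, conflicts

    profiles, regulons, regulon_conflicts = stage_load()
    logger.info("loaded %d profiles", len(profiles))

    # --- normalize / filter ------------------------------------------
    @_stage("normalize")
    def stage_normalize():
        return normalize_dsc(profiles, norm_config)

    normalized = stage_normalize()

    @_stage("filter")
    def stage_filter():
        return filter_low_signal(normalized, norm_config)

    kept, dropped = stage_filter()
    logger.info("low-signal filter: kept %d, dropped %d", len(kept), len(dropped))

    # --- group --------------------------------------------------------
    @_stage("group")
    def stage_group():
        groups, excluded = assign_groups(
            kept, regulons["auxin_up"], regulons["auxin_down"], tie_epsilon
        )
        afb_profiles = {p.gene_id: p for p in normalized}
        by_locus = {name: afb_profiles.get(locus) for name, locus in AFB_LOCI.items()}
        if all(p is not None for p in by_locus.values()):
            afb = assign_afb_groups(by_locus, tie_epsilon)
        else:
            warnings.warn(
                "AFB loci absent from the expression table; using the "
                "canonical AFB partition",
                stacklevel=2,
            )
            afb = AfbGroupAssignment(
                CANONICAL_AFB1_GROUP, CANONICAL_AFB5_GROUP, derived_from_data=False
            )
        return groups, excluded, afb

    groups, excluded, afb = stage_group()
    profile_by_gene = {p.gene_id: p for p in kept}
    group_lines = ["gene_id\tgroup_id\tauxin_response\tgradient\tfun\tcsc\tdsc_norm"]
    for group in groups:
        for gene in group.genes:
            p = profile_by_gene[gene]
            group_lines.append(
                f"{gene}\t{group.group_id}\t{group.auxin_response}\t"
                f"{group.gradient}\t{format_float(p.fun)}\t{format_float(p.csc)}\t"
                f"{format_float(p.dsc_norm)}"
            )
    emit("groups.tsv", "\n".join(group_lines) + "\n")
    excl_lines = ["gene_id\treason"] + [f"{e.gene_id}\t{e.reason}" for e in excluded]
    emit("excluded.tsv", "\n".join(excl_lines) + "\n")

    # --- subgroup -----------------------------------------------------
    @_stage("subgroup")
    def stage_subgroup():
        triples = profiles_to_3point(kept)
        all_subgroups = []
        matrix_lines = ["group_id\tgene_a\tgene_b\tr2"]
        degenerate_report: list[str] = []
        for group in groups:
            usable, degenerate = split_degenerate(group.genes, triples)
            degenerate_report.extend(degenerate)
            for i, a in enumerate(usable):
                for b in usable[i + 1 :]:
                    r2 = pairwise_r2(triples[a], triples[b])
                    matrix_lines.append(
                        f"{group.group_id}\t{a}\t{b}\t{format_float(r2)}"
                    )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                all_subgroups.extend(
                    cluster_subgroups(group, triples, r2_min, linkage, sign_constraint)
                )
        return all_subgroups, matrix_lines, triples, degenerate_report

    subgroups, matrix_lines, triples, degenerate_report = stage_subgroup()
    sub_lines = ["gene_id\tsubgroup_id\tmin_pairwise_r2"]
    for sg in subgroups:
        for gene in sg.members:
            sub_lines.append(
                f"{gene}\t{sg.subgroup_id}\t{format_float(sg.min_pairwise_r2)}"
            )
    for gene in degenerate_report:
        sub_lines.append(f"{gene}\t-\tdegenerate")
    emit("subgroups.tsv", "\n".join(sub_lines) + "\n")
    emit("r2_matrix.tsv", "\n".join(matrix_lines) + "\n")

    # --- validate (leave-one-out sums) --------------------------------
    @_stage("validate")
    def stage_validate():
        lines = ["subgroup_id\texcluded_gene\tloo_r2"]
        for sg in subgroups:
            if len(sg.members) < 2:
                continue
            excluded_gene = sg.members[0]  # smallest ID; published pick arbitrary
            r2 = loo_group_sum_r2(sg, triples, excluded_gene)
            lines.append(f"{sg.subgroup_id}\t{excluded_gene}\t{format_float(r2)}")
        return lines

    emit("loo_validation.tsv", "\n".join(stage_validate()) + "\n")

    # --- network ------------------------------------------------------
    @_stage("network")
    def stage_network():
        pathway_map = {
            k: tuple(v)
            for k, v in config.get(
                "pathway_map",
                {h: list(v) for h, v in DEFAULT_PATHWAY_MAP.items()},
            ).items()
        }
        afb_edges = infer_afb_edges(groups, afb)
        hormone_regulons = [
            regulons[k] for k in sorted(regulons) if not k.startswith("auxin")
        ]
        gene_nodes = sorted({g for group in groups for g in group.genes})
        hormone_edges = merge_hormone_edges(gene_nodes, hormone_regulons, pathway_map)
        edges = sorted(
            set(afb_edges + hormone_edges),
            key=lambda e: (e.source, e.target, e.sign, e.evidence),
        )

        annotation_path = config.get("annotations")
        try:
            annotated = {
                n.node_id: n for n in load_node_annotations(annotation_path)
            }
        except FileNotFoundError:
            annotated = {}
        nodes = [
            NetworkNode(AFB1_GROUP_NODE, "unknown", "afb"),
            NetworkNode(AFB5_GROUP_NODE, "unknown", "afb"),
        ]
        for pathway_nodes in pathway_map.values():
            for node_id in pathway_nodes:
                if node_id not in (AFB1_GROUP_NODE, AFB5_GROUP_NODE):
                    nodes.append(NetworkNode(node_id, "unknown", "pathway"))
        for gene in gene_nodes:
            nodes.append(
                annotated.get(gene, NetworkNode(gene, "unknown", "expression"))
            )
        unique_nodes = sorted(
            {n.node_id: n for n in nodes}.values(), key=lambda n: n.node_id
        )
        export_network(unique_nodes, edges, "sif", out_dir / "net.sif")
        export_network(unique_nodes, edges, "graphml", out_dir / "net.graphml")
        export_network(unique_nodes, edges, "tsv", out_dir / "net")
        written_names = ["net.sif", "net.graphml", "net.nodes.tsv", "net.edges.tsv"]
        return edges, unique_nodes, written_names

    edges, nodes, _network_files = stage_network()

    counts = {
        "loaded": len(profiles),
        "kept": len(kept),
        "dropped": len(dropped),
        "grouped": sum(len(g) for g in groups),
        "excluded": len(excluded),
        "regulon_conflicts": len(regulon_conflicts),
        "subgroups": len(subgroups),
        "subgrouped_genes": sum(len(s) for s in subgroups),
        "nodes": len(nodes),
        "edges": len(edges),
    }
    assert counts["loaded"] == counts["kept"] + counts["dropped"]
    manifest = RunManifest(
        config={k: str(v) if isinstance(v, Path) else v for k, v in config.items()},
        input_checksums=checksums,
        tool_version=gradientnet.__version__,
        counts=counts,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest
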