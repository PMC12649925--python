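"""Plain-text I/O: TSV/CSV matrices, id lists, truth JSON and Cytoscape
network exports (SIF, GraphML, node-attribute CSV)."""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    GroundTruthGRN,
    GroundTruthMetabolome,
    HierarchicalNetwork,
    MetaboliteMatrix,
)

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_expression",
    "write_expression",
    "read_metabolome",
    "write_metabolome",
    "read_id_list",
    "write_id_list",
    "write_truth_grn",
    "read_truth_grn",
    "write_truth_metabolome",
    "write_sif",
    "write_graphml",
    "write_node_attributes",
]


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Features x samples TSV with the feature id in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")


def read_expression(matrix_path: str | Path, metadata_path: str | Path, unit: str = "expression") -> ExpressionMatrix:
    values = read_matrix_tsv(matrix_path)
    meta = pd.read_csv(metadata_path, index_col=0)
    return ExpressionMatrix(values=values, metadata=meta, unit=unit)


def write_expression(expr: ExpressionMatrix, matrix_path: str | Path, metadata_path: str | Path) -> None:
    write_matrix_tsv(expr.values, matrix_path)
    Path(metadata_path).parent.mkdir(parents=True, exist_ok=True)
    expr.metadata.to_csv(metadata_path, index_label="sample_id")


def read_metabolome(
    matrix_path: str | Path,
    metadata_path: str | Path,
    class_path: str | Path | None = None,
) -> MetaboliteMatrix:
    values = read_matrix_tsv(matrix_path)
    meta = pd.read_csv(metadata_path, index_col=0)
    classes = {}
    if class_path is not None:
        cls = pd.read_csv(class_path, index_col=0)
        classes = cls.iloc[:, 0].to_dict()
    return MetaboliteMatrix(intensities=values, metadata=meta, class_labels=classes)


def write_metabolome(matrix: MetaboliteMatrix, matrix_path: str | Path, metadata_path: str | Path, class_path: str | Path | None = None) -> None:
    write_matrix_tsv(matrix.intensities, matrix_path)
    matrix.metadata.to_csv(metadata_path, index_label="sample_id")
    if class_path is not None and matrix.class_labels:
        pd.Series(matrix.class_labels, name="class").rename_axis("metabolite_id").to_csv(class_path)


def read_id_list(path: str | Path) -> list[str]:
    """One id per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_id_list(ids, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(str(i) for i in ids) + "\n")


def write_truth_grn(truth: GroundTruthGRN, path: str | Path) -> None:
    payload = {
        "layer_assignments": truth.layer_assignments,
        "edges": [[r, t, e] for r, t, e in truth.edges],
        "pathway_genes": truth.pathway_genes,
        "decoy_tfs": sorted(truth.decoy_tfs),
        "baselines": truth.baselines,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth_grn(path: str | Path) -> GroundTruthGRN:
    d = json.loads(Path(path).read_text())
    return GroundTruthGRN(
        layer_assignments={k: int(v) for k, v in d["layer_assignments"].items()},
        edges=[(r, t, float(e)) for r, t, e in d["edges"]],
        pathway_genes=d["pathway_genes"],
        decoy_tfs=set(d["decoy_tfs"]),
        baselines=d.get("baselines", {}),
    )


def write_truth_metabolome(truth: GroundTruthMetabolome, path: str | Path) -> None:
    payload = {
        "differential_ids": sorted(truth.differential_ids),
        "planted_log2fc": truth.planted_log2fc,
        "qc_cv_true": truth.qc_cv_true.to_dict(),
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=1))


def _network_graph(net: HierarchicalNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    for gene in net.pathway_genes:
        g.add_node(gene, role="pathway_gene", layer=0)
    for i, layer in enumerate(net.layers, start=1):
        for tf in layer:
            g.add_node(tf, role=f"tf_layer{i}", layer=i)
    for reg, tgt, w in net.tf_edges:
        g.add_edge(reg, tgt, interaction="regulates", weight=float(w))
    for gene, met, r, p in net.gene_metabolite_edges:
        if met not in g:
            g.add_node(met, role="metabolite", layer=-1)
        g.add_edge(gene, met, interaction="correlates", weight=float(r), p=float(p))
    return g


def write_sif(net: HierarchicalNetwork, path: str | Path) -> None:
    """Simple interaction format: source <tab> interaction <tab> target."""
    lines = [f"{reg}\tregulates\t{tgt}" for reg, tgt, _ in net.tf_edges]
    lines += [f"{gene}\tcorrelates\t{met}" for gene, met, _, _ in net.gene_metabolite_edges]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_graphml(net: HierarchicalNetwork, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(_network_graph(net), str(path))


def write_node_attributes(
    net: HierarchicalNetwork,
    path: str | Path,
    regulation_status: dict[str, str] | None = None,
) -> None:
    """Node-attribute CSV (id, role, layer, regulation) for Cytoscape import."""
    g = _network_graph(net)
    rows = []
    for node, data in g.nodes(data=True):
        rows.append(
            {
                "id": node,
                "role": data["role"],
                "layer": data["layer"],
                "regulation": (regulation_status or {}).get(node, "ns"),
            }
        )
    df = pd.DataFrame(rows).sort_values(["layer", "id"], ascending=[False, True])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
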