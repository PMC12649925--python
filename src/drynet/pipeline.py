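"""Configuration, validation and the end-to-end pipeline runner.

``run_pipeline`` wires the stages in the study's order — DEG screening
per stress timepoint against the day-0 control, the metabolite
imputation/QC/VIP screen, temporal K-means clustering, and the
hierarchical GRN build with metabolite linking — writing every result as
a plain TSV plus a JSON run manifest, so a run is fully auditable and
re-running a config reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clustering, grn, io, metabolome, transcript

logger = logging.getLogger("drynet")

__all__ = ["PipelineConfig", "validate_inputs", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths, thresholds and algorithm parameters for a pipeline run.

    Threshold defaults are the study's screening criteria: |log2FC| >= 1
    with FDR < 0.05 for genes; VIP > 1 with FC >= 2 or <= 0.5 for
    metabolites; QC CV < 0.5 retention; |r| >= 0.8 gene-metabolite links.
    """

    counts: str | None = None
    expression: str | None = None
    expression_metadata: str | None = None
    metabolome: str | None = None
    metabolome_metadata: str | None = None
    metabolite_classes: str | None = None
    tf_list: str | None = None
    pathway_genes: str | None = None

    lfc_min: float = 1.0
    alpha: float = 0.05
    vip_min: float = 1.0
    fc_up: float = 2.0
    fc_down: float = 0.5
    cv_max: float = 0.5
    r_min: float = 0.8

    k_impute: int = 10
    k_clusters: int = 8
    cluster_restarts: int = 50
    n_trees: int = 1000
    drop_fraction: float = 0.1
    n_layers: int = 2
    edges_per_target: int = 3
    max_layer_size: int | None = None
    n_orthogonal: int = 1
    control_group: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Report-only validation; returns a list of violation messages."""
    violations: list[str] = []
    for name in ("expression", "expression_metadata", "metabolome", "metabolome_metadata", "tf_list", "pathway_genes"):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            violations.append(f"{name}: file not found: {path}")
    for thr in ("lfc_min", "alpha", "vip_min", "fc_up", "fc_down", "cv_max", "r_min"):
        if getattr(config, thr) <= 0:
            violations.append(f"{thr} must be positive")

    if config.expression and config.expression_metadata and Path(config.expression).exists() and Path(config.expression_metadata).exists():
        values = io.read_matrix_tsv(config.expression)
        meta = pd.read_csv(config.expression_metadata, index_col=0)
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            violations.append(f"duplicated gene id(s): {dups[:5]}")
        uncovered = set(values.columns) - set(meta.index)
        if uncovered:
            violations.append(f"expression samples missing from metadata: {sorted(uncovered)[:5]}")
        neg = (values.values < 0)
        if neg.any():
            i, j = [x[0] for x in neg.nonzero()]
            violations.append(f"negative expression value at ({values.index[i]}, {values.columns[j]})")

    if config.metabolome and config.metabolome_metadata and Path(config.metabolome).exists() and Path(config.metabolome_metadata).exists():
        values = io.read_matrix_tsv(config.metabolome)
        meta = pd.read_csv(config.metabolome_metadata, index_col=0)
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            violations.append(f"duplicated metabolite id(s): {dups[:5]}")
        uncovered = set(values.columns) - set(meta.index)
        if uncovered:
            violations.append(f"metabolome samples missing from metadata: {sorted(uncovered)[:5]}")
        if "is_qc" in meta.columns:
            n_qc = int(meta.loc[list(set(values.columns) & set(meta.index)), "is_qc"].astype(bool).sum())
            if n_qc < 3:
                violations.append(f"fewer than 3 QC samples ({n_qc})")
        else:
            violations.append("metabolome metadata lacks is_qc column")
        obs = values.values
        neg = (obs < 0) & ~pd.isna(obs)
        if neg.any():
            i, j = [x[0] for x in neg.nonzero()]
            violations.append(f"negative intensity at ({values.index[i]}, {values.columns[j]})")
    return violations


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run screen -> cluster -> GRN on the configured inputs.

    Requires expression (or counts), metabolome, TF list and pathway gene
    list paths.  Writes per-stage TSVs, network exports, a ``manifest.json``
    (inputs, parameters, stage list, output checksums) and ``run.log``
    under ``out_dir``; on a stage failure, partial outputs move to
    ``out_dir/failed`` and the error is re-raised with the stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    required = {
        "counts or expression": config.counts or config.expression,
        "expression_metadata": config.expression_metadata,
        "metabolome": config.metabolome,
        "metabolome_metadata": config.metabolome_metadata,
        "tf_list": config.tf_list,
        "pathway_genes": config.pathway_genes,
    }
    missing = [k for k, v in required.items() if not v]
    if missing:
        raise ValueError(f"config missing required inputs: {missing}")
    hard = [v for v in validate_inputs(config) if "not found" in v or "duplicated" in v]
    if hard:
        raise ValueError("input validation failed: " + "; ".join(hard))

    manifest: dict = {
        "parameters": config.to_dict(),
        "seed": config.seed,
        "stages": [],
        "outputs": {},
    }
    stage = "setup"
    try:
        # ---- stage 1: transcript screen -------------------------------
        stage = "screen_deg"
        logger.info("stage %s: thresholds |log2FC|>=%s, FDR<%s", stage, config.lfc_min, config.alpha)
        expr = io.read_expression(
            config.expression or config.counts,
            config.expression_metadata,
            unit="counts" if config.counts else "expression",
        )
        meta = expr.metadata.loc[expr.values.columns]
        groups = sorted(meta["group"].unique(), key=str)
        control = config.control_group or groups[0]
        deg_sets: dict[str, set[str]] = {}
        for g in groups:
            if g == control:
                continue
            a = list(meta.index[meta["group"] == control])
            b = list(meta.index[meta["group"] == g])
            res = transcript.nb_wald_test(expr.values.round().astype(int), a, b)
            res = transcript.screen_degs(res, lfc_min=config.lfc_min, alpha=config.alpha)
            path = out / f"deg_{g}_vs_{control}.tsv"
            res.to_csv(path, sep="\t", index_label="feature_id")
            manifest["outputs"][path.name] = _file_checksum(path)
            deg_sets[g] = set(res.index[res["status"] != "ns"])
            logger.info("contrast %s vs %s: %d DEGs", g, control, len(deg_sets[g]))
        if len(deg_sets) >= 2:
            shared, exclusive = transcript.shared_exclusive_sets(deg_sets)
            io.write_id_list(sorted(shared), out / "deg_shared.txt")
            manifest["outputs"]["deg_shared.txt"] = _file_checksum(out / "deg_shared.txt")
            for lab, ids in exclusive.items():
                io.write_id_list(sorted(ids), out / f"deg_exclusive_{lab}.txt")
        manifest["stages"].append(stage)

        # ---- stage 2: metabolome screen + clustering ------------------
        stage = "screen_dam"
        metab = io.read_metabolome(
            config.metabolome, config.metabolome_metadata, config.metabolite_classes
        )
        logger.info(
            "stage %s: KNN k=%d, CV<%s, VIP>%s, FC>=%s or <=%s",
            stage, config.k_impute, config.cv_max, config.vip_min, config.fc_up, config.fc_down,
        )
        imputed = metabolome.knn_impute(metab, k=config.k_impute)
        retained, dropped = metabolome.qc_cv_filter(imputed, cv_max=config.cv_max)
        io.write_id_list(dropped, out / "dam_qc_dropped.txt")
        mmeta = retained.metadata.loc[retained.intensities.columns]
        bio = mmeta.index[~mmeta["is_qc"].astype(bool)]
        mgroups = sorted(mmeta.loc[bio, "group"].unique(), key=str)
        mcontrol = config.control_group if config.control_group in mgroups else mgroups[0]
        dam_sets: dict[str, set[str]] = {}
        for g in mgroups:
            if g == mcontrol:
                continue
            sel = bio[mmeta.loc[bio, "group"].isin([mcontrol, g])]
            x = retained.intensities[sel].T.values
            y = (mmeta.loc[sel, "group"] == g).astype(int).values
            model = metabolome.oplsda_fit(
                x, y, n_orthogonal=config.n_orthogonal,
                variable_ids=list(retained.intensities.index), sample_ids=list(sel),
            )
            vip = metabolome.vip_scores(model)
            fc = metabolome.fold_changes(retained, mcontrol, g)
            dams = metabolome.screen_dams(
                vip, fc, vip_min=config.vip_min, fc_up=config.fc_up, fc_down=config.fc_down
            )
            path = out / f"dam_{g}_vs_{mcontrol}.tsv"
            dams.to_csv(path, sep="\t", index_label="metabolite_id")
            manifest["outputs"][path.name] = _file_checksum(path)
            dam_sets[g] = set(dams.index[dams["status"] != "ns"])
            logger.info("contrast %s vs %s: %d DAMs", g, mcontrol, len(dam_sets[g]))
        if len(dam_sets) >= 2:
            shared_dams, _ = transcript.shared_exclusive_sets(dam_sets)
            io.write_id_list(sorted(shared_dams), out / "dam_shared.txt")
        manifest["stages"].append(stage)

        stage = "cluster"
        profiles = clustering.profile_matrix(retained)
        if len(profiles) >= config.k_clusters:
            cl = clustering.kmeans_cluster(
                profiles, k=config.k_clusters, restarts=config.cluster_restarts, seed=config.seed
            )
            pd.Series(cl.assignments, name="cluster").rename_axis("metabolite_id").to_csv(
                out / "clusters.tsv", sep="\t"
            )
            cl.centroids.rename_axis("cluster").to_csv(out / "cluster_centroids.tsv", sep="\t")
            manifest["outputs"]["clusters.tsv"] = _file_checksum(out / "clusters.tsv")
            logger.info("stage %s: k=%d, inertia %.4f", stage, cl.k, cl.inertia)
        else:
            logger.warning("too few profiles (%d) for k=%d; skipping clustering", len(profiles), config.k_clusters)
        manifest["stages"].append(stage)

        # ---- stage 3: hierarchical GRN --------------------------------
        stage = "grn"
        tfs = io.read_id_list(config.tf_list)
        pathway = io.read_id_list(config.pathway_genes)
        logger.info(
            "stage %s: n_layers=%d, n_trees=%d, drop_fraction=%s, |r|>=%s",
            stage, config.n_layers, config.n_trees, config.drop_fraction, config.r_min,
        )
        net = grn.build_hierarchy(
            expr,
            candidate_tfs=tfs,
            pathway_genes=pathway,
            n_layers=config.n_layers,
            drop_fraction=config.drop_fraction,
            n_trees=config.n_trees,
            edges_per_target=config.edges_per_target,
            max_layer_size=config.max_layer_size,
            seed=config.seed,
        )
        net.gene_metabolite_edges = grn.link_metabolites(
            expr, retained, genes=pathway, r_min=config.r_min, alpha=config.alpha
        )
        io.write_sif(net, out / "network.sif")
        io.write_graphml(net, out / "network.graphml")
        io.write_node_attributes(net, out / "network_nodes.csv")
        manifest["outputs"]["network.sif"] = _file_checksum(out / "network.sif")
        summary = grn.network_summary(net)
        (out / "network_summary.json").write_text(json.dumps(summary, indent=1))
        logger.info("stage %s: %s", stage, summary)
        manifest["stages"].append(stage)

        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        return out
    except Exception as err:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        for f in out.iterdir():
            if f.is_file() and f.name != "run.log":
                shutil.move(str(f), failed / f.name)
        logger.error("stage %s failed: %s", stage, err)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    finally:
        logger.removeHandler(handler)
        handler.close()
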