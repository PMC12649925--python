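"""Shared in-memory containers for the drought multi-omics pipeline.

Matrices follow the omics convention of features (genes / metabolites) on
rows and samples on columns, carried as :class:`pandas.DataFrame` with the
feature ids on the index.  Sample metadata is a DataFrame indexed by sample
id with at least ``timepoint``, ``replicate`` and ``group`` columns (plus
``is_qc`` for metabolome runs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "MetaboliteMatrix",
    "GroundTruthGRN",
    "GroundTruthMetabolome",
    "HierarchicalNetwork",
    "GmmFit",
    "OplsModel",
    "ProfileClustering",
]


def _check_metadata(values: pd.DataFrame, metadata: pd.DataFrame, required: Sequence[str]) -> None:
    missing = set(values.columns) - set(metadata.index)
    if missing:
        raise ValueError(f"metadata does not cover samples: {sorted(missing)[:5]}")
    for col in required:
        if col not in metadata.columns:
            raise ValueError(f"metadata lacks required column {col!r}")
    if values.index.has_duplicates:
        dup = values.index[values.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated feature ids: {dup[:5]}")
    if values.columns.has_duplicates:
        raise ValueError("duplicated sample ids")


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix with per-sample metadata.

    ``unit`` tags the scale: ``"expression"`` (simulated abundances),
    ``"counts"`` (NB read counts) or ``"fpkm"``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    unit: str = "expression"

    def __post_init__(self) -> None:
        _check_metadata(self.values, self.metadata, ("timepoint", "replicate", "group"))
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        meta = self.metadata.loc[self.values.columns]
        return list(meta.index[meta["group"] == group])


@dataclass
class MetaboliteMatrix:
    """Metabolites x samples peak-area matrix.

    ``missing_mask`` is True where the intensity is undefined (the stored
    value there is NaN).  QC samples are flagged in ``metadata["is_qc"]``
    and are excluded from group contrasts.
    """

    intensities: pd.DataFrame
    metadata: pd.DataFrame
    missing_mask: pd.DataFrame | None = None
    class_labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_metadata(self.intensities, self.metadata, ("group", "is_qc"))
        if self.missing_mask is None:
            self.missing_mask = self.intensities.isna()
        if not self.missing_mask.index.equals(self.intensities.index) or not self.missing_mask.columns.equals(
            self.intensities.columns
        ):
            raise ValueError("missing_mask must align with intensities")
        observed = self.intensities.values[~self.missing_mask.values]
        if (observed < 0).any():
            raise ValueError("intensities must be non-negative")

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def qc_samples(self) -> list[str]:
        meta = self.metadata.loc[self.intensities.columns]
        return list(meta.index[meta["is_qc"].astype(bool)])

    @property
    def biological_samples(self) -> list[str]:
        meta = self.metadata.loc[self.intensities.columns]
        return list(meta.index[~meta["is_qc"].astype(bool)])


@dataclass
class GroundTruthGRN:
    """Planted regulatory structure emitted by the hierarchy simulator.

    ``layer_assignments`` maps TF id to layer index (1 = immediately above
    the pathway genes, 2 = top).  ``edges`` are (regulator, target, signed
    effect) with the regulator exactly one layer above its target (pathway
    genes sit at layer 0).  ``baselines`` and ``signals`` record the
    deterministic part of each profile so noise-free identities can be
    checked exactly.
    """

    layer_assignments: dict[str, int]
    edges: list[tuple[str, str, float]]
    pathway_genes: list[str]
    decoy_tfs: set[str]
    baselines: dict[str, float] = field(default_factory=dict)
    signals: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        layer_of = dict(self.layer_assignments)
        layer_of.update({g: 0 for g in self.pathway_genes})
        for reg, tgt, eff in self.edges:
            if eff == 0:
                raise ValueError(f"zero effect size on edge {reg}->{tgt}")
            if layer_of[reg] != layer_of[tgt] + 1:
                raise ValueError(f"edge {reg}->{tgt} does not span adjacent layers")
            if reg in self.decoy_tfs or tgt in self.decoy_tfs:
                raise ValueError("decoy TF appears in a planted edge")

    def tfs_in_layer(self, layer: int) -> set[str]:
        return {t for t, l in self.layer_assignments.items() if l == layer}


@dataclass
class GroundTruthMetabolome:
    """Planted differential structure emitted by the metabolome simulator."""

    differential_ids: set[str]
    planted_log2fc: dict[str, float]
    missing_mask: pd.DataFrame
    qc_cv_true: pd.Series

    def __post_init__(self) -> None:
        if set(self.planted_log2fc) != set(self.differential_ids):
            raise ValueError("planted_log2fc keys must equal differential_ids")
        if any(v == 0 for v in self.planted_log2fc.values()):
            raise ValueError("planted log2fc must be nonzero on differential ids")


@dataclass
class HierarchicalNetwork:
    """Multi-layer hierarchical GRN: ordered TF layers above a pathway base.

    ``layers[0]`` is layer 1 (adjacent to the pathway genes); layers ascend.
    ``tf_edges`` are (regulator, target, weight) spanning exactly adjacent
    layers (layer-1 TFs regulate pathway genes).  ``gene_metabolite_edges``
    are (gene, metabolite, r, p) Pearson links.
    """

    layers: list[list[str]]
    tf_edges: list[tuple[str, str, float]]
    pathway_genes: list[str]
    gene_metabolite_edges: list[tuple[str, str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set(self.pathway_genes)
        for layer in self.layers:
            overlap = seen & set(layer)
            if overlap:
                raise ValueError(f"node(s) in more than one layer: {sorted(overlap)[:5]}")
            seen |= set(layer)
        layer_of = {g: 0 for g in self.pathway_genes}
        for i, layer in enumerate(self.layers, start=1):
            layer_of.update({t: i for t in layer})
        for reg, tgt, _ in self.tf_edges:
            if layer_of.get(reg, -1) != layer_of.get(tgt, -2) + 1:
                raise ValueError(f"tf_edge {reg}->{tgt} does not span adjacent layers")
        for _, _, r, _ in self.gene_metabolite_edges:
            if abs(r) > 1 + 1e-12:
                raise ValueError("correlation outside [-1, 1]")

    def layer_of(self, node: str) -> int | None:
        if node in self.pathway_genes:
            return 0
        for i, layer in enumerate(self.layers, start=1):
            if node in layer:
                return i
        return None


@dataclass
class GmmFit:
    """A fitted 1-D Gaussian mixture (EM), with the log-likelihood trace."""

    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    responsibilities: np.ndarray
    log_likelihood_trace: list[float]

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.weights)) - 1.0) > 1e-8:
            raise ValueError("mixture weights must sum to 1")
        row_sums = self.responsibilities.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-8):
            raise ValueError("responsibilities must sum to 1 per point")

    @property
    def n_components(self) -> int:
        return len(self.means)

    @property
    def log_likelihood(self) -> float:
        return self.log_likelihood_trace[-1]


@dataclass
class OplsModel:
    """Fitted O-PLS discriminant model (NIPALS).

    The predictive weight vector has unit norm; each orthogonal score
    vector is orthogonal to the centered class vector.  ``center`` and
    ``scale`` record the per-variable preprocessing applied to X.
    """

    variable_ids: list[str]
    sample_ids: list[str]
    predictive_scores: np.ndarray
    predictive_weights: np.ndarray
    predictive_loadings: np.ndarray
    y_loading: float
    orthogonal_scores: np.ndarray
    orthogonal_loadings: np.ndarray
    y_variance_explained: float
    center: np.ndarray
    scale: np.ndarray
    y_centered: np.ndarray

    def __post_init__(self) -> None:
        if abs(float(np.linalg.norm(self.predictive_weights)) - 1.0) > 1e-8:
            raise ValueError("predictive weights must have unit norm")
        for i in range(self.orthogonal_scores.shape[1]):
            if abs(float(self.orthogonal_scores[:, i] @ self.y_centered)) > 1e-8:
                raise ValueError("orthogonal scores must be orthogonal to y")

    @property
    def n_orthogonal(self) -> int:
        return self.orthogonal_scores.shape[1]


@dataclass
class ProfileClustering:
    """K-means result over temporal z-score profiles."""

    k: int
    assignments: dict[str, int]
    centroids: pd.DataFrame
    inertia: float
    inertia_trace: list[float] = field(default_factory=list)

    def members(self, cluster: int) -> list[str]:
        return [m for m, c in self.assignments.items() if c == cluster]
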