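"""Bottom-up weighted random-forest construction of a multi-layer
hierarchical gene regulatory network (ML-hGRN).

The construction starts from a base layer of pathway genes (e.g. the
flavonoid-biosynthesis or lipid-metabolism structural genes) and works
upward:

1.  For each target gene, a random-forest regression of the target's
    expression on all candidate TF profiles yields per-TF importance
    values.  The least important fraction of TFs is eliminated and the
    forest re-fit on the survivors; elimination repeats until a single TF
    remains (recursive backward elimination).  Each TF's importances over
    the iterations it survived are averaged, giving a per-(TF, target)
    aggregated importance.
2.  Aggregated importances are summed across all targets into a per-TF
    pathway score, and a two-component 1-D Gaussian mixture separates the
    high-scoring (regulatory) component from background; TFs whose
    posterior for the higher-mean component is at least 0.5 form the
    layer immediately above the targets.
3.  The selected layer becomes the new target set and the procedure
    repeats on the remaining TFs, stacking layers until the requested
    depth.

Gene-metabolite links are added by Pearson correlation with BH FDR
control.  Networks export to SIF / GraphML / node-attribute CSV for
Cytoscape.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.ensemble import RandomForestRegressor

from .datatypes import ExpressionMatrix, GmmFit, HierarchicalNetwork, MetaboliteMatrix
from .transcript import bh_fdr

__all__ = [
    "rf_importance",
    "bwerf_rank",
    "pathway_scores",
    "gmm_fit_1d",
    "select_layer_tfs",
    "permutation_separation_p",
    "build_hierarchy",
    "link_metabolites",
    "network_summary",
]

VARIANCE_FLOOR = 1e-10


def rf_importance(
    target_profile: np.ndarray | pd.Series,
    tf_profiles: pd.DataFrame,
    n_trees: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """Random-forest importance of each TF for one target gene.

    Fits a random-forest regression of the target on the TF expression
    matrix (TFs x samples) with ``sqrt(m)`` feature subsampling and
    returns impurity-decrease importances normalized to sum to 1.  TF
    columns are ordered canonically by id before fitting, so the result
    is invariant to the caller's row order at a fixed seed.  A constant
    target carries no signal: importances are uniform, with a warning.
    """
    y = np.asarray(target_profile, dtype=float)
    if tf_profiles.shape[0] < 2:
        raise ValueError("need at least 2 candidate TFs")
    if len(y) < 6 or tf_profiles.shape[1] != len(y):
        raise ValueError("need >= 6 samples and matching sample counts")
    order = sorted(tf_profiles.index)
    x = tf_profiles.loc[order].values.T  # samples x TFs, canonical order
    if np.ptp(y) < 1e-12:
        warnings.warn("constant target profile; importances are uniform")
        imp = np.full(len(order), 1.0 / len(order))
    else:
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=int(seed) % (2**31 - 1),
            n_jobs=1,
        )
        rf.fit(x, y)
        imp = rf.feature_importances_
        s = imp.sum()
        imp = imp / s if s > 0 else np.full(len(order), 1.0 / len(order))
    return pd.Series(imp, index=order, name="importance").reindex(tf_profiles.index)


def bwerf_rank(
    expr: ExpressionMatrix,
    candidate_tfs: list[str],
    pathway_genes: list[str],
    drop_fraction: float = 0.1,
    n_trees: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Recursive random-forest elimination ranking of TFs over pathway genes.

    For every pathway gene the candidate TFs are iteratively re-ranked:
    each iteration fits :func:`rf_importance` on the surviving TF set,
    records every survivor's importance, then removes the
    ``floor(drop_fraction * survivors)`` (at least one) lowest-importance
    TFs, so ``drop_fraction=0.5`` halves the list each round
    (``ceil(log2 m)`` rounds in total).  Elimination stops when one TF
    remains.  The aggregated
    importance of a (TF, gene) pair is the mean importance over the
    iterations the TF survived.

    Returns a tidy DataFrame with columns
    ``tf, target, importance, iterations_survived``; the per-TF pathway
    score used for layer selection is
    ``table.groupby("tf")["importance"].sum()``.
    """
    if len(candidate_tfs) < 2:
        raise ValueError("need at least 2 candidate TFs")
    if not 0 < drop_fraction < 1:
        raise ValueError("drop_fraction must be in (0, 1)")
    missing = set(pathway_genes) - set(expr.values.index)
    if missing:
        raise KeyError(f"pathway gene(s) absent from expression matrix: {sorted(missing)}")
    missing_tf = set(candidate_tfs) - set(expr.values.index)
    if missing_tf:
        raise KeyError(f"candidate TF(s) absent from expression matrix: {sorted(missing_tf)}")

    ss = np.random.SeedSequence(seed)
    rows = []
    for gene, gene_ss in zip(pathway_genes, ss.spawn(len(pathway_genes))):
        y = expr.values.loc[gene].values
        surviving = list(candidate_tfs)
        records: dict[str, list[float]] = {t: [] for t in candidate_tfs}
        it_seeds = iter(gene_ss.generate_state(1000))
        while len(surviving) >= 2:
            imp = rf_importance(
                y, expr.values.loc[surviving], n_trees=n_trees, seed=int(next(it_seeds))
            )
            for t, v in imp.items():
                records[t].append(float(v))
            n_drop = max(1, math.floor(drop_fraction * len(surviving)))
            ranked = sorted(surviving, key=lambda t: (imp[t], t))
            surviving = [t for t in surviving if t not in set(ranked[:n_drop])]
        for t in candidate_tfs:
            if records[t]:
                rows.append(
                    {
                        "tf": t,
                        "target": gene,
                        "importance": float(np.mean(records[t])),
                        "iterations_survived": len(records[t]),
                    }
                )
    return pd.DataFrame(rows, columns=["tf", "target", "importance", "iterations_survived"])


def pathway_scores(table: pd.DataFrame) -> pd.Series:
    """Per-TF pathway score: aggregated importance summed over targets."""
    return table.groupby("tf")["importance"].sum().rename("score")


def _em_loglik(x: np.ndarray, means: np.ndarray, variances: np.ndarray, weights: np.ndarray) -> tuple[float, np.ndarray]:
    log_comp = (
        np.log(weights)[None, :]
        - 0.5 * np.log(2 * np.pi * variances)[None, :]
        - 0.5 * (x[:, None] - means[None, :]) ** 2 / variances[None, :]
    )
    log_norm = special.logsumexp(log_comp, axis=1)
    resp = np.exp(log_comp - log_norm[:, None])
    return float(log_norm.sum()), resp


def gmm_fit_1d(
    values: np.ndarray | pd.Series,
    n_components: int = 2,
    n_init: int = 10,
    seed: int = 0,
    tol: float = 1e-10,
    max_iter: int = 500,
    init_params: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> GmmFit:
    """Fit a 1-D Gaussian mixture by EM, best of ``n_init`` initializations.

    Each initialization draws ``n_components`` distinct data points as
    starting means, with the sample variance and uniform weights; EM
    iterates until the log-likelihood improves by less than ``tol``.
    Variances are floored at 1e-10 to keep components from collapsing on
    a single point.  ``init_params`` (means, variances, weights) bypasses
    random initialization — useful for controlled comparisons.
    """
    x = np.asarray(values, dtype=float).ravel()
    if len(x) < 2 * n_components:
        raise ValueError("need at least 2 points per mixture component")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    def _run(means, variances, weights):
        means, variances, weights = (np.array(a, dtype=float) for a in (means, variances, weights))
        trace = []
        ll, resp = _em_loglik(x, means, variances, weights)
        trace.append(ll)
        for _ in range(max_iter):
            nk = resp.sum(axis=0)
            nk = np.maximum(nk, 1e-300)
            weights = nk / len(x)
            means = (resp * x[:, None]).sum(axis=0) / nk
            variances = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
            variances = np.maximum(variances, VARIANCE_FLOOR)
            ll_new, resp = _em_loglik(x, means, variances, weights)
            trace.append(ll_new)
            if ll_new - ll < tol:
                break
            ll = ll_new
        return means, variances, weights, resp, trace

    var0 = max(float(np.var(x)), VARIANCE_FLOOR)
    inits = []
    if init_params is not None:
        inits.append(init_params)
    else:
        for _ in range(n_init):
            idx = rng.choice(len(x), size=n_components, replace=False)
            inits.append((x[idx].copy(), np.full(n_components, var0), np.full(n_components, 1.0 / n_components)))

    best = None
    for m0, v0, w0 in inits:
        means, variances, weights, resp, trace = _run(m0, v0, w0)
        if best is None or trace[-1] > best[4][-1]:
            best = (means, variances, weights, resp, trace)
    means, variances, weights, resp, trace = best
    return GmmFit(
        means=means,
        variances=variances,
        weights=weights / weights.sum(),
        responsibilities=resp,
        log_likelihood_trace=trace,
    )


def select_layer_tfs(scores: pd.Series, gmm: GmmFit) -> set[str]:
    """TFs assigned to the high-score mixture component (posterior >= 0.5).

    The fit must be a 2-component mixture over exactly these scores.  If
    the two component means are numerically indistinguishable the mixture
    carries no separation; the top half of TFs by score is retained with
    a warning.
    """
    if len(scores) == 0:
        raise ValueError("empty score vector")
    if gmm.n_components != 2:
        raise ValueError("layer selection expects a 2-component mixture")
    if gmm.responsibilities.shape[0] != len(scores):
        raise ValueError("mixture fit does not match the score vector")
    if abs(float(gmm.means[0] - gmm.means[1])) < 1e-6:
        warnings.warn("degenerate mixture (equal means); retaining top half by score")
        n_keep = max(1, len(scores) // 2)
        return set(scores.sort_values(ascending=False).index[:n_keep])
    hi = int(np.argmax(gmm.means))
    keep = gmm.responsibilities[:, hi] >= 0.5
    return set(scores.index[keep])


def permutation_separation_p(
    scores: pd.Series,
    selected: set[str],
    n_permutations: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p-value for retained-vs-dropped score separation.

    Tests whether the mean score of the ``selected`` TFs exceeds that of
    the rest by permuting the selection labels.  To be meaningful the
    scores must come from data independent of the run that produced the
    selection — a replicate dataset or a held-out sample split.  Testing
    on the same data is circular even with a fresh forest seed, because
    a TF that chance-correlates with the targets in that dataset scores
    high in every pass.  Used as a null-control guard: when no regulation
    is planted, rescoring on independent data carries no information
    about the selection and the p-value is uniform.
    """
    if not selected or len(selected) >= len(scores):
        return 1.0
    labels = np.array([t in selected for t in scores.index])
    vals = scores.values.astype(float)
    obs = vals[labels].mean() - vals[~labels].mean()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if vals[perm].mean() - vals[~perm].mean() >= obs:
            count += 1
    return (1 + count) / (1 + n_permutations)


def build_hierarchy(
    expr: ExpressionMatrix,
    candidate_tfs: list[str],
    pathway_genes: list[str],
    n_layers: int = 2,
    drop_fraction: float = 0.1,
    n_trees: int = 1000,
    edges_per_target: int = 3,
    max_layer_size: int | None = None,
    gmm_n_init: int = 10,
    seed: int = 0,
) -> HierarchicalNetwork:
    """Construct the multi-layer hierarchical GRN bottom-up.

    Layer 1 is selected by Gaussian-mixture thresholding of the recursive
    random-forest pathway scores of all candidate TFs against the pathway
    genes; each subsequent layer repeats the procedure with the previous
    layer as the target set and the still-unplaced TFs as candidates.
    Edges between adjacent layers keep, per target, the
    ``edges_per_target`` selected TFs of highest aggregated importance,
    weighted by that importance.  If the candidate pool is exhausted (or a
    selection comes back empty) before ``n_layers`` is reached, the
    network is returned with fewer layers and a warning.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    ss = np.random.SeedSequence(seed)
    layer_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2 * n_layers)]

    layers: list[list[str]] = []
    tf_edges: list[tuple[str, str, float]] = []
    targets = list(pathway_genes)
    remaining = list(candidate_tfs)

    for layer_idx in range(n_layers):
        if len(remaining) < 2:
            warnings.warn(
                f"candidate pool exhausted after {layer_idx} layer(s); returning a shallower network"
            )
            break
        table = bwerf_rank(
            expr,
            remaining,
            targets,
            drop_fraction=drop_fraction,
            n_trees=n_trees,
            seed=layer_seeds[2 * layer_idx],
        )
        scores = pathway_scores(table).reindex(remaining).fillna(0.0)
        if len(scores) >= 4:
            gmm = gmm_fit_1d(
                scores.values, n_components=2, n_init=gmm_n_init, seed=layer_seeds[2 * layer_idx + 1]
            )
            selected = select_layer_tfs(scores, gmm)
        else:  # too few TFs for a mixture; keep the top half by score
            n_keep = max(1, len(scores) // 2)
            selected = set(scores.sort_values(ascending=False).index[:n_keep])
        if not selected:
            warnings.warn(f"empty layer selection at layer {layer_idx + 1}; stopping")
            break
        if max_layer_size is not None and len(selected) > max_layer_size:
            selected = set(
                scores.loc[list(selected)].sort_values(ascending=False).index[:max_layer_size]
            )
        layer = sorted(selected)
        layers.append(layer)

        sel_table = table[table["tf"].isin(selected)]
        for tgt, sub in sel_table.groupby("target"):
            top = sub.sort_values(["importance", "tf"], ascending=[False, True]).head(edges_per_target)
            for _, row in top.iterrows():
                tf_edges.append((row["tf"], tgt, float(row["importance"])))

        targets = layer
        remaining = [t for t in remaining if t not in selected]

    return HierarchicalNetwork(
        layers=layers,
        tf_edges=tf_edges,
        pathway_genes=list(pathway_genes),
    )


def _pearson_matrix(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson r and two-sided p between rows of a and rows of b."""
    n = a.shape[1]
    az = (a - a.mean(axis=1, keepdims=True))
    bz = (b - b.mean(axis=1, keepdims=True))
    asd = np.sqrt((az**2).sum(axis=1))
    bsd = np.sqrt((bz**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (az @ bz.T) / np.outer(asd, bsd)
    r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)
    # p from the t transform of r with n-2 df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    return r, p


def link_metabolites(
    gene_expr: ExpressionMatrix,
    metab: MetaboliteMatrix,
    genes: list[str] | None = None,
    r_min: float = 0.8,
    alpha: float = 0.05,
    mode: str = "timepoint_means",
) -> list[tuple[str, str, float, float]]:
    """Correlation edges between genes and metabolites.

    ``mode="timepoint_means"`` collapses both data sets to per-timepoint
    replicate means over the shared timepoints (the usual case when the
    transcriptome and metabolome were profiled on parallel material);
    ``mode="samples"`` matches shared sample ids directly.  Edges keep
    pairs with ``|r| >= r_min`` and BH-adjusted p < alpha.
    """
    gene_ids = genes if genes is not None else list(gene_expr.values.index)
    if mode == "samples":
        shared = [s for s in gene_expr.values.columns if s in set(metab.intensities.columns)]
        if len(shared) < 3:
            raise ValueError("need >= 3 matched samples")
        g = gene_expr.values.loc[gene_ids, shared].values
        m = metab.intensities[shared].values
        met_ids = list(metab.intensities.index)
    elif mode == "timepoint_means":
        gmeta = gene_expr.metadata.loc[gene_expr.values.columns]
        mmeta = metab.metadata.loc[metab.intensities.columns]
        bio = mmeta.index[~mmeta["is_qc"].astype(bool)]
        shared_tp = sorted(set(gmeta["timepoint"]) & set(mmeta.loc[bio, "timepoint"]))
        if len(shared_tp) < 3:
            raise ValueError("need >= 3 matched timepoints")
        g = np.column_stack(
            [
                gene_expr.values.loc[gene_ids, gmeta.index[gmeta["timepoint"] == t]].mean(axis=1)
                for t in shared_tp
            ]
        )
        m = np.column_stack(
            [
                metab.intensities[bio[mmeta.loc[bio, "timepoint"] == t]].mean(axis=1)
                for t in shared_tp
            ]
        )
        met_ids = list(metab.intensities.index)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    r, p = _pearson_matrix(np.asarray(g, dtype=float), np.asarray(m, dtype=float))
    fdr = bh_fdr(p.ravel()).reshape(p.shape)
    edges = []
    keep = (np.abs(r) >= r_min) & (fdr < alpha)
    for i, j in zip(*np.where(keep)):
        edges.append((gene_ids[i], met_ids[j], float(r[i, j]), float(p[i, j])))
    return edges


def network_summary(
    net: HierarchicalNetwork,
    regulation_status: dict[str, str] | None = None,
) -> dict:
    """Headline counts for a hierarchical network.

    Reports TFs per layer, functional (pathway) gene count, regulatory and
    metabolite edge counts, and — when per-node up/down annotations are
    supplied — the per-layer regulation tallies.
    """
    summary: dict = {
        "n_layers": len(net.layers),
        "tfs_per_layer": [len(l) for l in net.layers],
        "n_tfs": sum(len(l) for l in net.layers),
        "n_functional_genes": len(net.pathway_genes),
        "n_tf_edges": len(net.tf_edges),
        "n_metabolite_edges": len(net.gene_metabolite_edges),
        "n_metabolites": len({m for _, m, _, _ in net.gene_metabolite_edges}),
    }
    if regulation_status:
        tallies = []
        for layer in net.layers:
            tally = {"up": 0, "down": 0, "ns": 0}
            for t in layer:
                tally[regulation_status.get(t, "ns")] += 1
            tallies.append(tally)
        summary["regulation_by_layer"] = tallies
    return summary
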