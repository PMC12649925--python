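"""Metabolomics statistics: imputation, QC filtering, multivariate models
and the VIP/fold-change differential-accumulation screen.

The screening pipeline mirrors standard practice for widely-targeted
LC-MS metabolomics:

1. missing peak areas are imputed by k-nearest-neighbour averaging over
   metabolite rows;
2. compounds whose coefficient of variation across pooled-QC injections
   is not below 0.5 are discarded;
3. an orthogonal partial least squares discriminant analysis (OPLS-DA)
   model of treated vs control yields Variable Importance in Projection
   (VIP) scores;
4. a metabolite is differentially accumulated when VIP > 1 (strict) and
   the group fold change is >= 2 (up) or <= 0.5 (down).

A univariate Welch t-test on log intensities with BH FDR is reported
alongside for inspection but does not gate the screen.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _SkPCA

from .datatypes import MetaboliteMatrix, OplsModel
from .transcript import bh_fdr

__all__ = [
    "knn_impute",
    "knn_impute_values",
    "qc_cv_filter",
    "pca",
    "oplsda_fit",
    "vip_scores",
    "fold_changes",
    "screen_dams",
    "class_summary",
    "univariate_tests",
]


def knn_impute_values(values: np.ndarray, k: int = 10) -> np.ndarray:
    """Impute NaNs by inverse-distance-weighted k-nearest metabolite rows.

    For each missing cell the neighbours are the other rows with an
    observed value in that column; nearness is plain Euclidean distance
    over the columns observed in both rows.  The imputed value is the
    1/distance-weighted average of the ``k`` nearest neighbours' values in
    that column; neighbours at distance zero share equal weight and
    override all others.  Rows with no overlapping observations with a
    candidate neighbour skip that candidate; if no candidate overlaps, the
    column mean of observed values is used as a last resort.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = np.array(values, dtype=float)
    obs = ~np.isnan(x)
    empty = np.where(~obs.any(axis=1))[0]
    if empty.size:
        raise ValueError(f"metabolite row(s) with zero observed values at indices {empty.tolist()}")
    out = x.copy()
    miss_rows = np.where(~obs.all(axis=1))[0]
    for i in miss_rows:
        for j in np.where(~obs[i])[0]:
            cand = np.where(obs[:, j])[0]
            cand = cand[cand != i]
            dists = []
            for r in cand:
                both = obs[i] & obs[r]
                if not both.any():
                    continue
                d = float(np.sqrt(np.sum((x[i, both] - x[r, both]) ** 2)))
                dists.append((d, r))
            if not dists:
                out[i, j] = float(np.nanmean(x[:, j]))
                continue
            dists.sort(key=lambda t: (t[0], t[1]))
            nearest = dists[:k]
            zero = [r for d, r in nearest if d == 0.0]
            if zero:
                out[i, j] = float(np.mean([x[r, j] for r in zero]))
            else:
                w = np.array([1.0 / d for d, _ in nearest])
                v = np.array([x[r, j] for _, r in nearest])
                out[i, j] = float(np.sum(w * v) / np.sum(w))
    return out


def knn_impute(matrix: MetaboliteMatrix, k: int = 10) -> MetaboliteMatrix:
    """KNN-impute a :class:`MetaboliteMatrix`; the returned mask is all False."""
    vals = matrix.intensities.values.copy()
    vals[matrix.missing_mask.values] = np.nan
    filled = knn_impute_values(vals, k=k)
    intens = pd.DataFrame(filled, index=matrix.intensities.index, columns=matrix.intensities.columns)
    return MetaboliteMatrix(
        intensities=intens,
        metadata=matrix.metadata,
        missing_mask=pd.DataFrame(False, index=intens.index, columns=intens.columns),
        class_labels=dict(matrix.class_labels),
    )


def qc_cv_filter(
    matrix: MetaboliteMatrix, cv_max: float = 0.5
) -> tuple[MetaboliteMatrix, list[str]]:
    """Retain compounds whose QC coefficient of variation is below ``cv_max``.

    CV = sample sd (n-1 denominator) / mean over the QC injections.  The
    boundary is strict: CV exactly at ``cv_max`` is dropped.  A compound
    with mean 0 and sd 0 has CV defined as 0 (retained); mean 0 with
    positive sd is treated as infinite CV (dropped).
    """
    qc_cols = matrix.qc_samples
    if len(qc_cols) < 2:
        raise ValueError("need at least 2 QC samples to compute CV")
    qc = matrix.intensities[qc_cols].values.astype(float)
    mean = np.nanmean(qc, axis=1)
    sd = np.nanstd(qc, axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where((mean == 0) & (sd == 0), 0.0, sd / np.where(mean == 0, np.nan, mean))
    cv = np.where(np.isnan(cv), np.inf, cv)
    keep = cv < cv_max
    dropped = [m for m, k in zip(matrix.metabolite_ids, keep) if not k]
    kept_ids = [m for m, k in zip(matrix.metabolite_ids, keep) if k]
    retained = MetaboliteMatrix(
        intensities=matrix.intensities.loc[kept_ids],
        metadata=matrix.metadata,
        missing_mask=matrix.missing_mask.loc[kept_ids],
        class_labels={m: c for m, c in matrix.class_labels.items() if m in set(kept_ids)},
    )
    return retained, dropped


def pca(
    matrix: np.ndarray | pd.DataFrame, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD principal component analysis of a samples x variables matrix.

    The matrix is column-centered internally.  Returns
    ``(scores, loadings, explained_variance_ratio)`` with loadings as a
    ``n_components x variables`` orthonormal array.
    """
    x = np.asarray(matrix, dtype=float)
    if n_components > min(x.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    if np.allclose(x, x[0:1, :]):
        raise ValueError("constant matrix has no principal components")
    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    return scores, model.components_, model.explained_variance_ratio_


def _uv_scale(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = x.mean(axis=0)
    scale = x.std(axis=0, ddof=1)
    scale = np.where(scale < 1e-12, 1.0, scale)
    return (x - center) / scale, center, scale


def oplsda_fit(
    matrix: np.ndarray | pd.DataFrame,
    y: np.ndarray | list,
    n_orthogonal: int = 1,
    variable_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> OplsModel:
    """NIPALS O-PLS discriminant analysis of a two-class design.

    ``matrix`` is samples x variables (raw intensities; unit-variance
    scaling is applied internally), ``y`` a binary group label per sample.
    ``n_orthogonal`` components orthogonal to y are removed from X before
    the single predictive component is extracted; with ``n_orthogonal=0``
    the model reduces to one-component PLS-DA.
    """
    if isinstance(matrix, pd.DataFrame):
        variable_ids = variable_ids or list(matrix.columns)
        sample_ids = sample_ids or list(matrix.index)
        x = matrix.values.astype(float)
    else:
        x = np.asarray(matrix, dtype=float)
        variable_ids = variable_ids or [f"V{i}" for i in range(x.shape[1])]
        sample_ids = sample_ids or [f"S{i}" for i in range(x.shape[0])]
    y_arr = np.asarray(y)
    classes = np.unique(y_arr)
    if len(classes) != 2:
        raise ValueError("y must contain exactly two classes")
    counts = [(y_arr == c).sum() for c in classes]
    if min(counts) < 3:
        raise ValueError("each class needs >= 3 biological replicates")

    y_num = (y_arr == classes[1]).astype(float)
    y_c = y_num - y_num.mean()
    xs, center, scale = _uv_scale(x)

    t_orth_list, p_orth_list = [], []
    e = xs.copy()
    for _ in range(n_orthogonal):
        w = e.T @ y_c
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w = w / nw
        t = e @ w
        p_load = e.T @ t / (t @ t)
        w_orth = p_load - (w @ p_load) * w
        n_orth = np.linalg.norm(w_orth)
        if n_orth < 1e-12:
            break  # X loading already collinear with the predictive weight
        w_orth = w_orth / n_orth
        t_orth = e @ w_orth
        p_orth = e.T @ t_orth / (t_orth @ t_orth)
        e = e - np.outer(t_orth, p_orth)
        t_orth_list.append(t_orth)
        p_orth_list.append(p_orth)

    w = e.T @ y_c
    nw = np.linalg.norm(w)
    if nw < 1e-12:
        raise ValueError("X carries no covariance with the class labels")
    w = w / nw
    t = e @ w
    p_load = e.T @ t / (t @ t)
    q = float(y_c @ t / (t @ t))
    ss_y = float(y_c @ y_c)
    y_expl = float(q**2 * (t @ t) / ss_y) if ss_y > 0 else 0.0

    t_orth = np.column_stack(t_orth_list) if t_orth_list else np.empty((x.shape[0], 0))
    p_orth = np.column_stack(p_orth_list) if p_orth_list else np.empty((x.shape[1], 0))
    return OplsModel(
        variable_ids=list(variable_ids),
        sample_ids=list(sample_ids),
        predictive_scores=t,
        predictive_weights=w,
        predictive_loadings=p_load,
        y_loading=q,
        orthogonal_scores=t_orth,
        orthogonal_loadings=p_orth,
        y_variance_explained=y_expl,
        center=center,
        scale=scale,
        y_centered=y_c,
    )


def vip_scores(model: OplsModel) -> pd.Series:
    """Variable Importance in Projection over the predictive component.

    ``VIP_j = sqrt(p * SS * (w_j / ||w||)^2 / SS) = sqrt(p) * |w_j|`` for
    the single predictive component with unit-norm weights, so the mean
    squared VIP over variables is exactly 1.
    """
    w = model.predictive_weights
    p_vars = len(w)
    vip = np.sqrt(p_vars) * np.abs(w)
    return pd.Series(vip, index=model.variable_ids, name="vip")


def fold_changes(
    matrix: MetaboliteMatrix, group_control: str, group_treated: str
) -> pd.Series:
    """Treated / control ratio of arithmetic group means of intensities.

    Intended for imputed matrices (no NaNs); QC samples are never part of
    either group.
    """
    meta = matrix.metadata.loc[matrix.intensities.columns]
    ctrl = meta.index[(meta["group"] == group_control) & ~meta["is_qc"].astype(bool)]
    trt = meta.index[(meta["group"] == group_treated) & ~meta["is_qc"].astype(bool)]
    if len(ctrl) == 0 or len(trt) == 0:
        raise ValueError("empty contrast group")
    mean_c = matrix.intensities[ctrl].mean(axis=1)
    mean_t = matrix.intensities[trt].mean(axis=1)
    return (mean_t / mean_c).rename("fc")


def screen_dams(
    vip: pd.Series,
    fc: pd.Series,
    vip_min: float = 1.0,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
) -> pd.DataFrame:
    """Differential-accumulation screen: VIP > 1 (strict) and FC >= 2 or <= 0.5.

    Both fold-change boundaries are inclusive; the VIP boundary is strict,
    so VIP exactly 1 is not significant.  Returns a DataFrame indexed by
    metabolite with ``vip, fc, log2fc, status``.
    """
    missing = set(vip.index) - set(fc.index)
    if missing:
        raise ValueError(f"missing fold change for ids: {sorted(missing)[:5]}")
    fc = fc.loc[vip.index]
    if (fc <= 0).any():
        raise ValueError("fold changes must be positive")
    sig = vip.values > vip_min
    up = sig & (fc.values >= fc_up)
    down = sig & (fc.values <= fc_down)
    status = np.where(up, "up", np.where(down, "down", "ns"))
    return pd.DataFrame(
        {"vip": vip.values, "fc": fc.values, "log2fc": np.log2(fc.values), "status": status},
        index=vip.index,
    )


def class_summary(ids: set[str] | list[str], class_labels: dict[str, str]) -> dict[str, int]:
    """Count compound classes over an id set; unlabeled ids count as 'other'."""
    out: dict[str, int] = {}
    for i in ids:
        c = class_labels.get(i, "other")
        out[c] = out.get(c, 0) + 1
    return out


def univariate_tests(
    matrix: MetaboliteMatrix, group_control: str, group_treated: str
) -> pd.DataFrame:
    """Welch's t-test on log2 intensities per metabolite, with BH FDR.

    Reported for inspection alongside the multivariate screen; the
    VIP/fold-change screen does not use these p-values.
    """
    meta = matrix.metadata.loc[matrix.intensities.columns]
    ctrl = meta.index[(meta["group"] == group_control) & ~meta["is_qc"].astype(bool)]
    trt = meta.index[(meta["group"] == group_treated) & ~meta["is_qc"].astype(bool)]
    a = np.log2(matrix.intensities[ctrl].values + 1e-12)
    b = np.log2(matrix.intensities[trt].values + 1e-12)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    return pd.DataFrame(
        {"t": t, "p": p, "fdr": bh_fdr(p)}, index=matrix.intensities.index
    )
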