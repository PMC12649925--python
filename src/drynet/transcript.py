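"""Differential-expression screening for the drought time course.

The screen follows the criteria used throughout the study: per-timepoint
contrasts against the day-0 control, with a gene called differentially
expressed when ``|log2 fold change| >= 1`` (boundary included) and
``FDR < 0.05`` (boundary excluded).

The differential test itself is a deliberately simple negative-binomial
Wald test: median-of-ratios size factors, a single shared
method-of-moments dispersion, and a normal reference for the Wald
statistic.  It is calibrated for the synthetic NB data generated here and
is not intended to reproduce DESeq2 numerically; externally computed
(log2fc, p) tables can be screened through :func:`screen_degs` directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix

__all__ = [
    "compute_fpkm",
    "size_factors",
    "nb_wald_test",
    "bh_fdr",
    "screen_degs",
    "shared_exclusive_sets",
    "ddct_relative_expression",
]

PSEUDOCOUNT = 0.5  # added to normalized group means before log2 ratio
DISPERSION_FLOOR = 1e-8


def compute_fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series | np.ndarray,
    library_sizes: pd.Series | np.ndarray | None = None,
    metadata: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """FPKM = counts * 1e9 / (gene length [bp] * library size).

    ``library_sizes`` defaults to per-sample column sums.  Returns an
    :class:`ExpressionMatrix` tagged ``fpkm`` (with a minimal metadata
    frame when none is supplied).
    """
    lengths = np.asarray(gene_lengths, dtype=float)
    if lengths.shape[0] != counts.shape[0]:
        raise ValueError("gene_lengths must match the number of genes")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0).astype(float)
    lib = np.asarray(library_sizes, dtype=float)
    if lib.shape[0] != counts.shape[1]:
        raise ValueError("library_sizes must match the number of samples")
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")

    fpkm = counts.values * 1e9 / (lengths[:, None] * lib[None, :])
    if metadata is None:
        metadata = pd.DataFrame(
            {"timepoint": 0, "replicate": range(counts.shape[1]), "group": "all"},
            index=counts.columns,
        )
    return ExpressionMatrix(
        values=pd.DataFrame(fpkm, index=counts.index, columns=counts.columns),
        metadata=metadata,
        unit="fpkm",
    )


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference is the per-gene geometric mean over samples, computed on
    genes with nonzero counts in every sample.  Raises if no such gene
    exists (advising a pseudo-count on the input).
    """
    vals = counts.values.astype(float)
    usable = (vals > 0).all(axis=1)
    if not usable.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; add a pseudo-count "
            "to the count matrix before computing size factors"
        )
    ref = np.exp(np.log(vals[usable]).mean(axis=1))
    sf = np.median(vals[usable] / ref[:, None], axis=0)
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _shared_dispersion(q: np.ndarray, groups: list[np.ndarray]) -> float:
    """Shared method-of-moments NB dispersion on normalized counts.

    Per-gene moment estimates ``(s^2 - mu) / mu^2`` from within-group
    residuals are pooled by their mean across genes; a single shared
    value stabilizes the Wald reference at small replicate numbers, and
    mean pooling is close to unbiased for the common NB dispersion where
    the median of the skewed per-gene estimates is not.
    """
    mu = q.mean(axis=1)
    ss = np.zeros(q.shape[0])
    df = 0
    for idx in groups:
        sub = q[:, idx]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df += len(idx) - 1
    var_within = ss / max(df, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var_within - mu) / mu**2
    alpha = alpha[np.isfinite(alpha) & (mu > 0)]
    if alpha.size == 0:
        return DISPERSION_FLOOR
    return float(max(np.mean(alpha), DISPERSION_FLOOR))


def nb_wald_test(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
) -> pd.DataFrame:
    """Simplified NB Wald test of group B vs group A.

    Counts are normalized by median-of-ratios size factors; group means of
    normalized counts give ``log2fc = log2((mean_b + 0.5) / (mean_a + 0.5))``.
    The Wald statistic divides the log2 fold change by a delta-method
    standard error using NB variance ``mu + alpha * mu^2`` with the shared
    dispersion; two-sided p-values come from the normal distribution.
    Genes with all-zero counts in both groups get ``p = 1, log2fc = 0``.

    Returns a DataFrame indexed by gene with columns
    ``log2fc, stat, p, base_mean_a, base_mean_b``.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 samples per group")
    missing = (set(group_a) | set(group_b)) - set(counts.columns)
    if missing:
        raise KeyError(f"samples not in count matrix: {sorted(missing)}")

    sub = counts[list(group_a) + list(group_b)]
    try:
        sf = size_factors(sub)
    except ValueError:
        sf = size_factors(sub + 1)
    q = sub.values / sf.values[None, :]
    ia = np.arange(len(group_a))
    ib = np.arange(len(group_a), len(group_a) + len(group_b))

    alpha = _shared_dispersion(q, [ia, ib])
    mu_a = q[:, ia].mean(axis=1)
    mu_b = q[:, ib].mean(axis=1)

    log2fc = np.log2((mu_b + PSEUDOCOUNT) / (mu_a + PSEUDOCOUNT))
    var_a = (mu_a + alpha * mu_a**2) / len(ia)
    var_b = (mu_b + alpha * mu_b**2) / len(ib)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(var_a / (mu_a + PSEUDOCOUNT) ** 2 + var_b / (mu_b + PSEUDOCOUNT) ** 2) / np.log(2)
        stat = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(stat))

    zero = (mu_a == 0) & (mu_b == 0)
    log2fc[zero], stat[zero], p[zero] = 0.0, 0.0, 1.0
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "stat": stat,
            "p": np.clip(p, 0.0, 1.0),
            "base_mean_a": mu_a,
            "base_mean_b": mu_b,
        },
        index=counts.index,
    )


def bh_fdr(p_values: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("p-values contain NaN")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_degs(
    results: pd.DataFrame,
    lfc_min: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Apply the DEG screen: |log2FC| >= lfc_min (inclusive) and FDR < alpha (strict).

    Adds ``fdr`` (BH over the table's p column, if absent) and ``status``
    in {up, down, ns}.  A gene at exactly ``log2fc = lfc_min`` passes the
    fold-change gate; a gene at exactly ``fdr = alpha`` fails the FDR gate.
    """
    out = results.copy()
    if "fdr" not in out.columns:
        out["fdr"] = bh_fdr(out["p"].values)
    sig = out["fdr"].values < alpha
    up = sig & (out["log2fc"].values >= lfc_min)
    down = sig & (out["log2fc"].values <= -lfc_min)
    status = np.where(up, "up", np.where(down, "down", "ns"))
    out["status"] = status
    return out


def shared_exclusive_sets(
    deg_sets: dict[str, set[str]],
) -> tuple[set[str], dict[str, set[str]]]:
    """Venn-style decomposition: ids in every set, and ids unique to one.

    ``shared`` is the intersection of all sets (the genes involved at every
    stress duration); ``exclusive[label]`` holds the ids found only in that
    contrast.
    """
    if len(deg_sets) < 2:
        raise ValueError("need at least 2 sets")
    labels = list(deg_sets)
    shared = set.intersection(*(set(s) for s in deg_sets.values()))
    exclusive: dict[str, set[str]] = {}
    for lab in labels:
        others = set().union(*(deg_sets[o] for o in labels if o != lab))
        exclusive[lab] = set(deg_sets[lab]) - others
    return shared, exclusive


def ddct_relative_expression(
    ct_target: float,
    ct_ref: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ``ddCt = (Ct_target - Ct_ref) - (Ct_target_ctrl - Ct_ref_ctrl)``;
    the fold change relative to the control condition is ``2 ** -ddCt``.
    """
    for v in (ct_target, ct_ref, ct_target_ctrl, ct_ref_ctrl):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target - ct_ref) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
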