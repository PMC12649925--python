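"""Seeded simulators with planted ground truth.

Three generators mirror the study design of a progressive-drought
time-course experiment:

* :func:`simulate_hierarchy_expression` — bulk expression over a
  multi-timepoint, replicated design with a planted two-layer
  TF -> TF -> pathway-gene regulatory hierarchy plus decoy TFs.
* :func:`simulate_counts` — negative-binomial read counts from an
  expression matrix, for exercising the differential-expression screen.
* :func:`simulate_metabolome` — log-normal peak areas with planted group
  fold changes, MCAR missing values and pooled-QC injections of
  controlled coefficient of variation.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so each internal stage draws from
its own documented stream and reruns are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .datatypes import (
    ExpressionMatrix,
    GroundTruthGRN,
    GroundTruthMetabolome,
    MetaboliteMatrix,
)

__all__ = [
    "simulate_hierarchy_expression",
    "simulate_counts",
    "simulate_metabolome",
]

# Per-gene baseline abundance range; keeps simulated values positive while
# leaving the linear parent->child structure exact (baselines are recorded
# in the truth object).
_BASELINE_RANGE = (8.0, 12.0)


def _smooth_signal(rng: np.random.Generator, timepoints: np.ndarray) -> np.ndarray:
    """Random cubic spline through the timepoints, standardized to sd 1.

    A knot sits at every timepoint: at the sampled resolution the signal
    is a standardized random draw per timepoint, while the spline gives a
    smooth drought-like trajectory between observations.  Knots at a
    coarser grid would confine every signal TF to a low-dimensional
    smooth subspace in which unrelated regulators chance-correlate
    strongly, washing out the planted structure.
    """
    if len(timepoints) < 2:
        return np.zeros_like(timepoints, dtype=float)
    knots_y = rng.normal(size=len(timepoints))
    sig = CubicSpline(timepoints, knots_y)(timepoints)
    sd = sig.std(ddof=0)
    if sd < 1e-12:  # pathological flat draw; perturb deterministically
        sig = sig + rng.normal(size=len(timepoints)) * 1e-6
        sd = sig.std(ddof=0)
    return (sig - sig.mean()) / sd


def simulate_hierarchy_expression(
    n_pathway_genes: int,
    n_layer1_tfs: int,
    n_layer2_tfs: int,
    n_decoys: int,
    timepoints: int = 6,
    replicates: int = 3,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, GroundTruthGRN]:
    """Simulate expression with a planted 2-layer regulatory hierarchy.

    Layer-2 TFs follow independent smooth temporal trends plus per-sample
    biological fluctuation.  Each layer-1 TF is a linear combination of
    the realized per-sample profiles of 1-3 layer-2 parents plus its own
    noise; each pathway gene likewise combines 1-3 layer-1 parents.
    Regulation therefore propagates within each replicate plant — the
    child responds to the parent's realized level in that sample, not
    just to the timepoint trend — which is what makes the planted layers
    statistically tellable at few timepoints.  Decoy TFs are independent
    noise with no planted edge, variance-matched to the signal TFs.

    Every profile is standardized to unit variance, so each tier's noise
    contributes a ``noise_sd**2 / (1 + noise_sd**2)`` variance fraction
    and the attainable per-gene R^2 of a child regressed on its parents'
    profiles is ``1 / (1 + noise_sd**2)`` — the default ``noise_sd = 1``
    gives R^2 of 0.5.  In the ``noise_sd -> 0`` limit a child profile
    equals its linear combination of parent profiles exactly (up to the
    recorded affine shift).

    Parameters
    ----------
    n_pathway_genes, n_layer1_tfs, n_layer2_tfs, n_decoys
        Sizes of the planted tiers; all must be >= 1.
    timepoints, replicates
        Design: samples are ``timepoints x replicates`` columns.
    noise_sd
        Per-tier noise sd in signal units (> 0).
    seed
        Master seed; identical seeds give bitwise-identical output.

    Returns
    -------
    (ExpressionMatrix, GroundTruthGRN)
    """
    dims = dict(
        n_pathway_genes=n_pathway_genes,
        n_layer1_tfs=n_layer1_tfs,
        n_layer2_tfs=n_layer2_tfs,
        n_decoys=n_decoys,
        timepoints=timepoints,
        replicates=replicates,
    )
    for name, v in dims.items():
        if v < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")

    ss = np.random.SeedSequence(seed)
    # documented stream order: signals, wiring, baselines
    rng_sig, rng_wire, rng_base = (np.random.default_rng(s) for s in ss.spawn(3))

    tp = np.arange(timepoints, dtype=float)
    n_samples = timepoints * replicates
    l2_ids = [f"TF_L2_{i:03d}" for i in range(n_layer2_tfs)]
    l1_ids = [f"TF_L1_{i:03d}" for i in range(n_layer1_tfs)]
    decoy_ids = [f"TF_DEC_{i:03d}" for i in range(n_decoys)]
    gene_ids = [f"PG_{i:03d}" for i in range(n_pathway_genes)]

    # per-sample profiles, all standardized to sd 1
    profiles: dict[str, np.ndarray] = {}
    for t in l2_ids:
        trend = np.repeat(_smooth_signal(rng_sig, tp), replicates)
        raw = trend + rng_sig.normal(scale=noise_sd, size=n_samples)
        profiles[t] = (raw - raw.mean()) / raw.std(ddof=0)
    for d in decoy_ids:
        raw = rng_sig.normal(size=n_samples)
        profiles[d] = (raw - raw.mean()) / raw.std(ddof=0)

    edges: list[tuple[str, str, float]] = []
    _shifts: dict[str, float] = {}

    def _combine(child: str, parent_pool: list[str]) -> None:
        n_par = int(rng_wire.integers(1, min(3, len(parent_pool)) + 1))
        parents = list(rng_wire.choice(parent_pool, size=n_par, replace=False))
        coefs = rng_wire.uniform(0.5, 1.5, size=n_par) * rng_wire.choice([-1.0, 1.0], size=n_par)
        raw = sum(c * profiles[p] for c, p in zip(coefs, parents))
        sd = raw.std(ddof=0)
        if sd < 1e-12:
            # near-perfect cancellation; fall back to the first parent alone
            parents, coefs = parents[:1], np.array([1.0])
            raw = profiles[parents[0]].copy()
            sd = raw.std(ddof=0)
        u = (raw - raw.mean()) / sd
        v = u + rng_wire.normal(scale=noise_sd, size=n_samples)
        sd_v = v.std(ddof=0)
        profiles[child] = (v - v.mean()) / sd_v
        for c, p in zip(coefs, parents):
            edges.append((p, child, float(c / (sd * sd_v))))
        # affine residue so child = sum(effect * parent) - shift as noise -> 0
        _shifts[child] = float(raw.mean() / (sd * sd_v))

    for t in l1_ids:
        _combine(t, l2_ids)
    for g in gene_ids:
        _combine(g, l1_ids)

    all_ids = gene_ids + l1_ids + l2_ids + decoy_ids
    sample_ids = [f"T{t}_R{r}" for t in range(timepoints) for r in range(replicates)]
    baselines = {fid: float(rng_base.uniform(*_BASELINE_RANGE)) for fid in all_ids}

    prof_mat = np.vstack([profiles[fid] for fid in all_ids])  # features x samples
    base = np.array([baselines[fid] for fid in all_ids])[:, None]
    values = np.clip(base + prof_mat, 0.0, None)

    meta = pd.DataFrame(
        {
            "timepoint": [t for t in range(timepoints) for _ in range(replicates)],
            "replicate": [r for _ in range(timepoints) for r in range(replicates)],
            "group": [f"T{t}" for t in range(timepoints) for _ in range(replicates)],
        },
        index=sample_ids,
    )
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=all_ids, columns=sample_ids),
        metadata=meta,
        unit="expression",
    )
    truth = GroundTruthGRN(
        layer_assignments={**{t: 1 for t in l1_ids}, **{t: 2 for t in l2_ids}},
        edges=edges,
        pathway_genes=gene_ids,
        decoy_tfs=set(decoy_ids),
        baselines=baselines,
        signals=pd.DataFrame(prof_mat, index=all_ids, columns=sample_ids),
    )
    truth.shifts = _shifts  # affine residue of per-child standardization
    return expr, truth


def simulate_counts(
    expression: ExpressionMatrix,
    gene_lengths: np.ndarray | pd.Series,
    dispersion: float = 0.05,
    library_sizes: np.ndarray | pd.Series | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw NB read counts with mean ~ expression * length * library size.

    The mean is ``expr * (length/1e3) * (libsize/1e6)``, i.e. the inverse
    of the FPKM transform, so ``compute_fpkm`` recovers the expression
    scale in expectation.  Counts are gamma-Poisson with a single shared
    dispersion (variance ``mu + dispersion * mu^2``), matching the
    shared-dispersion NB Wald test downstream.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    vals = expression.values.values
    lengths = np.asarray(gene_lengths, dtype=float)
    if lengths.shape[0] != vals.shape[0]:
        raise ValueError("gene_lengths length must match number of genes")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if library_sizes is None:
        library_sizes = np.full(vals.shape[1], 1e7)
    lib = np.asarray(library_sizes, dtype=float)
    if lib.shape[0] != vals.shape[1]:
        raise ValueError("library_sizes length must match number of samples")
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    mu = vals * (lengths[:, None] / 1e3) * (lib[None, :] / 1e6)
    shape = 1.0 / dispersion
    lam = np.where(mu > 0, rng.gamma(shape, 1.0, size=mu.shape) * dispersion * mu, 0.0)
    counts = rng.poisson(lam)
    return pd.DataFrame(counts, index=expression.values.index, columns=expression.values.columns)


def simulate_metabolome(
    n_metabolites: int = 1000,
    n_groups: int = 2,
    replicates: int = 3,
    n_qc: int = 3,
    frac_differential: float = 0.1,
    log2fc: float = 2.0,
    missing_rate: float = 0.05,
    qc_cv: float | np.ndarray = 0.2,
    within_sd_log2: float = 0.25,
    seed: int = 0,
) -> tuple[MetaboliteMatrix, GroundTruthMetabolome]:
    """Simulate LC-MS peak areas with planted differential accumulation.

    Intensities are log-normal: per-metabolite base level on the log2
    scale, replicate noise of ``within_sd_log2`` (log2 sd, default 0.25 —
    typical of targeted LC-MS peak areas), and the planted ``log2fc``
    added in every treated group (group 0 is the control) for a random
    ``frac_differential`` subset.  Pooled-QC injections are drawn on the
    raw scale around the control mean with the target coefficient of
    variation ``qc_cv`` (scalar or per-metabolite array).  Missing values
    are completely at random among biological samples; QC injections stay
    complete so the CV filter sees every compound.

    Returns the matrix plus a :class:`GroundTruthMetabolome` recording the
    planted structure.
    """
    if not 0 <= missing_rate < 0.5:
        raise ValueError("missing_rate must be in [0, 0.5)")
    if n_qc < 3:
        raise ValueError("need at least 3 QC injections")
    if not 0 <= frac_differential <= 1:
        raise ValueError("frac_differential must be in [0, 1]")
    if n_groups < 2:
        raise ValueError("need a control and at least one treated group")

    ss = np.random.SeedSequence(seed)
    rng_base, rng_diff, rng_noise, rng_qc, rng_miss = (np.random.default_rng(s) for s in ss.spawn(5))

    met_ids = [f"M_{i:04d}" for i in range(n_metabolites)]
    groups = [f"G{g}" for g in range(n_groups)]
    bio_samples = [f"{g}_R{r}" for g in groups for r in range(replicates)]
    qc_samples = [f"QC_{i}" for i in range(n_qc)]

    base_log2 = rng_base.uniform(10.0, 20.0, size=n_metabolites)
    n_diff = int(round(frac_differential * n_metabolites))
    diff_idx = rng_diff.choice(n_metabolites, size=n_diff, replace=False)
    lfc = np.zeros(n_metabolites)
    lfc[diff_idx] = log2fc

    # biological samples: log-normal around base (+ shift in treated groups)
    log2_means = np.empty((n_metabolites, len(bio_samples)))
    for j, s in enumerate(bio_samples):
        treated = not s.startswith("G0_")
        log2_means[:, j] = base_log2 + (lfc if treated else 0.0)
    bio = np.exp2(log2_means + rng_noise.normal(scale=within_sd_log2, size=log2_means.shape))

    # QC injections: raw-scale normal around the control mean with target CV
    qc_cv_arr = np.broadcast_to(np.asarray(qc_cv, dtype=float), (n_metabolites,)).copy()
    qc_mean = np.exp2(base_log2)
    qc = rng_qc.normal(
        loc=qc_mean[:, None], scale=(qc_cv_arr * qc_mean)[:, None], size=(n_metabolites, n_qc)
    )
    qc = np.clip(qc, qc_mean[:, None] * 1e-3, None)

    intensities = np.concatenate([bio, qc], axis=1)
    sample_ids = bio_samples + qc_samples

    mask = np.zeros((n_metabolites, len(sample_ids)), dtype=bool)
    if missing_rate > 0:
        mask[:, : len(bio_samples)] = rng_miss.random((n_metabolites, len(bio_samples))) < missing_rate
        # guarantee >= 1 observed value per metabolite (pre-condition of imputation)
        all_missing = mask[:, : len(bio_samples)].all(axis=1)
        mask[all_missing, 0] = False

    values = intensities.copy()
    values[mask] = np.nan

    meta = pd.DataFrame(
        {
            "timepoint": [int(s.split("_R")[0][1:]) if not s.startswith("QC") else -1 for s in sample_ids],
            "replicate": [int(s.split("_")[-1].lstrip("R")) if not s.startswith("QC") else int(s.split("_")[1]) for s in sample_ids],
            "group": [s.split("_R")[0] if not s.startswith("QC") else "QC" for s in sample_ids],
            "is_qc": [s.startswith("QC") for s in sample_ids],
        },
        index=sample_ids,
    )

    mask_df = pd.DataFrame(mask, index=met_ids, columns=sample_ids)
    matrix = MetaboliteMatrix(
        intensities=pd.DataFrame(values, index=met_ids, columns=sample_ids),
        metadata=meta,
        missing_mask=mask_df,
        class_labels={m: ["flavonoid", "lipid", "alkaloid", "amino_acid", "other"][i % 5] for i, m in enumerate(met_ids)},
    )
    truth = GroundTruthMetabolome(
        differential_ids={met_ids[i] for i in diff_idx},
        planted_log2fc={met_ids[i]: float(log2fc) for i in diff_idx},
        missing_mask=mask_df,
        qc_cv_true=pd.Series(qc_cv_arr, index=met_ids),
    )
    return matrix, truth
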