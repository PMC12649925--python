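"""K-means clustering of metabolite temporal profiles.

Metabolite levels at each timepoint are collapsed to replicate means,
z-scored per metabolite, and clustered with Lloyd's algorithm under
k-means++ initialization (default k=8, mirroring the eight temporal
accumulation patterns typically distinguished in drought time courses).
Lloyd iterations are run in-house so the within-run inertia trace is
available; the best of ``restarts`` runs by final inertia is kept.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import kmeans_plusplus

from .datatypes import MetaboliteMatrix, ProfileClustering
from .metabolome import class_summary

__all__ = ["profile_matrix", "kmeans_cluster", "cluster_class_counts"]

_MAX_ITER = 300
_SHIFT_TOL = 1e-8


def profile_matrix(matrix: MetaboliteMatrix) -> pd.DataFrame:
    """Metabolite x timepoint z-score matrix of replicate-mean profiles.

    QC injections are excluded; replicates are collapsed by the mean at
    each timepoint; each row is standardized to mean 0, sd 1 (sample sd).
    Rows constant across timepoints carry no shape information and are
    dropped with a warning.
    """
    meta = matrix.metadata.loc[matrix.intensities.columns]
    bio = meta.index[~meta["is_qc"].astype(bool)]
    tps = sorted(meta.loc[bio, "timepoint"].unique())
    if len(tps) < 2:
        raise ValueError("need at least 2 timepoints for temporal profiles")
    cols = {}
    for t in tps:
        samples = bio[meta.loc[bio, "timepoint"] == t]
        cols[t] = matrix.intensities[samples].mean(axis=1)
    prof = pd.DataFrame(cols)
    sd = prof.std(axis=1, ddof=1)
    constant = sd < 1e-12
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} constant profile(s): "
            f"{list(prof.index[constant][:5])}"
        )
        prof = prof.loc[~constant]
        sd = sd.loc[~constant]
    return prof.sub(prof.mean(axis=1), axis=0).div(sd, axis=0)


def _lloyd(
    x: np.ndarray, centers: np.ndarray, max_iter: int = _MAX_ITER
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    k = centers.shape[0]
    trace: list[float] = []
    labels = np.zeros(len(x), dtype=int)
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        trace.append(float(d2[np.arange(len(x)), labels].sum()))
        new_centers = centers.copy()
        for c in range(k):
            members = x[labels == c]
            if len(members):
                new_centers[c] = members.mean(axis=0)
            else:
                # re-seed an empty cluster at the point farthest from its centroid
                far = int(d2[np.arange(len(x)), labels].argmax())
                new_centers[c] = x[far]
        shift = float(np.sqrt(((new_centers - centers) ** 2).sum(axis=1)).max())
        centers = new_centers
        if shift < _SHIFT_TOL:
            break
    d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    inertia = float(d2[np.arange(len(x)), labels].sum())
    trace.append(inertia)
    return labels, centers, inertia, trace


def kmeans_cluster(
    profiles: pd.DataFrame,
    k: int = 8,
    restarts: int = 50,
    seed: int = 0,
) -> ProfileClustering:
    """K-means over profile rows: k-means++ init, Lloyd to convergence.

    Runs ``restarts`` independent initializations (seeds spawned from
    ``seed``) and keeps the run with the lowest final inertia; within each
    run iteration stops when the largest centroid shift falls below 1e-8
    or after 300 iterations.  Deterministic given the seed.
    """
    x = profiles.values.astype(float)
    if k > len(x):
        raise ValueError(f"k={k} exceeds number of profiles {len(x)}")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    ss = np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(restarts):
        rs = int(child.generate_state(1)[0] % (2**31 - 1))
        centers, _ = kmeans_plusplus(x, n_clusters=k, random_state=rs)
        labels, centers, inertia, trace = _lloyd(x, centers)
        if best is None or inertia < best[2]:
            best = (labels, centers, inertia, trace)
    labels, centers, inertia, trace = best
    return ProfileClustering(
        k=k,
        assignments={m: int(c) for m, c in zip(profiles.index, labels)},
        centroids=pd.DataFrame(centers, index=range(k), columns=profiles.columns),
        inertia=inertia,
        inertia_trace=trace,
    )


def cluster_class_counts(
    clustering: ProfileClustering, class_labels: dict[str, str]
) -> dict[int, dict[str, int]]:
    """Per-cluster compound-class counts; counts sum to cluster sizes."""
    out: dict[int, dict[str, int]] = {}
    for c in range(clustering.k):
        out[c] = class_summary(clustering.members(c), class_labels)
    return out
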