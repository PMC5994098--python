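"""Restart-selected k-means on relative abundance profiles.

Entities (genes or gene-level protein rows) are clustered on their
*relative* profiles — each row divided by its sum over the selected
samples, so profiles live on the probability simplex.  Because Lloyd's
algorithm is sensitive to initialisation, :class:`FomKMeans` runs a fixed
number of independent restarts (default 25) and keeps the run with the
lowest clustering variance, where the variance of a cluster is the mean
over samples of the population variance of its members in that sample,
and the clustering variance is the unweighted mean over clusters.

The number of clusters is guided by a leave-one-sample-out figure of
merit (FOM): for each held-out sample the remaining samples are
clustered and the FOM records how well cluster membership predicts the
held-out values (root-mean-square deviation from the cluster mean in the
held-out sample).  The curve flattens once additional clusters stop
adding information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

from .matrix import ExpressionMatrix, PipelineError


def make_relative_profiles(
    averaged: ExpressionMatrix, samples: list[str] | None = None
) -> tuple[pd.DataFrame, list]:
    """Row-normalise an averaged matrix over the selected sample columns.

    Rows summing to zero carry no profile information and are dropped.

    Returns
    -------
    (profiles frame with rows summing to 1, list of dropped entity ids)
    """
    cols = list(samples) if samples is not None else list(averaged.values.columns)
    if not cols:
        raise PipelineError("no sample columns selected")
    block = averaged.values[cols]
    sums = block.sum(axis=1)
    keep = sums > 0
    dropped = list(block.index[~keep])
    profiles = block.loc[keep].div(sums[keep], axis=0)
    return profiles, dropped


def clustering_variance(labels: np.ndarray, X: np.ndarray) -> float:
    """Unweighted mean over clusters of the per-sample population variance.

    For each cluster the variance of member values is computed per sample
    (column) and averaged over samples; the clustering variance is the
    plain mean of these per-cluster values.  Singleton clusters have zero
    variance.
    """
    labels = np.asarray(labels)
    X = np.asarray(X, dtype=float)
    out = []
    for lab in np.unique(labels):
        members = X[labels == lab]
        out.append(float(members.var(axis=0, ddof=0).mean()))
    if not out:
        raise PipelineError("no clusters present")
    return float(np.mean(out))


class FomKMeans(BaseEstimator, ClusterMixin):
    """k-means with restart selection by clustering variance.

    Runs ``n_runs`` independent Lloyd fits, each initialised from ``k``
    data points drawn without replacement, and keeps the run whose
    clustering variance (see :func:`clustering_variance`) is lowest;
    ties go to the earliest run.

    Parameters
    ----------
    n_clusters
        Number of clusters ``k``.
    n_runs
        Independent restarts (default 25).
    random_state
        Seed for restart initialisation; fits are bit-reproducible.

    Attributes
    ----------
    labels_ : ndarray of shape (n_entities,)
        Cluster index (0-based) per entity.
    cluster_centers_ : ndarray of shape (n_clusters, n_samples)
        Arithmetic mean profile of each cluster's members.
    run_variances_ : ndarray of shape (n_runs,)
        Clustering variance of every restart.
    selected_run_ : int
        Index of the winning restart.
    variance_ : float
        Clustering variance of the winning restart.
    """

    def __init__(self, n_clusters: int = 15, n_runs: int = 25,
                 random_state: int | None = None):
        self.n_clusters = n_clusters
        self.n_runs = n_runs
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise PipelineError("expected a 2-D entity x sample array")
        n = X.shape[0]
        if self.n_clusters > n:
            raise PipelineError(
                f"k={self.n_clusters} exceeds the number of entities ({n})"
            )
        if self.n_runs < 1:
            raise PipelineError("n_runs must be >= 1")
        rng = np.random.default_rng(self.random_state)
        best = None
        variances = np.empty(self.n_runs)
        for run in range(self.n_runs):
            init_idx = rng.choice(n, size=self.n_clusters, replace=False)
            km = KMeans(
                n_clusters=self.n_clusters,
                init=X[init_idx],
                n_init=1,
                algorithm="lloyd",
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(X)
            var = clustering_variance(km.labels_, X)
            variances[run] = var
            if best is None or var < best[0]:
                best = (var, run, km.labels_.copy())
        assert best is not None
        self.run_variances_ = variances
        self.variance_, self.selected_run_, self.labels_ = best
        # centroids recomputed as exact member means of the winning run;
        # clusters left empty (fewer distinct points than k) fall back to
        # the overall mean rather than propagating NaN
        overall = X.mean(axis=0)
        self.cluster_centers_ = np.vstack([
            X[self.labels_ == lab].mean(axis=0)
            if (self.labels_ == lab).any() else overall
            for lab in range(self.n_clusters)
        ])
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        X = np.asarray(X, dtype=float)
        d = ((X[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        return d.argmin(axis=1)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass
class ClusterModel:
    """A fitted clustering bound to entity ids.

    ``assignment`` maps entity id -> 0-based cluster index; ``centroids``
    is a k x samples frame of member-mean profiles.
    """

    k: int
    assignment: pd.Series
    centroids: pd.DataFrame
    run_variances: np.ndarray
    selected_run: int
    variance: float
    seed: int | None = None

    def members(self, cluster: int) -> pd.Index:
        return self.assignment.index[self.assignment == cluster]

    @property
    def sizes(self) -> pd.Series:
        return self.assignment.value_counts().reindex(range(self.k), fill_value=0)


def fit_kmeans(
    profiles: pd.DataFrame,
    k: int,
    n_runs: int = 25,
    seed: int | None = None,
) -> ClusterModel:
    """Fit :class:`FomKMeans` on a profile frame and wrap the result."""
    est = FomKMeans(n_clusters=k, n_runs=n_runs, random_state=seed).fit(
        profiles.to_numpy()
    )
    return ClusterModel(
        k=k,
        assignment=pd.Series(est.labels_, index=profiles.index, name="cluster"),
        centroids=pd.DataFrame(
            est.cluster_centers_, columns=profiles.columns,
            index=pd.RangeIndex(k, name="cluster"),
        ),
        run_variances=est.run_variances_,
        selected_run=int(est.selected_run_),
        variance=float(est.variance_),
        seed=seed,
    )


@dataclass
class FomCurve:
    """Leave-one-sample-out figure-of-merit curve over candidate k."""

    k_values: list[int]
    fom: list[float]
    suggested_k: int
    gain_threshold: float = 0.10
    frame: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.frame = pd.DataFrame({"k": self.k_values, "fom": self.fom})


def figure_of_merit(
    profiles: pd.DataFrame,
    k_range,
    seed: int | None = None,
    n_runs: int = 10,
    gain_threshold: float = 0.10,
) -> FomCurve:
    """Leave-one-sample-out FOM curve and a suggested number of clusters.

    For every held-out sample, entities are clustered on the remaining
    samples and the FOM contribution is the RMS deviation of the held-out
    values from their cluster means in that sample; contributions are
    summed over held-out samples.  ``suggested_k`` is the largest k whose
    FOM drops by more than ``gain_threshold`` (relative) versus k-1 —
    the last substantial gain of information.
    """
    X = profiles.to_numpy(dtype=float)
    n, m = X.shape
    if m < 2:
        raise PipelineError("FOM requires at least 2 samples")
    k_values = sorted(int(k) for k in k_range)
    if not k_values or k_values[0] < 1 or k_values[-1] > n - 1:
        raise PipelineError("k_range must lie within [1, n_entities - 1]")
    rng = np.random.default_rng(seed)
    fom = []
    for k in k_values:
        total = 0.0
        for held in range(m):
            rest = np.delete(X, held, axis=1)
            if k == 1:
                labels = np.zeros(n, dtype=int)
            else:
                labels = FomKMeans(
                    n_clusters=k, n_runs=n_runs,
                    random_state=int(rng.integers(2**31 - 1)),
                ).fit(rest).labels_
            dev = 0.0
            for lab in np.unique(labels):
                vals = X[labels == lab, held]
                dev += float(((vals - vals.mean()) ** 2).sum())
            total += np.sqrt(dev / n)
        fom.append(total)
    suggested = k_values[0]
    for i in range(1, len(k_values)):
        prev = fom[i - 1]
        if prev > 0 and (prev - fom[i]) / prev > gain_threshold:
            suggested = k_values[i]
    return FomCurve(k_values, fom, suggested, gain_threshold)
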