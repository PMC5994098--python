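"""Per-stage heat-stress regulation calling from CO/HS profile clusters.

For each developmental stage and level, entities are represented by
their relative abundance across the two conditions — (CO, HS) divided by
their sum — and clustered with k = 7.  Clusters are ordered from
CO-dominated to HS-dominated by their centroid HS fraction; the first
cluster holds downregulated entities, the last upregulated ones, and
everything in between counts as stable.  A pseudocounted log2 HS/CO
ratio per entity serves as an independent diagnostic of the calls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clustering import ClusterModel
from .matrix import PipelineError


def make_condition_profiles(co: pd.Series, hs: pd.Series) -> pd.DataFrame:
    """Relative (CO, HS) profiles; entities zero in both conditions drop out.

    Entities detected under exactly one condition are retained and sit at
    the simplex corners (1, 0) or (0, 1).
    """
    co, hs = co.align(hs, fill_value=0.0)
    total = co + hs
    keep = total > 0
    out = pd.DataFrame(
        {"CO": co[keep] / total[keep], "HS": hs[keep] / total[keep]}
    )
    out.index.name = "entity_id"
    return out


def order_hs_clusters(model: ClusterModel) -> pd.Series:
    """Rank clusters 1..k by increasing centroid HS fraction.

    Rank 1 is the most CO-dominated cluster, rank k the most
    HS-dominated; ties keep cluster-index order (stable sort).
    """
    hs_frac = model.centroids["HS"]
    order = hs_frac.sort_values(kind="stable").index
    ranks = pd.Series(0, index=model.centroids.index, name="rank")
    for r, cl in enumerate(order, start=1):
        ranks[cl] = r
    return ranks


def categorize_regulation(model: ClusterModel, ranks: pd.Series) -> pd.DataFrame:
    """Down/stable/up category per entity from its cluster rank.

    Rank 1 -> down, rank k -> up, anything else -> stable.  Requires
    k >= 3 so that a stable band exists.
    """
    k = model.k
    if k < 3:
        raise PipelineError("regulation categories require k >= 3")
    rank_per_entity = model.assignment.map(ranks)
    category = pd.cut(
        rank_per_entity, bins=[0, 1, k - 1, k], labels=["down", "stable", "up"]
    ).astype(str)
    return pd.DataFrame(
        {"cluster_rank": rank_per_entity, "category": category},
        index=model.assignment.index,
    )


def cluster_distribution_curve(
    percent_per_rank: pd.Series, degree: int = 4
) -> tuple[np.ndarray, pd.Series]:
    """Least-squares polynomial through (rank, percent) — reporting only.

    Returns the polynomial coefficients (ascending order) and the fitted
    values at the observed ranks.  The degree is capped so the fit never
    interpolates exactly through more points than it should.
    """
    ranks = percent_per_rank.index.to_numpy(dtype=float)
    y = percent_per_rank.to_numpy(dtype=float)
    deg = min(degree, len(ranks) - 1)
    poly = np.polynomial.Polynomial.fit(ranks, y, deg).convert()
    fitted = pd.Series(poly(ranks), index=percent_per_rank.index)
    return poly.coef, fitted


def log2_ratio_check(
    co: pd.Series, hs: pd.Series, pseudocount: float = 1.0
) -> pd.Series:
    """Per-entity log2((HS + eps) / (CO + eps)) diagnostic.

    The pseudocount keeps entities detected under one condition finite;
    use 1 for TPM and the minimum positive intensity for LFQ data.
    """
    if pseudocount <= 0:
        raise PipelineError("pseudocount must be positive")
    co, hs = co.align(hs, fill_value=0.0)
    return np.log2((hs + pseudocount) / (co + pseudocount))


def regulation_summary(calls: pd.DataFrame, k: int) -> pd.DataFrame:
    """Percentage of entities per cluster rank."""
    counts = calls["cluster_rank"].value_counts().reindex(
        range(1, k + 1), fill_value=0
    )
    pct = 100.0 * counts / counts.sum() if counts.sum() else counts.astype(float)
    return pd.DataFrame({"count": counts, "percent": pct}).rename_axis("rank")
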