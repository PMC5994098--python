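"""Direct vs delayed translation calling from cluster overlaps.

A cluster is *stage-increased* when one developmental stage carries at
least two-thirds of its centroid's relative abundance — which guarantees
at least a two-fold excess of that stage over each other stage.  The
genes of stage-increased transcript clusters are traced into protein
clusters (and vice versa) through an overlap matrix restricted to genes
detected at both levels.  Overlap counts are min-max scaled per
stage-increased set; partners above 0.5 are interpreted by the dominant
stage of the partner cluster: the same stage means the protein rise
accompanies the transcript rise (direct translation), the next stage
means the protein rise lags by one stage (delayed translation).  Delayed
translation cannot be observed for the last sampled stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import ClusterModel
from .matrix import STAGES, PipelineError


@dataclass
class ModeConfig:
    """Thresholds for stage-increased classification and mode calling."""

    increase_threshold: float = 2.0 / 3.0
    mode_threshold: float = 0.5
    stage_order: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        if not (0 < self.increase_threshold < 1 and 0 < self.mode_threshold < 1):
            raise PipelineError("thresholds must lie strictly between 0 and 1")


@dataclass(frozen=True)
class TranslationCall:
    gene_id: str
    stage: str
    mode: str                     # "direct" or "delayed"
    direction: str                # transcript_to_protein / protein_to_transcript / both
    scaled_overlap: float


@dataclass
class StageIncreasedSet:
    """Stage-increased clusters at one level and their (dual) gene union."""

    stage: str
    level: str
    cluster_ids: list[int]
    gene_ids: pd.Index


def classify_stage_increased(centroid, cfg: ModeConfig) -> str | None:
    """Stage holding >= ``increase_threshold`` of the centroid mass, else None.

    ``centroid`` is a mapping/Series over stages summing to 1.  At most
    one stage can reach two-thirds, so the result is unique.
    """
    s = pd.Series(centroid, dtype=float)
    top = s.idxmax()
    if s[top] >= cfg.increase_threshold:
        return str(top)
    return None


def implied_min_fold(cfg: ModeConfig) -> float:
    """Worst-case fold excess guaranteed by the stage-increased rule.

    With a fraction t >= 1/2 in the increased stage, the largest any
    other stage can reach is 1 - t, so the guaranteed ratio is t/(1-t);
    t = 2/3 guarantees a two-fold increase over each other stage.
    """
    t = cfg.increase_threshold
    if t < 0.5:
        raise PipelineError(
            "increase_threshold below 0.5 guarantees no fold excess"
        )
    return t / (1.0 - t)


def dominant_stage(centroid) -> str:
    """Stage with the largest centroid fraction (no threshold)."""
    return str(pd.Series(centroid, dtype=float).idxmax())


def stage_increased_sets(
    model: ClusterModel, level: str, dual_genes, cfg: ModeConfig
) -> list[StageIncreasedSet]:
    """Stage-increased cluster sets at a level, genes restricted to dual detection."""
    dual = pd.Index(dual_genes)
    by_stage: dict[str, list[int]] = {}
    for cl in range(model.k):
        stage = classify_stage_increased(model.centroids.loc[cl], cfg)
        if stage is not None:
            by_stage.setdefault(stage, []).append(cl)
    out = []
    for stage in cfg.stage_order:
        if stage not in by_stage:
            continue
        clusters = by_stage[stage]
        members = model.assignment.index[model.assignment.isin(clusters)]
        out.append(
            StageIncreasedSet(
                stage=stage, level=level, cluster_ids=clusters,
                gene_ids=members.intersection(dual),
            )
        )
    return out


def build_overlap_matrix(
    tr_model: ClusterModel, pr_model: ClusterModel, dual_genes
) -> pd.DataFrame:
    """Transcript-cluster x protein-cluster shared-gene counts.

    Entry (i, j) counts genes, restricted to those detected at both
    levels, whose transcript sits in cluster i and whose protein sits in
    cluster j.  Genes absent from either model are excluded.
    """
    dual = pd.Index(dual_genes)
    genes = dual.intersection(tr_model.assignment.index).intersection(
        pr_model.assignment.index
    )
    counts = pd.DataFrame(
        0, index=pd.RangeIndex(tr_model.k, name="transcript_cluster"),
        columns=pd.RangeIndex(pr_model.k, name="protein_cluster"),
    )
    if len(genes):
        tab = pd.crosstab(
            tr_model.assignment.loc[genes], pr_model.assignment.loc[genes]
        )
        counts.loc[tab.index, tab.columns] = tab
    return counts


def scale_overlap_row(counts) -> tuple[np.ndarray, bool]:
    """Min-max scale a vector of overlap counts to [0, 1].

    Returns the scaled vector and a degenerate flag; a constant row has
    no defined lowest/highest overlap, scales to all zeros and must not
    produce calls.
    """
    x = np.asarray(counts, dtype=float)
    if x.size == 0:
        raise PipelineError("empty overlap row")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x), True
    return (x - lo) / (hi - lo), False


def _next_stage(stage: str, order) -> str | None:
    i = list(order).index(stage)
    return order[i + 1] if i + 1 < len(order) else None


def _prev_stage(stage: str, order) -> str | None:
    i = list(order).index(stage)
    return order[i - 1] if i > 0 else None


def call_translation_modes(
    tr_model: ClusterModel,
    pr_model: ClusterModel,
    dual_genes,
    cfg: ModeConfig | None = None,
) -> pd.DataFrame:
    """Call direct and delayed translation per gene and stage.

    Both directions are traced: stage-increased transcript clusters
    against all protein clusters, and stage-increased protein clusters
    against all transcript clusters.  For every partner cluster whose
    min-max-scaled overlap exceeds ``mode_threshold``, the partner's
    dominant stage decides the mode:

    * same stage -> direct translation at that stage;
    * one stage later on the protein side -> delayed translation at the
      transcript's stage (never at the final stage, which has no
      successor in the experiment);
    * anything else -> no call.

    Calls from the two directions are unioned per (gene, stage, mode);
    a gene with both a direct and a delayed call at the same stage keeps
    the call with the larger scaled overlap (a tie drops both).

    Returns a frame with columns gene_id, stage, mode, direction,
    scaled_overlap.
    """
    cfg = cfg or ModeConfig()
    order = cfg.stage_order
    dual = pd.Index(dual_genes)
    overlap = build_overlap_matrix(tr_model, pr_model, dual)

    raw: dict[tuple[str, str, str], dict] = {}

    def record(gene: str, stage: str, mode: str, direction: str, scaled: float):
        key = (gene, stage, mode)
        hit = raw.get(key)
        if hit is None:
            raw[key] = {"direction": direction, "scaled": scaled}
        else:
            if hit["direction"] != direction:
                hit["direction"] = "both"
            hit["scaled"] = max(hit["scaled"], scaled)

    def trace(sets, set_model, partner_model, counts, direction):
        # counts: rows = set-side clusters, cols = partner clusters
        for s in sets:
            row = counts.loc[s.cluster_ids].sum(axis=0)
            scaled, degenerate = scale_overlap_row(row.to_numpy())
            if degenerate:
                continue
            for j, val in zip(row.index, scaled):
                if val <= cfg.mode_threshold:
                    continue
                partner_stage = dominant_stage(partner_model.centroids.loc[j])
                if direction == "transcript_to_protein":
                    tr_stage, pr_stage = s.stage, partner_stage
                else:
                    tr_stage, pr_stage = partner_stage, s.stage
                if pr_stage == tr_stage:
                    mode, call_stage = "direct", tr_stage
                elif pr_stage == _next_stage(tr_stage, order):
                    mode, call_stage = "delayed", tr_stage
                else:
                    continue
                if mode == "delayed" and call_stage == order[-1]:
                    continue
                partner_members = partner_model.members(j)
                genes = s.gene_ids.intersection(partner_members)
                for g in genes:
                    record(str(g), call_stage, mode, direction, float(val))

    tr_sets = stage_increased_sets(tr_model, "transcript", dual, cfg)
    pr_sets = stage_increased_sets(pr_model, "protein", dual, cfg)
    trace(tr_sets, tr_model, pr_model, overlap, "transcript_to_protein")
    trace(pr_sets, pr_model, tr_model, overlap.T, "protein_to_transcript")

    # resolve direct-vs-delayed conflicts per (gene, stage)
    rows = []
    by_gene_stage: dict[tuple[str, str], list] = {}
    for (gene, stage, mode), hit in raw.items():
        by_gene_stage.setdefault((gene, stage), []).append((mode, hit))
    for (gene, stage), hits in by_gene_stage.items():
        if len(hits) == 1:
            mode, hit = hits[0]
        else:
            hits = sorted(hits, key=lambda h: -h[1]["scaled"])
            if np.isclose(hits[0][1]["scaled"], hits[1][1]["scaled"]):
                continue  # tie: unclassified
            mode, hit = hits[0]
        rows.append(
            {
                "gene_id": gene, "stage": stage, "mode": mode,
                "direction": hit["direction"],
                "scaled_overlap": hit["scaled"],
            }
        )
    cols = ["gene_id", "stage", "mode", "direction", "scaled_overlap"]
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["stage", "mode", "gene_id"]).reset_index(drop=True)
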