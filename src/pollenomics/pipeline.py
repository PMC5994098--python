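"""End-to-end orchestration: quantification -> clustering -> translation
modes -> heat-stress regulation -> functional and family summaries.

The pipeline mirrors the analysis design it implements: detection
thresholding with a control-gene-derived TPM cutoff, zero-ignoring
replicate averaging, developmental k-means (k = 15, 25 restarts,
lowest-variance selection) under control conditions, cluster-overlap
translation-mode calling, per-stage CO/HS clustering (k = 7) with
rank-based regulation categories, and KOG / family reporting.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from . import io as pio
from .annotation import (
    condition_detected_any,
    family_regulation_summary,
    functional_distribution,
)
from .clustering import (
    ClusterModel,
    FomCurve,
    figure_of_merit,
    fit_kmeans,
    make_relative_profiles,
)
from .hs_response import (
    categorize_regulation,
    cluster_distribution_curve,
    log2_ratio_check,
    make_condition_profiles,
    order_hs_clusters,
    regulation_summary,
)
from .matrix import CONDITIONS, STAGES, ExpressionMatrix, PipelineError
from .quantification import (
    DetectionConfig,
    apply_protein_detection,
    apply_transcript_detection,
    average_replicates,
    compute_tpm,
    derive_detection_threshold,
    gene_level_protein_matrix,
)
from .translation import ModeConfig, build_overlap_matrix, call_translation_modes

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters of a full pipeline run."""

    counts: str
    metadata: str
    aligned_totals: str
    protein_groups: str
    protein_gene_map: str
    control_genes: str | None = None
    kog: str | None = None
    families: str | None = None
    outdir: str = "results"
    tpm_threshold: float | None = None  # None -> derive from control genes
    k_dev: int = 15
    k_hs: int = 7
    n_runs: int = 25
    seed: int = 0
    compute_fom: bool = True
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    modes: ModeConfig = field(default_factory=ModeConfig)

    def __post_init__(self) -> None:
        if self.k_dev < 3 or self.k_hs < 3:
            raise PipelineError("cluster numbers must be >= 3")


@dataclass
class PipelineResult:
    """In-memory results of a pipeline run."""

    threshold: float
    tr_avg: ExpressionMatrix
    pr_avg: ExpressionMatrix
    tr_flags: pd.DataFrame
    pr_flags: pd.DataFrame
    dual_genes: pd.Index
    tr_model: ClusterModel
    pr_model: ClusterModel
    overlap: pd.DataFrame
    mode_calls: pd.DataFrame
    regulation: dict[tuple[str, str], pd.DataFrame]
    hs_models: dict[tuple[str, str], ClusterModel]
    fom: dict[str, FomCurve]
    summary: dict


def _stage_detected(flags: pd.DataFrame, condition: str) -> pd.DataFrame:
    out = pd.DataFrame(index=flags.index)
    for stage in STAGES:
        col = (stage, condition)
        out[stage] = flags[col] if col in flags.columns else False
    return out


def _venn(stage_detected: pd.DataFrame) -> dict:
    union = int(stage_detected.any(axis=1).sum())
    common = int(stage_detected.all(axis=1).sum())
    pct = 100.0 * common / union if union else float("nan")
    return {"union": union, "common": common, "common_percent": round(pct, 1)}


def pca_diagnostics(matrix: ExpressionMatrix, n_components: int = 3):
    """PCA of library profiles with variance-explained fractions.

    Libraries are observations; genes (variables) are standardised
    before projection, following common practice for expression PCA.
    Returns (coordinates frame indexed by library, explained-variance
    Series).
    """
    X = matrix.values.T.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise PipelineError("PCA requires at least 2 libraries")
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        logger.warning("constant matrix: PCA is degenerate")
        coords = pd.DataFrame(
            0.0, index=matrix.library_ids,
            columns=[f"PC{i+1}" for i in range(n_components)],
        )
        return coords, pd.Series(dtype=float)
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    k = min(n_components, X.shape[0] - 1, int(keep.sum()))
    pca = PCA(n_components=k, random_state=0).fit(Z)
    coords = pd.DataFrame(
        pca.transform(Z), index=matrix.library_ids,
        columns=[f"PC{i+1}" for i in range(k)],
    )
    return coords, pd.Series(pca.explained_variance_ratio_,
                             index=coords.columns, name="variance_fraction")


def run_pipeline_on_dataset(
    dataset,
    k_dev: int = 15,
    k_hs: int = 7,
    n_runs: int = 25,
    seed: int = 0,
    detection: DetectionConfig | None = None,
    modes: ModeConfig | None = None,
    tpm_threshold: float | None = None,
    compute_fom: bool = False,
) -> PipelineResult:
    """Run the full analysis on an in-memory dataset.

    ``dataset`` provides ``counts``, ``aligned_totals``, ``proteins``,
    ``protein_gene_map`` and optionally ``control_genes``, ``kog`` and
    ``families`` (the shape produced by the synthetic generator).
    """
    modes = modes or ModeConfig()
    rng = np.random.default_rng(seed)

    def child_seed() -> int:
        return int(rng.integers(2**31 - 1))

    # ---- quantification -------------------------------------------------
    tpm = compute_tpm(dataset.counts, dataset.aligned_totals)
    if tpm_threshold is None:
        controls = getattr(dataset, "control_genes", None)
        if controls:
            control_vals = tpm.values.loc[
                tpm.values.index.intersection(pd.Index(controls))
            ].to_numpy().ravel()
            tpm_threshold = derive_detection_threshold(control_vals)
            logger.info("derived detection threshold: %s TPM", tpm_threshold)
        else:
            tpm_threshold = DetectionConfig().tpm_threshold
    detection = detection or DetectionConfig()
    detection = DetectionConfig(
        tpm_threshold=tpm_threshold,
        transcript_min_replicates=detection.transcript_min_replicates,
        protein_min_replicates=detection.protein_min_replicates,
    )
    tpm_f, tr_flags = apply_transcript_detection(tpm, detection)
    tr_avg = average_replicates(tpm_f)

    pr_gene, unmapped = gene_level_protein_matrix(
        dataset.proteins, dataset.protein_gene_map
    )
    from .quantification import _detection_flags  # gene-level flags

    pr_flags = _detection_flags(pr_gene, detection.protein_min_replicates)
    pr_avg = average_replicates(pr_gene)

    tr_co = _stage_detected(tr_flags, "CO")
    pr_co = _stage_detected(pr_flags, "CO")
    dual_genes = tr_co.index[tr_co.any(axis=1)].intersection(
        pr_co.index[pr_co.any(axis=1)]
    )

    # ---- developmental clustering (CO) ---------------------------------
    co_cols = [f"{s}:CO" for s in STAGES]
    fom: dict[str, FomCurve] = {}
    models = {}
    for level, avg, det in (
        ("transcript", tr_avg, tr_co),
        ("protein", pr_avg, pr_co),
    ):
        included = det.index[det.any(axis=1)]
        profiles, dropped = make_relative_profiles(
            avg.subset(included), co_cols
        )
        profiles.columns = list(STAGES)  # sample labels = stages under CO
        if dropped:
            logger.info("%s: %d all-zero rows dropped before clustering",
                        level, len(dropped))
        if compute_fom:
            ks = range(2, min(21, len(profiles) - 1))
            fom[level] = figure_of_merit(profiles, ks, seed=child_seed())
        models[level] = fit_kmeans(profiles, k_dev, n_runs, child_seed())
    tr_model, pr_model = models["transcript"], models["protein"]

    overlap = build_overlap_matrix(tr_model, pr_model, dual_genes)
    mode_calls = call_translation_modes(tr_model, pr_model, dual_genes, modes)

    # ---- heat-stress response per stage and level ----------------------
    regulation: dict[tuple[str, str], pd.DataFrame] = {}
    hs_models: dict[tuple[str, str], ClusterModel] = {}
    for level, avg, flags in (
        ("transcript", tr_avg, tr_flags),
        ("protein", pr_avg, pr_flags),
    ):
        for stage in STAGES:
            co = avg.values[f"{stage}:CO"]
            hs = avg.values[f"{stage}:HS"]
            det_any = pd.Series(False, index=avg.values.index)
            for cond in CONDITIONS:
                col = (stage, cond)
                if col in flags.columns:
                    det_any |= flags[col].reindex(det_any.index, fill_value=False)
            profiles = make_condition_profiles(co[det_any], hs[det_any])
            model = fit_kmeans(profiles, k_hs, n_runs, child_seed())
            ranks = order_hs_clusters(model)
            calls = categorize_regulation(model, ranks)
            eps = 1.0 if level == "transcript" else max(
                float(co[co > 0].min() if (co > 0).any() else 1.0), 1e-9
            )
            calls["log2_hs_co"] = log2_ratio_check(co, hs, eps).reindex(calls.index)
            regulation[(level, stage)] = calls
            hs_models[(level, stage)] = model

    # ---- summaries ------------------------------------------------------
    detected_counts = {
        level: {
            f"{stage}:{cond}": int(flags[(stage, cond)].sum())
            for (stage, cond) in flags.columns
        }
        for level, flags in (("transcript", tr_flags), ("protein", pr_flags))
    }
    venn = {
        level: {
            cond: _venn(_stage_detected(flags, cond)) for cond in CONDITIONS
        }
        for level, flags in (("transcript", tr_flags), ("protein", pr_flags))
    }
    mode_counts = (
        mode_calls.groupby(["stage", "mode"]).size().to_dict()
        if len(mode_calls) else {}
    )
    reg_counts = {
        f"{level}:{stage}": frame["category"].value_counts().to_dict()
        for (level, stage), frame in regulation.items()
    }
    summary = {
        "seed": seed,
        "tpm_threshold": float(tpm_threshold),
        "n_unmapped_members": len(unmapped),
        "detected": detected_counts,
        "common_across_stages": venn,
        "mode_call_counts": {f"{s}:{m}": int(c) for (s, m), c in mode_counts.items()},
        "regulation_counts": reg_counts,
        "n_dual_genes": int(len(dual_genes)),
    }
    return PipelineResult(
        threshold=float(tpm_threshold),
        tr_avg=tr_avg, pr_avg=pr_avg,
        tr_flags=tr_flags, pr_flags=pr_flags,
        dual_genes=dual_genes,
        tr_model=tr_model, pr_model=pr_model,
        overlap=overlap, mode_calls=mode_calls,
        regulation=regulation, hs_models=hs_models,
        fom=fom, summary=summary,
    )


@dataclass
class _FileDataset:
    counts: ExpressionMatrix
    aligned_totals: dict
    proteins: object
    protein_gene_map: dict
    control_genes: list | None


def load_dataset(cfg: RunConfig) -> _FileDataset:
    meta = pio.read_metadata(cfg.metadata)
    counts = pio.read_counts(cfg.counts, meta)
    totals = pio.read_aligned_totals(cfg.aligned_totals)
    proteins = pio.read_protein_groups(cfg.protein_groups, meta)
    mapping = pio.read_protein_gene_map(cfg.protein_gene_map)
    controls = pio.read_gene_list(cfg.control_genes) if cfg.control_genes else None
    return _FileDataset(counts, totals, proteins, mapping, controls)


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """File-based pipeline run: read inputs, analyse, write all outputs."""
    dataset = load_dataset(cfg)
    if len(dataset.counts.entity_ids) == 0:
        raise PipelineError("empty input gene set")
    result = run_pipeline_on_dataset(
        dataset,
        k_dev=cfg.k_dev, k_hs=cfg.k_hs, n_runs=cfg.n_runs, seed=cfg.seed,
        detection=cfg.detection, modes=cfg.modes,
        tpm_threshold=cfg.tpm_threshold, compute_fom=cfg.compute_fom,
    )
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    # cluster assignments and centroids
    assign = []
    for level, model in (("transcript", result.tr_model),
                         ("protein", result.pr_model)):
        prefix = "Tr" if level == "transcript" else "Pr"
        for entity, cl in model.assignment.items():
            assign.append(
                {"entity_id": entity, "level": level, "k": model.k,
                 "cluster_id": f"{prefix}{cl + 1}"}
            )
        model.centroids.rename(
            index=lambda c: f"{prefix}{c + 1}"
        ).to_csv(out / f"centroids_{level}.tsv", sep="\t")
    pd.DataFrame(assign).to_csv(out / "clusters_developmental.tsv",
                                sep="\t", index=False)
    result.overlap.rename(index=lambda i: f"Tr{i + 1}",
                          columns=lambda j: f"Pr{j + 1}").to_csv(
        out / "overlap_matrix.tsv", sep="\t")
    result.mode_calls.to_csv(out / "translation_modes.tsv", sep="\t", index=False)

    reg_rows = []
    for (level, stage), frame in result.regulation.items():
        for entity, row in frame.iterrows():
            reg_rows.append(
                {"entity_id": entity, "stage": stage, "level": level,
                 "cluster_rank": int(row["cluster_rank"]),
                 "category": row["category"]}
            )
    pd.DataFrame(reg_rows).to_csv(out / "hs_regulation.tsv", sep="\t", index=False)

    pct_rows = []
    for (level, stage), frame in result.regulation.items():
        summary_tab = regulation_summary(frame, cfg.k_hs)
        coefs, fitted = cluster_distribution_curve(summary_tab["percent"])
        for rank, row in summary_tab.iterrows():
            pct_rows.append(
                {"level": level, "stage": stage, "rank": rank,
                 "count": int(row["count"]), "percent": row["percent"],
                 "fitted_percent": float(fitted[rank])}
            )
    pd.DataFrame(pct_rows).to_csv(out / "hs_cluster_distribution.tsv",
                                  sep="\t", index=False)

    for level, curve in result.fom.items():
        curve.frame.to_csv(out / f"fom_{level}.tsv", sep="\t", index=False)

    # optional annotation summaries
    if cfg.kog:
        kog = pio.read_kog(cfg.kog)
        func_rows = []
        for (stage, mode), grp in result.mode_calls.groupby(["stage", "mode"]):
            dist = functional_distribution(grp["gene_id"], kog)
            for cat, row in dist.iterrows():
                func_rows.append(
                    {"stage": stage, "mode": mode, "category": cat,
                     "count": int(row["count"]), "percent": row["percent"],
                     "below_cutoff": bool(row["below_cutoff"])}
                )
        pd.DataFrame(func_rows).to_csv(out / "functional_distribution.tsv",
                                       sep="\t", index=False)
    if cfg.families:
        families = pio.read_families(cfg.families)
        fam_frames = []
        tr_det = condition_detected_any(result.tr_flags)
        pr_det = condition_detected_any(result.pr_flags)
        for level, det in (("transcript", tr_det), ("protein", pr_det)):
            reg = pd.DataFrame(
                [
                    {"entity_id": e, "stage": st, "category": row["category"]}
                    for (lev, st), fr in result.regulation.items()
                    if lev == level
                    for e, row in fr.iterrows()
                ]
            )
            fam = family_regulation_summary(
                families, reg, det, level,
                transcript_detected=tr_det if level == "protein" else None,
            )
            fam["level"] = level
            fam_frames.append(fam)
        pd.concat(fam_frames).to_csv(out / "family_regulation.tsv",
                                     sep="\t", index=False)

    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete; outputs in %s", out)
    return result
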