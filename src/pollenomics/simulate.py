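"""Synthetic multi-omics datasets with planted ground truth.

The generator emulates the experimental design the pipeline targets:
three pollen developmental stages x two temperature conditions, with two
transcript replicates (3'-tag count libraries) and three protein
replicates (label-free intensity libraries) per group.  Transcript
counts are negative-binomial around class-implied means; protein
intensities are log-normal with per-replicate technical dropout encoded
as zero.  Background genes follow stage-detection masks that shrink the
transcriptome and grow the proteome from tetrads to mature pollen, the
qualitative pattern the analysis assumes.

Planted classes
---------------
* ``control`` — plastid-like genes with expected TPM below the detection
  threshold everywhere;
* ``direct_<stage>`` — transcript and protein elevated at the same stage;
* ``delayed_<stage>`` — transcript elevated at the stage, protein
  elevated one stage later (not plantable for the final stage);
* ``hs_up`` / ``hs_down`` at each level and stage — heat stress
  multiplies (divides) the affected level's mean at that stage;
* ``background`` — constitutive or stage-masked genes with no planted
  structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import CONDITIONS, STAGES, ExpressionMatrix, PipelineError, ProteinQuantTable
from . import io as pio

KOG_LETTERS = "ACDEFGIJKLMNOPQTUVWYZBRS"
FAMILY_NAMES = ("Hsp100", "Hsp90", "Hsp70", "Hsp60", "Hsp40", "sHsp", "Hsp10", "Hsf")


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic dataset.

    Defaults reflect the targeted experimental design: ~3000 genes, two
    transcript and three protein replicates, moderate tag-count
    overdispersion and multiplicative intensity noise, and planted
    stage/HS effects strong enough to be biologically meaningful
    (stage fold 6, i.e. three-quarters of the profile mass in one stage;
    HS fold 8).
    """

    n_genes: int = 3000
    n_controls: int = 16
    n_direct_per_stage: int = 100
    n_delayed_per_stage: int = 100
    n_hs_up_transcript: int = 40
    n_hs_down_transcript: int = 40
    n_hs_up_protein: int = 50
    n_hs_down_protein: int = 50
    background_protein_fraction: float = 0.35
    n_paired_groups: int = 30
    # stage-detection masks for background genes (shrinking transcriptome,
    # growing proteome from tetrad to mature)
    transcript_stage_prob: tuple[float, float, float] = (0.95, 0.80, 0.60)
    protein_stage_prob: tuple[float, float, float] = (0.50, 0.65, 0.80)
    # abundance model
    library_depth: float = 2e6
    base_tpm_log_mean: float = float(np.log(60.0))
    base_tpm_log_sd: float = 0.8
    base_tpm_min: float = 20.0
    control_tpm: float = 1.0
    count_dispersion: float = 0.05
    intensity_log_mean: float = float(np.log(1e7))
    intensity_log_sd: float = 1.0
    intensity_noise_sd: float = 0.4
    protein_dropout: float = 0.05
    stage_fold: float = 6.0
    stage_fold_log_sd: float = 0.2
    hs_fold: float = 8.0
    n_transcript_replicates: int = 2
    n_protein_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        planted = (
            self.n_controls
            + 3 * self.n_direct_per_stage
            + 2 * self.n_delayed_per_stage
            + 3 * (self.n_hs_up_transcript + self.n_hs_down_transcript)
            + 3 * (self.n_hs_up_protein + self.n_hs_down_protein)
        )
        if planted > self.n_genes:
            raise PipelineError(
                f"planted classes ({planted}) exceed n_genes ({self.n_genes})"
            )
        if self.stage_fold <= 1 or self.hs_fold <= 1:
            raise PipelineError("fold parameters must exceed 1")
        for p in (*self.transcript_stage_prob, *self.protein_stage_prob,
                  self.protein_dropout):
            if not 0 <= p <= 1:
                raise PipelineError("probabilities must lie in [0, 1]")


@dataclass
class SimulatedDataset:
    """All pipeline inputs plus the planted truth."""

    counts: ExpressionMatrix
    aligned_totals: dict[str, float]
    proteins: ProteinQuantTable
    control_genes: list[str]
    kog: dict[str, set[str]]
    families: dict[str, list[str]]
    protein_gene_map: dict[str, str]
    truth: pd.DataFrame

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        meta = pd.concat([self.counts.meta, self.proteins.meta])
        pio.write_metadata(meta, out / "libraries.tsv")
        pio.write_counts(self.counts, out / "counts.tsv")
        pio.write_aligned_totals(self.aligned_totals, out / "aligned_totals.tsv")
        pio.write_protein_groups(self.proteins, out / "proteinGroups.tsv")
        pio.write_gene_list(self.control_genes, out / "control_genes.txt")
        pio.write_kog(self.kog, out / "kog.tsv")
        pio.write_families(self.families, out / "families.tsv")
        pio.write_protein_gene_map(self.protein_gene_map, out / "protein_gene_map.tsv")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """Negative-binomial draw with var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros_like(mean)
    pos = mean > 0
    if dispersion <= 0:
        out[pos] = rng.poisson(mean[pos])
        return out
    n = 1.0 / dispersion
    p = n / (n + mean[pos])
    out[pos] = rng.negative_binomial(n, p)
    return out


def simulate_dataset(cfg: SimConfig | None = None) -> SimulatedDataset:
    """Generate a full synthetic dataset, deterministic given ``cfg.seed``."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    stages = list(STAGES)
    last = len(stages) - 1

    genes = [f"Gene{i:05d}" for i in range(1, cfg.n_genes + 1)]
    # --- class assignment (deterministic block layout) -------------------
    rows = []
    cursor = 0

    def take(n):
        nonlocal cursor
        block = genes[cursor:cursor + n]
        cursor += n
        return block

    controls = take(cfg.n_controls)
    for g in controls:
        rows.append((g, "control", "", "", "", ""))
    direct: dict[str, list[str]] = {}
    delayed: dict[str, list[str]] = {}
    for s in stages:
        direct[s] = take(cfg.n_direct_per_stage)
        for g in direct[s]:
            rows.append((g, f"direct_{s}", s, "both", "direct", ""))
    for s in stages[:last]:
        delayed[s] = take(cfg.n_delayed_per_stage)
        for g in delayed[s]:
            rows.append((g, f"delayed_{s}", s, "both", "delayed", ""))
    hs_planted: dict[tuple[str, str, str], list[str]] = {}
    for level, n_up, n_down in (
        ("transcript", cfg.n_hs_up_transcript, cfg.n_hs_down_transcript),
        ("protein", cfg.n_hs_up_protein, cfg.n_hs_down_protein),
    ):
        for s in stages:
            hs_planted[("up", level, s)] = take(n_up)
            for g in hs_planted[("up", level, s)]:
                rows.append((g, f"hs_up_{level}_{s}", s, level, "", "up"))
            hs_planted[("down", level, s)] = take(n_down)
            for g in hs_planted[("down", level, s)]:
                rows.append((g, f"hs_down_{level}_{s}", s, level, "", "down"))
    background = take(cfg.n_genes - cursor)
    for g in background:
        rows.append((g, "background", "", "", "", ""))
    truth = pd.DataFrame(
        rows,
        columns=["gene_id", "gene_class", "stage", "level", "true_mode",
                 "true_regulation"],
    )
    gene_class = dict(zip(truth["gene_id"], truth["gene_class"]))

    # --- transcript expected TPM per gene x stage x condition ------------
    n = cfg.n_genes
    base = np.exp(
        rng.normal(cfg.base_tpm_log_mean, cfg.base_tpm_log_sd, size=n)
    ).clip(min=cfg.base_tpm_min)
    stage_fold = np.exp(
        rng.normal(np.log(cfg.stage_fold), cfg.stage_fold_log_sd, size=n)
    )
    gidx = {g: i for i, g in enumerate(genes)}
    exp_tpm = np.zeros((n, len(stages), 2))  # gene x stage x condition

    tr_mask = rng.random((n, len(stages))) < np.asarray(cfg.transcript_stage_prob)
    for g in genes:
        i = gidx[g]
        cls = gene_class[g]
        if cls == "control":
            exp_tpm[i, :, :] = cfg.control_tpm
            continue
        if cls == "background":
            prof = tr_mask[i].astype(float)
        else:
            prof = np.ones(len(stages))  # planted genes expressed everywhere
        if cls.startswith(("direct_", "delayed_")):
            s = stages.index(cls.split("_", 1)[1])
            prof = prof.copy()
            prof[s] *= stage_fold[i]
        vals = base[i] * prof
        exp_tpm[i, :, 0] = vals
        exp_tpm[i, :, 1] = vals
        if cls.startswith("hs_up_transcript_"):
            s = stages.index(cls.removeprefix("hs_up_transcript_"))
            exp_tpm[i, s, 1] *= cfg.hs_fold
        elif cls.startswith("hs_down_transcript_"):
            s = stages.index(cls.removeprefix("hs_down_transcript_"))
            exp_tpm[i, s, 1] /= cfg.hs_fold

    # --- draw transcript counts -----------------------------------------
    t_libs, t_meta, t_cols = [], [], {}
    totals: dict[str, float] = {}
    for si, s in enumerate(stages):
        for ci, c in enumerate(CONDITIONS):
            for r in range(1, cfg.n_transcript_replicates + 1):
                lib = f"T_{s}_{c}_{r}"
                mean_counts = exp_tpm[:, si, ci] * cfg.library_depth / 1e6
                t_cols[lib] = _nb_draw(rng, mean_counts, cfg.count_dispersion)
                t_meta.append(
                    {"library_id": lib, "level": "transcript", "stage": s,
                     "condition": c, "replicate": r}
                )
                totals[lib] = cfg.library_depth
                t_libs.append(lib)
    counts = ExpressionMatrix(
        pd.DataFrame(t_cols, index=pd.Index(genes, name="gene_id")),
        pd.DataFrame(t_meta).set_index("library_id"),
        "count",
    )

    # --- protein universe and expected intensities -----------------------
    n_bg_protein = int(round(cfg.background_protein_fraction * len(background)))
    bg_protein = list(background[:n_bg_protein])
    protein_genes = (
        [g for s in stages for g in direct[s]]
        + [g for s in stages[:last] for g in delayed[s]]
        + [g for key, gl in hs_planted.items() if key[1] == "protein" for g in gl]
        + bg_protein
    )
    pidx = {g: i for i, g in enumerate(protein_genes)}
    np_ = len(protein_genes)
    ibase = np.exp(rng.normal(cfg.intensity_log_mean, cfg.intensity_log_sd, size=np_))
    pr_mask = rng.random((np_, len(stages))) < np.asarray(cfg.protein_stage_prob)
    exp_int = np.zeros((np_, len(stages), 2))
    for g in protein_genes:
        i = pidx[g]
        cls = gene_class[g]
        if cls == "background":
            prof = pr_mask[i].astype(float)
        else:
            prof = np.ones(len(stages))
        if cls.startswith("direct_"):
            s = stages.index(cls.split("_", 1)[1])
            prof = prof.copy()
            prof[s] *= stage_fold[gidx[g]]
        elif cls.startswith("delayed_"):
            s = stages.index(cls.split("_", 1)[1])
            prof = prof.copy()
            prof[s + 1] *= stage_fold[gidx[g]]  # protein lags by one stage
        vals = ibase[i] * prof
        exp_int[i, :, 0] = vals
        exp_int[i, :, 1] = vals
        if cls.startswith("hs_up_protein_"):
            s = stages.index(cls.removeprefix("hs_up_protein_"))
            exp_int[i, s, 1] *= cfg.hs_fold
        elif cls.startswith("hs_down_protein_"):
            s = stages.index(cls.removeprefix("hs_down_protein_"))
            exp_int[i, s, 1] /= cfg.hs_fold

    # --- protein groups: pair some background genes, rest singletons -----
    members: dict[str, list[str]] = {}
    group_rows: list[np.ndarray] = []
    p_meta = []
    p_lib_ids = []
    for si, s in enumerate(stages):
        for c in CONDITIONS:
            for r in range(1, cfg.n_protein_replicates + 1):
                lib = f"P_{s}_{c}_{r}"
                p_lib_ids.append(lib)
                p_meta.append(
                    {"library_id": lib, "level": "protein", "stage": s,
                     "condition": c, "replicate": r}
                )

    def draw_intensities(i: int) -> np.ndarray:
        vals = []
        for si in range(len(stages)):
            for ci in range(2):
                mu = exp_int[i, si, ci]
                for _ in range(cfg.n_protein_replicates):
                    if mu <= 0 or rng.random() < cfg.protein_dropout:
                        vals.append(0.0)
                    else:
                        vals.append(mu * np.exp(rng.normal(0, cfg.intensity_noise_sd)))
        return np.array(vals)

    n_pairs = min(cfg.n_paired_groups, len(bg_protein) // 2)
    paired = set()
    gi = 0
    for p in range(n_pairs):
        g1, g2 = bg_protein[2 * p], bg_protein[2 * p + 1]
        paired.update((g1, g2))
        gi += 1
        members[f"PG{gi}"] = [f"{g1}.1", f"{g2}.1"]
        group_rows.append(draw_intensities(pidx[g1]))
    for g in protein_genes:
        if g in paired:
            continue
        gi += 1
        members[f"PG{gi}"] = [f"{g}.1"]
        group_rows.append(draw_intensities(pidx[g]))
    intens = pd.DataFrame(
        np.vstack(group_rows),
        index=pd.Index(members.keys(), name="group_id"),
        columns=p_lib_ids,
    )
    # reorder draw layout (stage, cond, rep) to library order (already matches)
    proteins = ProteinQuantTable(
        members, intens, pd.DataFrame(p_meta).set_index("library_id")
    )
    protein_gene_map = {f"{g}.1": g for g in protein_genes}

    # --- annotations ------------------------------------------------------
    kog: dict[str, set[str]] = {}
    informative = [c for c in KOG_LETTERS if c not in "RS"]
    for g in genes:
        u = rng.random()
        if u < 0.15:
            continue  # unannotated
        if u < 0.25:
            kog[g] = set(rng.choice(["R", "S"], size=1))
            continue
        n_cat = 1 + int(rng.random() < 0.3)
        cats = set(rng.choice(informative, size=n_cat, replace=False))
        if rng.random() < 0.1:
            cats.add("R")
        kog[g] = cats

    families: dict[str, list[str]] = {}
    # family members mix HS-responsive and unresponsive proteins so the
    # summaries exercise every regulation category
    up_pool = [g for s in stages for g in hs_planted[("up", "protein", s)]]
    bg_pool = bg_protein[2 * n_pairs:]
    fam_pool = [g for pair in zip(up_pool, bg_pool) for g in pair]
    pool_iter = iter(fam_pool)
    for fam in FAMILY_NAMES:
        members_f = [next(pool_iter) for _ in range(8)]
        families[fam] = members_f

    return SimulatedDataset(
        counts=counts,
        aligned_totals=totals,
        proteins=proteins,
        control_genes=controls,
        kog=kog,
        families=families,
        protein_gene_map=protein_gene_map,
        truth=truth,
    )


def recovery_report(
    truth: pd.DataFrame,
    mode_calls: pd.DataFrame,
    regulation: dict[tuple[str, str], pd.DataFrame],
) -> pd.DataFrame:
    """Sensitivity/precision of mode and regulation calls against truth.

    ``regulation`` maps (level, stage) -> frame indexed by entity with a
    ``category`` column.  Mode metrics are pooled over stages per mode;
    regulation metrics are per level and direction, restricted to the
    stage each effect was planted at.
    """
    out = []
    for mode in ("direct", "delayed"):
        truth_set = {
            (r.gene_id, r.stage)
            for r in truth.itertuples(index=False)
            if r.true_mode == mode
        }
        call_set = {
            (r.gene_id, r.stage)
            for r in mode_calls.itertuples(index=False)
            if r.mode == mode
        }
        tp = len(truth_set & call_set)
        sens = tp / len(truth_set) if truth_set else float("nan")
        prec = tp / len(call_set) if call_set else float("nan")
        out.append(
            {"call": mode, "level": "both", "n_true": len(truth_set),
             "n_called": len(call_set), "sensitivity": sens, "precision": prec}
        )
    for direction in ("up", "down"):
        for level in ("transcript", "protein"):
            truth_set = {
                (r.gene_id, r.stage)
                for r in truth.itertuples(index=False)
                if r.true_regulation == direction and r.level == level
            }
            call_set = set()
            for (lev, stage), frame in regulation.items():
                if lev != level:
                    continue
                hits = frame.index[frame["category"] == direction]
                call_set.update((g, stage) for g in hits)
            tp = len(truth_set & call_set)
            sens = tp / len(truth_set) if truth_set else float("nan")
            prec = tp / len(call_set) if call_set else float("nan")
            out.append(
                {"call": f"hs_{direction}", "level": level,
                 "n_true": len(truth_set), "n_called": len(call_set),
                 "sensitivity": sens, "precision": prec}
            )
    return pd.DataFrame(out)


def end_to_end_recovery(cfg: SimConfig | None = None, **pipeline_kwargs):
    """Simulate, run the full pipeline and score calls against truth.

    Returns (recovery frame, pipeline result, dataset).
    """
    from .pipeline import run_pipeline_on_dataset

    ds = simulate_dataset(cfg)
    result = run_pipeline_on_dataset(ds, **pipeline_kwargs)
    rec = recovery_report(ds.truth, result.mode_calls, result.regulation)
    return rec, result, ds
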