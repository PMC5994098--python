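"""Detection-thresholded quantification of 3'-tag transcript counts and
label-free protein intensities.

MACE is a 3'-tag protocol producing one tag per transcript molecule, so
TPM here is *tags per million*: read count divided by the library's
aligned-read total, times 1e6 — no transcript-length term.

A gene counts as detected at the transcript level when its TPM clears a
threshold derived from control genes (plastid light-harvesting genes,
which pollen cannot express) in a minimum number of replicates; a protein
group counts as detected when its intensity is non-zero in a minimum
number of replicates.  Replicate averaging ignores zero replicates, so an
averaged value reflects only the libraries in which the entity was seen.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .matrix import CONDITIONS, STAGES, ExpressionMatrix, PipelineError, ProteinQuantTable

logger = logging.getLogger(__name__)


@dataclass
class DetectionConfig:
    """Detection rules for transcripts and protein groups.

    Parameters
    ----------
    tpm_threshold
        TPM values strictly below this are zeroed (default 5, derived
        from the plastid control genes).
    transcript_min_replicates
        Replicates that must remain non-zero for a transcript to count as
        detected in a (stage, condition) group (default 2 of 2).
    protein_min_replicates
        Non-zero replicates required for a protein group (default 2 of 3).
    """

    tpm_threshold: float = 5
    transcript_min_replicates: int = 2
    protein_min_replicates: int = 2

    def __post_init__(self) -> None:
        if self.tpm_threshold < 1 or self.transcript_min_replicates < 1 \
                or self.protein_min_replicates < 1:
            raise PipelineError("detection parameters must be >= 1")


def compute_tpm(
    counts: ExpressionMatrix, aligned_totals: Mapping[str, float]
) -> ExpressionMatrix:
    """Tags-per-million normalisation of a raw count matrix.

    ``tpm[g, lib] = 1e6 * count[g, lib] / aligned_totals[lib]``.

    ``aligned_totals`` gives the number of aligned reads per library; it
    must cover every library and be at least the column sum (a library
    cannot have fewer aligned reads than reads assigned to genes).
    """
    if counts.unit != "count":
        raise PipelineError(f"expected count unit, got {counts.unit!r}")
    totals = []
    for lib in counts.library_ids:
        if lib not in aligned_totals:
            raise KeyError(f"no aligned-read total for library {lib!r}")
        tot = float(aligned_totals[lib])
        if tot <= 0:
            raise PipelineError(f"aligned total for {lib!r} must be positive")
        if counts.values[lib].sum() > tot:
            raise PipelineError(
                f"library {lib!r}: assigned reads exceed aligned total"
            )
        totals.append(tot)
    tpm = counts.values.div(pd.Series(totals, index=counts.library_ids)) * 1e6
    return ExpressionMatrix(tpm, counts.meta.copy(), "TPM")


def derive_detection_threshold(control_tpms: Iterable[float]) -> int:
    """Smallest positive integer strictly above the maximal control TPM.

    Control genes are biologically silent, so any signal they show is
    background; the detection threshold is placed just above their
    maximum (e.g. a maximal control TPM of 4.3 yields a threshold of 5).
    """
    vals = np.asarray(list(control_tpms), dtype=float)
    if vals.size == 0:
        raise PipelineError("control gene set is empty; supply a threshold directly")
    top = float(vals.max())
    return max(1, math.floor(top) + 1)


def apply_transcript_detection(
    tpm: ExpressionMatrix, cfg: DetectionConfig
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Zero sub-threshold TPMs and flag detection per gene and group.

    Values strictly below ``cfg.tpm_threshold`` are set to 0 cell-wise;
    a gene is detected in a (stage, condition) group iff at least
    ``cfg.transcript_min_replicates`` of its replicate columns remain
    non-zero.  Returns the filtered matrix and a boolean gene x
    (stage, condition) flag frame.
    """
    if tpm.unit != "TPM":
        raise PipelineError(f"expected TPM unit, got {tpm.unit!r}")
    vals = tpm.values.where(tpm.values >= cfg.tpm_threshold, 0.0)
    filtered = ExpressionMatrix(vals, tpm.meta.copy(), "TPM")
    flags = _detection_flags(filtered, cfg.transcript_min_replicates)
    return filtered, flags


def apply_protein_detection(
    pq: ProteinQuantTable, cfg: DetectionConfig
) -> pd.DataFrame:
    """Detection flags per protein group and (stage, condition).

    A group is detected iff at least ``cfg.protein_min_replicates``
    replicates carry a non-zero intensity.
    """
    return _detection_flags(pq.as_matrix(), cfg.protein_min_replicates)


def _detection_flags(matrix: ExpressionMatrix, min_replicates: int) -> pd.DataFrame:
    groups = matrix.group_columns()
    cols = pd.MultiIndex.from_tuples(groups.keys(), names=["stage", "condition"])
    flags = pd.DataFrame(False, index=matrix.entity_ids, columns=cols)
    for key, libs in groups.items():
        if len(libs) < min_replicates:
            raise PipelineError(
                f"group {key} has {len(libs)} replicates, fewer than the "
                f"required {min_replicates}"
            )
        flags[key] = (matrix.values[libs] > 0).sum(axis=1) >= min_replicates
    return flags


def average_replicates(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Average replicates per (stage, condition), ignoring zero replicates.

    The mean is taken over strictly positive replicate values only; an
    entity with all-zero replicates in a group averages to 0.
    """
    groups = matrix.group_columns()
    data = {}
    meta_rows = []
    for (stage, cond), libs in groups.items():
        lib_id = f"{stage}:{cond}"
        block = matrix.values[libs]
        pos = block.where(block > 0)
        data[lib_id] = pos.mean(axis=1).fillna(0.0)
        meta_rows.append(
            {
                "library_id": lib_id,
                "level": matrix.meta.loc[libs[0], "level"],
                "stage": stage,
                "condition": cond,
                "replicate": 1,
            }
        )
    meta = pd.DataFrame(meta_rows).set_index("library_id")
    return ExpressionMatrix(pd.DataFrame(data), meta, matrix.unit)


def mask_undetected(
    averaged: ExpressionMatrix, flags: pd.DataFrame
) -> ExpressionMatrix:
    """Zero averaged values in groups where the entity is not detected."""
    vals = averaged.values.copy()
    for (stage, cond) in flags.columns:
        lib_id = f"{stage}:{cond}"
        if lib_id in vals.columns:
            vals.loc[~flags[(stage, cond)], lib_id] = 0.0
    return ExpressionMatrix(vals, averaged.meta.copy(), averaged.unit)


def ungroup_proteins(
    pq: ProteinQuantTable, protein_to_gene: Mapping[str, str]
) -> tuple[pd.DataFrame, list[str]]:
    """Expand protein groups to per-gene intensity rows.

    Every member protein of a group inherits the group's intensities;
    member ids are resolved to gene ids and duplicates collapsed to one
    row per gene, keeping the per-library maximum.  Members with no gene
    mapping are excluded and returned for logging.

    Returns
    -------
    (gene x library intensity frame, list of unmapped member ids)
    """
    rows = []
    genes = []
    unmapped: list[str] = []
    for gid, members in pq.members.items():
        intens = pq.intensities.loc[gid]
        for mem in members:
            gene = protein_to_gene.get(mem)
            if gene is None:
                unmapped.append(mem)
                continue
            genes.append(gene)
            rows.append(intens)
    if unmapped:
        logger.warning(
            "%d protein group members had no gene mapping and were excluded: %s",
            len(unmapped), ", ".join(sorted(unmapped)[:10]),
        )
    if not rows:
        return pd.DataFrame(columns=pq.intensities.columns), unmapped
    frame = pd.DataFrame(rows)
    frame.index = pd.Index(genes, name="gene_id")
    frame = frame.groupby(level=0).max()
    return frame, unmapped


def gene_level_protein_matrix(
    pq: ProteinQuantTable, protein_to_gene: Mapping[str, str]
) -> tuple[ExpressionMatrix, list[str]]:
    """Ungrouped per-gene protein intensities as an :class:`ExpressionMatrix`."""
    frame, unmapped = ungroup_proteins(pq, protein_to_gene)
    return ExpressionMatrix(frame, pq.meta.copy(), "LFQ_intensity"), unmapped
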