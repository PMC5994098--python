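"""Readers and writers for the pipeline's tab-separated file dialects.

* count matrix: TSV, first column ``gene_id``, one column per library;
* library metadata: TSV with columns library_id, level, stage,
  condition, replicate;
* protein table: MaxQuant ``proteinGroups`` dialect — a "Protein IDs"
  column with semicolon-separated member ids and one
  "LFQ intensity <library>" column per library; contaminant/reverse rows
  (ids prefixed ``CON__`` / ``REV__``) are dropped;
* control-gene list: one gene id per line;
* KOG table: TSV gene_id, categories (concatenated letters);
* family table: TSV family, gene_id;
* protein-to-gene map: TSV protein_id, gene_id.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from .matrix import ExpressionMatrix, PipelineError, ProteinQuantTable

logger = logging.getLogger(__name__)

LFQ_PREFIX = "LFQ intensity "
_FLAGGED_PREFIXES = ("CON__", "REV__")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"library_id": str})
    required = {"library_id", "level", "stage", "condition", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise PipelineError(f"metadata file missing columns: {sorted(missing)}")
    return meta.set_index("library_id")


def read_counts(path, meta: pd.DataFrame) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    libs = meta.index[meta["level"] == "transcript"]
    return ExpressionMatrix(values[list(libs)], meta.loc[libs], "count")


def write_counts(matrix: ExpressionMatrix, path) -> None:
    matrix.values.rename_axis("gene_id").to_csv(path, sep="\t")


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.rename_axis("library_id").to_csv(path, sep="\t")


def read_aligned_totals(path) -> dict[str, float]:
    frame = pd.read_csv(path, sep="\t", dtype={"library_id": str})
    return dict(zip(frame["library_id"], frame["aligned_total"].astype(float)))


def write_aligned_totals(totals: Mapping[str, float], path) -> None:
    pd.DataFrame(
        {"library_id": list(totals), "aligned_total": list(totals.values())}
    ).to_csv(path, sep="\t", index=False)


def read_protein_groups(path, meta: pd.DataFrame) -> ProteinQuantTable:
    """Parse a MaxQuant-style proteinGroups table.

    Library ids are taken from the "LFQ intensity <library>" headers and
    must appear in the protein-level metadata.  Rows whose id field
    contains a contaminant or reverse-hit prefix are dropped.
    """
    table = pd.read_csv(path, sep="\t")
    if "Protein IDs" not in table.columns:
        raise PipelineError('protein table lacks a "Protein IDs" column')
    lfq_cols = [c for c in table.columns if c.startswith(LFQ_PREFIX)]
    if not lfq_cols:
        raise PipelineError("protein table has no LFQ intensity columns")
    flagged = table["Protein IDs"].str.contains(
        "|".join(_FLAGGED_PREFIXES), regex=True
    )
    if flagged.any():
        logger.info("dropping %d contaminant/reverse protein groups", flagged.sum())
        table = table[~flagged]
    members = {}
    for i, ids in enumerate(table["Protein IDs"]):
        gid = f"PG{i + 1}"
        members[gid] = [p for p in str(ids).split(";") if p]
    intens = table[lfq_cols].astype(float)
    intens.index = pd.Index(members.keys(), name="group_id")
    intens.columns = [c[len(LFQ_PREFIX):] for c in lfq_cols]
    libs = meta.index[meta["level"] == "protein"]
    missing = set(intens.columns) - set(libs)
    if missing:
        raise PipelineError(f"LFQ columns without metadata: {sorted(missing)}")
    return ProteinQuantTable(members, intens[list(libs)], meta.loc[libs])


def write_protein_groups(pq: ProteinQuantTable, path) -> None:
    out = pd.DataFrame(
        {"Protein IDs": [";".join(pq.members[g]) for g in pq.group_ids]}
    )
    for lib in pq.intensities.columns:
        out[f"{LFQ_PREFIX}{lib}"] = pq.intensities[lib].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> list[str]:
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_kog(path) -> dict[str, set[str]]:
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return {
        row.gene_id: set(row.categories)
        for row in frame.itertuples(index=False)
    }


def write_kog(annotations: Mapping[str, set[str]], path) -> None:
    pd.DataFrame(
        {
            "gene_id": list(annotations),
            "categories": ["".join(sorted(c)) for c in annotations.values()],
        }
    ).to_csv(path, sep="\t", index=False)


def read_families(path) -> dict[str, list[str]]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, list[str]] = {}
    for row in frame.itertuples(index=False):
        out.setdefault(row.family, []).append(row.gene_id)
    return out


def write_families(families: Mapping[str, list[str]], path) -> None:
    rows = [
        {"family": fam, "gene_id": g}
        for fam, genes in families.items()
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_protein_gene_map(path) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(frame["protein_id"], frame["gene_id"]))


def write_protein_gene_map(mapping: Mapping[str, str], path) -> None:
    pd.DataFrame(
        {"protein_id": list(mapping), "gene_id": list(mapping.values())}
    ).to_csv(path, sep="\t", index=False)
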