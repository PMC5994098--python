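"""Core data containers for abundance matrices and library metadata.

The pipeline operates on gene x library (or protein-group x library)
abundance matrices whose columns are annotated with the experimental
design: developmental stage, temperature condition and biological
replicate.  A thin :class:`ExpressionMatrix` wrapper around two pandas
DataFrames keeps values and metadata aligned and validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Developmental stages of pollen, in temporal order.
STAGES = ("tetrad", "post_meiotic", "mature")

#: Temperature conditions: control (25 degC) and heat stress (1 h 38 degC).
CONDITIONS = ("CO", "HS")

#: Measurement levels.
LEVELS = ("transcript", "protein")

META_COLUMNS = ("level", "stage", "condition", "replicate")


class PipelineError(Exception):
    """Base error for invalid inputs or configuration."""


@dataclass
class ExpressionMatrix:
    """Genes (or protein groups) x libraries abundance matrix.

    Parameters
    ----------
    values
        Non-negative abundances; index = entity ids, columns = library ids.
    meta
        Per-library metadata indexed by library id, with columns
        ``level``, ``stage``, ``condition`` and ``replicate``.
    unit
        One of ``count``, ``TPM`` or ``LFQ_intensity``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    unit: str = "count"

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values).astype(float)
        self.meta = pd.DataFrame(self.meta)
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if not self.values.index.is_unique:
            raise PipelineError("entity ids are not unique")
        if not self.values.columns.is_unique:
            raise PipelineError("library ids are not unique")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise PipelineError(f"metadata missing columns: {missing}")
        if set(self.values.columns) != set(self.meta.index):
            raise PipelineError("metadata rows do not match matrix columns")
        # align metadata to column order
        self.meta = self.meta.loc[self.values.columns]
        if (self.values.to_numpy() < 0).any():
            raise PipelineError("negative abundance values")
        bad_stage = set(self.meta["stage"]) - set(STAGES)
        if bad_stage:
            raise PipelineError(f"unknown stages: {sorted(bad_stage)}")
        bad_cond = set(self.meta["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise PipelineError(f"unknown conditions: {sorted(bad_cond)}")
        for (stage, cond), grp in self.meta.groupby(["stage", "condition"]):
            if grp["replicate"].duplicated().any():
                raise PipelineError(
                    f"duplicate replicate index in group ({stage}, {cond})"
                )

    # -- convenience ------------------------------------------------------
    @property
    def entity_ids(self) -> pd.Index:
        return self.values.index

    @property
    def library_ids(self) -> pd.Index:
        return self.values.columns

    def group_columns(self) -> dict[tuple[str, str], list[str]]:
        """Library ids per (stage, condition) group, stages in temporal order."""
        out: dict[tuple[str, str], list[str]] = {}
        for stage in STAGES:
            for cond in CONDITIONS:
                libs = self.meta.index[
                    (self.meta["stage"] == stage) & (self.meta["condition"] == cond)
                ]
                if len(libs):
                    out[(stage, cond)] = list(libs)
        return out

    def subset(self, entities) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[entities], self.meta.copy(), self.unit)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.meta.copy(), self.unit)


@dataclass
class ProteinQuantTable:
    """Protein groups with member ids and per-library label-free intensities.

    ``members`` maps group id -> list of member protein ids (from the
    semicolon-separated "Protein IDs" field).  ``intensities`` has one row
    per group id and one column per library; zero encodes not-detected.
    """

    members: dict[str, list[str]]
    intensities: pd.DataFrame
    meta: pd.DataFrame
    _matrix: ExpressionMatrix = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not set(self.members) == set(self.intensities.index):
            raise PipelineError("member map does not match intensity rows")
        for gid, mem in self.members.items():
            if not mem:
                raise PipelineError(f"protein group {gid!r} has no members")
        self._matrix = ExpressionMatrix(self.intensities, self.meta, "LFQ_intensity")
        self.intensities = self._matrix.values

    @property
    def group_ids(self) -> pd.Index:
        return self.intensities.index

    def as_matrix(self) -> ExpressionMatrix:
        return self._matrix
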