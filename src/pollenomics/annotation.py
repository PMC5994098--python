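"""Functional (KOG) category distributions and Hsp/Hsf family summaries.

KOG categories are single letters; categories R (general function
prediction only) and S (function unknown) carry no functional
information and are removed before computing distributions.  A gene may
carry several categories and is counted once in each, so percentages may
sum to more than 100%.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd

from .matrix import STAGES, PipelineError

logger = logging.getLogger(__name__)

#: Poorly characterised KOG categories, excluded from all distributions.
EXCLUDED_CATEGORIES = frozenset({"R", "S"})


def functional_distribution(
    genes: Iterable[str],
    annotations: Mapping[str, set[str] | str],
    display_cutoff: float = 5.0,
) -> pd.DataFrame:
    """Percentage of a gene set per KOG category.

    The denominator is the number of (deduplicated) genes in the set
    that retain at least one category after dropping R and S; the
    numerator per category is the number of such genes carrying it.
    Categories below ``display_cutoff`` percent are flagged, not removed.
    """
    gene_set = pd.Index(genes).unique()
    retained: dict[str, set[str]] = {}
    for g in gene_set:
        cats = annotations.get(g, set())
        cats = set(cats) - EXCLUDED_CATEGORIES
        if cats:
            retained[g] = cats
    if not retained:
        logger.warning("no genes with informative KOG categories in the set")
        return pd.DataFrame(columns=["count", "percent", "below_cutoff"])
    denom = len(retained)
    counts: dict[str, int] = {}
    for cats in retained.values():
        for c in cats:
            counts[c] = counts.get(c, 0) + 1
    out = pd.DataFrame(
        {"count": pd.Series(counts).sort_index()}
    ).rename_axis("category")
    out["percent"] = 100.0 * out["count"] / denom
    out["below_cutoff"] = out["percent"] < display_cutoff
    return out


def family_regulation_summary(
    families: Mapping[str, Iterable[str]],
    regulation: pd.DataFrame,
    detected: pd.DataFrame,
    level: str,
    transcript_detected: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-family, per-stage fractions of down/stable/up/undetected members.

    ``regulation`` holds columns entity_id, stage, category for the
    level.  ``detected`` is a boolean gene x stage frame for the level;
    at the protein level, members whose transcript is not detected at a
    stage (``transcript_detected``) are counted as undetected, since a
    protein call without transcript evidence cannot be interpreted.
    Denominator is always the annotated family size, so the four
    fractions sum to 1.
    """
    if level == "protein" and transcript_detected is None:
        raise PipelineError("protein-level summary needs transcript detection flags")
    reg_lookup = {
        (row.entity_id, row.stage): row.category
        for row in regulation.itertuples(index=False)
    }
    rows = []
    for fam, members in families.items():
        members = pd.Index(members).unique()
        if len(members) == 0:
            raise PipelineError(f"family {fam!r} has no annotated members")
        for stage in STAGES:
            tally = {"down": 0, "stable": 0, "up": 0, "undetected": 0}
            for g in members:
                is_det = bool(detected.at[g, stage]) if g in detected.index else False
                if level == "protein" and is_det:
                    tr_ok = (
                        g in transcript_detected.index
                        and bool(transcript_detected.at[g, stage])
                    )
                    if not tr_ok:
                        is_det = False
                cat = reg_lookup.get((g, stage))
                if is_det and cat is not None:
                    tally[cat] += 1
                else:
                    tally["undetected"] += 1
            n = len(members)
            rows.append(
                {
                    "family": fam, "stage": stage, "n_members": n,
                    **{f"frac_{k}": v / n for k, v in tally.items()},
                }
            )
    return pd.DataFrame(rows)


def condition_detected_any(flags: pd.DataFrame) -> pd.DataFrame:
    """Collapse gene x (stage, condition) flags to gene x stage (any condition)."""
    out = pd.DataFrame(index=flags.index)
    for stage in STAGES:
        cols = [c for c in flags.columns if c[0] == stage]
        out[stage] = flags[cols].any(axis=1) if cols else False
    return out
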