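"""Rank-level abundance tables, detection filters and the gut-family screen.

Authenticated read assignments are collapsed into samples x taxa count tables
at a chosen taxonomic rank, filtered by minimum hit counts, restricted to the
24 bacterial/archaeal families treated as the conserved family-level core of
the hominid gut microbiome, and cleaned of taxa that appear in extraction or
library blanks (negative controls).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("paleogut")

__all__ = [
    "RANKS",
    "GUT_FAMILIES",
    "GutFamilyReference",
    "AbundanceTable",
    "collapse_taxonomy",
    "filter_min_hits",
    "restrict_to_families",
    "subtract_blank_taxa",
    "relative_abundance",
]

RANKS = ("phylum", "family", "genus", "species")

#: The 24 families common to the gut microbiome of hominids.
GUT_FAMILIES = frozenset(
    {
        "Methanobacteriaceae",
        "Bifidobacteriaceae",
        "Coriobacteriaceae",
        "Bacteroidaceae",
        "Porphyromonadaceae",
        "Prevotellaceae",
        "Rikenellaceae",
        "Tannerellaceae",
        "Enterococcaceae",
        "Lactobacillaceae",
        "Streptococcaceae",
        "Christensenellaceae",
        "Clostridiaceae",
        "Eubacteriaceae",
        "Lachnospiraceae",
        "Oscillospiraceae",
        "Peptostreptococcaceae",
        "Ruminococcaceae",
        "Erysipelotrichaceae",
        "Veillonellaceae",
        "Desulfovibrionaceae",
        "Succinivibrionaceae",
        "Enterobacteriaceae",
        "Spirochaetaceae",
    }
)


@dataclass(frozen=True)
class GutFamilyReference:
    """Packaged reference list of hominid-gut core families."""

    families: frozenset = field(default_factory=lambda: GUT_FAMILIES)

    def __contains__(self, family: str) -> bool:
        return family in self.families

    def __len__(self) -> int:
        return len(self.families)


@dataclass
class AbundanceTable:
    """Samples x taxa count (or fraction) matrix at a single taxonomic rank.

    counts: DataFrame indexed by sample id, columns are taxon names at
    ``rank``. ``lineages`` maps each taxon name to its rank->name labels at
    this rank and above, so tables stay re-collapsible and family-screenable.
    """

    counts: pd.DataFrame
    rank: str
    lineages: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"rank must be one of {RANKS}, got {self.rank!r}")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("sample and taxon labels must be unique")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def family_of(self, taxon: str) -> str | None:
        return self.lineages.get(taxon, {}).get("family")


def collapse_taxonomy(assignments: pd.DataFrame, rank: str = "species") -> AbundanceTable:
    """Collapse per-read (or pre-counted) assignments to a rank-level table.

    ``assignments`` is tidy: one row per read (or per group with an ``n``
    count column), with a ``sample`` column and lineage columns from
    ``RANKS``. Reads lacking a label at ``rank`` are grouped under
    "unclassified". Per-sample totals are conserved across ranks.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}, got {rank!r}")
    if "sample" not in assignments.columns:
        raise ValueError("assignments must have a 'sample' column")
    df = assignments.copy()
    if "n" not in df.columns:
        df["n"] = 1
    label = df[rank] if rank in df.columns else pd.Series(np.nan, index=df.index)
    df["_taxon"] = label.fillna("unclassified").replace("", "unclassified")
    counts = (
        df.pivot_table(index="sample", columns="_taxon", values="n", aggfunc="sum", fill_value=0)
        .astype(int)
        .rename_axis(index=None, columns=None)
    )
    # lineage above the collapse rank, first occurrence wins
    upper = RANKS[: RANKS.index(rank) + 1]
    lineages: dict[str, dict[str, str]] = {}
    for taxon, sub in df.groupby("_taxon"):
        row = sub.iloc[0]
        lineages[str(taxon)] = {
            r: str(row[r]) for r in upper if r in df.columns and pd.notna(row[r])
        }
    return AbundanceTable(counts=counts, rank=rank, lineages=lineages)


def filter_min_hits(
    table: AbundanceTable, min_hits: int = 2, strict: bool = False
) -> AbundanceTable:
    """Keep taxa reaching ``min_hits`` in at least one sample.

    Detection presets: min_hits=2, strict=False keeps taxa with >= 2 hits in
    some sample (species heat-map rule); min_hits=4, strict=True keeps taxa
    with > 4 hits in some sample (phylogenetic-tree inclusion rule).
    """
    peaks = table.counts.max(axis=0)
    keep = peaks > min_hits if strict else peaks >= min_hits
    kept = table.counts.loc[:, keep]
    return AbundanceTable(
        counts=kept,
        rank=table.rank,
        lineages={t: table.lineages[t] for t in kept.columns if t in table.lineages},
    )


def restrict_to_families(
    table: AbundanceTable, ref: GutFamilyReference | None = None
) -> AbundanceTable:
    """Keep only taxa whose lineage family is in the gut-family reference."""
    if ref is None:
        ref = GutFamilyReference()
    keep = [t for t in table.taxa if table.family_of(t) in ref.families]
    if not keep:
        logger.warning("gut-family restriction removed every taxon")
    kept = table.counts.loc[:, keep]
    return AbundanceTable(
        counts=kept,
        rank=table.rank,
        lineages={t: table.lineages[t] for t in keep if t in table.lineages},
    )


def subtract_blank_taxa(table: AbundanceTable, blank_table: AbundanceTable) -> AbundanceTable:
    """Remove any taxon detected (count > 0) in the blank controls."""
    if blank_table.rank != table.rank:
        raise ValueError("blank table must be at the same rank")
    blank_present = set(blank_table.counts.columns[(blank_table.counts > 0).any(axis=0)])
    removed = [t for t in table.taxa if t in blank_present]
    if removed:
        logger.info("removed %d blank-contaminant taxa: %s", len(removed), sorted(removed))
    kept = table.counts.drop(columns=removed)
    return AbundanceTable(
        counts=kept,
        rank=table.rank,
        lineages={t: table.lineages[t] for t in kept.columns if t in table.lineages},
    )


def relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Per-sample fractions; zero-total samples become NaN rows and are logged."""
    totals = table.counts.sum(axis=1)
    zero = totals[totals == 0].index
    if len(zero):
        logger.warning("samples with zero total counts: %s", list(zero))
    fractions = table.counts.div(totals.replace(0, np.nan), axis=0)
    return AbundanceTable(counts=fractions, rank=table.rank, lineages=dict(table.lineages))
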