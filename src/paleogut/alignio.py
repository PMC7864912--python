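"""Alignment input: per-column reconstruction from CIGAR+MD and read filters.

Reads SAM/BAM via pysam and rebuilds, for every aligned read, the list of
(reference base, read base) column pairs together with each column's distance
from the original molecule's 5' and 3' ends. Reverse-strand records are
re-oriented (bases complemented, positions flipped) so that damage statistics
are always counted from the molecule's own 5' end, which is where cytosine
deamination accumulates.

Coordinates are 0-based half-open internally; SAM's 1-based POS is converted
at the boundary. Indel and clipped positions carry no ref/read base pair:
they are excluded from damage-informative columns but remain counted in the
edit distance (NM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pysam

logger = logging.getLogger("paleogut")

__all__ = [
    "AlignedColumn",
    "AlignedRead",
    "parse_alignments",
    "filter_alignments",
    "edit_distance",
    "load_assignments",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignedColumn:
    """One matched alignment column, in original-molecule orientation.

    z5/z3: distance of this base from the molecule's 5'/3' end (0-based).
    epsilon: base error probability 10**(-q/10) from the PHRED quality.
    """

    z5: int
    z3: int
    ref_base: str
    read_base: str
    epsilon: float


@dataclass
class AlignedRead:
    """An aligned read with reconstructed columns and filter metadata."""

    read_id: str
    taxon_id: str
    columns: list[AlignedColumn]
    mapq: int
    nm: int
    unique_best: bool
    ref_name: str = ""
    ref_start: int = 0  # 0-based
    ref_end: int = 0  # half-open
    is_reverse: bool = False
    read_length: int = 0

    @property
    def n_mismatches(self) -> int:
        return sum(1 for c in self.columns if c.ref_base != c.read_base)

    def n_terminal_mismatches(self, window: int = 10) -> int:
        """Mismatching columns within ``window`` bases of the 5' end."""
        return sum(
            1 for c in self.columns if c.z5 < window and c.ref_base != c.read_base
        )

    def reconstruct(self) -> tuple[str, str]:
        """(read sequence, reference sequence) over matched columns,
        in molecule orientation — the round-trip check for gold alignments."""
        cols = sorted(self.columns, key=lambda c: c.z5)
        return (
            "".join(c.read_base for c in cols),
            "".join(c.ref_base for c in cols),
        )


def load_assignments(path) -> dict[str, str]:
    """Read a read->taxon assignment TSV (read_id, taxon_id[, lineage...])."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    if "read_id" not in df.columns or "taxon_id" not in df.columns:
        raise ValueError("assignment table must have read_id and taxon_id columns")
    return dict(zip(df["read_id"], df["taxon_id"]))


def _columns_from_record(rec: pysam.AlignedSegment) -> list[AlignedColumn]:
    """Rebuild matched columns from CIGAR+MD, re-orienting reverse reads."""
    seq = rec.query_sequence
    quals = rec.query_qualities
    if seq is None:
        raise ValueError("record has no sequence")
    length = len(seq)
    cols: list[AlignedColumn] = []
    # with_seq=True decodes the MD tag into per-column reference bases
    for qpos, rpos, ref_base in rec.get_aligned_pairs(with_seq=True):
        if qpos is None or rpos is None or ref_base is None:
            continue  # indel or clipped: no base pair
        read_base = seq[qpos]
        rb = ref_base.upper()
        q = quals[qpos] if quals is not None else 30
        eps = 10.0 ** (-q / 10.0)
        if rec.is_reverse:
            z5 = length - 1 - qpos
            rb = rb.translate(_COMPLEMENT)
            read_base = read_base.translate(_COMPLEMENT)
        else:
            z5 = qpos
        cols.append(
            AlignedColumn(
                z5=z5,
                z3=length - 1 - z5,
                ref_base=rb,
                read_base=read_base,
                epsilon=eps,
            )
        )
    return cols


def _unique_best(rec: pysam.AlignedSegment) -> bool:
    """BWA's X0 (number of best hits) when present; otherwise approximate
    as 'no alternative-hit XA tag and MAPQ > 0'."""
    if rec.has_tag("X0"):
        return int(rec.get_tag("X0")) == 1
    return not rec.has_tag("XA") and rec.mapping_quality > 0


def parse_alignments(
    source,
    assignments: Mapping[str, str] | None = None,
) -> Iterator[AlignedRead]:
    """Iterate AlignedRead objects from a SAM/BAM path or pysam AlignmentFile.

    Records lacking an MD tag (or unmapped/secondary records) are skipped;
    skipped-for-missing-MD counts are logged so silent data loss is visible.
    Taxon ids come from the assignment table when given, else from the
    reference (chromosome) name.
    """
    own = False
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        source = pysam.AlignmentFile(str(source), check_sq=False)
        own = True
    n_missing_md = 0
    try:
        for rec in source:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            try:
                cols = _columns_from_record(rec)
            except ValueError as exc:
                n_missing_md += 1
                logger.debug("skipping %s: %s", rec.query_name, exc)
                continue
            n_mis = sum(1 for c in cols if c.ref_base != c.read_base)
            nm = int(rec.get_tag("NM")) if rec.has_tag("NM") else None
            if nm is None:
                # substitutions plus inserted/deleted bases
                indel = sum(
                    ln for op, ln in (rec.cigartuples or []) if op in (1, 2)
                )
                nm = n_mis + indel
            taxon = (
                assignments.get(rec.query_name, rec.reference_name)
                if assignments
                else rec.reference_name
            )
            yield AlignedRead(
                read_id=rec.query_name,
                taxon_id=taxon or "",
                columns=cols,
                mapq=rec.mapping_quality,
                nm=nm,
                unique_best=_unique_best(rec),
                ref_name=rec.reference_name or "",
                ref_start=rec.reference_start,
                ref_end=rec.reference_end or rec.reference_start,
                is_reverse=rec.is_reverse,
                read_length=rec.query_length,
            )
    finally:
        if own:
            source.close()
    if n_missing_md:
        logger.warning("skipped %d records without a usable MD tag", n_missing_md)


def filter_alignments(
    reads: Iterable[AlignedRead],
    mapq_min: int = 20,
    require_unique_best: bool = True,
) -> list[AlignedRead]:
    """Keep reads with MAPQ strictly above ``mapq_min`` and (optionally) a
    unique best hit. Idempotent; discard counts are logged."""
    kept: list[AlignedRead] = []
    n_mapq = n_unique = 0
    for r in reads:
        if r.mapq <= mapq_min:
            n_mapq += 1
            continue
        if require_unique_best and not r.unique_best:
            n_unique += 1
            continue
        kept.append(r)
    if n_mapq or n_unique:
        logger.info(
            "filtered alignments: %d below MAPQ threshold, %d without unique best hit",
            n_mapq,
            n_unique,
        )
    return kept


def edit_distance(read: AlignedRead) -> int:
    """NM: substitutions + indel bases relative to the reference."""
    return read.nm
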