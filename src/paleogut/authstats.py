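"""Per-taxon / per-sample authentication statistics and decision rules.

For each candidate taxon the pipeline gathers six pieces of evidence: the
number of assigned reads, the number with weak damage support (PMDS > 1),
depth and breadth of coverage of the reference genome, the pooled 5' C->T
rate among damage-supported reads, and the negative difference proportion
(-d%) of their edit-distance histogram. A taxon is called ancient when read
support, damage support, terminal deamination and a monotonically declining
edit-distance distribution all hold simultaneously. Analogous rules cover
mitochondrial-DNA detection screens and per-sample ancient-mtDNA calls.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alignio import AlignedRead
from .damage import (
    DamageProfile,
    PMDResult,
    ct5_rate,
    estimate_damage_profile,
)

logger = logging.getLogger("paleogut")

__all__ = [
    "EditDistanceHistogram",
    "CoverageStats",
    "TaxonEvidence",
    "MtSampleEvidence",
    "Decision",
    "TaxonRule",
    "MtSampleRule",
    "edit_distance_histogram",
    "neg_delta",
    "coverage_stats",
    "compute_taxon_evidence",
    "authenticate_taxon",
    "authenticate_mtdna_sample",
    "screen_mtdna_detection",
]

#: -d% = 1 is an exact-decline predicate; compare with this slack only.
NEG_DELTA_TOL = 1e-9


@dataclass
class EditDistanceHistogram:
    """Read counts per edit distance, support 0..k (k = max observed)."""

    counts: np.ndarray
    flagged_empty: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("histogram counts must be non-negative")

    @property
    def k(self) -> int:
        return len(self.counts) - 1 if len(self.counts) else 0

    @property
    def n_reads(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class CoverageStats:
    doc: float  # mean per-base depth
    breadth_pct: float  # % reference positions with depth >= 1


@dataclass
class TaxonEvidence:
    """The six per-taxon authentication statistics plus the read-level screen."""

    taxon_id: str
    n_reads: int
    n_pmds1: int
    coverage: CoverageStats | None = None
    ct5: float | None = None  # pooled 5' C->T fraction on PMDS>1 reads
    neg_delta: float | None = None  # on PMDS>1 reads
    has_terminal_mismatch_support: bool = True

    def __post_init__(self) -> None:
        if self.n_pmds1 > self.n_reads:
            raise ValueError("n_pmds1 cannot exceed n_reads")


@dataclass
class MtSampleEvidence:
    """Per-sample mtDNA evidence; contamination comes from an external estimator."""

    sample_id: str
    n_pmds1_reads: int
    breadth_pct: float
    neg_delta: float
    contamination_pct: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.contamination_pct <= 100.0):
            raise ValueError("contamination_pct must be in [0, 100]")


@dataclass(frozen=True)
class Decision:
    accept: bool
    failed: tuple[str, ...] = ()


@dataclass(frozen=True)
class TaxonRule:
    """Ancient-origin rule: reads > 200, PMDS>1 reads > 50, -d% = 1,
    5' C->T > 10%, and at least one mismatch in the first 10 bases."""

    min_reads: int = 200  # strict >
    min_pmds1: int = 50  # strict >
    neg_delta_min: float = 1.0  # >= within NEG_DELTA_TOL
    ct5_min: float = 0.10  # strict >
    require_terminal_mismatch: bool = True


@dataclass(frozen=True)
class MtSampleRule:
    """Ancient-human-mtDNA sample rule: >1000 PMDS>1 reads, breadth > 10%,
    -d% >= 0.9, contamination < 2%."""

    min_pmds1_reads: int = 1000  # strict >
    min_breadth_pct: float = 10.0  # strict >
    neg_delta_min: float = 0.9  # >=
    max_contamination_pct: float = 2.0  # strict <


def edit_distance_histogram(
    reads: Sequence[AlignedRead],
    pmds: Mapping[str, float] | None = None,
    pmds_min: float = 1.0,
    terminal_window: int | None = None,
) -> EditDistanceHistogram:
    """Edit-distance histogram over reads with PMDS strictly above ``pmds_min``.

    ``terminal_window=None`` histograms the full-alignment NM; an integer w
    instead counts only mismatches within the first w bases from the 5' end
    (the restriction used when the statistic is computed on damage-selected
    reads, whose full NM is >= 1 by construction). ``pmds=None`` uses all
    reads. An empty selection yields a flagged empty histogram.
    """
    selected = [
        r for r in reads if pmds is None or pmds.get(r.read_id, 0.0) > pmds_min
    ]
    if not selected:
        return EditDistanceHistogram(counts=np.zeros(0, dtype=np.int64), flagged_empty=True)
    if terminal_window is None:
        values = [r.nm for r in selected]
    else:
        values = [r.n_terminal_mismatches(terminal_window) for r in selected]
    counts = np.bincount(np.asarray(values, dtype=np.int64))
    return EditDistanceHistogram(counts=counts)


def neg_delta(h: EditDistanceHistogram) -> float:
    """Negative difference proportion of an edit-distance histogram.

    With successive differences d_i = c_{i+1} - c_i, returns
    sum(|d_i| for d_i < 0) / sum(|d_i|), i.e. the fraction of total
    bin-to-bin change that is a decline. Equals 1 exactly when the histogram
    never increases (and decreases at least once) -- the signature of a
    correct ancient assignment. A flat or sub-2-bin histogram returns 0.
    """
    if len(h.counts) < 2:
        if not h.flagged_empty:
            logger.warning("neg_delta: histogram has <2 bins, returning 0")
        return 0.0
    d = np.diff(h.counts.astype(np.int64))
    total = int(np.abs(d).sum())
    if total == 0:
        return 0.0
    return float(np.abs(d[d < 0]).sum()) / total


def coverage_stats(reads: Iterable[AlignedRead], ref_length: int) -> CoverageStats:
    """Depth (total aligned bases / reference length) and breadth (% positions
    covered at least once) from alignment intervals."""
    if ref_length <= 0:
        raise ValueError("ref_length must be positive")
    depth_delta = np.zeros(ref_length + 1, dtype=np.int64)
    total_bases = 0
    for r in reads:
        start = max(0, r.ref_start)
        end = min(ref_length, r.ref_end)
        if end <= start:
            continue
        depth_delta[start] += 1
        depth_delta[end] -= 1
        total_bases += end - start
    depth = np.cumsum(depth_delta[:-1])
    breadth = 100.0 * float((depth > 0).sum()) / ref_length
    return CoverageStats(doc=total_bases / ref_length, breadth_pct=breadth)


def compute_taxon_evidence(
    taxon_id: str,
    reads: Sequence[AlignedRead],
    pmds: Mapping[str, float],
    ref_length: int,
    window: int = 10,
    pmds_min: float = 1.0,
    terminal_window: int | None = 10,
) -> TaxonEvidence:
    """Assemble the evidence record for one taxon from its aligned reads.

    C->T rate and -d% are computed on the PMDS > ``pmds_min`` subset;
    coverage uses every assigned read. ``terminal_window`` selects whether
    the edit-distance histogram counts full-read NM or only mismatches in
    the first 10 bases (see :func:`edit_distance_histogram`).
    """
    damaged = [r for r in reads if pmds.get(r.read_id, 0.0) > pmds_min]
    profile = estimate_damage_profile(damaged, window=window)
    hist = edit_distance_histogram(
        reads, pmds=pmds, pmds_min=pmds_min, terminal_window=terminal_window
    )
    ct5 = ct5_rate(profile)
    return TaxonEvidence(
        taxon_id=taxon_id,
        n_reads=len(reads),
        n_pmds1=len(damaged),
        coverage=coverage_stats(reads, ref_length),
        ct5=None if math.isnan(ct5) else ct5,
        neg_delta=neg_delta(hist),
        has_terminal_mismatch_support=any(
            r.n_terminal_mismatches(window) >= 1 for r in damaged
        ),
    )


def authenticate_taxon(e: TaxonEvidence, rule: TaxonRule | None = None) -> Decision:
    """Apply the ancient-origin decision rule; failures are enumerated.

    Monotone in every statistic: improving any single value never flips an
    accept into a reject.
    """
    if rule is None:
        rule = TaxonRule()
    if e.ct5 is None or e.neg_delta is None:
        raise ValueError(f"incomplete evidence for {e.taxon_id}")
    failed: list[str] = []
    if not e.n_reads > rule.min_reads:
        failed.append(f"reads>{rule.min_reads}")
    if not e.n_pmds1 > rule.min_pmds1:
        failed.append(f"pmds1_reads>{rule.min_pmds1}")
    if not e.neg_delta >= rule.neg_delta_min - NEG_DELTA_TOL:
        failed.append(f"neg_delta>={rule.neg_delta_min}")
    if not e.ct5 > rule.ct5_min:
        failed.append(f"ct5>{rule.ct5_min}")
    if rule.require_terminal_mismatch and not e.has_terminal_mismatch_support:
        failed.append("terminal_mismatch")
    return Decision(accept=not failed, failed=tuple(failed))


def authenticate_mtdna_sample(
    e: MtSampleEvidence, rule: MtSampleRule | None = None
) -> Decision:
    """Per-sample ancient-human-mtDNA rule (all four criteria must hold)."""
    if rule is None:
        rule = MtSampleRule()
    failed: list[str] = []
    if not e.n_pmds1_reads > rule.min_pmds1_reads:
        failed.append(f"pmds1_reads>{rule.min_pmds1_reads}")
    if not e.breadth_pct > rule.min_breadth_pct:
        failed.append(f"breadth>{rule.min_breadth_pct}%")
    if not e.neg_delta >= rule.neg_delta_min:
        failed.append(f"neg_delta>={rule.neg_delta_min}")
    if not e.contamination_pct < rule.max_contamination_pct:
        failed.append(f"contamination<{rule.max_contamination_pct}%")
    return Decision(accept=not failed, failed=tuple(failed))


def screen_mtdna_detection(
    sample_hits: Mapping[str, int], blank_taxa: set[str] | frozenset[str]
) -> set[str]:
    """Detection screen over PMDS>5 hit counts: a taxon is retained with
    strictly more than 2 hits and no presence in the blank controls."""
    return {
        taxon
        for taxon, hits in sample_hits.items()
        if hits > 2 and taxon not in blank_taxa
    }
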