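"""Packaged reference data: the published per-taxon evidence table.

The bundled TSV transcribes the six authentication statistics reported for
the 36 most abundant gut-family taxa recovered from Middle Paleolithic
sediment metagenomes (assigned reads, reads with PMDS > 1, depth and breadth
of coverage, pooled 5' C->T percentage and negative difference proportion,
the latter two computed on the PMDS > 1 read subset). It serves as the
worked example for the ancient-origin decision rule.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .authstats import CoverageStats, TaxonEvidence

__all__ = ["load_taxon_evidence_frame", "load_taxon_evidence", "evidence_from_frame"]

_EVIDENCE_RESOURCE = "data/taxon_evidence.tsv"


def load_taxon_evidence_frame() -> pd.DataFrame:
    """The packaged evidence table as a DataFrame (ct5 in percent)."""
    with files("paleogut").joinpath(_EVIDENCE_RESOURCE).open() as fh:
        return pd.read_csv(fh, sep="\t")


def evidence_from_frame(df: pd.DataFrame) -> list[TaxonEvidence]:
    """Convert an evidence TSV frame (percent-scale ct5) to evidence records."""
    records = []
    for row in df.itertuples(index=False):
        records.append(
            TaxonEvidence(
                taxon_id=str(row.species),
                n_reads=int(row.reads),
                n_pmds1=int(row.reads_pmds1),
                coverage=CoverageStats(doc=float(row.doc), breadth_pct=float(row.breadth_pct)),
                ct5=float(row.ct5_pct) / 100.0,
                neg_delta=float(row.neg_delta),
            )
        )
    return records


def load_taxon_evidence() -> list[TaxonEvidence]:
    """The packaged evidence table as TaxonEvidence records."""
    return evidence_from_frame(load_taxon_evidence_frame())
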