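"""Synthetic sediment-metagenome generator with per-read ground truth.

Emulates the data structure the authentication pipeline assumes: a mixture of
"ancient" reads (short fragments carrying terminal C->T / G->A deamination
that decays into the read interior, optionally confined to the terminal
overhang window as after UDG-half library treatment) and "modern contaminant"
reads (longer, damage-free), drawn from a panel of simulated taxon genomes
that includes both hominid-gut-family taxa and environmental-family taxa.
Blank (negative-control) samples contain only damage-free environmental
reads.

Every read comes with a gold-standard SAM record (correct POS/CIGAR/MD/NM,
reverse-strand records stored reference-forward) and a truth row recording
its origin and the exact damage events planted, so each downstream stage can
be tested against known answers. Output is byte-deterministic under a fixed
seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .damage import DamageModelParams, damage_probability
from .profiles import GUT_FAMILIES

__all__ = [
    "ReferenceTaxon",
    "ReferenceSet",
    "SimConfig",
    "SimRead",
    "SimulatedDataset",
    "generate_reference_set",
    "simulate_reads",
    "ENVIRONMENTAL_FAMILIES",
]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Environmental (soil/sediment) families used for non-gut simulated taxa.
ENVIRONMENTAL_FAMILIES = (
    "Streptomycetaceae",
    "Bacillaceae",
    "Rhodobacteraceae",
    "Comamonadaceae",
    "Xanthomonadaceae",
    "Sphingomonadaceae",
    "Micromonosporaceae",
    "Nocardiaceae",
)

_GUT_FAMILY_CYCLE = tuple(sorted(GUT_FAMILIES))


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceTaxon:
    taxon_id: str
    lineage: dict  # rank -> name, phylum..species
    genome: str

    @property
    def length(self) -> int:
        return len(self.genome)

    @property
    def is_gut(self) -> bool:
        return self.lineage.get("family") in GUT_FAMILIES


@dataclass
class ReferenceSet:
    taxa: list[ReferenceTaxon]

    def __post_init__(self) -> None:
        ids = [t.taxon_id for t in self.taxa]
        if len(set(ids)) != len(ids):
            raise ValueError("taxon ids must be unique")
        for t in self.taxa:
            if t.length < 1000:
                raise ValueError(f"{t.taxon_id}: genome shorter than 1 kb")
            if set(t.genome) - set("ACGT"):
                raise ValueError(f"{t.taxon_id}: genome alphabet must be A/C/G/T")

    def __iter__(self):
        return iter(self.taxa)

    def __len__(self) -> int:
        return len(self.taxa)

    def by_id(self, taxon_id: str) -> ReferenceTaxon:
        for t in self.taxa:
            if t.taxon_id == taxon_id:
                return t
        raise KeyError(taxon_id)

    def gut_taxa(self) -> list[str]:
        return [t.taxon_id for t in self.taxa if t.is_gut]

    def environmental_taxa(self) -> list[str]:
        return [t.taxon_id for t in self.taxa if not t.is_gut]


def generate_reference_set(
    n_taxa: int,
    length_bp: int = 10_000,
    gc: float = 0.5,
    seed: int = 0,
    gut_fraction: float = 0.5,
) -> ReferenceSet:
    """Random genomes with lineages split between gut and environmental families.

    The first ``round(n_taxa * gut_fraction)`` taxa are assigned to hominid
    gut families (cycling through the 24-family reference list), the rest to
    common sediment families. Deterministic for a fixed seed.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    if length_bp < 1000:
        raise ValueError("length_bp must be >= 1000 (1 kb)")
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.Generator(np.random.PCG64(seed))
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    n_gut = int(round(n_taxa * gut_fraction))
    taxa: list[ReferenceTaxon] = []
    for i in range(n_taxa):
        genome = "".join(rng.choice(_BASES, size=length_bp, p=p))
        if i < n_gut:
            family = _GUT_FAMILY_CYCLE[i % len(_GUT_FAMILY_CYCLE)]
            phylum = "Firmicutes"
            tag = "gut"
        else:
            family = ENVIRONMENTAL_FAMILIES[(i - n_gut) % len(ENVIRONMENTAL_FAMILIES)]
            phylum = "Actinobacteria"
            tag = "env"
        genus = f"{family[:-4]}genus{i}"
        species = f"{genus} sp{i}"
        taxa.append(
            ReferenceTaxon(
                taxon_id=f"{tag}_taxon_{i}",
                lineage={
                    "phylum": phylum,
                    "family": family,
                    "genus": genus,
                    "species": species,
                },
                genome=genome,
            )
        )
    return ReferenceSet(taxa=taxa)


@dataclass
class SimConfig:
    """Sample-level simulation settings.

    Fragment-length defaults reflect the usual ancient/modern separation:
    ancient fragments short (mean 60 bp, sd 15), modern contaminants long
    (mean 150 bp, sd 30); both truncated below at 25 bp. ``blank`` makes the
    sample a negative control: only damage-free reads from environmental
    taxa, regardless of ``n_ancient``.
    """

    n_ancient: int = 0
    n_modern: int = 0
    ancient_len: tuple[float, float] = (60.0, 15.0)
    modern_len: tuple[float, float] = (150.0, 30.0)
    seq_error: float = 0.001
    phred_base: int = 30
    seed: int = 0
    taxon_weights: dict[str, float] | None = None
    blank: bool = False
    min_len: int = 25

    def __post_init__(self) -> None:
        if self.n_ancient < 0 or self.n_modern < 0:
            raise ValueError("read counts must be >= 0")
        if not (0.0 <= self.seq_error < 1.0):
            raise ValueError("seq_error must be in [0, 1)")
        if self.taxon_weights is not None:
            total = sum(self.taxon_weights.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"taxon_weights must sum to 1, got {total}")


@dataclass
class SimRead:
    """One simulated read plus its gold alignment and ground truth."""

    read_id: str
    taxon_id: str
    is_ancient: bool
    strand: str  # '+' or '-'
    pos: int  # 0-based leftmost reference position
    seq: str  # molecule orientation (as sequenced / FASTQ)
    ref_fragment: str  # reference forward-strand substring
    qual: int
    damage_events: list[tuple[int, str]]  # (position from molecule 5', 'C>T'|'G>A')
    n_seq_errors: int

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def seq_aligned(self) -> str:
        """Read sequence in reference-forward orientation (SAM SEQ field)."""
        return self.seq if self.strand == "+" else _revcomp(self.seq)

    @property
    def nm(self) -> int:
        return sum(1 for a, b in zip(self.seq_aligned, self.ref_fragment) if a != b)

    @property
    def md(self) -> str:
        return _md_tag(self.ref_fragment, self.seq_aligned)


def _md_tag(ref: str, read: str) -> str:
    """MD string for an ungapped alignment (match runs + mismatch ref bases)."""
    parts: list[str] = []
    run = 0
    for r, q in zip(ref, read):
        if r == q:
            run += 1
        else:
            parts.append(str(run))
            parts.append(r)
            run = 0
    parts.append(str(run))
    return "".join(parts)


@dataclass
class SimulatedDataset:
    refs: ReferenceSet
    reads: list[SimRead]
    phred_offset: int = 33

    def fastq_text(self) -> str:
        buf = io.StringIO()
        for r in self.reads:
            q = chr(r.qual + self.phred_offset) * r.length
            buf.write(f"@{r.read_id}\n{r.seq}\n+\n{q}\n")
        return buf.getvalue()

    def sam_text(self) -> str:
        buf = io.StringIO()
        buf.write("@HD\tVN:1.6\tSO:unknown\n")
        for t in self.refs:
            buf.write(f"@SQ\tSN:{t.taxon_id}\tLN:{t.length}\n")
        for r in self.reads:
            flag = 16 if r.strand == "-" else 0
            qual = chr(r.qual + self.phred_offset) * r.length
            buf.write(
                "\t".join(
                    [
                        r.read_id,
                        str(flag),
                        r.taxon_id,
                        str(r.pos + 1),  # SAM POS is 1-based
                        "60",
                        f"{r.length}M",
                        "*",
                        "0",
                        "0",
                        r.seq_aligned,
                        qual,
                        f"NM:i:{r.nm}",
                        f"MD:Z:{r.md}",
                        "X0:i:1",
                    ]
                )
                + "\n"
            )
        return buf.getvalue()

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.reads:
            events = ";".join(f"{p}:{kind}" for p, kind in r.damage_events)
            rows.append(
                {
                    "read_id": r.read_id,
                    "taxon_id": r.taxon_id,
                    "is_ancient": r.is_ancient,
                    "damage_events": events,
                    "n_seq_errors": r.n_seq_errors,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["read_id", "taxon_id", "is_ancient", "damage_events", "n_seq_errors"],
        )

    def assignment_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.reads:
            lin = self.refs.by_id(r.taxon_id).lineage
            rows.append({"read_id": r.read_id, "taxon_id": r.taxon_id, **lin})
        return pd.DataFrame(rows)

    def write_fastq(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.fastq_text())

    def write_sam(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.sam_text())

    def write_truth(self, path) -> None:
        self.truth_frame().to_csv(path, sep="\t", index=False)


def _sample_length(rng, mean: float, sd: float, floor: int, cap: int) -> int:
    # truncated normal via resampling, hard floor/cap
    for _ in range(100):
        val = int(round(rng.normal(mean, sd)))
        if floor <= val <= cap:
            return val
    return int(min(max(floor, round(mean)), cap))


def simulate_reads(
    refs: ReferenceSet,
    cfg: SimConfig,
    dmg: DamageModelParams | None = None,
    read_prefix: str = "r",
) -> SimulatedDataset:
    """Draw reads from the reference panel and plant damage per the model.

    Ancient reads: each molecule base that is C gets C->T with probability
    D(z) at its distance z from the molecule 5' end; each G gets G->A with
    probability D(z') at its distance z' from the 3' end (independent
    Bernoulli draws). Modern reads receive no damage. Sequencing errors are
    applied afterwards at ``cfg.seq_error`` per base, uniformly over the
    three other bases. Strand is drawn uniformly; reverse-strand gold SAM
    records store the reverse-complemented sequence at the correct POS.
    """
    if dmg is None:
        dmg = DamageModelParams()
    if len(refs) == 0:
        raise ValueError("reference set is empty")

    if cfg.blank:
        pool = refs.environmental_taxa()
        if not pool:
            raise ValueError("blank sample requires environmental taxa in the panel")
        weights = None
        if cfg.taxon_weights is not None:
            w = {t: cfg.taxon_weights.get(t, 0.0) for t in pool}
            total = sum(w.values())
            weights = {t: v / total for t, v in w.items()} if total > 0 else None
        plan = [(False, cfg.n_ancient + cfg.n_modern)]
    else:
        pool = [t.taxon_id for t in refs]
        weights = cfg.taxon_weights
        plan = [(True, cfg.n_ancient), (False, cfg.n_modern)]

    if weights is None:
        probs = np.full(len(pool), 1.0 / len(pool))
    else:
        missing = set(weights) - set(pool)
        if missing:
            raise KeyError(f"weights refer to unknown taxa: {sorted(missing)}")
        probs = np.array([weights.get(t, 0.0) for t in pool])
        probs = probs / probs.sum()

    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    reads: list[SimRead] = []
    idx = 0
    for is_ancient, n in plan:
        mean, sd = cfg.ancient_len if is_ancient else cfg.modern_len
        for _ in range(n):
            taxon_id = pool[rng.choice(len(pool), p=probs)]
            genome = refs.by_id(taxon_id).genome
            length = _sample_length(rng, mean, sd, cfg.min_len, len(genome))
            pos = int(rng.integers(0, len(genome) - length + 1))
            fragment = genome[pos : pos + length]
            strand = "+" if rng.random() < 0.5 else "-"
            molecule = list(fragment if strand == "+" else _revcomp(fragment))

            events: list[tuple[int, str]] = []
            if is_ancient:
                for i, base in enumerate(molecule):
                    if base == "C":
                        if rng.random() < damage_probability(i, dmg):
                            molecule[i] = "T"
                            events.append((i, "C>T"))
                    elif base == "G":
                        if rng.random() < damage_probability(length - 1 - i, dmg):
                            molecule[i] = "A"
                            events.append((i, "G>A"))

            n_err = 0
            if cfg.seq_error > 0:
                for i in range(length):
                    if rng.random() < cfg.seq_error:
                        alt = [b for b in "ACGT" if b != molecule[i]]
                        molecule[i] = alt[int(rng.integers(0, 3))]
                        n_err += 1

            reads.append(
                SimRead(
                    read_id=f"{read_prefix}{idx:07d}",
                    taxon_id=taxon_id,
                    is_ancient=is_ancient,
                    strand=strand,
                    pos=pos,
                    seq="".join(molecule),
                    ref_fragment=fragment,
                    qual=cfg.phred_base,
                    damage_events=events,
                    n_seq_errors=n_err,
                )
            )
            idx += 1
    return SimulatedDataset(refs=refs, reads=reads)
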