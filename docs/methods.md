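# Methods

## The damage model

Terminal cytosine deamination is modeled as a geometric decay over distance
from the fragment end,

    D(z) = d_max · γ^z + d_const,

with defaults `d_max = 0.3`, `γ = 0.5`, `d_const = 0.01` (all dimensionless
probabilities; `z` in bases, `z = 0` the terminal base). This single-
exponential form is the standard parameterisation of terminal deamination;
`d_max + d_const` is the probability of a C→T at the very 5′ terminus (0.31
under the defaults), `γ` sets how quickly the excess decays (half per base),
and `d_const` is the residual interior rate. For UDG-half libraries
(`udg_half = True`) — where uracil-DNA-glycosylase treatment removes most
internal deaminated bases, leaving damage in the single-stranded terminal
overhangs — the terminal excess applies only at `z < window` (default 10
bases) and positions beyond fall back to `d_const`. How much residual damage
a given UDG-half library retains is library-specific, so the parameters are
exposed rather than fixed; the non-UDG defaults are used throughout the test
suite.

Reference G columns are treated symmetrically using the distance from the 3′
end, which on the reference forward strand is where the complementary-strand
deamination appears as G→A. The single-stranded-overhang biochemistry is not
modeled beyond this two-ended symmetry.

## PMD scoring

The per-read postmortem degradation score is a natural-log likelihood ratio
summed over damage-informative columns (reference C scored at its 5′
distance, reference G at its 3′ distance):

    P(T | damage) = D(z)(1−ε) + (1−D(z))·ε/3        P(T | null) = ε/3
    P(C | damage) = (1−D(z))(1−ε) + D(z)·ε/3        P(C | null) = 1−ε

where ε = 10^(−q/10) from the base quality, floored at 10⁻⁶ so a q = ∞ base
cannot contribute an infinite ratio. Columns whose read base is neither the
reference base nor the deamination product contribute nothing (their
likelihood is ε/3 under both models), as do indel columns, which carry no
ref/read base pair. A read with no informative column scores exactly 0. The
score is additive over columns by construction.

Thresholds follow the published convention: PMDS > 5 (strict) defines the
ancient read set; PMDS > 1 the weak-damage-support set on which the
per-taxon damage statistics are computed. On simulated undamaged reads with
ε = 10⁻³ the PMDS > 5 false-positive rate is well under 1%.

## Alignment handling

SAM/BAM records are read with pysam; per-column reference bases are decoded
from CIGAR + MD (`get_aligned_pairs(with_seq=True)`). Reverse-strand records
are re-oriented — bases complemented, positions flipped — so `z5` always
counts from the original molecule's 5′ end. Coordinates are 0-based
half-open internally; SAM's 1-based POS is converted at the boundary.
Records without a usable MD tag are skipped with a logged count rather than
silently dropped. Filters are the published ones: MAPQ strictly greater
than 20, and a unique best hit. The unique-best flag uses BWA's X0 tag when
present; otherwise it is approximated as "no XA alternative-hit tag and
MAPQ > 0", which keeps the filter applicable to non-BWA aligners.

## Per-taxon evidence and the decision rule

For each taxon: assigned-read count; PMDS > 1 read count; depth of coverage
(total aligned bases / reference length) and breadth (% positions with depth
≥ 1), computed from alignment intervals; the pooled 5′ C→T rate over the
first 10 bases (mismatch count / reference-C count, summed over positions)
among PMDS > 1 reads; and the negative difference proportion −Δ% of their
edit-distance histogram. A taxon is accepted as ancient iff reads > 200,
PMDS > 1 reads > 50, −Δ% = 1, pooled C→T > 10%, and at least one PMDS > 1
read has a mismatch in its first 10 bases. The rule is monotone in every
statistic.

−Δ% is computed after exact integer arithmetic on the histogram; the "= 1"
criterion is evaluated as ≥ 1 − 10⁻⁹, because it is an exact-decline
predicate, not a float comparison. A flat histogram (all successive
differences zero) returns 0 — no decline evidence — and a histogram with
fewer than two bins returns 0 with a logged flag.

Two histogram modes are exposed via `terminal_window`: full-alignment NM, or
mismatches restricted to the first 10 bases of the read. The evidence
builder defaults to the restricted mode. The reason is structural: every
PMDS > 1 read carries at least one damage-consistent mismatch, so on the
PMDS > 1 subset the full-NM histogram has an empty zero bin and its first
successive difference is positive — −Δ% = 1 would be unreachable by
construction. Restricting the count to the 5′ terminal window (where only a
subset of damaged reads have their mismatch) restores the declining shape
that the criterion tests for.

Mitochondrial screening mirrors the taxon logic at the sample level: a
detection screen keeps taxa with more than 2 hits among PMDS > 5 reads and
no presence in the negative controls; a sample is called positive for
ancient human mtDNA iff it has more than 1,000 PMDS > 1 reads, breadth of
coverage above 10%, −Δ% ≥ 0.9, and a modern-contamination estimate below 2%.
The contamination estimate is consumed as an external input (e.g. from a
consensus-based estimator); this package does not compute it.

## The synthetic-data generator

The simulator emulates the statistical structure the pipeline assumes, not
real genomes. Reference panels are i.i.d. nucleotide sequences at a chosen
GC content (≥ 1 kb), with lineages split between the 24 hominid-gut core
families and common sediment families. A sample mixes "ancient" reads —
short fragments (truncated normal, mean 60 bp, sd 15, floor 25 bp) with
per-base Bernoulli damage at probability D(z) applied to molecule Cs from
the 5′ end and molecule Gs from the 3′ end — and "modern contaminant" reads
(mean 150 bp, sd 30, no damage). Sequencing errors are applied after damage
at a per-base rate (default 10⁻³, uniform over the three other bases) and
qualities are constant PHRED 30, which keeps the ε term of the PMD
likelihood exercised without a full quality model. Strand is uniform; gold
SAM records carry correct POS/CIGAR/MD/NM (reverse-strand records stored
reference-forward), and a truth table records each read's origin and planted
damage events. Blank samples contain only damage-free environmental-taxon
reads, mirroring how negative controls behave. All output is
byte-deterministic under a fixed seed.

What the simulator does *not* capture: realistic genome composition (k-mer
structure, repeats, shared sequence between taxa — so mapping ambiguity and
cross-mapping false positives are not exercised), capture enrichment, PCR
duplicates, quality-score variation, indel errors, and reference divergence
between the ancient organism and its modern reference. Passing the
end-to-end tests therefore demonstrates that the statistics and decision
rules behave correctly on data satisfying the model assumptions; it does not
validate robustness to mis-assignment, which in real data is exactly what
the edit-distance and coverage diagnostics are for.

Under the default damage model the *unconditional* pooled 5′ C→T rate over
10 bases is ≈ 7%; conditioning on PMDS > 1 (as the evidence builder does)
enriches for terminally damaged reads and yields pooled rates of 11–18% on
simulated ancient libraries — the same double-digit magnitude reported for
authentic ancient taxa — which is why the > 10% criterion is attainable
without inflating the damage amplitude.

## Compositional statistics

Bray–Curtis dissimilarity (scipy) between per-sample profiles; principal
coordinates by classical Torgerson scaling (double-center −½D², eigh,
coordinates = eigenvectors × √eigenvalue). Axes with non-positive
eigenvalues are dropped and no Cailliez/Lingoes correction is applied;
negative eigenvalues — expected, since Bray–Curtis is a semimetric — are
reported and flagged. PERMANOVA uses the one-way pseudo-F on squared
distances with a seeded permutation null, p = (1 + #{F_perm ≥ F_obs}) /
(1 + n_perm), default n_perm = 999; the implementation is cross-checked
against scikit-bio's in the test suite. The Wilcoxon rank-sum test uses the
exact null distribution for untied groups of ≤ 12 (small sample groups make
the exact test feasible) and the normal approximation with continuity
correction otherwise; two-sided by default.

## Abundance profiling

Read assignments (tidy table with sample + phylum/family/genus/species
lineage columns) collapse to counts at any rank, with unlabeled-at-rank
reads pooled under "unclassified"; per-sample totals are conserved across
ranks. By default abundance tables are built from PMDS > 5 reads (the
ancient read set); an all-reads mode supports comparisons against modern
datasets processed without the damage filter. Detection filters come in two
presets: ≥ 2 hits in at least one sample (inclusive; species-level
reporting) and > 4 hits in at least one sample (strict; tree-inclusion
rule). Taxa observed in blank controls are removed outright, and the
gut-family screen keeps only lineages whose family is among the 24 packaged
hominid-gut core families (the packaged list follows the published naming,
including both *Oscillospiraceae*/*Ruminococcaceae* and
*Tannerellaceae*/*Porphyromonadaceae*; no taxonomy reconciliation is
attempted).

## Problem sizes and numerical conventions

The test suite and acceptance checks run on simulations of 10,000 reads or
fewer against 6-taxon, 20-kb panels — large enough that binomial sampling
error on the terminal rate (±3 SD ≈ ±0.03 at n ≈ 2,500 terminal Cs) is well
inside the margins being tested, and small enough to run in seconds.
Statistical assertions use 3-SD binomial intervals or fixed seeds throughout;
the PMD likelihood's frozen single-column values were computed by direct
hand evaluation before the scorer was written.

## Known limitations

- PMDS parity with any specific external scorer is not a goal; the
  likelihood is the standard two-term deamination model, but implementations
  differ in windowing and quality handling.
- The authentication rule treats taxa independently; shared genomic content
  between related species is neither simulated nor corrected for.
- Paired-end merging is assumed already done (merged single-end
  orientation); the parser does not reconstruct pairs.
- The mtDNA contamination fraction is an input, not an output.
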