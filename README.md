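# paleogut

Authentication of ancient gut-microbiome DNA in sediment metagenomes.

Shotgun sequencing of archaeological sediments yields a mixture of truly
ancient microbial DNA and modern contamination. `paleogut` implements the
analysis chain used to decide, read by read and taxon by taxon, what is
ancient: damage-aware read scoring, per-taxon authentication rules,
gut-family abundance profiling, and compositional comparison between sample
groups. It is aimed at paleomicrobiology / sedimentary ancient-DNA (sedaDNA)
practitioners who already have alignments (SAM/BAM with MD/NM tags) and
taxonomic read assignments, and at method developers who need a fully
ground-truthed synthetic benchmark.

## The model

Postmortem cytosine deamination converts C to U, read as **C→T at the 5′ end**
of a fragment (and G→A at the 3′ end on the reference forward strand), with a
probability that decays into the read interior:

```
D(z) = d_max · γ^z + d_const,        0 < γ < 1,  z = distance from the end
```

Each aligned read receives a **postmortem degradation score (PMDS)** — the
log-likelihood ratio of a damage model against a damage-free null, summed
over damage-informative columns. For a reference C at distance `z` from the
5′ end with base-error probability ε:

```
P(read = T | damage) = D(z)(1−ε) + (1−D(z))·ε/3      P(read = T | null) = ε/3
P(read = C | damage) = (1−D(z))(1−ε) + D(z)·ε/3      P(read = C | null) = 1−ε
PMDS = Σ ln [ P(column | damage) / P(column | null) ]
```

Reference G columns are scored symmetrically from the 3′ end. Reads with
PMDS > 5 are treated as ancient; PMDS > 1 marks weak damage support.

A taxon is called **ancient** when, after MAPQ > 20 / unique-best-hit
filtering, it shows: more than 200 assigned reads, more than 50 reads with
PMDS > 1, a pooled 5′ C→T rate above 10% among those reads, at least one
mismatch in their first 10 bases, and a **negative difference proportion**
(−Δ%) of exactly 1 — with histogram bin differences `d_i = c_{i+1} − c_i`,

```
−Δ% = Σ_{d_i<0} |d_i| / Σ_i |d_i|
```

equal to 1 iff the edit-distance histogram never increases (a monotone
decline is the signature of a correct, ancient assignment). Abundance
profiles restricted to the 24 bacterial/archaeal families common to hominid
gut microbiomes are compared across samples with Bray–Curtis distances,
principal coordinates, a permutation pseudo-F test, and Wilcoxon rank-sum
tests.

## Worked example

Plant three damaged gut-family taxa and three undamaged environmental taxa,
run the full pipeline on the simulator's gold alignments, and authenticate:

```python
import tempfile, os
from paleogut import (generate_reference_set, simulate_reads, SimConfig,
                      parse_alignments, filter_alignments, DamageModelParams,
                      pmd_score, compute_taxon_evidence, authenticate_taxon)

refs = generate_reference_set(n_taxa=6, length_bp=20_000, gc=0.5, seed=1)
gut, env = refs.gut_taxa(), refs.environmental_taxa()
w_gut = {t: (1/len(gut) if t in gut else 0.0) for t in gut + env}
w_env = {t: (1/len(env) if t in env else 0.0) for t in gut + env}
anc = simulate_reads(refs, SimConfig(n_ancient=1500, seed=10, taxon_weights=w_gut), read_prefix="a")
mod = simulate_reads(refs, SimConfig(n_modern=1500, seed=11, taxon_weights=w_env), read_prefix="m")

reads = []
with tempfile.TemporaryDirectory() as d:
    for i, ds in enumerate((anc, mod)):
        path = os.path.join(d, f"{i}.sam"); ds.write_sam(path)
        reads += list(parse_alignments(path))
reads = filter_alignments(reads)                       # MAPQ > 20, X0 = 1
params = DamageModelParams()                           # d_max=0.3, γ=0.5, d_const=0.01
pmds = {r.read_id: pmd_score(r, params).pmds for r in reads}
by_taxon = {}
for r in reads: by_taxon.setdefault(r.taxon_id, []).append(r)
for t in sorted(by_taxon):
    ev = compute_taxon_evidence(t, by_taxon[t], pmds, refs.by_id(t).length)
    d = authenticate_taxon(ev)
    print(f"{t:<14} {ev.n_reads:>5} {ev.n_pmds1:>6} {100*ev.ct5:>8.1f} "
          f"{ev.neg_delta:>5.2f}  {'ancient' if d.accept else 'rejected: ' + ','.join(d.failed)}")
```

prints:

```
env_taxon_3      483      5      0.0  0.00  rejected: pmds1_reads>50,neg_delta>=1.0,ct5>0.1,terminal_mismatch
env_taxon_4      512     12      8.3  1.00  rejected: pmds1_reads>50,ct5>0.1
env_taxon_5      505     14      0.0  0.00  rejected: pmds1_reads>50,neg_delta>=1.0,ct5>0.1,terminal_mismatch
gut_taxon_0      512    236     15.1  1.00  ancient
gut_taxon_1      470    231     13.3  1.00  ancient
gut_taxon_2      518    249     12.6  1.00  ancient
```

Columns are assigned reads, reads with PMDS > 1, pooled 5′ C→T percentage and
−Δ% (both on the PMDS > 1 subset). The three planted ancient taxa show the
expected double-digit terminal deamination and a perfectly declining
edit-distance histogram; the undamaged contaminants fail the damage criteria
even where read counts are high.

The same stages are available as a CLI (`paleogut simulate | score |
authenticate | profile | compare`); run `paleogut --help` for the options and
`paleogut simulate --preset site14` for a 14-sample, 5-layer-group synthetic
site layout.

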