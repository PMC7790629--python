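# Methods

## The damage model

Post-mortem DNA decay leaves three measurable signatures that this package
models and exploits:

- **Terminal deamination.** Cytosine deaminates to uracil preferentially in
  the single-stranded overhangs at fragment ends; sequencing reads it as
  C→T at the 5′ end and, for double-stranded library protocols, as G→A at
  the 3′ end (the complement of 5′ C→T on the opposite strand).
  Single-stranded protocols show C→T at both ends. The frequency is highest
  at the terminal base and decays roughly geometrically inward.
- **Fragmentation.** Ancient fragments are short; most libraries sit in the
  30–70 bp range with means around 45–58 bp.
- **Depurination.** Strand breaks occur preferentially 3′ of a purine, so
  the reference base immediately preceding a fragment's 5′ end is enriched
  for A/G.

A damage profile is the pair of per-position probability vectors
`p5[d], p3[d]` for `d = 1..W` (distance from the respective end, 1-based)
together with a fragment-length distribution and the library protocol.
Frequencies are defined conditionally on the reference base: `p5[d]` is
P(read = T | reference = C, distance d from 5′ end).

## Profiling (measurement)

`misincorporation_table` walks each alignment's CIGAR against the reference
FASTA, rotates reverse-strand alignments into molecule orientation
(complementing both bases and measuring distances from the molecule's own
ends), and accumulates numerator/denominator counts per distance. Soft
clips and insertions have no aligned reference base and contribute to
neither count; deletions consume reference only; N on either side is
skipped. Reads shorter than `2W` contribute a position to both windows
independently. A zero denominator reports frequency 0; the per-position
denominators are kept on the profile (`opportunities5/3`) so the two cases
are distinguishable. Mismatches are always recomputed from the reference,
never taken from MD tags, which makes the profiler robust to aligner
dialects and MD-less BAMs.

The default window is W = 25 positions per end (the usual damage-plot
convention). The shipped demo/benchmark profile uses W = 15, matching the
widest filter window exercised.

## Simulation (generation)

The generator mimics the standard three-step ancient-DNA simulation recipe:

1. **Fragment.** Lengths are i.i.d. draws from the profile's length
   distribution; the contig is chosen proportional to the number of start
   positions admitting the drawn length; the start is uniform among them;
   the strand is uniform; windows containing N are re-drawn (up to 1,000
   attempts, then fatal). Reverse-strand fragments are reverse-complemented
   into molecule orientation.
2. **Damage.** Each C within W of the 5′ end flips to T independently with
   probability `p5[d]`; each G within W of the 3′ end flips to A with
   `p3[d]` (C→T for single-strand chemistry; a base falling in both windows
   flips with the combined probability `1 − (1−p5)(1−p3)`). No other base
   ever changes. An optional uniform per-base sequencing-error model
   (default rate 0, substitution to a uniformly chosen different base) runs
   afterwards on endogenous reads.
3. **Mix.** Exactly `round(n_reads × cont_rate)` contaminant reads are
   added — exact rather than binomial allocation, so an identity evaluation
   returns the configured rate bit-exactly. Contaminants carry no damage:
   drawn from a genome they are error-free reference fragments (homologous
   modern contamination); supplied as FASTQ they pass through unmodified
   (a real-contamination spike-in). By default genome-derived contaminants
   use the same length distribution as the endogenous class, so length
   alone cannot separate the classes; a separate modern-DNA length
   distribution can be supplied.

Every read's provenance is encoded in its name (`endo:`/`cont:` prefix)
and every introduced base change is recorded in a per-read ledger with its
cause (`deamination` or `seq_error`). Reference-derived reads keep truth
alignments (full-length match, MAPQ 60), so the filter can be evaluated
with a "perfect aligner" and no external mapping step. All randomness flows
from a single integer seed through one `numpy` generator; identical
configurations produce byte-identical FASTQ output.

What the generator deliberately does **not** emulate: nick/overhang
biochemistry (positional flip probabilities are sufficient because every
downstream computation only observes positional substitution frequencies),
per-cycle quality-score error profiles, paired-end reads, microbial
community composition, and adapter artefacts. Passing tests on this
synthetic data therefore demonstrate the correctness and the separating
power of the screens under the stated damage model — not performance on
real libraries with indel errors, reference bias or unmodelled microbial
reads.

## Filtering

`filter_alignments` applies, in a fixed staged order, (1) a
mapping-quality gate (default MAPQ ≥ 30, the usual validity threshold for
ancient-DNA mapping hits), (2) the deamination screen, (3) optionally the
depurination screen, (4) optionally the length screen. Screens combine
conjunctively; each can also be used alone through the CLI. Rejections are
counted per stage, the output preserves input order, and the run is
deterministic and idempotent.

Decisions taken where the design was genuinely open:

- **`and`/`or` semantics.** `and` requires at least `DeamNum` qualifying
  mismatches in *each* terminal window; `or` in at least one.
- **Substitution types per window.** Both C→T and G→A count in both
  windows by default — terminal G→A at the 5′ end is still damage evidence
  under single-strand-like chemistry and costs nothing under the null. A
  `--strict-orientation` flag restricts C→T to the 5′ window and G→A to
  the 3′ window for strictly double-stranded libraries.
- **Distances are counted on the read** (distance 1 = terminal base).
  Soft-clipped and inserted bases consume distance — they are physical
  read bases — but can never be mismatches; deletions consume none.
- **Depurination geometry.** Forward strand: reference base at `start − 1`
  ∈ {A, G}. Reverse strand: the molecule's 5′ end maps to the alignment's
  right edge, so the test is the complement of the reference base at `end`
  (i.e. reference ∈ {T, C}). A fragment flush with a contig edge has no
  preceding base and fails the screen.
- **Verdict invariance.** Because all evidence is computed in molecule
  orientation, a molecule and its reverse-strand-stored twin always
  receive identical verdicts (property-tested).

The recommended preset is `DeamNum=1, DetectRange=15, DoubleOrSingle=or`:
the single-mismatch, wide-window, either-end setting maximises endogenous
retention while still removing essentially all undamaged contamination.

## Evaluation

CRT, LRE and the removal fraction are pure count ratios over the truth
tags; reports serialize to TSV at 10 significant digits and satisfy
`removal_fraction = 1 − cont_after/cont_before` identically. At the
mapping stage only records mapped with MAPQ ≥ 30 count as valid hits
("higher than 30" is read inclusively). CRT of an empty retained set is
undefined and reported as NaN with a warning; LRE without endogenous truth
reads is an error. Runtime is carried as an informational field only — it
is hardware-dependent and never compared.

## Benchmark conditions and numerical choices

The acceptance benchmarks (`scripts/acceptance.py`, mirrored in the test
suite) use: a seeded random 100 kb reference of uniform base composition;
100,000 reads; endogenous fragment lengths 30–70 bp (discretised Gaussian
centred at 50 bp, σ = 9); terminal deamination 25% + 0.5% background at
position 1 decaying by ×0.55 per position over a 15 bp window on both ends;
contamination rates 0.95 and 0.99 with error-free reference-derived
contaminants; the recommended filter preset applied to truth alignments.
Under these conditions an undamaged, error-free contaminant read can never
exhibit a qualifying mismatch, so the screen removes 100% of
contamination; the benchmark checks the removal percentages against their
published floors (≥ 99% at 99% contamination, ≥ 99.9% at 95%). Structural
tests run at smaller sizes chosen for statistical sufficiency: parameter
recovery at 50,000 reads (3 binomial SE per position), oracle equivalence
at 1,000 reads, the 18-combination parameter grid and the nine-rate
exact-allocation identity at 2,000 reads per condition.

Statistical tolerances follow the usual Monte-Carlo conventions: 3
standard errors for binomial recovery checks, 4 standard errors for the
closed-form retention cross-check
`E[retention] = 1 − E[(1−p)^(c5+g3)]` under a uniform per-position damage
probability, and the 1% Kolmogorov–Smirnov critical value (conservative
for discrete distributions) for length-distribution agreement.

## Known limitations

- The simulator's damage is positionally independent; real damage shows
  correlated overhang lengths and nick positions.
- Homologous contamination is modelled as fragments of the *same*
  reference; real present-day contamination differs from the ancient
  genome at polymorphic sites, which slightly helps real-world filtering
  and is not modelled here.
- The FASTQ contamination path is a spike-in mechanism, not a
  reconstruction of any particular metagenomic community.
- LRE under the recommended preset is substantial by construction (only
  terminally damaged molecules are retained); the package reports it but
  takes no position on downstream coverage sufficiency.
- CRAM, paired-end mates and quality-aware trimming are out of scope.
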