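"""Tagged ancient-DNA read simulation with controlled contamination mixing.

The generator follows the three-step recipe of gargammel-style simulators:

1. cut the reference into fragments whose lengths follow an empirical
   fragment-length distribution (uniform N-free start, uniform strand);
2. inject positional deamination damage — each terminal C (and, for
   double-strand protocols, each terminal G at the 3′ end) flips
   independently with the profile's per-position probability;
3. mix in contamination at a specified rate.  Contaminant reads are NOT
   fragmented by the ancient length model and carry NO deamination damage:
   drawn from a genome they are error-free reference fragments (homologous
   modern contamination), read from FASTQ they pass through unmodified
   (a real-contamination spike-in).

The endogenous/contaminant split is exact — ``round(n_reads * cont_rate)``
contaminants, remainder endogenous — so the configured contamination rate is
recovered exactly by a no-op evaluation.  Every reference-derived read keeps
a truth alignment, letting the filter be tested with a perfect aligner and
no external mapping step.  All randomness flows from one ``numpy`` seed;
identical configs give byte-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from paleosift.damage_profiling import (
    DOUBLE_STRAND,
    SINGLE_STRAND,
    DamageProfile,
    LengthDistribution,
)
from paleosift.io_bridge import (
    AlignmentRecord,
    Genome,
    ReadTag,
    Strand,
    TaggedRead,
    read_fastq,
    revcomp,
    write_alignments,
    write_tagged_fastq,
)

__all__ = [
    "BENCHMARK_CONT_RATES",
    "Fragment",
    "SimulationConfig",
    "TruthSet",
    "apply_damage",
    "draw_fragments",
    "make_contamination",
    "simulate_dataset",
    "write_truth_set",
]

#: The contamination-rate grid exercised by the benchmark experiments.
BENCHMARK_CONT_RATES = (0.20, 0.40, 0.60, 0.80, 0.90, 0.95, 0.99, 0.995, 0.999)

#: Truth alignments carry the maximum mapping quality (perfect aligner).
TRUTH_MAPQ = 60

_MAX_RESAMPLE = 1000


@dataclass
class Fragment:
    """A reference substring in molecule orientation (reverse strand ⇒
    ``sequence`` is the reverse complement of the reference slice)."""

    contig: str
    start: int
    strand: Strand
    sequence: str


@dataclass
class LedgerEntry:
    """One introduced base change: molecule-oriented 0-based position."""

    read_name: str
    position: int
    original: str
    emitted: str
    cause: str  # "deamination" | "seq_error"


@dataclass
class SimulationConfig:
    n_reads: int
    cont_rate: float
    profile: DamageProfile
    endo_source: Genome
    cont_source: Genome | str | Path | None = None  # None → endo_source
    cont_length_dist: LengthDistribution | dict[int, float] | None = None
    seq_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if not 0.0 <= self.cont_rate <= 1.0:
            raise ValueError("cont_rate must be in [0, 1]")
        if not 0.0 <= self.seq_error_rate < 1.0:
            raise ValueError("seq_error_rate must be in [0, 1)")
        if not self.profile.length_dist:
            raise ValueError("profile must carry a length distribution")

    @property
    def endo_rate(self) -> float:
        return 1.0 - self.cont_rate


@dataclass
class TruthSet:
    """Simulator output: reads, truth alignments and the damage ledger."""

    reads: list[TaggedRead]
    truth_alignments: list[AlignmentRecord]
    ledger: list[LedgerEntry]
    config: SimulationConfig | None = None

    def counts(self) -> dict[ReadTag, int]:
        out: dict[ReadTag, int] = {}
        for r in self.reads:
            out[r.tag] = out.get(r.tag, 0) + 1
        return out


def _length_arrays(
    length_dist: LengthDistribution | dict[int, float],
) -> tuple[np.ndarray, np.ndarray]:
    probs = (
        length_dist.probabilities
        if isinstance(length_dist, LengthDistribution)
        else length_dist
    )
    lengths = np.array(sorted(probs), dtype=np.int64)
    p = np.array([probs[l] for l in lengths], dtype=float)
    return lengths, p / p.sum()


def draw_fragments(
    genome: Genome,
    length_dist: LengthDistribution | dict[int, float],
    n: int,
    rng: np.random.Generator,
) -> list[Fragment]:
    """Draw ``n`` fragments: i.i.d. lengths, uniform N-free start, uniform strand.

    Contigs are weighted by the number of start positions admitting the drawn
    length.  Windows containing N are re-drawn up to 1,000 times, then fatal.
    """
    lengths, probs = _length_arrays(length_dist)
    cids = list(genome.contigs)
    clens = np.array([genome.length(c) for c in cids], dtype=np.int64)
    if lengths.max() > clens.max():
        raise ValueError(
            f"max fragment length {lengths.max()} exceeds longest contig "
            f"({clens.max()} bp)"
        )
    drawn = rng.choice(lengths, size=n, p=probs)
    strands = rng.integers(0, 2, size=n)
    fragments: list[Fragment] = []
    for i in range(n):
        L = int(drawn[i])
        weights = np.maximum(clens - L + 1, 0)
        total = int(weights.sum())
        if total == 0:
            raise ValueError(f"no contig admits fragment length {L}")
        wp = weights / total
        for attempt in range(_MAX_RESAMPLE):
            ci = int(rng.choice(len(cids), p=wp))
            start = int(rng.integers(0, clens[ci] - L + 1))
            seq = genome[cids[ci]][start : start + L]
            if "N" not in seq:
                break
        else:
            raise ValueError(
                f"no N-free window of length {L} found in {_MAX_RESAMPLE} draws"
            )
        strand = Strand.reverse if strands[i] else Strand.forward
        if strand == Strand.reverse:
            seq = revcomp(seq)
        fragments.append(Fragment(cids[ci], start, strand, seq))
    return fragments


def apply_damage(
    sequence: str, profile: DamageProfile, rng: np.random.Generator
) -> tuple[str, list[tuple[int, str, str]]]:
    """Inject deamination into one molecule-oriented fragment sequence.

    Each C within ``window`` of the 5′ end flips to T with the profile's
    per-position probability; at the 3′ end, G→A for double-strand
    protocols, C→T for single-strand.  A short fragment's base that sits in
    both windows (single-strand only) flips with the combined probability
    ``1 - (1-p5)(1-p3)``.  Returns the damaged sequence and a list of
    ``(position, original, emitted)`` changes (0-based, molecule oriented).
    """
    W = profile.window
    L = len(sequence)
    t5 = "C"
    t3 = "G" if profile.protocol == DOUBLE_STRAND else "C"
    alt = {"C": "T", "G": "A"}
    # accumulate flip probability per candidate index
    pflip: dict[int, float] = {}
    for d in range(1, min(W, L) + 1):
        if sequence[d - 1] == t5 and profile.p5[d - 1] > 0:
            pflip[d - 1] = profile.p5[d - 1]
        idx3 = L - d
        if sequence[idx3] == t3 and profile.p3[d - 1] > 0:
            prev = pflip.get(idx3, 0.0)
            pflip[idx3] = 1.0 - (1.0 - prev) * (1.0 - profile.p3[d - 1])
    if not pflip:
        return sequence, []
    changes: list[tuple[int, str, str]] = []
    chars = list(sequence)
    for idx in sorted(pflip):
        if rng.random() < pflip[idx]:
            orig = chars[idx]
            chars[idx] = alt[orig]
            changes.append((idx, orig, chars[idx]))
    if not changes:
        return sequence, []
    return "".join(chars), changes


_BASES = "ACGT"


def _apply_seq_errors(
    sequence: str, rate: float, rng: np.random.Generator
) -> tuple[str, list[tuple[int, str, str]]]:
    """Uniform per-base substitution to a uniformly chosen different base."""
    if rate <= 0.0:
        return sequence, []
    hits = np.flatnonzero(rng.random(len(sequence)) < rate)
    if hits.size == 0:
        return sequence, []
    chars = list(sequence)
    changes = []
    for idx in hits:
        orig = chars[idx]
        choices = [b for b in _BASES if b != orig] or list(_BASES)
        new = choices[int(rng.integers(0, len(choices)))]
        chars[idx] = new
        changes.append((int(idx), orig, new))
    return "".join(chars), changes


def make_contamination(
    source: Genome | str | Path,
    n: int,
    length_dist: LengthDistribution | dict[int, float] | None,
    rng: np.random.Generator,
) -> tuple[list[TaggedRead], list[AlignmentRecord]]:
    """Generate ``n`` contaminant reads, tagged ``cont``, damage-free.

    From a :class:`Genome`: error-free reference fragments drawn with
    ``length_dist`` (truth alignments returned).  From a FASTQ path: reads
    pass through unmodified, renamed with the ``cont:`` prefix; if the file
    holds fewer than ``n`` reads they are resampled with replacement (with a
    warning).  No truth alignments exist for FASTQ-derived contaminants.
    """
    if n == 0:
        return [], []
    if isinstance(source, Genome):
        if length_dist is None:
            raise ValueError("genome-derived contamination needs a length distribution")
        frags = draw_fragments(source, length_dist, n, rng)
        reads: list[TaggedRead] = []
        alns: list[AlignmentRecord] = []
        for i, frag in enumerate(frags):
            name = f"cont:c{i:06d}"
            read = TaggedRead(name, frag.sequence)
            reads.append(read)
            sam_seq = (
                revcomp(frag.sequence)
                if frag.strand == Strand.reverse
                else frag.sequence
            )
            alns.append(
                AlignmentRecord(
                    read=TaggedRead(name, sam_seq),
                    contig=frag.contig,
                    start=frag.start,
                    strand=frag.strand,
                    cigar=[("M", len(frag.sequence))],
                    mapq=TRUTH_MAPQ,
                )
            )
        return reads, alns
    pool = read_fastq(source)
    if not pool:
        raise ValueError(f"contamination FASTQ {source} holds no reads")
    if len(pool) < n:
        warnings.warn(
            f"contamination FASTQ has {len(pool)} reads < {n}; "
            "sampling with replacement",
            stacklevel=2,
        )
        idx = rng.integers(0, len(pool), size=n)
    else:
        idx = rng.permutation(len(pool))[:n]
    reads = [
        TaggedRead(f"cont:c{i:06d}:{pool[j].name}", pool[j].sequence, pool[j].qualities)
        for i, j in enumerate(idx)
    ]
    return reads, []


def simulate_dataset(config: SimulationConfig) -> TruthSet:
    """Run the full simulation: fragment, damage, mix, tag.

    Exactly ``round(n_reads * cont_rate)`` contaminant reads are generated;
    the remainder are endogenous.  Endogenous fragments pass through
    :func:`draw_fragments`, :func:`apply_damage` and the optional uniform
    sequencing-error model; contaminants stay pristine.  The output read
    order is a seeded shuffle of the two classes.
    """
    rng = np.random.default_rng(config.seed)
    n_cont = int(round(config.n_reads * config.cont_rate))
    n_endo = config.n_reads - n_cont

    reads: list[TaggedRead] = []
    alignments: list[AlignmentRecord] = []
    ledger: list[LedgerEntry] = []

    if n_endo:
        frags = draw_fragments(
            config.endo_source, config.profile.length_dist, n_endo, rng
        )
        for i, frag in enumerate(frags):
            name = f"endo:e{i:06d}"
            seq, dmg = apply_damage(frag.sequence, config.profile, rng)
            for pos, orig, new in dmg:
                ledger.append(LedgerEntry(name, pos, orig, new, "deamination"))
            seq, errs = _apply_seq_errors(seq, config.seq_error_rate, rng)
            for pos, orig, new in errs:
                ledger.append(LedgerEntry(name, pos, orig, new, "seq_error"))
            reads.append(TaggedRead(name, seq))
            sam_seq = revcomp(seq) if frag.strand == Strand.reverse else seq
            alignments.append(
                AlignmentRecord(
                    read=TaggedRead(name, sam_seq),
                    contig=frag.contig,
                    start=frag.start,
                    strand=frag.strand,
                    cigar=[("M", len(seq))],
                    mapq=TRUTH_MAPQ,
                )
            )

    if n_cont:
        source = config.cont_source if config.cont_source is not None else config.endo_source
        cont_ld = (
            config.cont_length_dist
            if config.cont_length_dist is not None
            else config.profile.length_dist
        )
        cont_reads, cont_alns = make_contamination(source, n_cont, cont_ld, rng)
        reads.extend(cont_reads)
        alignments.extend(cont_alns)

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    by_name = {a.read.name: a for a in alignments}
    alignments = [by_name[r.name] for r in reads if r.name in by_name]
    return TruthSet(reads, alignments, ledger, config)


def write_truth_set(truth: TruthSet, prefix: str | Path) -> dict[str, Path]:
    """Write PREFIX.fq, PREFIX.truth.sam and PREFIX.ledger.tsv."""
    prefix = Path(prefix)
    genome = truth.config.endo_source if truth.config else None
    fq = Path(f"{prefix}.fq")
    sam = Path(f"{prefix}.truth.sam")
    tsv = Path(f"{prefix}.ledger.tsv")
    write_tagged_fastq(truth.reads, fq)
    if genome is not None:
        contigs = dict(genome.contigs)
        if truth.config and isinstance(truth.config.cont_source, Genome):
            for cid, seq in truth.config.cont_source.items():
                contigs.setdefault(cid, seq)
        write_alignments(truth.truth_alignments, Genome(contigs), sam)
    with open(tsv, "w") as fh:
        fh.write("read\tposition\toriginal\temitted\tcause\n")
        for e in truth.ledger:
            fh.write(f"{e.read_name}\t{e.position}\t{e.original}\t{e.emitted}\t{e.cause}\n")
    return {"fastq": fq, "truth_sam": sam, "ledger": tsv}
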