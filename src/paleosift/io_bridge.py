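"""Formats and conventions shared by the whole pipeline.

Reads and writes FASTA, FASTQ and SAM/BAM through Biopython and pysam, and
enforces the read-name tag convention that carries endogenous/contaminant
truth through every downstream step: a read named ``endo:<id>`` is a true
endogenous (ancient) molecule, ``cont:<id>`` a contaminant; any other name
maps to :attr:`ReadTag.unknown`.  The prefix survives aligners and
``samtools`` round-trips, so truth never has to live in auxiliary tags.

Coordinates are 0-based half-open internally; SAM's 1-based POS is converted
at the boundary by pysam.  The sequence stored in an
:class:`AlignmentRecord` is the SAM-oriented (reference-forward) sequence;
molecule orientation is recovered from the ``strand`` field where a
computation needs it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam
from Bio import SeqIO

__all__ = [
    "COMPLEMENT",
    "AlignmentRecord",
    "Genome",
    "ReadTag",
    "TaggedRead",
    "read_fasta",
    "read_fastq",
    "revcomp",
    "stream_alignments",
    "write_alignments",
    "write_tagged_fastq",
]

_COMP_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Base-complement map used throughout (N is self-complementary).
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: Phred quality emitted for simulated reads lacking measured qualities
#: (Phred 40; qualities are not consumed by any computation here).
DEFAULT_QUALITY_CHAR = "I"


def revcomp(seq: str) -> str:
    """Reverse-complement a nucleotide string (case preserved, N fixed)."""
    return seq.translate(_COMP_TABLE)[::-1]


class ReadTag(str, Enum):
    """Truth provenance of a read, encoded in its name prefix."""

    endo = "endo"
    cont = "cont"
    unknown = "unknown"


def parse_tag(name: str) -> ReadTag:
    """Recover the truth tag from a read name (``endo:``/``cont:`` prefix)."""
    prefix, _, rest = name.partition(":")
    if rest and prefix == "endo":
        return ReadTag.endo
    if rest and prefix == "cont":
        return ReadTag.cont
    return ReadTag.unknown


@dataclass
class Genome:
    """Named contig sequences; the mapping and simulation substrate.

    Contig sequences are uppercase strings over ``A C G T N``.
    """

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {cid!r} is empty")

    def __getitem__(self, contig: str) -> str:
        return self.contigs[contig]

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def items(self):
        return self.contigs.items()


@dataclass
class TaggedRead:
    """A sequenced fragment with truth provenance.

    ``tag`` defaults to whatever the naming convention says; passing it
    explicitly is only needed for reads whose names do not carry a prefix.
    A standalone ``TaggedRead`` (e.g. from FASTQ) is in sequencing /
    molecule orientation.
    """

    name: str
    sequence: str
    qualities: str | None = None
    tag: ReadTag = None  # type: ignore[assignment]  # derived in __post_init__

    def __post_init__(self) -> None:
        if self.tag is None:
            self.tag = parse_tag(self.name)
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.name!r}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class Strand(str, Enum):
    forward = "+"
    reverse = "-"


@dataclass
class AlignmentRecord:
    """A read's placement on the reference.

    ``read.sequence`` is the SAM-stored, reference-forward sequence;
    for ``strand == reverse`` the molecule is its reverse complement.
    ``cigar`` is a list of ``(op, length)`` with ops in ``M I D S``
    (``=``/``X`` collapse to ``M`` on input).
    """

    read: TaggedRead
    contig: str | None
    start: int
    strand: Strand
    cigar: list[tuple[str, int]]
    mapq: int
    is_mapped: bool = True

    @property
    def ref_span(self) -> int:
        """Reference bases consumed (sum of M and D lengths)."""
        return sum(n for op, n in self.cigar if op in "MD")

    @property
    def end(self) -> int:
        """0-based exclusive reference end."""
        return self.start + self.ref_span

    def query_consumed(self) -> int:
        return sum(n for op, n in self.cigar if op in "MIS")

    def validate(self, genome: Genome | None = None) -> None:
        """Check CIGAR/sequence/reference consistency; raise on violation."""
        if not self.is_mapped:
            return
        bad = [op for op, _ in self.cigar if op not in "MIDS"]
        if bad:
            raise ValueError(f"{self.read.name}: unsupported CIGAR ops {bad}")
        if self.query_consumed() != len(self.read.sequence):
            raise ValueError(
                f"{self.read.name}: CIGAR consumes {self.query_consumed()} "
                f"query bases but sequence has {len(self.read.sequence)}"
            )
        if genome is not None:
            if self.contig not in genome:
                raise KeyError(f"contig {self.contig!r} not in genome")
            if self.start < 0 or self.end > genome.length(self.contig):
                raise ValueError(
                    f"{self.read.name}: span [{self.start}, {self.end}) "
                    f"outside contig {self.contig!r}"
                )


def read_fasta(path: str | Path) -> Genome:
    """Load a FASTA file into a :class:`Genome`, uppercasing sequences.

    Raises on a missing/empty file or duplicate contig ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate contig {rec.id!r} in {path}")
        contigs[rec.id] = str(rec.seq).upper()
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    return Genome(contigs)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    """Write a :class:`Genome` as wrapped FASTA."""
    with open(path, "w") as fh:
        for cid, seq in genome.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[TaggedRead]:
    """Load a FASTQ file; tags are parsed from read names."""
    reads: list[TaggedRead] = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(TaggedRead(rec.id, str(rec.seq).upper(), quals))
    return reads


def write_tagged_fastq(reads: Iterable[TaggedRead], path: str | Path) -> int:
    """Write reads as 4-line FASTQ records; returns the count written.

    Reads without qualities get a constant Phred-40 quality string.
    """
    n = 0
    with open(path, "w") as fh:
        for read in reads:
            quals = read.qualities or DEFAULT_QUALITY_CHAR * len(read.sequence)
            fh.write(f"@{read.name}\n{read.sequence}\n+\n{quals}\n")
            n += 1
    return n


_CIGAR_OPS = "MIDNSHP=X"


def _cigar_from_pysam(seg: pysam.AlignedSegment) -> list[tuple[str, int]]:
    cigar: list[tuple[str, int]] = []
    for code, length in seg.cigartuples or []:
        op = _CIGAR_OPS[code]
        if op in "=X":
            op = "M"
        if op == "H":  # hard clip consumes neither sequence nor reference
            continue
        if op not in "MIDS":
            raise ValueError(f"unsupported CIGAR op {op!r} in {seg.query_name}")
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + length)
        else:
            cigar.append((op, length))
    return cigar


def stream_alignments(
    path: str | Path, mapq_min: int = 0
) -> Iterator[AlignmentRecord]:
    """Stream SAM/BAM records as :class:`AlignmentRecord` in file order.

    Records with ``mapq < mapq_min`` are suppressed; unmapped records are
    yielded (with ``is_mapped=False``) only when ``mapq_min == 0``.  Tags
    come from the read-name convention.
    """
    if mapq_min < 0:
        raise ValueError("mapq_min must be >= 0")
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
        for i, seg in enumerate(af.fetch(until_eof=True)):
            try:
                if seg.is_unmapped:
                    if mapq_min == 0:
                        read = TaggedRead(
                            seg.query_name, (seg.query_sequence or "").upper()
                        )
                        yield AlignmentRecord(
                            read, None, -1, Strand.forward, [], 0, is_mapped=False
                        )
                    continue
                if seg.mapping_quality < mapq_min:
                    continue
                if seg.query_sequence is None:
                    raise ValueError("record has no sequence")
                quals = None
                if seg.query_qualities is not None:
                    quals = "".join(chr(q + 33) for q in seg.query_qualities)
                read = TaggedRead(seg.query_name, seg.query_sequence.upper(), quals)
                yield AlignmentRecord(
                    read=read,
                    contig=seg.reference_name,
                    start=seg.reference_start,
                    strand=Strand.reverse if seg.is_reverse else Strand.forward,
                    cigar=_cigar_from_pysam(seg),
                    mapq=seg.mapping_quality,
                )
            except ValueError as exc:
                raise ValueError(f"unparseable record #{i} in {path}: {exc}") from exc


def _sam_header(genome: Genome) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": cid, "LN": len(seq)} for cid, seq in genome.items()],
    }


def write_alignments(
    alignments: Sequence[AlignmentRecord] | Iterable[AlignmentRecord],
    genome: Genome,
    path: str | Path,
) -> int:
    """Write alignment records as SAM (or BAM if the path ends in .bam)."""
    mode = "wb" if str(path).endswith(".bam") else "wh"
    header = _sam_header(genome)
    ids = {cid: i for i, cid in enumerate(genome.contigs)}
    n = 0
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for rec in alignments:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = rec.read.name
            seg.query_sequence = rec.read.sequence
            if rec.read.qualities is not None:
                seg.query_qualities = pysam.qualitystring_to_array(rec.read.qualities)
            if rec.is_mapped:
                seg.flag = 16 if rec.strand == Strand.reverse else 0
                seg.reference_id = ids[rec.contig]
                seg.reference_start = rec.start
                seg.mapping_quality = rec.mapq
                seg.cigarstring = "".join(f"{ln}{op}" for op, ln in rec.cigar)
            else:
                seg.flag = 4
                seg.mapping_quality = 0
            out.write(seg)
            n += 1
    return n
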