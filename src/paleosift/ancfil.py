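"""AncFil-style read filtering: keep aligned reads with ancient-DNA damage evidence.

Endogenous ancient molecules accumulate post-mortem C→T (and complementary
G→A) substitutions concentrated at fragment ends, and tend to begin just
after a purine (depurination-driven strand breaks).  Modern homologous
contamination shows neither.  The filter exploits this with three screens:

- **deamination screen** — retain a read with at least ``deam_num``
  C→T or G→A mismatches within the terminal ``detect_range`` bases of its
  5′ and/or 3′ end (``double_or_single`` = ``and`` requires both ends,
  ``or`` either end).  Recommended preset: ``deam_num=1``,
  ``detect_range=15``, ``double_or_single='or'``.
- **depurination screen** (optional, weak) — retain a read whose reference
  position immediately preceding the molecule's 5′ end is a purine (A/G).
- **length screen** (optional, weak) — retain reads within length bounds.

Screens are applied conjunctively after a mapping-quality gate
(default MAPQ ≥ 30).  All mismatch evidence is recomputed against the
reference FASTA in molecule orientation, so verdicts are identical for a
molecule however it is stored (forward or reverse strand).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from paleosift.io_bridge import (
    COMPLEMENT,
    AlignmentRecord,
    Genome,
    ReadTag,
    Strand,
)

__all__ = [
    "FilterParams",
    "FilterStats",
    "RECOMMENDED_PARAMS",
    "TerminalMismatch",
    "deamination_pass",
    "depurination_pass",
    "filter_alignments",
    "length_pass",
    "terminal_mismatches",
]

#: Substitutions that count as deamination evidence (molecule orientation).
_DEAM_SUBS = {("C", "T"), ("G", "A")}


@dataclass(frozen=True)
class FilterParams:
    """Screening parameters.

    ``deam_num`` — minimum qualifying terminal mismatches ("DeamNum");
    ``detect_range`` — terminal window in bp ("DetectRange");
    ``double_or_single`` — require the count at both ends (``and``) or at
    least one end (``or``) ("DoubleOrSingle").  ``strict_orientation``
    restricts C→T to the 5′ window and G→A to the 3′ window (double-strand
    chemistry); by default both substitution types count in both windows.
    """

    deam_num: int = 1
    detect_range: int = 15
    double_or_single: str = "or"
    use_depurination: bool = False
    length_bounds: tuple[int, int] | None = None
    mapq_min: int = 30
    strict_orientation: bool = False

    def __post_init__(self) -> None:
        if self.deam_num < 1:
            raise ValueError("deam_num must be >= 1")
        if self.detect_range < 1:
            raise ValueError("detect_range must be >= 1")
        if self.double_or_single not in ("and", "or"):
            raise ValueError("double_or_single must be 'and' or 'or'")
        if self.length_bounds is not None:
            lo, hi = self.length_bounds
            if lo > hi:
                raise ValueError("length_bounds: min > max")
        if self.mapq_min < 0:
            raise ValueError("mapq_min must be >= 0")


#: The recommended screening preset.
RECOMMENDED_PARAMS = FilterParams(deam_num=1, detect_range=15, double_or_single="or")


@dataclass(frozen=True)
class TerminalMismatch:
    """One read/reference mismatch in molecule orientation.

    ``dist5``/``dist3`` are 1-based distances from the molecule's own
    5′/3′ ends (distance 1 = the terminal base, counted on the read).
    """

    dist5: int
    dist3: int
    ref_base: str
    read_base: str


def terminal_mismatches(
    alignment: AlignmentRecord, genome: Genome
) -> list[TerminalMismatch]:
    """Enumerate all aligned-position mismatches of a mapped read.

    Soft-clipped and inserted bases consume distance-from-end (they are
    physical read bases) but cannot be mismatches; deletions consume no read
    distance; N in read or reference never counts as a mismatch.  For
    reverse-strand alignments, bases are complement-mapped and distances
    measured from the molecule's own ends.
    """
    if alignment.contig not in genome:
        raise KeyError(f"contig {alignment.contig!r} not found in genome")
    ref = genome[alignment.contig]
    seq = alignment.read.sequence
    L = len(seq)
    reverse = alignment.strand == Strand.reverse
    out: list[TerminalMismatch] = []
    qpos = 0
    rpos = alignment.start
    for op, n in alignment.cigar:
        if op == "M":
            for k in range(n):
                qb = seq[qpos + k]
                rb = ref[rpos + k]
                if qb != rb and qb != "N" and rb != "N":
                    if reverse:
                        out.append(
                            TerminalMismatch(
                                dist5=L - (qpos + k),
                                dist3=qpos + k + 1,
                                ref_base=COMPLEMENT[rb],
                                read_base=COMPLEMENT[qb],
                            )
                        )
                    else:
                        out.append(
                            TerminalMismatch(
                                dist5=qpos + k + 1,
                                dist3=L - (qpos + k),
                                ref_base=rb,
                                read_base=qb,
                            )
                        )
            qpos += n
            rpos += n
        elif op in "IS":
            qpos += n
        elif op == "D":
            rpos += n
        else:
            raise ValueError(f"unsupported CIGAR op {op!r}")
    if reverse:
        out.reverse()  # molecule 5'→3' order
    return out


def deamination_pass(
    alignment: AlignmentRecord, genome: Genome, params: FilterParams
) -> bool:
    """Does the read carry enough terminal deamination evidence?"""
    mms = terminal_mismatches(alignment, genome)
    m5 = 0
    m3 = 0
    R = params.detect_range
    for mm in mms:
        sub = (mm.ref_base, mm.read_base)
        if sub not in _DEAM_SUBS:
            continue
        if mm.dist5 <= R and (not params.strict_orientation or sub == ("C", "T")):
            m5 += 1
        if mm.dist3 <= R and (not params.strict_orientation or sub == ("G", "A")):
            m3 += 1
    if params.double_or_single == "and":
        return m5 >= params.deam_num and m3 >= params.deam_num
    return m5 >= params.deam_num or m3 >= params.deam_num


def depurination_pass(alignment: AlignmentRecord, genome: Genome) -> bool:
    """Is the reference base preceding the molecule's 5′ end a purine?

    Forward strand: reference base at ``start - 1`` ∈ {A, G}.  Reverse
    strand: the molecule's 5′ end maps to the alignment's right edge, so the
    test is on the complement of the reference base at ``end`` — i.e. the
    reference base ∈ {T, C}.  An alignment flush with the contig edge has no
    preceding base and fails.
    """
    if alignment.contig not in genome:
        raise KeyError(f"contig {alignment.contig!r} not found in genome")
    ref = genome[alignment.contig]
    if alignment.strand == Strand.forward:
        if alignment.start == 0:
            return False
        return ref[alignment.start - 1] in "AG"
    pos = alignment.end
    if pos >= len(ref):
        return False
    return COMPLEMENT[ref[pos]] in "AG"


def length_pass(
    alignment: AlignmentRecord, bounds: tuple[int, int] | None
) -> bool:
    """Is the read length within [min, max]?  Always true without bounds."""
    if bounds is None:
        return True
    lo, hi = bounds
    return lo <= len(alignment.read.sequence) <= hi


@dataclass
class FilterStats:
    """Per-criterion accounting for one filtering run (staged order:
    mapq → deamination → depurination → length)."""

    total: int = 0
    retained: int = 0
    rejected_mapq: int = 0
    rejected_deamination: int = 0
    rejected_depurination: int = 0
    rejected_length: int = 0
    input_by_tag: dict[ReadTag, int] = field(default_factory=dict)
    retained_by_tag: dict[ReadTag, int] = field(default_factory=dict)
    wall_seconds: float = 0.0

    @property
    def rejected(self) -> int:
        return (
            self.rejected_mapq
            + self.rejected_deamination
            + self.rejected_depurination
            + self.rejected_length
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "total\tretained\trejected_mapq\trejected_deamination\t"
                "rejected_depurination\trejected_length\t"
                "endo_in\tcont_in\tendo_retained\tcont_retained\twall_seconds\n"
            )
            fh.write(
                f"{self.total}\t{self.retained}\t{self.rejected_mapq}\t"
                f"{self.rejected_deamination}\t{self.rejected_depurination}\t"
                f"{self.rejected_length}\t"
                f"{self.input_by_tag.get(ReadTag.endo, 0)}\t"
                f"{self.input_by_tag.get(ReadTag.cont, 0)}\t"
                f"{self.retained_by_tag.get(ReadTag.endo, 0)}\t"
                f"{self.retained_by_tag.get(ReadTag.cont, 0)}\t"
                f"{self.wall_seconds:.3f}\n"
            )


def filter_alignments(
    alignments: Iterable[AlignmentRecord],
    genome: Genome,
    params: FilterParams,
) -> tuple[list[AlignmentRecord], FilterStats]:
    """Apply the enabled screens conjunctively; preserve input order.

    Returns the retained records and per-criterion rejection counts.  The
    run is deterministic and idempotent: filtering its own output with the
    same parameters changes nothing.
    """
    t0 = time.perf_counter()
    stats = FilterStats()
    retained: list[AlignmentRecord] = []
    for aln in alignments:
        stats.total += 1
        tag = aln.read.tag
        stats.input_by_tag[tag] = stats.input_by_tag.get(tag, 0) + 1
        if not aln.is_mapped or aln.mapq < params.mapq_min:
            stats.rejected_mapq += 1
            continue
        if not deamination_pass(aln, genome, params):
            stats.rejected_deamination += 1
            continue
        if params.use_depurination and not depurination_pass(aln, genome):
            stats.rejected_depurination += 1
            continue
        if not length_pass(aln, params.length_bounds):
            stats.rejected_length += 1
            continue
        retained.append(aln)
        stats.retained += 1
        stats.retained_by_tag[tag] = stats.retained_by_tag.get(tag, 0) + 1
    stats.wall_seconds = time.perf_counter() - t0
    return retained, stats
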