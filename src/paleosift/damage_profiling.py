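"""Terminal misincorporation frequencies and fragment-length distributions.

Post-mortem cytosine deamination leaves an excess of C→T substitutions at
the 5′ ends of ancient DNA fragments and, for double-stranded library
protocols, a mirrored G→A excess at 3′ ends (single-stranded protocols show
C→T at both ends).  This module measures those per-position frequencies from
aligned reads plus the reference — the same counting that mapDamage-style
profilers perform — together with the fragment-length histogram.  The two
results jointly parameterise the read simulator.

Frequencies are conditional on the reference base: ``p5[d]`` is the fraction
of aligned positions at distance ``d`` (1-based) from the molecule's 5′ end
where the reference has C and the read has T, among positions where the
reference has C.  Reverse-strand alignments are rotated into molecule
orientation first, so profiles are strand-invariant.  Mismatches are always
recomputed against the reference FASTA, never taken from MD tags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from paleosift.io_bridge import (
    COMPLEMENT,
    AlignmentRecord,
    Genome,
    Strand,
    TaggedRead,
)

__all__ = [
    "DamageProfile",
    "LengthDistribution",
    "length_distribution",
    "misincorporation_table",
    "read_profile",
    "write_profile",
]

#: Positions tracked per fragment end (mapDamage's plotting window).
DEFAULT_WINDOW = 25

DOUBLE_STRAND = "double_strand"
SINGLE_STRAND = "single_strand"


@dataclass
class LengthDistribution:
    """Exact histogram of fragment lengths (bp → count)."""

    counts: dict[int, int]

    def __post_init__(self) -> None:
        if not self.counts or not any(c > 0 for c in self.counts.values()):
            raise ValueError("length distribution needs at least one positive count")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative length count")

    @property
    def probabilities(self) -> dict[int, float]:
        total = sum(self.counts.values())
        return {l: c / total for l, c in sorted(self.counts.items()) if c > 0}

    @property
    def mean(self) -> float:
        total = sum(self.counts.values())
        return sum(l * c for l, c in self.counts.items()) / total

    @property
    def median(self) -> float:
        lengths = np.repeat(
            list(self.counts.keys()), list(self.counts.values())
        )
        return float(np.median(lengths))


@dataclass
class DamageProfile:
    """Positional terminal misincorporation probabilities + length distribution.

    ``p5[d-1]`` is the substitution probability at distance ``d`` from the 5′
    end, ``p3[d-1]`` from the 3′ end, for ``d = 1..window``.  Which
    substitution each vector describes depends on ``protocol``:
    double-strand libraries show C→T at 5′ and G→A at 3′; single-strand
    libraries show C→T at both ends.  ``length_dist`` maps fragment length
    (bp) to probability and may be empty when only the misincorporation side
    has been measured.  ``opportunities5``/``opportunities3`` optionally hold
    the per-position denominators from measurement (zero denominator means
    the frequency was reported as 0 by convention).
    """

    p5: np.ndarray
    p3: np.ndarray
    protocol: str = DOUBLE_STRAND
    length_dist: dict[int, float] = field(default_factory=dict)
    opportunities5: np.ndarray | None = None
    opportunities3: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.p5 = np.asarray(self.p5, dtype=float)
        self.p3 = np.asarray(self.p3, dtype=float)
        if self.p5.ndim != 1 or self.p3.ndim != 1:
            raise ValueError("p5/p3 must be 1-D probability vectors")
        if len(self.p5) != len(self.p3) or len(self.p5) < 1:
            raise ValueError("p5 and p3 must have the same length W >= 1")
        for name, vec in (("p5", self.p5), ("p3", self.p3)):
            if np.any((vec < 0) | (vec > 1)):
                raise ValueError(f"{name}: probability out of range [0, 1]")
        if self.protocol not in (DOUBLE_STRAND, SINGLE_STRAND):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.length_dist:
            total = sum(self.length_dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"length_dist sums to {total}, not 1")
            if any(p < 0 for p in self.length_dist.values()):
                raise ValueError("length_dist: probability out of range [0, 1]")

    @property
    def window(self) -> int:
        return len(self.p5)

    def substitutions(self) -> tuple[str, str]:
        """(5′ substitution, 3′ substitution) labels, e.g. ('C>T', 'G>A')."""
        if self.protocol == DOUBLE_STRAND:
            return "C>T", "G>A"
        return "C>T", "C>T"


def length_distribution(
    items: Sequence[TaggedRead | AlignmentRecord],
) -> LengthDistribution:
    """Exact length histogram of reads or alignments."""
    if not items:
        raise ValueError("no reads")
    counts: dict[int, int] = {}
    for item in items:
        seq = item.read.sequence if isinstance(item, AlignmentRecord) else item.sequence
        counts[len(seq)] = counts.get(len(seq), 0) + 1
    return LengthDistribution(counts)


def misincorporation_table(
    alignments: Iterable[AlignmentRecord],
    genome: Genome,
    window: int = DEFAULT_WINDOW,
    protocol: str = DOUBLE_STRAND,
) -> DamageProfile:
    """Count terminal misincorporation frequencies from aligned reads.

    Positions are indexed by distance from the molecule's own 5′/3′ ends
    (reverse-strand alignments are complement-mapped first).  Insertions,
    deletions and soft-clips contribute no aligned pairs; N in read or
    reference is skipped.  Reads shorter than ``2 * window`` contribute a
    position to both windows independently.  A zero denominator yields
    frequency 0 (inspect ``opportunities5``/``opportunities3`` to tell the
    two cases apart).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    t5_ref, t5_alt = "C", "T"
    if protocol == DOUBLE_STRAND:
        t3_ref, t3_alt = "G", "A"
    elif protocol == SINGLE_STRAND:
        t3_ref, t3_alt = "C", "T"
    else:
        raise ValueError(f"unknown protocol {protocol!r}")

    num5 = np.zeros(window, dtype=np.int64)
    den5 = np.zeros(window, dtype=np.int64)
    num3 = np.zeros(window, dtype=np.int64)
    den3 = np.zeros(window, dtype=np.int64)

    for aln in alignments:
        if not aln.is_mapped:
            continue
        if aln.contig not in genome:
            raise KeyError(f"contig {aln.contig!r} not found in genome")
        ref = genome[aln.contig]
        seq = aln.read.sequence
        L = len(seq)
        reverse = aln.strand == Strand.reverse
        qpos = 0
        rpos = aln.start
        for op, n in aln.cigar:
            if op == "M":
                for k in range(n):
                    qb = seq[qpos + k]
                    rb = ref[rpos + k]
                    if qb == "N" or rb == "N":
                        continue
                    if reverse:
                        dist5 = L - (qpos + k)
                        dist3 = qpos + k + 1
                        qb = COMPLEMENT[qb]
                        rb = COMPLEMENT[rb]
                    else:
                        dist5 = qpos + k + 1
                        dist3 = L - (qpos + k)
                    if dist5 <= window and rb == t5_ref:
                        den5[dist5 - 1] += 1
                        if qb == t5_alt:
                            num5[dist5 - 1] += 1
                    if dist3 <= window and rb == t3_ref:
                        den3[dist3 - 1] += 1
                        if qb == t3_alt:
                            num3[dist3 - 1] += 1
                qpos += n
                rpos += n
            elif op in "IS":
                qpos += n
            elif op == "D":
                rpos += n
            else:
                raise ValueError(f"unsupported CIGAR op {op!r}")

    with np.errstate(invalid="ignore"):
        p5 = np.where(den5 > 0, num5 / np.maximum(den5, 1), 0.0)
        p3 = np.where(den3 > 0, num3 / np.maximum(den3, 1), 0.0)
    return DamageProfile(
        p5=p5,
        p3=p3,
        protocol=protocol,
        opportunities5=den5,
        opportunities3=den3,
    )


# ---------------------------------------------------------------------------
# Profile file interface
#
# A single tab-delimited text file holding both tables:
#
#   # protocol	double_strand
#   End	Pos	Sub	Freq
#   5p	1	C>T	0.2500
#   ...
#   Length	Count
#   40	123
#   ...
#
# The Length section also accepts a `Prob` column (probabilities instead of
# raw counts); mapDamage-layout extra substitution rows (e.g. C>A) are
# ignored with a warning.
# ---------------------------------------------------------------------------


def write_profile(profile: DamageProfile, path: str | Path) -> None:
    """Serialize a profile (misincorporation + length tables) to one file."""
    sub5, sub3 = profile.substitutions()
    with open(path, "w") as fh:
        fh.write(f"# protocol\t{profile.protocol}\n")
        fh.write("End\tPos\tSub\tFreq\n")
        for d in range(profile.window):
            fh.write(f"5p\t{d + 1}\t{sub5}\t{profile.p5[d]:.12g}\n")
        for d in range(profile.window):
            fh.write(f"3p\t{d + 1}\t{sub3}\t{profile.p3[d]:.12g}\n")
        if profile.length_dist:
            fh.write("Length\tProb\n")
            for length, p in sorted(profile.length_dist.items()):
                fh.write(f"{length}\t{p:.12g}\n")


def read_profile(path: str | Path) -> DamageProfile:
    """Parse a profile file written by :func:`write_profile` (or compatible).

    Malformed rows raise with the offending line number; frequencies outside
    [0, 1] are rejected; substitution rows other than the protocol's two
    expected types are ignored with a warning.
    """
    path = Path(path)
    protocol = DOUBLE_STRAND
    freqs: dict[tuple[str, int, str], float] = {}
    lengths: dict[int, float] = {}
    length_col: str | None = None
    section = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if line.startswith("#"):
                if fields[0].strip("# ") == "protocol" and len(fields) > 1:
                    protocol = fields[1].strip()
                continue
            if fields[0] == "End":
                section = "mis"
                continue
            if fields[0] == "Length":
                section = "len"
                length_col = fields[1] if len(fields) > 1 else "Count"
                continue
            if section == "mis":
                if len(fields) != 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 columns")
                end, pos_s, sub, freq_s = fields
                try:
                    pos = int(pos_s)
                    freq = float(freq_s)
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed row") from exc
                if end not in ("5p", "3p"):
                    raise ValueError(f"{path}:{lineno}: unknown end {end!r}")
                if not 0.0 <= freq <= 1.0:
                    raise ValueError(
                        f"{path}:{lineno}: probability out of range: {freq}"
                    )
                freqs[(end, pos, sub)] = freq
            elif section == "len":
                if len(fields) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns")
                try:
                    lengths[int(fields[0])] = float(fields[1])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed row") from exc
            else:
                raise ValueError(f"{path}:{lineno}: row outside any section")

    if not freqs:
        raise ValueError(f"{path}: no misincorporation rows")
    sub5 = "C>T"
    sub3 = "G>A" if protocol == DOUBLE_STRAND else "C>T"
    extra = {s for (_, _, s) in freqs} - {sub5, sub3}
    if extra:
        warnings.warn(
            f"{path}: ignoring substitution rows {sorted(extra)}", stacklevel=2
        )
    w5 = max((p for (e, p, s) in freqs if e == "5p" and s == sub5), default=0)
    w3 = max((p for (e, p, s) in freqs if e == "3p" and s == sub3), default=0)
    window = max(w5, w3)
    if window < 1:
        raise ValueError(f"{path}: no usable misincorporation rows")
    p5 = np.array([freqs.get(("5p", d, sub5), 0.0) for d in range(1, window + 1)])
    p3 = np.array([freqs.get(("3p", d, sub3), 0.0) for d in range(1, window + 1)])

    length_dist: dict[int, float] = {}
    if lengths:
        total = sum(lengths.values())
        if total <= 0:
            raise ValueError(f"{path}: length table sums to {total}")
        if length_col == "Prob" and abs(total - 1.0) > 1e-6:
            raise ValueError(f"{path}: length probabilities sum to {total}")
        length_dist = {l: v / total for l, v in lengths.items() if v > 0}

    return DamageProfile(p5=p5, p3=p3, protocol=protocol, length_dist=length_dist)
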