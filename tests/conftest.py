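"""Shared fixtures: seeded toy genomes, damage profiles, hand-built alignments."""

from __future__ import annotations

import numpy as np
import pytest

from paleosift.damage_profiling import DamageProfile
from paleosift.io_bridge import AlignmentRecord, Genome, Strand, TaggedRead, revcomp


def random_genome(seed: int, length: int = 50_000, contig: str = "chr_t") -> Genome:
    rng = np.random.default_rng(seed)
    return Genome({contig: "".join(rng.choice(list("ACGT"), size=length))})


@pytest.fixture(scope="session")
def toy_genome() -> Genome:
    return random_genome(1234)


def decaying_profile(
    window: int = 15, p1: float = 0.25, decay: float = 0.55, floor: float = 0.005
) -> DamageProfile:
    """Realistic double-strand profile: terminal rate p1 decaying inward."""
    d = np.arange(window)
    p = p1 * decay**d + floor
    lengths = np.arange(30, 71)
    w = np.exp(-0.5 * ((lengths - 50) / 9.0) ** 2)
    ld = {int(l): float(x) for l, x in zip(lengths, w / w.sum())}
    return DamageProfile(p5=p, p3=p.copy(), length_dist=ld)


@pytest.fixture(scope="session")
def damage_profile() -> DamageProfile:
    return decaying_profile()


def place_read(
    genome: Genome,
    contig: str,
    start: int,
    molecule_seq: str,
    strand: Strand,
    name: str = "endo:r0",
    mapq: int = 60,
    cigar=None,
) -> AlignmentRecord:
    """Build an alignment record from a molecule-oriented sequence."""
    sam_seq = revcomp(molecule_seq) if strand == Strand.reverse else molecule_seq
    return AlignmentRecord(
        read=TaggedRead(name, sam_seq),
        contig=contig,
        start=start,
        strand=strand,
        cigar=cigar or [("M", len(molecule_seq))],
        mapq=mapq,
    )
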