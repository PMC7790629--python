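"""Terminal-damage screening: mismatch enumeration, screens, filter invariants."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleosift.ancfil import (
    RECOMMENDED_PARAMS,
    FilterParams,
    deamination_pass,
    depurination_pass,
    filter_alignments,
    length_pass,
    terminal_mismatches,
)
from paleosift.damage_profiling import DamageProfile
from paleosift.io_bridge import (
    COMPLEMENT,
    Genome,
    ReadTag,
    Strand,
    revcomp,
)
from paleosift.simulator import SimulationConfig, simulate_dataset

from conftest import decaying_profile, place_read


def naive_verdict(aln, genome, deam_num, detect_range, mode):
    """Brute-force oracle: rebuild the read/reference pairing column by
    column, rotate to molecule orientation, then slice the terminal windows
    and count C->T / G->A columns directly."""
    ref = genome[aln.contig]
    cols = []  # one (read_base, ref_base_or_None) per physical read base
    q, r = 0, aln.start
    for op, n in aln.cigar:
        if op == "M":
            for k in range(n):
                cols.append((aln.read.sequence[q + k], ref[r + k]))
            q += n
            r += n
        elif op in "IS":
            for k in range(n):
                cols.append((aln.read.sequence[q + k], None))
            q += n
        elif op == "D":
            r += n
    if aln.strand == Strand.reverse:
        cols = [
            (COMPLEMENT[qb], COMPLEMENT[rb] if rb else None)
            for qb, rb in reversed(cols)
        ]

    def count(window_cols):
        return sum(
            1
            for qb, rb in window_cols
            if rb is not None
            and (rb, qb) in {("C", "T"), ("G", "A")}
            and "N" not in (qb, rb)
        )

    m5 = count(cols[:detect_range])
    m3 = count(cols[-detect_range:])
    if mode == "and":
        return m5 >= deam_num and m3 >= deam_num
    return m5 >= deam_num or m3 >= deam_num


class TestTerminalMismatches:
    def test_perfect_read_has_no_mismatches(self, toy_genome):
        seq = toy_genome["chr_t"][10:50]
        aln = place_read(toy_genome, "chr_t", 10, seq, Strand.forward)
        assert terminal_mismatches(aln, toy_genome) == []

    def test_forward_hand_walk(self):
        genome = Genome({"c": "AACCGGTTAACCGGTT"})
        mol = list(genome["c"][2:12])  # CCGGTTAACC, L = 10
        assert mol[2] == "G"
        mol[2] = "A"  # ref G -> read A at 0-based offset 2
        aln = place_read(genome, "c", 2, "".join(mol), Strand.forward)
        (mm,) = terminal_mismatches(aln, genome)
        assert (mm.dist5, mm.dist3) == (3, 8)
        assert (mm.ref_base, mm.read_base) == ("G", "A")

    def test_reverse_twin_yields_identical_entries(self, toy_genome):
        contig = toy_genome["chr_t"]
        start, L = 700, 45
        mol = list(revcomp(contig[start : start + L]))
        mol[0] = {"C": "T"}.get(mol[0], "G")
        mol[7] = {"G": "A"}.get(mol[7], "C")
        mol = "".join(mol)
        rev = place_read(toy_genome, "chr_t", start, mol, Strand.reverse)
        rc_genome = Genome({"chr_t": revcomp(contig)})
        fwd = place_read(
            rc_genome, "chr_t", len(contig) - start - L, mol, Strand.forward
        )
        assert terminal_mismatches(rev, toy_genome) == terminal_mismatches(
            fwd, rc_genome
        )

    def test_soft_clip_consumes_distance_without_mismatching(self):
        genome = Genome({"c": "AAAACCCCGGGGTTTT"})
        # read: 3 clipped bases + 8 aligned starting at ref 4 (CCCCGGGG)
        mol = "TTT" + "TCCCGGGG"  # aligned part has C->T at its first column
        aln = place_read(genome, "c", 4, mol, Strand.forward,
                         cigar=[("S", 3), ("M", 8)])
        (mm,) = terminal_mismatches(aln, genome)
        assert mm.dist5 == 4  # 3 clipped bases push the mismatch inward
        assert (mm.ref_base, mm.read_base) == ("C", "T")

    def test_missing_contig_fatal(self, toy_genome):
        aln = place_read(toy_genome, "chr_t", 0, toy_genome["chr_t"][:30],
                         Strand.forward)
        aln.contig = "ghost"
        with pytest.raises(KeyError):
            terminal_mismatches(aln, toy_genome)


class TestDeaminationPass:
    def _aln_with_ct(self, dists5, dists3=(), L=40):
        """A synthetic contig engineered so the read carries C->T mismatches
        exactly at the requested 5'/3' distances."""
        ref = list("A" * L)
        mol = list("A" * L)
        for d in dists5:
            ref[d - 1] = "C"
            mol[d - 1] = "T"
        for d in dists3:
            ref[L - d] = "C"
            mol[L - d] = "T"
        genome = Genome({"c": "".join(ref)})
        return place_read(genome, "c", 0, "".join(mol), Strand.forward), genome

    def test_no_mismatches_never_passes(self, toy_genome):
        seq = toy_genome["chr_t"][0:40]
        aln = place_read(toy_genome, "chr_t", 0, seq, Strand.forward)
        for mode in ("and", "or"):
            params = FilterParams(deam_num=1, detect_range=15,
                                  double_or_single=mode)
            assert deamination_pass(aln, toy_genome, params) is False

    def test_single_terminal_ct_passes_or(self):
        aln, genome = self._aln_with_ct(dists5=[4])
        assert deamination_pass(aln, genome, RECOMMENDED_PARAMS) is True

    def test_and_requires_both_windows(self):
        aln, genome = self._aln_with_ct(dists5=[2])
        and_params = FilterParams(1, 15, "and")
        assert deamination_pass(aln, genome, and_params) is False
        aln2, genome2 = self._aln_with_ct(dists5=[2], dists3=[9])
        assert deamination_pass(aln2, genome2, and_params) is True

    def test_internal_mismatch_outside_window_ignored(self):
        aln, genome = self._aln_with_ct(dists5=[20], L=40)  # dist3 = 21
        assert deamination_pass(aln, genome, RECOMMENDED_PARAMS) is False

    def test_strict_orientation_drops_ga_at_five_prime(self):
        L = 40
        ref = list("A" * L)
        mol = list("A" * L)
        ref[2] = "G"
        mol[2] = "A"  # G->A at 5' end only
        genome = Genome({"c": "".join(ref)})
        aln = place_read(genome, "c", 0, "".join(mol), Strand.forward)
        assert deamination_pass(aln, genome, RECOMMENDED_PARAMS) is True
        strict = FilterParams(1, 15, "or", strict_orientation=True)
        assert deamination_pass(aln, genome, strict) is False


class TestDepurinationPass:
    def test_forward_preceding_base(self):
        genome = Genome({"c": "GAAAATTTT"})
        aln = place_read(genome, "c", 1, "AAAATTTT", Strand.forward)
        assert depurination_pass(aln, genome) is True  # preceding base G
        genome2 = Genome({"c": "CAAAATTTT"})
        aln2 = place_read(genome2, "c", 1, "AAAATTTT", Strand.forward)
        assert depurination_pass(aln2, genome2) is False

    def test_reverse_uses_complement_past_alignment_end(self):
        # molecule 5' end maps to the right edge; ref T there complements to A
        genome = Genome({"c": "AAAAGGGGT" + "TCC"})
        mol = revcomp(genome["c"][0:9])
        aln = place_read(genome, "c", 0, mol, Strand.reverse)
        assert depurination_pass(aln, genome) is True  # ref[9] = T -> A
        genome2 = Genome({"c": "AAAAGGGGT" + "GCC"})
        aln2 = place_read(genome2, "c", 0, mol, Strand.reverse)
        assert depurination_pass(aln2, genome2) is False  # ref G -> C pyrimidine

    def test_contig_edge_fails(self):
        genome = Genome({"c": "AAAATTTT"})
        aln = place_read(genome, "c", 0, "AAAATTTT", Strand.forward)
        assert depurination_pass(aln, genome) is False
        rev = place_read(genome, "c", 0, revcomp("AAAATTTT"), Strand.reverse)
        assert depurination_pass(rev, genome) is False


@pytest.mark.parametrize(
    "bounds,length,expected",
    [(None, 85, True), ((30, 70), 58, True), ((30, 70), 85, False),
     ((30, 70), 30, True), ((30, 70), 70, True)],
)
def test_length_pass(bounds, length, expected, toy_genome):
    aln = place_read(toy_genome, "chr_t", 0, toy_genome["chr_t"][:length],
                     Strand.forward)
    assert length_pass(aln, bounds) is expected


@pytest.fixture(scope="module")
def simulated(toy_genome):
    cfg = SimulationConfig(
        n_reads=1000, cont_rate=0.5, profile=decaying_profile(),
        endo_source=toy_genome, seed=17,
    )
    return simulate_dataset(cfg)


class TestFilterAlignments:
    def test_undamaged_contamination_fully_rejected(self, simulated, toy_genome):
        cont = [a for a in simulated.truth_alignments
                if a.read.tag is ReadTag.cont]
        retained, stats = filter_alignments(cont, toy_genome, RECOMMENDED_PARAMS)
        assert retained == []
        assert stats.rejected_deamination == stats.total == len(cont)

    def test_hand_built_mixture(self):
        """3 reads with terminal C->T, 1 internal-only C->T, 2 clean:
        the recommended preset keeps exactly the 3 terminal-damaged."""
        L = 40
        ref = list("A" * 200)
        recs = []
        genome_seq = ref[:]
        # reads at offsets 0, 50, 100 with C->T at 5' distances 1, 5, 15
        for i, d in enumerate((1, 5, 15)):
            start = i * 50
            genome_seq[start + d - 1] = "C"
        genome = Genome({"c": "".join(genome_seq)})
        for i, d in enumerate((1, 5, 15)):
            start = i * 50
            mol = list(genome["c"][start : start + L])
            mol[d - 1] = "T"
            recs.append(place_read(genome, "c", start, "".join(mol),
                                   Strand.forward, name=f"endo:d{i}"))
        # internal-only C->T at distance 20 from both ends (L=40 -> dist3=21)
        internal_genome = Genome({"c": genome["c"][:150] + "C" + genome["c"][151:]})
        mol = list(internal_genome["c"][131:171])
        assert mol[19] == "C"
        mol[19] = "T"
        recs.append(place_read(internal_genome, "c", 131, "".join(mol),
                               Strand.forward, name="endo:internal"))
        # two clean reads
        for j, start in enumerate((60, 110)):
            recs.append(place_read(internal_genome, "c",
                                   start, internal_genome["c"][start : start + L],
                                   Strand.forward, name=f"cont:clean{j}"))
        # recs 0-2 were built against `genome`, the rest against
        # `internal_genome`; filter each half against its own reference
        retained_names = {
            r.read.name
            for r in filter_alignments(recs[:3], genome, RECOMMENDED_PARAMS)[0]
        } | {
            r.read.name
            for r in filter_alignments(recs[3:], internal_genome,
                                       RECOMMENDED_PARAMS)[0]
        }
        assert retained_names == {"endo:d0", "endo:d1", "endo:d2"}

    def test_mapq_gate_applied_first(self, simulated, toy_genome):
        import dataclasses

        low = simulated.truth_alignments[:10]
        lowered = [dataclasses.replace(a, mapq=10) for a in low]
        retained, stats = filter_alignments(lowered, toy_genome,
                                            RECOMMENDED_PARAMS)
        assert retained == [] and stats.rejected_mapq == 10

    def test_idempotence(self, simulated, toy_genome):
        retained, _ = filter_alignments(simulated.truth_alignments, toy_genome,
                                        RECOMMENDED_PARAMS)
        again, stats = filter_alignments(retained, toy_genome,
                                         RECOMMENDED_PARAMS)
        assert again == retained and stats.rejected == 0

    def test_and_subset_of_or(self, simulated, toy_genome):
        kept_or, _ = filter_alignments(
            simulated.truth_alignments, toy_genome, FilterParams(1, 15, "or")
        )
        kept_and, _ = filter_alignments(
            simulated.truth_alignments, toy_genome, FilterParams(1, 15, "and")
        )
        assert {a.read.name for a in kept_and} <= {a.read.name for a in kept_or}

    def test_stats_account_for_every_read(self, simulated, toy_genome):
        params = FilterParams(2, 10, "or", use_depurination=True,
                              length_bounds=(30, 70))
        retained, stats = filter_alignments(simulated.truth_alignments,
                                            toy_genome, params)
        assert stats.retained + stats.rejected == stats.total
        assert stats.retained == len(retained)


class TestOracleEquivalence:
    @pytest.mark.parametrize("deam_num,detect_range,mode",
                             [(1, 15, "or"), (2, 10, "and"), (3, 5, "or")])
    def test_verdicts_match_brute_force(self, simulated, toy_genome,
                                        deam_num, detect_range, mode):
        params = FilterParams(deam_num, detect_range, mode)
        for aln in simulated.truth_alignments:
            assert deamination_pass(aln, toy_genome, params) == naive_verdict(
                aln, toy_genome, deam_num, detect_range, mode
            ), aln.read.name


class TestAnalyticRetention:
    def test_uniform_damage_retention_matches_closed_form(self, toy_genome):
        """With constant flip probability p per terminal C (5') and G (3'),
        retention under (deam_num=1, detect_range=W, or) is
        1 - E[(1-p)^(c5+g3)] over the undamaged fragments."""
        p, W, n = 0.18, 15, 4000
        vec = np.full(W, p)
        profile = DamageProfile(p5=vec, p3=vec.copy(),
                                length_dist={40: 0.5, 60: 0.5})
        cfg = SimulationConfig(n_reads=n, cont_rate=0.0, profile=profile,
                               endo_source=toy_genome, seed=23)
        truth = simulate_dataset(cfg)
        # undamaged molecule = reference at truth coordinates
        exps = []
        for aln in truth.truth_alignments:
            ref = toy_genome[aln.contig][aln.start : aln.end]
            mol = revcomp(ref) if aln.strand is Strand.reverse else ref
            c5 = mol[:W].count("C")
            g3 = mol[-W:].count("G")
            exps.append(1 - (1 - p) ** (c5 + g3))
        expected = float(np.mean(exps))
        params = FilterParams(1, W, "or")
        retained, _ = filter_alignments(truth.truth_alignments, toy_genome,
                                        params)
        observed = len(retained) / n
        mc_se = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 4 * mc_se


@st.composite
def placed_molecule(draw):
    length = draw(st.integers(min_value=30, max_value=70))
    start = draw(st.integers(min_value=0, max_value=400))
    n_mut = draw(st.integers(min_value=0, max_value=6))
    positions = draw(
        st.lists(st.integers(min_value=0, max_value=length - 1),
                 min_size=n_mut, max_size=n_mut, unique=True)
    )
    bases = draw(st.lists(st.sampled_from("ACGT"), min_size=n_mut,
                          max_size=n_mut))
    return length, start, positions, bases


class TestStrandInvariance:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(placed_molecule())
    def test_verdicts_agree_for_both_storages(self, toy_genome, placed):
        length, start, positions, bases = placed
        contig = toy_genome["chr_t"]
        # a reverse-strand molecule with arbitrary mutations
        mol = list(revcomp(contig[start : start + length]))
        for pos, b in zip(positions, bases):
            mol[pos] = b
        mol = "".join(mol)
        rev = place_read(toy_genome, "chr_t", start, mol, Strand.reverse)
        rc_genome = Genome({"chr_t": revcomp(contig)})
        fwd = place_read(rc_genome, "chr_t", len(contig) - start - length, mol,
                         Strand.forward)
        for params in (RECOMMENDED_PARAMS, FilterParams(2, 5, "and")):
            assert deamination_pass(rev, toy_genome, params) == deamination_pass(
                fwd, rc_genome, params
            )
        assert depurination_pass(rev, toy_genome) == depurination_pass(
            fwd, rc_genome
        )
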