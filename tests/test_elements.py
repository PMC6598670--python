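import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_dna
from oracles import naive_motif_hits, naive_pqs_candidates, naive_strs

from promkit.elements import (
    canonical_unit,
    element_density,
    find_cpg_islands,
    find_pqs,
    find_strs,
    gc_profile,
    is_primitive_unit,
    pqs_candidates,
    scan_motif,
)
from promkit.seqio import Sequence, reverse_complement


class TestGcProfile:
    def test_all_g_promoters_profile_is_one(self):
        prof = gc_profile([Sequence("a", "G" * 500)])
        assert (prof["mean_gc"] == 1.0).all()

    def test_all_at_promoters_profile_is_zero(self):
        prof = gc_profile([Sequence("a", "AT" * 250)])
        assert (prof["mean_gc"] == 0.0).all()

    def test_step_profile_distal_at_proximal_gc(self):
        s = Sequence("a", "AT" * 500 + "GC" * 500)
        prof = gc_profile([s])
        # offset 0 is distal; the TSS-proximal half is pure GC
        distal = prof[prof["distance_to_tss"] > 1100]
        proximal = prof[prof["distance_to_tss"] < 900]
        assert (distal["mean_gc"] == 0.0).all()
        assert (proximal["mean_gc"] == 1.0).all()

    def test_empty_promoter_set_rejected(self):
        with pytest.raises(ValueError):
            gc_profile([])


class TestCpGIslands:
    def test_cg_repeat_is_one_island_with_oe_two(self):
        (island,) = find_cpg_islands(Sequence("x", "CG" * 300))
        assert (island.interval.start, island.interval.end) == (0, 600)
        assert island.gc_fraction == 1.0
        assert island.obs_exp == pytest.approx(2.0)

    def test_poly_a_has_no_islands(self):
        assert find_cpg_islands(Sequence("x", "A" * 2000)) == []

    def test_short_cg_block_fails_min_length(self):
        s = Sequence("x", "A" * 500 + "CG" * 75 + "A" * 500)
        assert find_cpg_islands(s) == []

    def test_reported_islands_satisfy_invariants(self, rng):
        # mixed background with embedded CG-rich blocks
        seq = (
            random_dna(rng, 400, gc=0.4)
            + "CG" * 150
            + random_dna(rng, 400, gc=0.4)
        )
        for island in find_cpg_islands(Sequence("x", seq)):
            region = seq[island.interval.start : island.interval.end]
            L = len(region)
            c, g, n_cpg = region.count("C"), region.count("G"), region.count("CG")
            assert L >= 200
            assert (c + g) / L > 0.5
            assert n_cpg * L / (c * g) > 0.6
            assert island.gc_fraction == pytest.approx((c + g) / L)
            assert island.obs_exp == pytest.approx(n_cpg * L / (c * g))


class TestStrs:
    def test_simple_dinucleotide_array(self):
        (locus,) = find_strs(Sequence("y", "TT" + "AC" * 7 + "GG"))
        assert (locus.interval.start, locus.interval.end) == (2, 16)
        assert locus.unit == "AC"
        assert locus.canonical_unit == "AC"
        assert locus.copies == 7

    def test_six_copies_not_reported(self):
        assert find_strs(Sequence("y", "TT" + "AC" * 6 + "GG")) == []

    def test_only_primitive_unit_reported(self):
        loci = find_strs(Sequence("y", "G" + "AC" * 10 + "T"))
        assert len(loci) == 1
        assert loci[0].unit == "AC"

    def test_mononucleotide_runs_never_reported(self):
        assert find_strs(Sequence("y", "A" * 50)) == []

    def test_matches_bruteforce_on_random_sequences(self, rng):
        for _ in range(20):
            seq = random_dna(rng, 500, gc=0.5)
            got = {
                (l.interval.start, l.interval.end, l.unit, l.copies)
                for l in find_strs(Sequence("r", seq), min_copies=3)
            }
            assert got == naive_strs(seq, min_copies=3)

    def test_strand_symmetry_of_canonical_units(self, rng):
        seq = "TT" + "AC" * 8 + "GG" + "GAA" * 7 + "TT"
        fwd = find_strs(Sequence("f", seq))
        rev = find_strs(Sequence("r", reverse_complement(seq)))
        assert sorted(l.canonical_unit for l in fwd) == sorted(
            l.canonical_unit for l in rev
        )
        n = len(seq)
        assert {(n - l.interval.end, n - l.interval.start) for l in rev} == {
            (l.interval.start, l.interval.end) for l in fwd
        }


class TestCanonicalUnit:
    @pytest.mark.parametrize(
        "unit,expected", [("AC", "AC"), ("TG", "AC"), ("GAA", "AAG")]
    )
    def test_known_values(self, unit, expected):
        assert canonical_unit(unit) == expected

    @settings(derandomize=True, max_examples=150)
    @given(st.text(alphabet="ACGT", min_size=2, max_size=6))
    def test_invariant_under_rotation_and_strand(self, u):
        rotated = u[1:] + u[0]
        assert canonical_unit(rotated) == canonical_unit(u)
        assert canonical_unit(reverse_complement(u)) == canonical_unit(u)

    def test_primitivity_detector(self):
        assert is_primitive_unit("AC")
        assert not is_primitive_unit("ACAC")
        assert not is_primitive_unit("AA")


class TestPqs:
    def test_telomeric_quadruplex(self):
        (hit,) = find_pqs(Sequence("z", "GGGTTAGGGTTAGGGTTAGGG"), both_strands=False)
        assert (hit.interval.start, hit.interval.end) == (0, 21)
        assert hit.g_run_length == 3
        assert hit.loop_lengths == (3, 3, 3)

    def test_poly_a_has_no_hits(self):
        assert find_pqs(Sequence("z", "A" * 100)) == []

    def test_minimal_two_g_runs(self):
        (hit,) = find_pqs(Sequence("z", "GGAGGAGGAGG"), both_strands=False)
        assert hit.g_run_length == 2
        assert hit.loop_lengths == (1, 1, 1)
        assert len(hit.interval) == 11

    def test_candidates_match_bruteforce(self, rng):
        for _ in range(10):
            seq = random_dna(rng, 300, gc=0.6)
            got = set(pqs_candidates(seq))
            assert got == naive_pqs_candidates(seq)

    def test_resolved_hits_do_not_overlap(self, rng):
        seq = random_dna(rng, 2000, gc=0.6)
        hits = find_pqs(Sequence("z", seq))
        spans = sorted((h.interval.start, h.interval.end) for h in hits)
        assert all(a2 >= b1 for (_, b1), (a2, _) in zip(spans, spans[1:]))

    def test_minus_strand_hit_on_c_rich_sequence(self):
        seq = reverse_complement("GGGTTAGGGTTAGGGTTAGGG")
        (hit,) = find_pqs(Sequence("z", seq))
        assert hit.interval.strand == "-"
        assert (hit.interval.start, hit.interval.end) == (0, 21)


class TestMotifScan:
    def test_degenerate_positions_match(self):
        hits = scan_motif(Sequence("m", "GCCACAGC"), "GCYRCAGC", both_strands=False)
        assert [(h.interval.start, h.strand) for h in hits] == [(0, "+")]

    def test_w_matches_t(self):
        hits = scan_motif(Sequence("m", "AAAATAAA"), "AAAAWAAA", both_strands=False)
        assert len(hits) == 1

    def test_empty_sequence_no_hits(self):
        assert scan_motif(Sequence("m", ""), "ACGT") == []

    def test_invalid_symbol_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            scan_motif(Sequence("m", "ACGT"), "AC9T")

    def test_matches_expansion_oracle(self, rng):
        for motif in ("GCYRCAGC", "AAAAWAAA", "CATATGS"):
            seq = random_dna(rng, 1000, gc=0.5)
            got = {(h.interval.start, h.strand) for h in scan_motif(Sequence("m", seq), motif)}
            assert got == naive_motif_hits(seq, motif)

    def test_strand_symmetry(self, rng):
        seq = random_dna(rng, 500, gc=0.5)
        motif = "GCYRCAGC"
        fwd = scan_motif(Sequence("m", seq), motif)
        rev = scan_motif(Sequence("m", reverse_complement(seq)), motif)
        n = len(seq)
        assert {(n - h.interval.end, {"+": "-", "-": "+"}[h.strand]) for h in rev} == {
            (h.interval.start, h.strand) for h in fwd
        }


class TestDensity:
    @pytest.mark.parametrize(
        "hits,n,expected",
        [
            ([[], []], 10, (0, 0.0)),
            ([[1, 2], [3]], 2, (3, 1.5)),
        ],
    )
    def test_density(self, hits, n, expected):
        assert element_density(hits, n) == expected

    def test_density_matches_survey_reporting_convention(self):
        total, per = element_density([[0] * 1556], 3310)
        assert per == pytest.approx(0.47, abs=0.005)

    def test_zero_promoters_rejected(self):
        with pytest.raises(ValueError):
            element_density([], 0)
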