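import math

import numpy as np
import pytest

from promkit.classify import (
    expressed_tissue_count,
    fold_range_check,
    ks_uniformity_pvalue,
)
from promkit.simulate import (
    PlantSpec,
    make_cpg_payload,
    make_pqs_payload,
    make_str_payload,
    simulate_divergent_pair,
    simulate_expression_matrix,
    simulate_promoter_set,
)


class TestExpressionSimulator:
    def test_zero_noise_hk_is_constant(self):
        m, _ = simulate_expression_matrix(1, 0, 0, noise_cv=0.0, seed=1)
        v = m.values.iloc[0].to_numpy()
        assert (v == v[0]).all()

    def test_ts_expressed_in_requested_tissue_count(self):
        m, _ = simulate_expression_matrix(0, 1, 0, ts_tissues=2, seed=7)
        assert expressed_tissue_count(m.values.iloc[0].to_numpy(), 1.0) == 2

    def test_seed_determinism(self):
        m1, _ = simulate_expression_matrix(5, 5, 5, seed=42)
        m2, _ = simulate_expression_matrix(5, 5, 5, seed=42)
        assert m1.values.equals(m2.values)

    def test_too_few_tissues_rejected(self):
        with pytest.raises(ValueError):
            simulate_expression_matrix(1, 0, 0, n_tissues=3)

    def test_other_transcripts_violate_exactly_their_target_criterion(self):
        m, truth = simulate_expression_matrix(0, 0, 9, noise_cv=0.1, seed=5)
        n = m.n_tissues
        for tid, mode in truth.violation_of.items():
            v = m.values.loc[tid].to_numpy()
            detected_all = expressed_tissue_count(v, 1.0) == n
            ks_ok = ks_uniformity_pvalue(v) > 0.1
            fold_ok = fold_range_check(v)
            failed = {
                "detection": not detected_all,
                "ks": not ks_ok,
                "fold": not fold_ok,
            }
            assert failed[mode], f"{tid} should violate {mode}"
            others = {k: v for k, v in failed.items() if k != mode}
            assert not any(others.values()), f"{tid} violates extra criteria {others}"


class TestPromoterSimulator:
    def test_planted_str_interval_recorded(self):
        proms, truth = simulate_promoter_set(
            1,
            plant=[PlantSpec(0, "str", 100, make_str_payload("AC", 8), "AC")],
            seed=1,
        )
        (pid, kind, iv, label) = truth.planted_elements[0]
        assert (iv.start, iv.end) == (100, 116)
        assert proms[0].residues[100:116] == "AC" * 8

    def test_zero_gc_background_is_at_only(self):
        proms, _ = simulate_promoter_set(3, length=500, gc_background=0.0, seed=2)
        assert all(set(p.residues) <= {"A", "T"} for p in proms)

    def test_planted_telomeric_pqs_recovered_verbatim(self):
        payload = "GGGTTAGGGTTAGGGTTAGGG"
        proms, truth = simulate_promoter_set(
            1, plant=[PlantSpec(0, "pqs", 500, payload)], seed=3
        )
        (_, _, iv, _) = truth.planted_elements[0]
        assert proms[0].residues[iv.start : iv.end] == payload

    def test_overlapping_plants_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            simulate_promoter_set(
                1,
                plant=[
                    PlantSpec(0, "str", 100, make_str_payload("AC", 8), "AC"),
                    PlantSpec(0, "motif", 110, "GCCACAGC"),
                ],
                seed=1,
            )

    def test_seed_determinism(self):
        a, _ = simulate_promoter_set(3, seed=9)
        b, _ = simulate_promoter_set(3, seed=9)
        assert a == b

    def test_cpg_payload_composition(self):
        block = make_cpg_payload(300)
        assert len(block) == 300
        assert set(block) == {"C", "G"}

    def test_pqs_payload_structure(self):
        assert make_pqs_payload(3, "TTA") == "GGGTTAGGGTTAGGGTTAGGG"


class TestDivergentPairs:
    def test_promoter_mode_zero_rate_identical(self):
        (a, b), _ = simulate_divergent_pair(mode="promoter", p_site=0.0, n_sites=500, seed=1)
        assert a == b

    def test_codon_mode_zero_rate_identical(self):
        (a, b), _ = simulate_divergent_pair(
            n_codons=100, omega=0.5, t_expected_subs_per_codon=0.0, seed=1
        )
        assert a == b

    def test_promoter_mode_mismatch_fraction_near_p_site(self):
        (a, b), _ = simulate_divergent_pair(
            mode="promoter", p_site=0.1, n_sites=10_000, seed=11
        )
        frac = sum(x != y for x, y in zip(a, b)) / len(a)
        assert abs(frac - 0.1) < 3 * math.sqrt(0.1 * 0.9 / 10_000)

    def test_codon_mode_has_no_stops(self):
        from promkit.evolution import STOP_CODONS

        (a, b), _ = simulate_divergent_pair(n_codons=300, omega=5.0, seed=3)
        for seq in (a, b):
            codons = {seq[i : i + 3] for i in range(0, len(seq), 3)}
            assert not (codons & STOP_CODONS)

    def test_zero_codons_rejected(self):
        with pytest.raises(ValueError):
            simulate_divergent_pair(n_codons=0, mode="codon")

    def test_seed_determinism(self):
        p1, _ = simulate_divergent_pair(n_codons=50, omega=1.0, seed=6)
        p2, _ = simulate_divergent_pair(n_codons=50, omega=1.0, seed=6)
        assert p1 == p2
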