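"""Probe scoring, window enumeration and shared-vs-specific selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitochip import probe_design, synthetic_data
from mitochip.genome_io import OrthologPair
from mitochip.probe_design import (
    CandidateWindow,
    DesignConstraints,
    align_pair,
    best_shared_window,
    centrality_penalty,
    design_probe_set,
    enumerate_windows,
    gc_fraction,
    score_window,
    select_probe,
    validate_probe_set,
)
from tests.conftest import oracle_best_window

C = DesignConstraints()


class TestGcFraction:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ATGC", 0.5), ("GGGG", 1.0), ("ATATATAT", 0.0), ("ACGTACGT", 0.5)],
    )
    def test_values(self, seq, expected):
        assert gc_fraction(seq) == expected

    def test_rejects_n(self):
        with pytest.raises(ValueError):
            gc_fraction("ACGN")


class TestCentralityPenalty:
    def test_zero_at_both_ends(self):
        assert centrality_penalty(0, 70) == 0.0
        assert centrality_penalty(69, 70) == 0.0

    def test_near_center_value(self):
        assert centrality_penalty(34, 70) == pytest.approx(
            1 - 2 * abs(34 / 69 - 0.5)
        )
        assert centrality_penalty(34, 70) == pytest.approx(0.9855, abs=1e-4)

    def test_exact_center_odd_length(self):
        assert centrality_penalty(34, 69) == 1.0

    def test_short_length_rejected(self):
        with pytest.raises(ValueError):
            centrality_penalty(0, 1)

    @given(st.integers(2, 200), st.data())
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_symmetric(self, length, data):
        pos = data.draw(st.integers(0, length - 1))
        p = centrality_penalty(pos, length)
        assert 0.0 <= p <= 1.0
        assert p == pytest.approx(centrality_penalty(length - 1 - pos, length))


def _window(seq_b, mism=(), length=None):
    length = length or len(seq_b)
    return CandidateWindow(
        gene="g", offset_a=0, offset_b=0, length=length,
        seq_a=seq_b, seq_b=seq_b, mismatch_positions=tuple(mism),
        gc_b=gc_fraction(seq_b), feasible=True,
    )


class TestScoreWindow:
    def test_perfect_window_scores_zero(self):
        w = _window("AT" * 35)  # gc 0.5? no — AT only
        w = _window(("AC" * 35))
        assert score_window(w, C) == pytest.approx(0.0)

    def test_end_mismatch_costs_nothing(self):
        w = _window("AC" * 35, mism=(0,))
        assert score_window(w, C) == pytest.approx(0.0)

    def test_composite_score(self):
        seq = "AC" * 35  # 70-mer, gc 0.5
        w = CandidateWindow(
            gene="g", offset_a=0, offset_b=0, length=70, seq_a=seq,
            seq_b=seq, mismatch_positions=(0, 34), gc_b=0.45, feasible=True,
        )
        expected = 1.0 * 0.05 + 1.0 * (0.0 + centrality_penalty(34, 70))
        assert score_window(w, C) == pytest.approx(expected)
        assert score_window(w, C) == pytest.approx(1.0355, abs=1e-3)

    def test_infeasible_window_never_scored(self):
        w = CandidateWindow(
            gene="g", offset_a=0, offset_b=0, length=70, seq_a="A" * 70,
            seq_b="A" * 70, mismatch_positions=(), gc_b=0.0, feasible=False,
            infeasible_reason="contains N",
        )
        with pytest.raises(ValueError, match="infeasible"):
            score_window(w, C)


class TestAlignPair:
    def test_identical_sequences_gapless(self):
        ga, gb = align_pair("ACGTACGT", "ACGTACGT")
        assert ga == gb == "ACGTACGT"

    def test_single_mismatch(self):
        ga, gb = align_pair("ACGT", "AGGT")
        assert ga == "ACGT" and gb == "AGGT"

    def test_planted_insertion_reproduced(self, rng):
        base = synthetic_data.random_sequence(rng, 120, 0.5)
        with_ins = base[:60] + "TTT" + base[60:]
        ga, gb = align_pair(base, with_ins)
        assert ga.count("-") == 3 and gb.count("-") == 0
        assert ga.replace("-", "") == base


class TestEnumerateWindows:
    def test_window_count_formula(self, rng):
        seq = synthetic_data.random_sequence(rng, 100, 0.5)
        windows = enumerate_windows((seq, seq), C)
        expected = sum(100 - L + 1 for L in range(68, 72))
        assert len(windows) == expected == 126
        assert all(w.feasible for w in windows)

    def test_no_window_spans_a_gap(self, rng):
        base = synthetic_data.random_sequence(rng, 150, 0.5)
        with_del = base[:75] + base[78:]
        alignment = align_pair(base, with_del)
        windows = enumerate_windows(alignment, C)
        gap_cols = [i for i, ch in enumerate(alignment[1]) if ch == "-"]
        assert gap_cols
        for w in windows:
            assert "-" not in w.seq_a and "-" not in w.seq_b

    def test_dense_mismatches_make_all_windows_infeasible(self):
        pair, _ = synthetic_data.gen_ortholog_pair(
            seed=5, length=200,
            mismatch_positions=synthetic_data._dense_mismatch_positions(200),
        )
        windows = enumerate_windows((pair.seq_a, pair.seq_b), C)
        assert windows and not any(w.feasible for w in windows)

    def test_exon_boundary_excluded(self, rng):
        seq = synthetic_data.random_sequence(rng, 200, 0.5)
        windows = enumerate_windows(
            (seq, seq), C, boundaries_a=frozenset({100}),
            boundaries_b=frozenset({100}),
        )
        for w in windows:
            if w.feasible:
                assert not (w.offset_b < 100 < w.offset_b + w.length)

    def test_n_makes_window_infeasible(self):
        seq = "AC" * 50 + "N" + "AC" * 50
        windows = enumerate_windows((seq, seq), C)
        for w in windows:
            if "N" in w.seq_b:
                assert not w.feasible


def _pair(seq_a, seq_b, **kw):
    return OrthologPair(gene="g", seq_a=seq_a, seq_b=seq_b,
                        category="protein", **kw)


class TestSelectProbe:
    def test_identical_orthologs_yield_shared_probe(self, rng):
        seq = synthetic_data.random_sequence(rng, 200, 0.5)
        probes, decision = select_probe(_pair(seq, seq))
        assert len(probes) == 1 and probes[0].scope == "shared"
        assert probes[0].mismatches_vs_other_species == 0
        assert probes[0].sequence in seq
        assert decision.decision == "shared"

    def test_divergent_orthologs_yield_two_specific_probes(self):
        pair, _ = synthetic_data.gen_ortholog_pair(
            seed=6, length=250,
            mismatch_positions=synthetic_data._dense_mismatch_positions(250),
        )
        probes, decision = select_probe(pair)
        assert sorted(p.scope for p in probes) == ["specific_A", "specific_B"]
        assert decision.decision == "specific_both"

    def test_short_gene_in_one_species_gives_single_specific_probe(self, rng):
        seq_b = synthetic_data.random_sequence(rng, 150, 0.5)
        probes, decision = select_probe(_pair("ACGT" * 10, seq_b))
        assert len(probes) == 1
        assert probes[0].scope == "specific_B"

    def test_matches_exhaustive_optimum_on_seeded_pair(self):
        pair, _ = synthetic_data.gen_ortholog_pair(
            seed=7, length=220, n_mismatches=5
        )
        oracle = oracle_best_window(pair.seq_a, pair.seq_b, C)
        probes, _ = select_probe(pair)
        if oracle is None:
            assert all(p.scope != "shared" for p in probes)
        else:
            assert probes[0].scope == "shared"
            assert probes[0].sequence == oracle[1]
            assert probes[0].design_score == pytest.approx(oracle[0][0])


class TestDesignProbeSet:
    def test_counts_match_construction(self, genome_pair, designed_probe_set):
        *_, truth = genome_pair
        assert designed_probe_set.summary() == truth.expected_counts()

    def test_all_probe_lengths_in_range(self, designed_probe_set):
        for p in designed_probe_set.probes:
            assert C.min_len <= p.length <= C.max_len

    def test_shared_probes_within_mismatch_budget(self, designed_probe_set):
        for p in designed_probe_set.probes:
            if p.scope == "shared":
                assert p.mismatches_vs_other_species <= C.max_mismatches

    def test_trna_rrna_flagged_not_quantifiable(self, designed_probe_set, genome_pair):
        *_, truth = genome_pair
        by_gene = {p.genes[0]: p for p in designed_probe_set.probes}
        for gene, info in truth.genes.items():
            if info["category"] in ("tRNA", "rRNA"):
                assert not by_gene[gene].quantifiable
            elif gene in by_gene:
                assert by_gene[gene].quantifiable

    def test_every_gene_has_one_decision_entry(self, designed_probe_set, genome_pair):
        *_, truth = genome_pair
        report_genes = [d.gene for d in designed_probe_set.design_report]
        assert sorted(report_genes) == sorted(truth.genes)

    def test_deterministic_output(self, genome_pair):
        rec_a, rec_b, editing_b, _ = genome_pair
        ps1 = design_probe_set(rec_a, rec_b, editing_b=editing_b)
        ps2 = design_probe_set(rec_a, rec_b, editing_b=editing_b)
        assert [(p.probe_id, p.sequence) for p in ps1.probes] == [
            (p.probe_id, p.sequence) for p in ps2.probes
        ]

    def test_validate_probe_set_passes_qc(self, designed_probe_set):
        qc = validate_probe_set(designed_probe_set)
        assert qc["qc_pass"]
        assert qc["length_violations"] == []
        assert qc["mismatch_violations"] == []

    def test_loosening_mismatch_budget_is_monotone(self):
        rec_a, rec_b, editing_b, _ = synthetic_data.gen_genome_pair(
            seed=9, n_shared=4, n_divergent=2
        )
        shared_counts = []
        for budget in (0, 1, 3, 6, 12):
            c = DesignConstraints(max_mismatches=budget)
            ps = design_probe_set(rec_a, rec_b, editing_b=editing_b, c=c)
            shared_counts.append(ps.summary()["n_shared_genes"])
        assert shared_counts == sorted(shared_counts)

    def test_editing_site_changes_emitted_probe(self):
        # a gene barely longer than the probe: the chosen window must
        # cover any planted editing site
        pair, _ = synthetic_data.gen_ortholog_pair(
            seed=11, length=70, n_mismatches=0
        )
        probes_before, _ = select_probe(pair)
        c_positions = [i for i, b in enumerate(pair.seq_b) if b == "C"]
        pos = c_positions[len(c_positions) // 2]
        from mitochip.genome_io import EditingSite, apply_editing

        site = EditingSite("g", pos)
        edited = _pair(
            apply_editing(pair.seq_a, [EditingSite("g", pos)], check=False),
            apply_editing(pair.seq_b, [site]),
        )
        probes_after, _ = select_probe(edited)
        before, after = probes_before[0].sequence, probes_after[0].sequence
        diffs = [i for i, (a, b) in enumerate(zip(before, after)) if a != b]
        assert diffs == [pos]


class TestOracleEquivalence:
    def test_designer_equals_brute_force_on_random_pairs(self):
        root = np.random.default_rng(2024)
        for _ in range(60):
            length = int(root.integers(C.min_len, 301))
            n_mm = int(root.integers(0, 7))
            pair, _ = synthetic_data.gen_ortholog_pair(
                seed=int(root.integers(2**31)), length=length,
                n_mismatches=min(n_mm, length),
            )
            oracle = oracle_best_window(pair.seq_a, pair.seq_b, C)
            probes, _ = select_probe(pair)
            shared = [p for p in probes if p.scope == "shared"]
            if oracle is None:
                assert not shared
            else:
                assert len(shared) == 1
                assert shared[0].sequence == oracle[1]
                assert shared[0].design_score == pytest.approx(oracle[0][0])
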