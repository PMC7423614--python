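"""Profile construction, window scanning vs exhaustive oracle, empirical-null
threshold calibration, iterative search, classification rules, trimming."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mcukit import screen
from mcukit.alphabet import AMINO_ACIDS, encode, mutate, random_protein
from mcukit.screen import (Alignment, ScreenConfig, build_profile,
                           calibrate_threshold, classify_family,
                           scan_sequence, trim_alignment)


def make_profile(rng, length=30, n_seqs=4, divergence=0.05, fpr=1e-3,
                 seed=0, n_null=10_000):
    template = random_protein(length, rng)
    aln = Alignment.from_pairs(
        [(f"s{i}", mutate(template, divergence, rng)) for i in range(n_seqs)])
    profile = build_profile(aln)
    profile.accept_threshold = calibrate_threshold(
        profile, fpr=fpr, n_null=n_null, seed=seed)
    return template, profile


class TestBuildProfile:
    def test_large_pseudocount_drives_scores_to_zero(self):
        aln = Alignment.from_pairs([("a", "AC"), ("b", "AD")])
        profile = build_profile(aln, pseudocount_weight=1e9)
        assert np.allclose(profile.log_odds, 0.0, atol=1e-6)

    def test_single_sequence_zero_pseudocount_scores_log2_20(self):
        profile = build_profile(Alignment.from_pairs([("x", "A")]),
                                pseudocount_weight=0.0)
        assert profile.log_odds[0][0] == pytest.approx(np.log2(20))

    def test_majority_gap_column_dropped_from_match_states(self):
        rows = ["A-C"] * 4 + ["A-C"] * 2 + ["AAC"] * 4
        aln = Alignment.from_pairs([(f"s{i}", r) for i, r in enumerate(rows)])
        profile = build_profile(aln)  # middle column: 6 gaps / 4 residues
        assert profile.length == 2

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            Alignment((), ())

    def test_formula_matches_hand_computation(self):
        # column 'AAAC', w=1, uniform background
        aln = Alignment.from_pairs([(f"s{i}", c) for i, c in enumerate("AAAC")])
        profile = build_profile(aln, pseudocount_weight=1.0)
        expected_a = np.log2(((3 + 0.05) / 5) / 0.05)
        expected_c = np.log2(((1 + 0.05) / 5) / 0.05)
        assert profile.log_odds[0][AMINO_ACIDS.index("A")] == pytest.approx(expected_a)
        assert profile.log_odds[0][AMINO_ACIDS.index("C")] == pytest.approx(expected_c)


class TestScan:
    def test_consensus_in_flanks_yields_exact_hit(self):
        rng = np.random.default_rng(0)
        template, profile = make_profile(rng)
        seq = random_protein(40, rng) + profile.consensus() + random_protein(35, rng)
        hits = scan_sequence(profile, seq)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (40, 40 + profile.length)
        assert hits[0].score == pytest.approx(profile.max_score)

    def test_short_sequence_yields_no_hits(self):
        rng = np.random.default_rng(1)
        _, profile = make_profile(rng)
        assert scan_sequence(profile, "ACDEF") == []

    def test_greedy_matches_exhaustive_enumeration(self):
        """Greedy best-first selection vs a brute-force reimplementation."""
        rng = np.random.default_rng(2)
        template, profile = make_profile(rng, length=12)
        profile.accept_threshold = -20.0  # permissive: force overlaps
        for rep in range(20):
            seq = random_protein(100, rng)
            if rep % 3 == 0:
                insert = mutate(template, 0.2, rng)
                pos = int(rng.integers(0, 100 - len(insert)))
                seq = seq[:pos] + insert + seq[pos + len(insert):]
            idx = encode(seq)
            scores = [(sum(profile.log_odds[c][idx[s + c]]
                           for c in range(profile.length)), s)
                      for s in range(len(seq) - profile.length + 1)]
            chosen = []
            for sc, s in sorted(scores, key=lambda t: (-t[0], t[1])):
                if sc < profile.accept_threshold:
                    continue
                if all(s + profile.length <= b or e <= s for b, e in chosen):
                    chosen.append((s, s + profile.length))
            expected = sorted(chosen)
            got = [(h.start, h.end) for h in scan_sequence(profile, seq)]
            assert got == expected

    def test_decoy_hit_count_within_binomial_bounds(self):
        from scipy.stats import binom
        rng = np.random.default_rng(3)
        _, profile = make_profile(rng, fpr=1e-3, seed=42, n_null=20_000)
        n_decoys = 1000
        n_hits = sum(
            bool(scan_sequence(profile, random_protein(200, rng)))
            for _ in range(n_decoys))
        lo, hi = binom.ppf([0.005, 0.995], n_decoys, 1e-3)
        assert lo <= n_hits <= hi

    def test_planted_domain_recall_at_moderate_divergence(self):
        rng = np.random.default_rng(4)
        template, profile = make_profile(rng, fpr=1e-3, seed=7)
        found = 0
        n = 200
        for _ in range(n):
            domain = mutate(template, 0.25, rng)
            seq = random_protein(30, rng) + domain + random_protein(30, rng)
            hits = scan_sequence(profile, seq)
            # >= 50% overlap with the planted interval
            found += any(min(h.end, 30 + len(domain)) - max(h.start, 30)
                         >= len(domain) // 2 for h in hits)
        assert found / n >= 0.95


class TestCalibrateThreshold:
    def test_fpr_one_returns_null_minimum(self):
        rng = np.random.default_rng(5)
        _, profile = make_profile(rng, length=8)
        thr = calibrate_threshold(profile, fpr=1.0, n_null=500, seed=1)
        thr_tight = calibrate_threshold(profile, fpr=0.01, n_null=500, seed=1)
        assert thr <= thr_tight

    def test_threshold_monotone_in_fpr(self):
        rng = np.random.default_rng(6)
        _, profile = make_profile(rng, length=10)
        thresholds = [calibrate_threshold(profile, fpr=f, n_null=2000, seed=3)
                      for f in (0.4, 0.2, 0.1, 0.05)]
        assert thresholds == sorted(thresholds)

    def test_median_matches_brute_force_null(self):
        rng = np.random.default_rng(7)
        _, profile = make_profile(rng, length=5)
        thr = calibrate_threshold(profile, fpr=0.5, n_null=10_000,
                                  null_length=60, seed=11)
        # independent brute force with the same RNG stream
        rng2 = np.random.default_rng(11)
        bg = profile.background
        maxima = []
        for _ in range(10_000):
            idx = rng2.choice(20, size=60, p=bg)
            best = max(sum(profile.log_odds[c][idx[s + c]] for c in range(5))
                       for s in range(60 - 5 + 1))
            maxima.append(best)
        assert thr == pytest.approx(
            float(np.quantile(maxima, 0.5, method="higher")))

    def test_unstable_quantile_warns(self):
        rng = np.random.default_rng(8)
        _, profile = make_profile(rng, length=6)
        with pytest.warns(UserWarning):
            calibrate_threshold(profile, fpr=1e-3, n_null=100, seed=0)


class TestIterativeSearch:
    def test_single_iteration_equals_plain_scan(self):
        rng = np.random.default_rng(9)
        template = random_protein(25, rng)
        aln = Alignment.from_pairs(
            [(f"s{i}", mutate(template, 0.05, rng)) for i in range(4)])
        seqs = {"sp1|a": random_protein(20, rng) + mutate(template, 0.1, rng)
                        + random_protein(20, rng),
                "sp2|b": random_protein(90, rng)}
        cfg = ScreenConfig(max_iterations=1, seed=5)
        hits, profiles = screen.iterative_search(aln, seqs, cfg)
        assert len(profiles) == 1
        direct = screen.scan_proteome(profiles[0], seqs)
        assert [(h.seq_id, h.start) for h in hits] == \
               [(h.seq_id, h.start) for h in direct]
        assert all(h.iteration == 1 for h in hits)

    def test_hit_sets_nested_across_iterations(self):
        from mcukit.pipeline import second_iteration_fixture
        aln, seqs, _, _, cfg, bg = second_iteration_fixture(seed=3)
        hits1, _ = screen.iterative_search(
            aln, seqs, ScreenConfig(max_iterations=1, fpr=cfg.fpr,
                                    n_null=cfg.n_null,
                                    null_length=cfg.null_length,
                                    seed=cfg.seed), background=bg)
        hits2, _ = screen.iterative_search(aln, seqs, cfg, background=bg)
        keys1 = {(h.seq_id, h.start) for h in hits1}
        keys2 = {(h.seq_id, h.start) for h in hits2}
        assert keys1 <= keys2

    def test_divergent_homologs_found_only_in_second_iteration(self):
        """The second search pass discovers relatives the seed profile misses,
        mirroring the second-iteration discovery of chytrid EMREs."""
        from mcukit.pipeline import second_iteration_fixture
        aln, seqs, close_ids, distant_ids, cfg, bg = second_iteration_fixture(0)
        hits, _ = screen.iterative_search(aln, seqs, cfg, background=bg)
        iteration_of = {h.seq_id: h.iteration for h in hits}
        for cid in close_ids:
            assert iteration_of[cid] == 1
        for did in distant_ids:
            assert iteration_of[did] == 2
        assert not any("decoy" in h.seq_id for h in hits)

    def test_fixpoint_exits_early(self):
        rng = np.random.default_rng(10)
        template = random_protein(25, rng)
        aln = Alignment.from_pairs(
            [(f"s{i}", mutate(template, 0.05, rng)) for i in range(4)])
        seqs = {"sp1|a": random_protein(80, rng)}  # nothing to find
        cfg = ScreenConfig(max_iterations=5, seed=2)
        hits, profiles = screen.iterative_search(aln, seqs, cfg)
        assert hits == [] and len(profiles) == 1


class TestClassifyFamily:
    def _hit(self, sid, score, pid):
        return screen.DomainHit(sid, 0, 10, score, pid)

    def test_mcu_domain_implies_mcu(self):
        out = classify_family({"MCU-domain": [self._hit("s1", 50, "MCU-domain")]},
                              {"MCU-domain": "MCU-domain"})
        assert out["s1"].family == "MCU"

    def test_micu_candidate_with_carrier_domain_excluded_as_aralar(self):
        out = classify_family(
            {"Mito_carr": [self._hit("s2", 40, "Mito_carr")]},
            {"Mito_carr": "Mito_carr"},
            {"MICU": {"s2", "s3"}})
        assert out["s2"].family == "ARALAR_EXCLUDED"
        assert out["s3"].family == "MICU"

    def test_nclx_requires_candidate_membership(self):
        hits = {"NCLX-domain": [self._hit("s4", 30, "NCLX-domain"),
                                self._hit("s5", 30, "NCLX-domain")]}
        out = classify_family(hits, {"NCLX-domain": "NCLX-domain"},
                              {"NCLX": {"s4"}})
        assert out["s4"].family == "NCLX"
        assert out["s5"].family == "UNASSIGNED"

    def test_conflict_resolved_by_score_and_flagged(self):
        hits = {"MCU-domain": [self._hit("s6", 60, "MCU-domain")],
                "DDDD": [self._hit("s6", 20, "DDDD")]}
        out = classify_family(hits, {"MCU-domain": "MCU-domain",
                                     "DDDD": "DDDD"})
        assert out["s6"].family == "MCU"
        assert any("AMBIGUOUS" in t for t in out["s6"].rule_trace)

    def test_no_hits_unassigned_with_empty_trace(self):
        out = classify_family({}, {}, all_sequences={"s7"})
        assert out["s7"].family == "UNASSIGNED"
        assert out["s7"].rule_trace == ()


class TestTrimAlignment:
    def test_all_gap_column_removed(self):
        aln = Alignment.from_pairs([("a", "A-C"), ("b", "A-C")])
        trimmed, kept = trim_alignment(aln)
        assert trimmed.rows == ("AC", "AC") and kept == [0, 2]

    def test_gapless_alignment_unchanged(self):
        aln = Alignment.from_pairs([("a", "ACD"), ("b", "ACD")])
        trimmed, kept = trim_alignment(aln)
        assert trimmed.rows == aln.rows and kept == [0, 1, 2]

    def test_boundary_99_of_100_gaps_kept(self):
        """Gap fraction exactly at the cutoff is kept (strictly-greater rule),
        cross-checked by brute-force recount."""
        rows_99 = ["-" + "A"] * 99 + ["AA"]          # col0: 99/100 gaps
        rows_100 = ["-" + "A"] * 100                 # col0: 100/100 gaps
        aln99 = Alignment.from_pairs([(f"s{i}", r) for i, r in enumerate(rows_99)])
        aln100 = Alignment.from_pairs([(f"s{i}", r) for i, r in enumerate(rows_100)])
        t99, kept99 = trim_alignment(aln99, 0.99)
        t100, kept100 = trim_alignment(aln100, 0.99)
        # brute-force recount
        frac0 = sum(r[0] == "-" for r in rows_99) / 100
        assert frac0 == 0.99 and not frac0 > 0.99
        assert kept99 == [0, 1]
        assert kept100 == [1]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.text(alphabet="ACD-", min_size=8, max_size=8),
                    min_size=2, max_size=10))
    def test_idempotent(self, rows):
        aln = Alignment.from_pairs([(f"s{i}", r) for i, r in enumerate(rows)])
        once, _ = trim_alignment(aln)
        twice, _ = trim_alignment(once)
        assert once.rows == twice.rows
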