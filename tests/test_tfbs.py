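"""PWM scanning, matched controls, and motif gain/loss statistics."""

import numpy as np
import pytest

from dremap.tfbs import (Pwm, SnpContext, gc_content, motif_change_stats,
                         reverse_complement, sample_background_positions,
                         sample_matched_controls, scan_sequence,
                         tfbs_enrichment)

from oracles import rescan_all_windows


def strong_pwm(consensus="ACGTACGT", motif_id="m0", p_major=0.9):
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    probs = np.full((len(consensus), 4), (1 - p_major) / 3)
    for i, b in enumerate(consensus):
        probs[i, idx[b]] = p_major
    return Pwm(motif_id, probs)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestPwm:
    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError):
            Pwm("bad", np.full((6, 4), 0.3))

    def test_minimum_width(self):
        with pytest.raises(ValueError):
            Pwm("short", np.full((3, 4), 0.25))

    def test_consensus_string(self):
        assert strong_pwm("ACGTAACC").consensus == "ACGTAACC"

    def test_score_distribution_is_probability(self):
        pwm = strong_pwm()
        pmf = pwm.score_distribution()
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
        assert (pmf >= 0).all()


class TestScan:
    def test_planted_consensus_found_at_offset(self, rng):
        pwm = strong_pwm("ACGTTGCA")
        seq = random_seq(rng, 300)
        planted = seq[:137] + pwm.consensus + seq[137 + 8:]
        hits = scan_sequence(pwm, planted)
        assert any(h.offset == 137 and h.strand == "+" for h in hits)

    def test_short_sequence_empty(self):
        assert scan_sequence(strong_pwm(), "ACGT") == []

    def test_windows_with_n_skipped(self):
        pwm = strong_pwm("ACGTTGCA")
        seq = "ACGTTGCA".replace("T", "N", 1)
        assert scan_sequence(pwm, seq) == []

    def test_reverse_complement_symmetry(self, rng):
        pwm = strong_pwm("ACGTTGCA")
        seq = random_seq(rng, 400)
        seq = seq[:50] + pwm.consensus + seq[58:200] + \
            reverse_complement(pwm.consensus) + seq[208:]
        fwd = {(h.offset, h.strand) for h in scan_sequence(pwm, seq)}
        rc = {(h.offset, h.strand) for h in scan_sequence(pwm, reverse_complement(seq))}
        L, w = len(seq), pwm.width
        mirrored = {(L - w - off, "+-"["+-".index(s) ^ 1]) for off, s in rc}
        assert fwd == mirrored

    @pytest.mark.parametrize("seed", range(4))
    def test_exhaustive_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pwm = strong_pwm("ACGTTGCA" if seed % 2 else "TTGACGGAC", p_major=0.85)
        seq = random_seq(rng, 1000)
        # plant a few sites so the hit set is nonempty
        for off in (100, 450, 800):
            seq = seq[:off] + pwm.consensus + seq[off + pwm.width:]
        got = {(h.offset, h.strand) for h in scan_sequence(pwm, seq)}
        assert got == rescan_all_windows(pwm, seq)


class TestMatchedControls:
    def test_tolerance_saturation_accepts_everything(self, rng):
        genome = {"chr1": random_seq(rng, 20_000)}
        controls = sample_matched_controls(genome["chr1"][100:400], 0.0, genome,
                                           {}, n=10, gc_tol=1.0, repeat_tol=1.0,
                                           seed=5)
        assert len(controls) == 10

    def test_length_matches_region(self, rng):
        genome = {"chr1": random_seq(rng, 20_000)}
        region = genome["chr1"][100:397]
        controls = sample_matched_controls(region, 0.0, genome, {}, n=5,
                                           gc_tol=1.0, repeat_tol=1.0, seed=5)
        assert all(len(c) == len(region) for c in controls)

    def test_accepted_controls_satisfy_tolerances(self, rng):
        genome = {"chr1": random_seq(rng, 50_000)}
        region = genome["chr1"][1000:1500]
        controls = sample_matched_controls(region, 0.0, genome, {}, n=8,
                                           gc_tol=0.05, repeat_tol=1.0, seed=5)
        target = gc_content(region)
        for c in controls:
            assert abs(gc_content(c) - target) <= 0.05

    def test_budget_exhaustion_warns(self, rng):
        genome = {"chr1": random_seq(rng, 5_000)}
        region = "G" * 200  # GC=1 unattainable in random sequence
        with pytest.warns(UserWarning, match="budget"):
            controls = sample_matched_controls(region, 0.0, genome, {}, n=5,
                                               gc_tol=0.01, repeat_tol=1.0,
                                               seed=5, max_attempts=50)
        assert len(controls) < 5


class TestEnrichment:
    def test_identical_sets_unity(self, rng):
        pwm = strong_pwm("ACGTTGCA")
        seqs = [random_seq(rng, 500) for _ in range(4)]
        seqs = [s[:60] + pwm.consensus + s[68:] for s in seqs]
        table = tfbs_enrichment(seqs, list(seqs), [pwm])
        assert table["density_ratio"].iloc[0] == pytest.approx(1.0)

    def test_motif_only_in_regions_sentinel(self, rng):
        pwm = strong_pwm("ACGTTGCA")
        regions = [random_seq(rng, 300)[:50] + pwm.consensus + random_seq(rng, 242)
                   for _ in range(3)]
        controls = ["AC" * 150 for _ in range(3)]
        table = tfbs_enrichment(regions, controls, [pwm])
        row = table.iloc[0]
        assert row["region_hits"] > 0
        assert np.isinf(row["density_ratio"])


class TestBackgroundPositions:
    def ctx(self, seq, offset, wt, mu):
        return SnpContext("s", seq, offset, wt, mu)

    def test_wt_mismatch_rejected(self):
        with pytest.raises(ValueError, match="WT allele"):
            self.ctx("ACGT" * 10, 0, "C", "G")

    def test_all_candidates_when_fewer_than_n(self):
        seq = "ATTTTTTTGA"  # A at offsets 0 and 9 only
        bg = sample_background_positions(self.ctx(seq, 0, "A", "G"), n=30, seed=0)
        assert [b.offset for b in bg] == [9]

    def test_no_candidates_flagged_empty(self):
        seq = "GTTTTTTTTC"
        bg = sample_background_positions(self.ctx(seq, 0, "G", "A"), n=5, seed=0)
        assert bg == []

    def test_sampled_positions_carry_wt_base(self, rng):
        seq = random_seq(rng, 500)
        offset = seq.index("A", 100)
        bg = sample_background_positions(self.ctx(seq, offset, "A", "T"),
                                         n=30, seed=3)
        assert 0 < len(bg) <= 30
        assert all(b.sequence[b.offset] == "A" for b in bg)
        assert offset not in {b.offset for b in bg}


class TestChangeStats:
    def brute_force_counts(self, contexts, pwm):
        """Full-sequence rescoring diff oracle: scan entire WT and MU
        sequences, keep hits overlapping the substituted base, diff."""
        n_wt = n_wt_not_mu = n_mu = n_mu_not_wt = 0
        for ctx in contexts:
            wt_hits = {(h.offset, h.strand)
                       for h in scan_sequence(pwm, ctx.sequence)
                       if h.offset <= ctx.offset < h.offset + pwm.width}
            mu_hits = {(h.offset, h.strand)
                       for h in scan_sequence(pwm, ctx.mutant_sequence())
                       if h.offset <= ctx.offset < h.offset + pwm.width}
            n_wt += len(wt_hits)
            n_wt_not_mu += len(wt_hits - mu_hits)
            n_mu += len(mu_hits)
            n_mu_not_wt += len(mu_hits - wt_hits)
        return n_wt, n_wt_not_mu, n_mu, n_mu_not_wt

    def make_contexts(self, rng, pwms, n=20):
        contexts = []
        for i in range(n):
            seq = random_seq(rng, 400)
            pwm = pwms[i % len(pwms)]
            off = 50 + 13 * i
            seq = seq[:off] + pwm.consensus + seq[off + pwm.width:]
            snp_off = off + pwm.width // 2
            wt = seq[snp_off]
            mu = "ACGT"[("ACGT".index(wt) + 1 + int(rng.integers(0, 3))) % 4]
            contexts.append(SnpContext(f"snp{i}", seq, snp_off, wt, mu))
        return contexts

    def test_mu_equals_wt_zero_fractions(self, rng):
        pwm = strong_pwm("ACGTTGCA")
        contexts = [SnpContext(c.snp_id, c.sequence, c.offset,
                               c.wt_allele, c.wt_allele)
                    for c in self.make_contexts(rng, [pwm], n=6)]
        for direction in ("lost", "gained"):
            for st in motif_change_stats(contexts, [pwm], direction, contexts):
                assert st.fraction == 0.0 and st.n_changed == 0

    def test_planted_destroy_full_loss(self, rng):
        pwm = strong_pwm("ACGTTGCA")
        contexts = []
        for i in range(5):
            seq = random_seq(rng, 200)
            seq = seq[:40] + pwm.consensus + seq[48:]
            snp_off = 44  # middle of the planted site
            wt = seq[snp_off]
            probs = pwm.probs[4]
            mu = "ACGT"[int(np.argmin(probs))]
            contexts.append(SnpContext(f"d{i}", seq, snp_off, wt, mu))
        stats = motif_change_stats(contexts, [pwm], "lost", [])
        assert stats[0].fraction == 1.0
        assert stats[0].n_ref >= 5

    def test_brute_force_diff_oracle_20_snps_5_pwms(self, rng):
        pwms = [strong_pwm(cons, motif_id=f"m{i}", p_major=0.88)
                for i, cons in enumerate(
                    ["ACGTTGCA", "TTGACGG", "GATACCAT", "CCGTATG", "TGCATGCA"])]
        contexts = self.make_contexts(rng, pwms, n=20)
        for pwm in pwms:
            expected = self.brute_force_counts(contexts, pwm)
            stats_lost = motif_change_stats(contexts, [pwm], "lost", contexts)
            stats_gained = motif_change_stats(contexts, [pwm], "gained", contexts)
            n_wt, n_wt_not_mu, n_mu, n_mu_not_wt = expected
            if n_wt:
                assert (stats_lost[0].n_ref, stats_lost[0].n_changed) == (n_wt, n_wt_not_mu)
            else:
                assert stats_lost == []
            if n_mu:
                assert (stats_gained[0].n_ref, stats_gained[0].n_changed) == (n_mu, n_mu_not_wt)
            else:
                assert stats_gained == []

    def test_lost_gained_antisymmetry_under_allele_swap(self, rng):
        pwm = strong_pwm("ACGTTGCA")
        contexts = self.make_contexts(rng, [pwm], n=10)
        swapped = [SnpContext(c.snp_id, c.mutant_sequence(), c.offset,
                              c.mu_allele, c.wt_allele) for c in contexts]
        lost = motif_change_stats(contexts, [pwm], "lost", contexts)
        gained_swapped = motif_change_stats(swapped, [pwm], "gained", swapped)
        if lost and gained_swapped:
            assert lost[0].n_ref == gained_swapped[0].n_ref
            assert lost[0].n_changed == gained_swapped[0].n_changed

    def test_invalid_direction(self):
        with pytest.raises(ValueError):
            motif_change_stats([], [], "sideways", [])
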