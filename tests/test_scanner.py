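import math

import numpy as np
import pytest

from oracles import brute_background, brute_cluster_merge, brute_subset_probs, brute_ti
from tiscan import (
    InputError,
    ModelMismatchError,
    MotifAlignment,
    MotifProbabilityModel,
    ScoredWindow,
    TrainedDetector,
    UnscorableSiteError,
    compute_mti,
    count_background,
    estimate_subset_probs,
    generate_background_sequence,
    marginal_prob,
    merge_hits,
    scan,
    split_training,
    ti_score,
    train_detector,
    uniform_background,
)
from tiscan.background_model import BackgroundModel
from conftest import random_alignment


def _toy_detector(rng, L=6, r=2, N=10, ref_len=4000, pseudocount=0.0):
    al = random_alignment(rng, N=N, L=L)
    ref = generate_background_sequence(ref_len, 0.45, rng)
    bg = count_background([ref], L=L, r=r)
    det, _ = train_detector(al, bg, r=r, pseudocount=pseudocount)
    return al, bg, det


class TestTiScore:
    def test_motif_equal_to_background_scores_zero(self):
        """When p~ and q coincide the log-ratio vanishes termwise."""
        L, r = 6, 2
        bg = uniform_background(L, r)
        import itertools

        tables = {
            s: np.full(16, 1 / 16)
            for s in itertools.combinations(range(1, L + 1), r)
        }
        motif = MotifProbabilityModel("flat", L, r, 0, 0.0, tables)
        det = TrainedDetector(motif, bg, mti=0.0)
        for seq in ("ACGTAC", "TTTTTT", "GATTAC"):
            is1, is2, ti = ti_score(det, seq)
            assert ti == pytest.approx(0.0, abs=1e-12)
            assert is1 == pytest.approx(is2, abs=1e-12)

    def test_r1_reduces_to_pwm_log_odds(self, rng):
        """At r=1 the TI is the classic PWM log-odds sum over columns."""
        al, bg, det = _toy_detector(rng, L=5, r=1, pseudocount=0.1)
        for site in al.sites[:5]:
            expected = sum(
                math.log2(
                    marginal_prob(det.motif, j, site[j - 1]) / bg.prob(site[j - 1])
                )
                for j in range(1, 6)
            )
            _, _, ti = ti_score(det, site)
            assert ti == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("r", [1, 2, 3])
    def test_matches_brute_force(self, rng, r):
        al, bg, det = _toy_detector(rng, L=6, r=r)
        tables = brute_subset_probs(al.sites, r, 0.0)
        q, _ = brute_background([generate_background_sequence(300, 0.5, rng)], 6, r)
        bg2 = BackgroundModel(
            r=r,
            L=6,
            q=np.array(
                [q["".join(t)] for t in __import__("itertools").product("ACGT", repeat=r)]
            ),
            total_count=1,
        )
        det2 = TrainedDetector(det.motif, bg2, mti=0.0)
        for seq in al.sites[:4]:
            _, _, ti = ti_score(det2, seq)
            assert ti == pytest.approx(brute_ti(tables, q, seq, 6, r), abs=1e-9)

    def test_training_sites_always_finite(self, rng):
        al, bg, det = _toy_detector(rng)
        for site in al.sites:
            _, _, ti = ti_score(det, site)
            assert math.isfinite(ti)

    def test_unobserved_motif_tuple_rejects(self, rng):
        al = MotifAlignment("m", ("AAAA", "AAAA", "AAAA"))
        bg = uniform_background(4, 2)
        motif = estimate_subset_probs(al, 2, 0.0)
        det = TrainedDetector(motif, bg, mti=0.0)
        _, is2, ti = ti_score(det, "AAAC")
        assert ti == -math.inf and is2 == math.inf

    def test_zero_background_accepts_with_warning(self):
        al = MotifAlignment("m", ("AAAC", "AAAC"))
        bg = count_background(["A" * 50], L=4, r=1)  # q(C)=0
        motif = estimate_subset_probs(al, 1, 0.0)
        det = TrainedDetector(motif, bg, mti=0.0)
        with pytest.warns(RuntimeWarning):
            _, _, ti = ti_score(det, "AAAC")
        assert ti == math.inf

    def test_decomposition_ti_is_is1_minus_is2(self, rng):
        al, bg, det = _toy_detector(rng)
        for site in al.sites:
            is1, is2, ti = ti_score(det, site)
            assert ti == pytest.approx(is1 - is2, abs=1e-9)

    def test_window_length_and_alphabet_checks(self, rng):
        _, _, det = _toy_detector(rng)
        with pytest.raises(InputError):
            ti_score(det, "ACGT")
        with pytest.raises(InputError):
            ti_score(det, "ACGTNN")

    def test_mismatched_models_rejected(self, rng):
        al = random_alignment(rng, N=5, L=6)
        motif = estimate_subset_probs(al, 2, 0.0)
        with pytest.raises(ModelMismatchError):
            TrainedDetector(motif, uniform_background(6, 1), mti=0.0)
        with pytest.raises(ModelMismatchError):
            TrainedDetector(motif, uniform_background(8, 2), mti=0.0)


class TestMti:
    def test_single_site_mti_is_its_ti(self, rng):
        al, bg, det = _toy_detector(rng, N=1, L=5, r=1)
        _, _, ti = ti_score(det, al.sites[0])
        assert det.mti == pytest.approx(ti, abs=1e-12)

    def test_mti_is_minimum_of_training_tis(self, rng):
        al, bg, det = _toy_detector(rng, N=8)
        tis = [ti_score(det, s)[2] for s in al.sites]
        assert det.mti == pytest.approx(min(tis), abs=1e-12)

    def test_every_training_site_is_a_hit_after_training(self, rng):
        al, bg, det = _toy_detector(rng, N=8)
        for site in al.sites:
            _, _, ti = ti_score(det, site)
            assert ti >= det.mti

    def test_unscorable_training_site_raises(self):
        al = MotifAlignment("m", ("AAAC", "AAAC"))
        bg = count_background(["A" * 50], L=4, r=1)
        motif = estimate_subset_probs(al, 1, 0.0)
        with pytest.warns(RuntimeWarning):
            with pytest.raises(UnscorableSiteError):
                compute_mti(motif, bg, al.sites)


class TestSplitTraining:
    def test_quarter_of_eight_sites_keeps_two(self, fig2):
        train, held = split_training(fig2, 0.25, seed=1)
        assert train.N == 2 and len(held) == 6

    def test_same_seed_same_split(self, fig2):
        a, ha = split_training(fig2, 0.5, seed=9)
        b, hb = split_training(fig2, 0.5, seed=9)
        assert a.sites == b.sites and ha == hb

    def test_full_fraction_keeps_everything(self, fig2):
        train, held = split_training(fig2, 1.0, seed=0)
        assert train.sites == fig2.sites and held == ()


class TestScan:
    def test_window_count_both_strands(self, rng):
        _, _, det = _toy_detector(rng, L=10)
        query = generate_background_sequence(100, 0.5, rng)
        windows = scan(det, query, strands="both")
        assert len(windows) == 2 * 91
        assert sum(w.strand == "+" for w in windows) == 91

    def test_embedded_training_site_is_recovered(self, rng):
        al, bg, det = _toy_detector(rng, L=8, r=2)
        flank = generate_background_sequence(60, 0.5, rng)
        query = flank + al.sites[0] + generate_background_sequence(60, 0.5, rng)
        windows = scan(det, query, strands="forward")
        hits = {(w.start, w.end) for w in windows if w.is_hit}
        assert (60, 68) in hits

    def test_reverse_windows_score_the_reverse_complement(self, rng):
        from tiscan.sequence import reverse_complement

        al, bg, det = _toy_detector(rng, L=6)
        query = generate_background_sequence(40, 0.5, rng)
        windows = scan(det, query, strands="both")
        by_key = {(w.start, w.strand): w for w in windows}
        for start in (0, 10, 30):
            window_seq = query[start : start + 6]
            _, _, ti_rc = ti_score(det, reverse_complement(window_seq))
            assert by_key[(start, "-")].ti == pytest.approx(ti_rc, abs=1e-9)

    def test_palindromic_model_gives_mirror_spectra(self):
        """A reverse-complement-symmetric detector scores both strands of
        any window identically."""
        al = MotifAlignment("pal", ("ACGT", "AGCT", "TCGA", "AATT", "GGCC", "ACGT"))
        # alignment closed under reverse complement => symmetric r=1 tables
        bg = uniform_background(4, 1)
        motif = estimate_subset_probs(al, 1, 0.01)
        det = TrainedDetector(motif, bg, mti=0.0)
        query = "ACGTTGCATTAACGGT"
        windows = scan(det, query, strands="both")
        by_key = {(w.start, w.strand): w for w in windows}
        for s in range(len(query) - 4 + 1):
            assert by_key[(s, "+")].ti == pytest.approx(
                by_key[(s, "-")].ti, abs=1e-9
            )

    def test_ambiguous_windows_are_skipped(self, rng):
        _, _, det = _toy_detector(rng, L=6)
        query = generate_background_sequence(20, 0.5, rng) + "N" + \
            generate_background_sequence(20, 0.5, rng)
        windows = scan(det, query, strands="forward")
        assert all("N" not in query[w.start : w.end] for w in windows)

    def test_short_query_raises(self, rng):
        _, _, det = _toy_detector(rng, L=10)
        with pytest.raises(InputError):
            scan(det, "ACGTACG")


def _win(start, ti, seq="s", strand="+", L=5, hit=True):
    return ScoredWindow(seq, start, start + L, strand, 0.0, 0.0, ti, hit)


class TestMergeHits:
    def test_overlapping_hits_collapse_to_maximum(self):
        ws = [_win(0, 4.0), _win(2, 6.0), _win(4, 5.0)]
        merged = merge_hits(ws)
        assert len(merged) == 1 and merged[0].ti == 6.0 and merged[0].start == 2

    def test_non_overlapping_hits_pass_through(self):
        ws = [_win(0, 4.0), _win(10, 6.0), _win(20, 5.0)]
        assert len(merge_hits(ws)) == 3

    def test_tie_breaks_leftmost(self):
        ws = [_win(0, 6.0), _win(2, 6.0)]
        merged = merge_hits(ws)
        assert len(merged) == 1 and merged[0].start == 0

    def test_none_policy_passes_hits_through(self):
        ws = [_win(0, 4.0), _win(2, 6.0, hit=False)]
        assert merge_hits(ws, policy="none") == [ws[0]]

    def test_strands_merge_independently(self):
        ws = [_win(0, 4.0, strand="+"), _win(2, 6.0, strand="-")]
        assert len(merge_hits(ws)) == 2

    def test_randomized_overlaps_match_cluster_oracle(self, rng):
        for _ in range(20):
            ws = [
                _win(int(s), float(t), L=int(l))
                for s, t, l in zip(
                    rng.integers(0, 60, size=12),
                    rng.normal(5, 2, size=12),
                    rng.integers(3, 9, size=12),
                )
            ]
            assert merge_hits(ws) == brute_cluster_merge(ws)


class TestSelectivity:
    def test_higher_order_never_hits_more_windows(self, rng):
        """On the same data, the r=2 detector accepts no more windows than
        the r=1 detector (higher-order selectivity)."""
        al = random_alignment(rng, N=12, L=8)
        ref = generate_background_sequence(8000, 0.45, rng)
        query = generate_background_sequence(400, 0.45, rng)
        counts = {}
        for r in (1, 2):
            bg = count_background([ref], L=8, r=r)
            det, _ = train_detector(al, bg, r=r)
            counts[r] = sum(w.is_hit for w in scan(det, query))
        assert counts[2] <= counts[1]
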