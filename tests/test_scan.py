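"""Scanner correctness: brute-force oracle equality, exact p-values,
BH filtering, overlap removal, and strand symmetry."""

import itertools

import numpy as np
import pytest

from motifbag.motifs import ALPHABET, BackgroundModel, PWM, reverse_complement
from motifbag.scan import (MotifHit, ScoreDistribution, qvalue_filter,
                           remove_overlapping_hits, scan_motifs, score_pvalue)
from motifbag.synthetic import make_motif_set
from oracles import brute_force_hits, oracle_overlap_removal, random_sequences


def test_scanner_equals_brute_force_oracle(random_pwms):
    sequences = random_sequences(100, 500, seed=9)
    bg = BackgroundModel.uniform()
    hits = scan_motifs(sequences, random_pwms, bg, p_threshold=1e-4)
    got = sorted((h.seq_id, h.motif_id, h.start, h.strand, h.score) for h in hits)
    expected = sorted(brute_force_hits(sequences, random_pwms, bg, 1e-4))
    assert len(got) == len(expected)
    for g, e in zip(got, expected):
        assert g[:4] == e[:4]
        assert abs(g[4] - e[4]) < 1e-9


def test_palindrome_reported_on_both_strands():
    probs = np.full((4, 4), 0.001)
    for i, b in enumerate((0, 1, 2, 3)):
        probs[i, b] = 0.997
    pwm = PWM("acgt", probs)
    hits = scan_motifs({"s": "AAACGTAA"}, [pwm], p_threshold=0.01)
    assert {(h.start, h.strand) for h in hits} == {(2, "+"), (2, "-")}
    assert len({round(h.score, 9) for h in hits}) == 1


def test_windows_with_n_are_skipped():
    probs = np.full((4, 4), 0.001)
    for i in range(4):
        probs[i, i] = 0.997
    hits = scan_motifs({"s": "AANCGTAA"}, [PWM("m", probs)], p_threshold=0.5)
    assert all(h.start > 2 or h.end <= 2 for h in hits)


def test_motif_wider_than_sequence_yields_no_hits(random_pwms):
    assert scan_motifs({"tiny": "ACG"}, random_pwms) == []


def test_reverse_complement_symmetry(random_pwms):
    seqs = random_sequences(5, 200, seed=21)
    bg = BackgroundModel.uniform()
    fwd = scan_motifs(seqs, random_pwms, bg, p_threshold=1e-3)
    rc = scan_motifs({k: reverse_complement(v) for k, v in seqs.items()},
                     random_pwms, bg, p_threshold=1e-3)
    L = 200
    mirrored = sorted((h.seq_id, h.motif_id, L - h.end, "+-"[h.strand == "+"],
                       round(h.score, 9)) for h in rc)
    original = sorted((h.seq_id, h.motif_id, h.start, h.strand,
                       round(h.score, 9)) for h in fwd)
    assert mirrored == original


class TestScorePvalue:
    def test_minimum_score_has_pvalue_one(self, random_pwms):
        bg = BackgroundModel.uniform()
        for pwm in random_pwms[:3]:
            dist = score_pvalue(pwm.log_odds(bg), bg)
            assert dist.pvalue(float(pwm.log_odds(bg).min(axis=1).sum())) == 1.0

    def test_width2_closed_form(self):
        lo = np.array([[2.0, -1, -1, -1], [-1, 2.0, -1, -1]])
        dist = score_pvalue(lo, BackgroundModel.uniform())
        assert abs(dist.pvalue(4.0) - 1 / 16) < 1e-12

    @pytest.mark.parametrize("width", [4, 6, 8])
    def test_dp_matches_exhaustive_enumeration(self, width):
        rng = np.random.default_rng(width)
        pwm = PWM("m", rng.dirichlet(np.ones(4) * 0.8, size=width))
        bg = BackgroundModel(rng.dirichlet([5, 5, 5, 5]))
        dist = score_pvalue(pwm.log_odds(bg), bg)
        words = np.array(list(itertools.product(range(4), repeat=width)))
        ints = dist.int_matrix[np.arange(width)[None, :], words].sum(axis=1)
        weights = np.prod(bg.freqs[words], axis=1)
        for t in rng.choice(np.unique(ints), size=20, replace=True):
            exact = weights[ints >= t].sum()
            assert abs(dist.pvalue_of_int(int(t)) - exact) < 1e-9

    def test_monotone_non_increasing(self, random_pwms):
        bg = BackgroundModel.uniform()
        dist = score_pvalue(random_pwms[0].log_odds(bg), bg)
        tail = dist.tail[: dist.max_total + 1]
        assert np.all(np.diff(tail) <= 1e-15)

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(ValueError):
            score_pvalue(np.array([[np.inf, 0, 0, 0]]), BackgroundModel.uniform())


def _hit(seq, motif, start, end, score, p=0.01):
    return MotifHit(seq, motif, start, end, "+", score, p)


class TestQvalueFilter:
    def test_bh_hand_computed_example(self):
        hits = [_hit("s", "m", i * 10, i * 10 + 5, 1.0, p)
                for i, p in enumerate([0.001, 0.01, 0.04, 0.2])]
        kept = qvalue_filter(hits, q_cutoff=0.5)
        assert [round(h.q_value, 6) for h in kept] == [0.004, 0.02, round(0.16 / 3, 6), 0.2]

    def test_equal_pvalues(self):
        hits = [_hit("s", "m", i, i + 2, 1.0, 0.3) for i in range(5)]
        kept = qvalue_filter(hits)
        assert all(abs(h.q_value - 0.3) < 1e-12 for h in kept) and len(kept) == 5

    def test_single_high_p_removed(self):
        kept = qvalue_filter([_hit("s", "m", 0, 5, 1.0, 0.6)], q_cutoff=0.5)
        assert kept == []

    def test_step_up_monotone_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            m = int(rng.integers(1, 30))
            ps = rng.random(m)
            hits = [_hit("s", "m", i * 50, i * 50 + 5, 1.0, p)
                    for i, p in enumerate(ps)]
            kept = qvalue_filter(hits, q_cutoff=1.0)
            order = np.argsort(ps)
            qs = np.array([h.q_value for h in kept])[order]
            assert np.all(np.diff(qs) >= -1e-12)        # step-up monotone
            assert np.all(qs >= np.sort(ps) - 1e-12)    # q >= p
            assert np.all((qs > 0) & (qs <= 1))

    def test_empty_input(self):
        assert qvalue_filter([]) == []

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(4)
        hits = [_hit("s", "m", i * 20, i * 20 + 5, 1.0, float(p))
                for i, p in enumerate(rng.random(50))]
        sizes = [len(qvalue_filter([_hit(h.seq_id, h.motif_id, h.start, h.end,
                                         h.score, h.p_value) for h in hits], q))
                 for q in (0.1, 0.3, 0.5)]
        assert sizes == sorted(sizes)


class TestOverlapRemoval:
    def test_non_overlapping_unchanged(self):
        hits = [_hit("s", "a", 0, 5, 1.0), _hit("s", "b", 10, 15, 2.0)]
        assert remove_overlapping_hits(hits, seed=0) == hits

    def test_worked_chain_example(self):
        a = _hit("s", "a", 0, 10, 5.0)
        b = _hit("s", "b", 5, 15, 7.0)
        c = _hit("s", "c", 12, 20, 6.0)
        assert remove_overlapping_hits([a, b, c], seed=0) == [b]

    def test_tie_broken_deterministically(self):
        a = _hit("s", "a", 0, 10, 5.0)
        b = _hit("s", "b", 5, 15, 5.0)
        survivors = {remove_overlapping_hits([a, b], seed=3)[0].motif_id
                     for _ in range(5)}
        assert len(survivors) == 1

    def test_matches_oracle_on_random_configurations(self):
        rng = np.random.default_rng(7)
        for trial in range(1000):
            n = int(rng.integers(2, 12))
            hits = []
            for i in range(n):
                start = int(rng.integers(0, 60))
                width = int(rng.integers(4, 12))
                hits.append(_hit("s", f"m{i}", start, start + width,
                                 float(rng.random())))
            got = remove_overlapping_hits(list(hits), seed=trial)
            expected = oracle_overlap_removal(hits)
            assert sorted(h.motif_id for h in got) == \
                sorted(h.motif_id for h in expected)
            for h1, h2 in itertools.combinations(got, 2):
                assert h1.end <= h2.start or h2.end <= h1.start
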