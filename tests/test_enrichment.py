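"""Exact enrichment tails, controls and miRNA calling rules."""

import math

import numpy as np
import pytest
from scipy import stats

from sigmotif.enrichment import (
    MirnaCall,
    bh_qvalues,
    binomial_overlap_test,
    common_mirnas,
    hypergeom_overlap_test,
    mirna_regulates_gs,
    random_group_control,
)


def brute_binomial_tail(x, n, p0):
    """Term-wise summation of P(X >= x)."""
    return sum(math.comb(n, i) * p0**i * (1 - p0) ** (n - i)
               for i in range(x, n + 1))


def brute_hypergeom_tail(x, N, K, n):
    """Exact enumeration of P(X >= x) over all possible overlaps."""
    total = math.comb(N, n)
    return sum(math.comb(K, i) * math.comb(N - K, n - i)
               for i in range(x, min(K, n) + 1)
               if n - i <= N - K) / total


def _universe(n):
    return frozenset(f"G{i}" for i in range(n))


class TestBinomial:
    def test_worked_example(self):
        # universe 100, set 20, targets 10, overlap 5
        uni = sorted(_universe(100))
        gene_set = frozenset(uni[:20])
        targets = frozenset(uni[15:25])  # overlap 5
        res = binomial_overlap_test(targets, gene_set, frozenset(uni))
        assert res.overlap == 5
        assert res.p_value == pytest.approx(
            brute_binomial_tail(5, 10, 0.2), rel=1e-12)
        assert res.p_value == pytest.approx(0.0328, abs=5e-5)

    def test_zero_overlap_is_one(self):
        uni = sorted(_universe(50))
        res = binomial_overlap_test(frozenset(uni[:5]),
                                    frozenset(uni[40:]), frozenset(uni))
        assert res.p_value == 1.0

    def test_degenerate_full_set(self):
        uni = _universe(10)
        res = binomial_overlap_test(uni, uni, uni)
        assert res.p_value == pytest.approx(1.0)

    def test_empty_targets_give_p_one(self):
        uni = _universe(10)
        res = binomial_overlap_test(frozenset(), frozenset(list(uni)[:3]),
                                    uni)
        assert res.p_value == 1.0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            binomial_overlap_test(frozenset(), frozenset(), frozenset())

    def test_matches_enumeration_small_universes(self):
        """Exact tail vs brute-force enumeration for N <= 20."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            N = int(rng.integers(3, 21))
            uni = sorted(_universe(N))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            gene_set = frozenset(rng.choice(uni, K, replace=False))
            targets = frozenset(rng.choice(uni, n, replace=False))
            res = binomial_overlap_test(targets, gene_set, frozenset(uni))
            want = brute_binomial_tail(res.overlap, n, K / N)
            assert res.p_value == pytest.approx(want, rel=1e-12)

    def test_monotone_in_overlap(self):
        ps = [stats.binom.sf(x - 1, 30, 0.2) for x in range(31)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestHypergeometric:
    def test_worked_example(self):
        # N=10, K=5, n=4, x=3 -> 55/210
        uni = sorted(_universe(10))
        mirna = frozenset(uni[:5])
        targets = frozenset(uni[2:6])  # overlap 3
        res = hypergeom_overlap_test(targets, mirna, frozenset(uni))
        assert res.overlap == 3
        assert res.p_value == pytest.approx(55 / 210, rel=1e-12)

    def test_zero_overlap_is_one(self):
        uni = sorted(_universe(10))
        res = hypergeom_overlap_test(frozenset(uni[:3]),
                                     frozenset(uni[7:]), frozenset(uni))
        assert res.p_value == 1.0

    def test_full_mirna_set_forces_p_one(self):
        uni = _universe(12)
        res = hypergeom_overlap_test(frozenset(list(uni)[:4]), uni, uni)
        assert res.overlap == 4
        assert res.p_value == pytest.approx(1.0)

    def test_sets_restricted_to_universe(self):
        uni = _universe(10)
        outside = frozenset({"X1", "X2"}) | frozenset(list(uni)[:2])
        res = hypergeom_overlap_test(outside, outside, uni)
        assert res.n_targets == 2 and res.set_size == 2

    def test_matches_enumeration_small_universes(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            N = int(rng.integers(3, 21))
            uni = sorted(_universe(N))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            mirna = frozenset(rng.choice(uni, K, replace=False))
            targets = frozenset(rng.choice(uni, n, replace=False))
            res = hypergeom_overlap_test(targets, mirna, frozenset(uni))
            want = brute_hypergeom_tail(res.overlap, N, K, n)
            assert res.p_value == pytest.approx(want, rel=1e-12)

    def test_monotone_in_overlap(self):
        ps = [stats.hypergeom.sf(x - 1, 40, 15, 12) for x in range(13)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestRandomGroupControl:
    def test_embedded_targets_beat_replicates(self):
        uni = sorted(_universe(500))
        gene_set = frozenset(uni[:50])
        targets = frozenset(uni[:20])  # fully inside the set
        out = random_group_control(targets, gene_set, uni, n_reps=300,
                                   seed=4)
        assert out["fraction_actual_beats"] >= 0.99

    def test_random_targets_beat_about_half(self):
        rng = np.random.default_rng(8)
        uni = sorted(_universe(500))
        gene_set = frozenset(uni[:100])
        targets = frozenset(rng.choice(uni, 30, replace=False))
        out = random_group_control(targets, gene_set, uni, n_reps=1000,
                                   seed=5)
        assert 0.2 <= out["fraction_actual_beats"] <= 0.8

    def test_seed_determinism(self):
        uni = sorted(_universe(100))
        args = (frozenset(uni[:10]), frozenset(uni[5:30]), uni)
        a = random_group_control(*args, n_reps=50, seed=9)
        b = random_group_control(*args, n_reps=50, seed=9)
        assert np.array_equal(a["replicate_p"], b["replicate_p"])


class TestMirnaCalls:
    def _targets(self, uni, rng, n_motifs, overlap_frac, mirna):
        out = {}
        for i in range(n_motifs):
            inside = rng.choice(sorted(mirna),
                                int(overlap_frac * len(mirna)),
                                replace=False)
            outside = rng.choice(sorted(set(uni) - set(mirna)), 3,
                                 replace=False)
            out[f"m{i}"] = frozenset(inside) | frozenset(outside)
        return out

    def test_majority_rule_strict(self):
        uni = _universe(40)
        # craft calls directly: 4 motifs, significance for exactly half
        call = MirnaCall("mir", "GS", 4, 2, regulates=2 > 0.5 * 4)
        assert call.regulates is False
        call = MirnaCall("mir", "GS", 4, 3, regulates=3 > 0.5 * 4)
        assert call.regulates is True

    def test_single_significant_motif_regulates(self):
        rng = np.random.default_rng(3)
        uni = sorted(_universe(40))
        mirna = frozenset(uni[:20])
        targets = {"m0": frozenset(uni[:15])}  # strongly overlapping
        call = mirna_regulates_gs("GS", targets, "mir", mirna,
                                  frozenset(uni))
        assert call.n_shared_motifs_in_gs == 1
        assert call.regulates is True

    def test_no_shared_motifs_flagged_negative(self):
        call = mirna_regulates_gs("GS", {}, "mir", frozenset({"G1"}),
                                  _universe(5))
        assert call.regulates is False
        assert call.n_shared_motifs_in_gs == 0

    def test_common_requires_every_signature(self):
        def mk(name, gs, yes):
            return MirnaCall(name, gs, 1, int(yes), yes)
        calls = {
            "GS1": [mk("mirA", "GS1", True), mk("mirB", "GS1", True)],
            "GS2": [mk("mirA", "GS2", True), mk("mirB", "GS2", False)],
        }
        assert common_mirnas(calls) == ["mirA"]

    def test_common_empty_without_calls(self):
        assert common_mirnas({}) == []


def test_bh_qvalues_monotone_and_bounded():
    ps = [0.001, 0.02, 0.5, 0.04, 0.9]
    qs = bh_qvalues(ps)
    assert all(0 <= q <= 1 for q in qs)
    order = np.argsort(ps)
    sorted_q = np.array(qs)[order]
    assert all(a <= b + 1e-12 for a, b in zip(sorted_q, sorted_q[1:]))
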