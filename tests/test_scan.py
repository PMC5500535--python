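"""Segment scoring and promoter scanning against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sigmotif.io import PromoterSet
from sigmotif.pwm import PWM, decode, revcomp
from sigmotif.scan import (
    combination_targets,
    scan_gene,
    segment_score,
    target_genes,
    TargetGeneSet,
)
from sigmotif.simulate import sample_pwm


def brute_force_segment_score(matrix, segment):
    """Direct term-by-term evaluation of the max-min normalized score."""
    order = {"A": 0, "C": 1, "G": 2, "T": 3}
    num = den = 0.0
    for i, base in enumerate(segment):
        row = matrix[i]
        num += row[order[base]] - min(row)
        den += max(row) - min(row)
    return num / den


def brute_force_best_hit(matrix, promoter):
    """Exhaustive maximum over every window of both strands."""
    k = len(matrix)
    best = None
    for strand, seq in (("+", promoter), ("-", revcomp(promoter))):
        L = len(seq)
        for i in range(L - k + 1):
            seg = seq[i : i + k]
            if any(c not in "ACGT" for c in seg):
                continue
            s = brute_force_segment_score(matrix, seg)
            pos = i if strand == "+" else L - k - i
            key = (-s, pos, strand != "+")
            if best is None or key < best[0]:
                best = (key, s, pos, strand)
    return None if best is None else best[1:]


class TestSegmentScore:
    def test_max_base_everywhere_scores_one(self, sharp_pwm):
        consensus = decode(sharp_pwm.matrix.argmax(axis=1))
        assert segment_score(sharp_pwm, consensus) == pytest.approx(1.0)

    def test_min_base_everywhere_scores_zero(self, sharp_pwm):
        worst = decode(sharp_pwm.matrix.argmin(axis=1))
        assert segment_score(sharp_pwm, worst) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # uniform middle column contributes zero to both sums
        pwm = PWM(np.array([
            [0.7, 0.1, 0.1, 0.1],
            [0.25, 0.25, 0.25, 0.25],
            [0.1, 0.1, 0.4, 0.4],
            [0.7, 0.1, 0.1, 0.1],
            [0.7, 0.1, 0.1, 0.1],
            [0.7, 0.1, 0.1, 0.1],
        ]))
        # first three columns mirror the worked example: (0.6+0+0) over
        # (0.6+0+0.3); the appended consensus columns add 0.6 to both
        got = segment_score(pwm, "AACAAA")
        want = (0.6 + 0 + 0 + 3 * 0.6) / (0.6 + 0 + 0.3 + 3 * 0.6)
        assert got == pytest.approx(want, abs=1e-12)

    def test_all_uniform_pwm_rejected(self):
        pwm = PWM(np.full((8, 4), 0.25))
        with pytest.raises(ValueError, match="uniform"):
            segment_score(pwm, "ACGTACGT")

    def test_masked_segment_rejected(self, sharp_pwm):
        with pytest.raises(ValueError):
            segment_score(sharp_pwm, "ACGTacgtNN")

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_column_affine_invariance(self, seed):
        """Adding a constant to a column or rescaling it leaves the
        score unchanged (the formula is per-column affine-invariant)."""
        rng = np.random.default_rng(seed)
        mat = rng.dirichlet([0.8] * 4, size=8)
        seg = decode(rng.integers(0, 4, size=8))
        base = brute_force_segment_score(mat, seg)
        # affine transform per column, renormalized into a valid PWM
        shifted = (mat + 0.35) / (1 + 4 * 0.35)
        assert brute_force_segment_score(shifted, seg) == \
            pytest.approx(base, abs=1e-9)


class TestScanGene:
    def test_planted_consensus_found_at_position(self, sharp_pwm, rng):
        consensus = decode(sharp_pwm.matrix.argmax(axis=1))
        bg = decode(rng.integers(0, 4, size=300))
        promoter = bg[:100] + consensus + bg[100:]
        hit = scan_gene(sharp_pwm, promoter)
        assert hit.score == pytest.approx(1.0)
        assert hit.position == 100
        assert hit.strand == "+"

    def test_reverse_complement_plant(self, sharp_pwm, rng):
        consensus = decode(sharp_pwm.matrix.argmax(axis=1))
        bg = decode(rng.integers(0, 4, size=300))
        promoter = bg[:50] + revcomp(consensus) + bg[50:]
        hit = scan_gene(sharp_pwm, promoter)
        assert hit.score == pytest.approx(1.0)
        assert hit.strand == "-"
        assert hit.position == 50

    def test_fully_masked_promoter_returns_none(self, sharp_pwm):
        assert scan_gene(sharp_pwm, "acgt" * 100) is None

    def test_strand_symmetry(self, rng):
        pwm = sample_pwm(8, 1.4, rng)
        seq = decode(rng.integers(0, 4, size=500))
        a = scan_gene(pwm, seq)
        b = scan_gene(pwm, revcomp(seq))
        assert a.score == pytest.approx(b.score, abs=1e-12)

    @pytest.mark.parametrize("case", range(25))
    def test_matches_exhaustive_brute_force(self, case):
        """Seeded (PWM, 1500-mer) pairs: the vectorized scan equals the
        window-by-window maximum, bitwise on the formula terms."""
        rng = np.random.default_rng(7000 + case)
        pwm = sample_pwm(int(rng.integers(8, 13)), 1.3, rng)
        seq = decode(rng.integers(0, 4, size=1500))
        got = scan_gene(pwm, seq)
        want_score, want_pos, want_strand = brute_force_best_hit(
            pwm.matrix, seq)
        assert got.score == pytest.approx(want_score, abs=1e-12)
        assert (got.position, got.strand) == (want_pos, want_strand)


class TestTargetGenes:
    def test_strictly_above_cutoff(self, sharp_pwm, rng):
        consensus = decode(sharp_pwm.matrix.argmax(axis=1))
        bg = decode(rng.integers(0, 4, size=200))
        universe = PromoterSet("u", {
            "carrier": bg[:90] + consensus + bg[90:190],
            "plain": decode(rng.integers(0, 4, size=300)),
        }, nominal_length=400)
        targets = target_genes(sharp_pwm, universe, cutoff=0.9)
        assert "carrier" in targets.genes
        # exact-cutoff exclusion: a gene whose best score equals the
        # cutoff must not be a target
        best = scan_gene(sharp_pwm, universe.entries["plain"]).score
        t2 = target_genes(sharp_pwm, universe, cutoff=best)
        assert "plain" not in t2.genes

    def test_recovers_planted_set_with_brute_force_oracle(self, rng):
        pwm = sample_pwm(10, 1.8, rng)
        consensus = decode(pwm.matrix.argmax(axis=1))
        entries = {}
        planted = set()
        for i in range(60):
            seq = decode(rng.integers(0, 4, size=400))
            if i % 3 == 0:
                pos = int(rng.integers(0, 390))
                seq = seq[:pos] + consensus + seq[pos + 10 :]
                planted.add(f"g{i}")
            entries[f"g{i}"] = seq[:400]
        universe = PromoterSet("u", entries, nominal_length=400)
        targets = target_genes(pwm, universe, cutoff=0.9)
        oracle = {
            g for g, seq in entries.items()
            if brute_force_best_hit(pwm.matrix, seq)[0] > 0.9
        }
        assert targets.genes == frozenset(oracle)
        assert planted <= targets.genes


class TestCombinationTargets:
    def test_intersection(self):
        a = TargetGeneSet("A", frozenset({"a", "b", "c"}), 10)
        b = TargetGeneSet("B", frozenset({"b", "c", "d"}), 10)
        assert combination_targets([a, b]).genes == {"b", "c"}

    def test_empty_member_gives_empty(self):
        a = TargetGeneSet("A", frozenset({"a"}), 10)
        b = TargetGeneSet("B", frozenset(), 10)
        assert combination_targets([a, b]).genes == frozenset()

    def test_order_invariant_three_way(self):
        sets = [TargetGeneSet(n, frozenset(g), 10) for n, g in
                [("A", "abc"), ("B", "bcd"), ("C", "cde")]]
        fwd = combination_targets(sets).genes
        rev = combination_targets(sets[::-1]).genes
        assert fwd == rev == {"c"}

    def test_universe_mismatch_rejected(self):
        a = TargetGeneSet("A", frozenset({"a"}), 10)
        b = TargetGeneSet("B", frozenset({"a"}), 11)
        with pytest.raises(ValueError, match="universe"):
            combination_targets([a, b])
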