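"""De novo discovery: support rule, permutation, combinations, recovery."""

import numpy as np
import pytest
from scipy import stats as sps

from sigmotif.discovery import (
    DiscoveryParams,
    MarkovBackground,
    build_combinations,
    discover_motifs,
    permute_sequences,
    support_threshold,
)
from sigmotif.io import PromoterSet
from sigmotif.pwm import Motif, encode
from sigmotif.similarity import compare_pwms
from sigmotif.simulate import SyntheticStudySpec, generate_study


class TestSupportThreshold:
    @pytest.mark.parametrize("T,expected", [
        (100, 5),   # 5% of 100
        (10, 2),    # clamped to the floor of 2
        (41, 3),    # ceil(2.05)
        (1, 2),
        (200, 10),
    ])
    def test_formula(self, T, expected):
        assert support_threshold(T) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            support_threshold(0)


class TestPermuteSequences:
    def test_monobase_sequence_unchanged(self):
        pset = PromoterSet("x", {"g": "AAAA"}, nominal_length=10)
        assert permute_sequences(pset, 1).entries["g"] == "AAAA"

    def test_anagram_conservation(self, rng):
        seq = "".join("ACGTacgtN"[i] for i in rng.integers(0, 9, size=400))
        pset = PromoterSet("x", {"g": seq}, nominal_length=400)
        out = permute_sequences(pset, 3).entries["g"]
        assert sorted(out) == sorted(seq)
        assert out != seq  # astronomically unlikely to be unchanged

    def test_seed_determinism(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=300))
        pset = PromoterSet("x", {"g": seq}, nominal_length=300)
        assert permute_sequences(pset, 7).entries == \
            permute_sequences(pset, 7).entries


class TestMarkovBackground:
    def test_word_probabilities_sum_to_one(self, rng):
        seqs = [encode("".join("ACGT"[i]
                               for i in rng.integers(0, 4, size=500)))
                for _ in range(5)]
        bg = MarkovBackground(seqs, order=2)
        total = sum(
            bg.word_prob(np.array([a, b, c]))
            for a in range(4) for b in range(4) for c in range(4)
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_composition_reflects_input(self):
        seqs = [encode("G" * 200 + "C" * 200)]
        bg = MarkovBackground(seqs, order=2)
        q = bg.base_composition()
        assert q[1] + q[2] > 0.9  # G/C dominate


class TestBuildCombinations:
    def _motif(self, mid, genes, pwm):
        return Motif(id=mid, pwm=pwm, consensus=pwm.consensus(), support=10,
                     source_gs="GS", enrichment_p=1e-6,
                     occurrences={g: [(0, "+")] for g in genes})

    def test_perfect_cooccurrence_exact_p(self, sharp_pwm, rng):
        genes = [f"g{i}" for i in range(20)]
        pset = PromoterSet("GS", {g: "ACGT" * 10 for g in genes},
                           nominal_length=40)
        shared = genes[:10]
        a = self._motif("A", shared, sharp_pwm)
        b = self._motif("B", shared, sharp_pwm)
        combos = build_combinations([a, b], pset, DiscoveryParams())
        assert len(combos) == 1
        # exact hypergeometric point mass: C(10,10) C(10,0) / C(20,10)
        want = sps.hypergeom.pmf(10, 20, 10, 10)
        assert combos[0].cooccurrence_p == pytest.approx(want, rel=1e-9)
        assert combos[0].supporting_sequences == frozenset(shared)

    def test_disjoint_motifs_no_combination(self, sharp_pwm):
        genes = [f"g{i}" for i in range(20)]
        pset = PromoterSet("GS", {g: "ACGT" * 10 for g in genes},
                           nominal_length=40)
        a = self._motif("A", genes[:10], sharp_pwm)
        b = self._motif("B", genes[10:], sharp_pwm)
        assert build_combinations([a, b], pset, DiscoveryParams()) == []

    def test_triple_extension(self, sharp_pwm):
        genes = [f"g{i}" for i in range(20)]
        pset = PromoterSet("GS", {g: "ACGT" * 10 for g in genes},
                           nominal_length=40)
        shared = genes[:9]
        motifs = [self._motif(m, shared, sharp_pwm) for m in "ABC"]
        combos = build_combinations(motifs, pset, DiscoveryParams())
        sizes = sorted(len(c.motif_ids) for c in combos)
        assert sizes == [2, 2, 2, 3]


class TestDiscovery:
    @pytest.fixture(scope="class")
    def planted_study(self):
        spec = SyntheticStudySpec(cancer_types=(("t", 6, 40),),
                                  universe_size=300, seed=11)
        return generate_study(spec)

    def test_planted_motif_recovered_in_carrier(self, planted_study,
                                                calibration):
        truth = planted_study.truth.planted_pwms["planted_1"]
        recovered = 0
        carriers = planted_study.truth.carrier_gs["planted_1"][:2]
        for sid in carriers:
            motifs = discover_motifs(planted_study.promoters[sid],
                                     DiscoveryParams(), calibration)
            if any(compare_pwms(m.pwm, truth, calibration).e_value < 1e-8
                   for m in motifs):
                recovered += 1
        assert recovered == len(carriers)

    def test_permuted_input_yields_no_motifs(self, planted_study,
                                             calibration):
        sid = planted_study.truth.carrier_gs["planted_1"][0]
        perm = permute_sequences(planted_study.promoters[sid], 991)
        assert discover_motifs(perm, DiscoveryParams(), calibration) == []

    def test_reported_support_meets_rule(self, planted_study, calibration):
        sid = planted_study.truth.carrier_gs["planted_1"][0]
        pset = planted_study.promoters[sid]
        s = support_threshold(len(pset.entries))
        for m in discover_motifs(pset, DiscoveryParams(), calibration):
            assert m.support >= s
            assert set(m.occurrences) <= set(pset.entries)
            # support re-derives from the occurrence map
            assert m.support == len(m.occurrences)
            # consensus is regenerated from the PWM
            assert m.consensus == m.pwm.consensus()

    def test_fully_masked_input_warns_empty(self, calibration):
        pset = PromoterSet("GS", {f"g{i}": "acgt" * 50 for i in range(5)},
                           nominal_length=200)
        with pytest.warns(UserWarning, match="masked"):
            assert discover_motifs(pset, DiscoveryParams(),
                                   calibration) == []

    def test_too_few_sequences_warns_empty(self, calibration):
        pset = PromoterSet("GS", {"g": "ACGT" * 50}, nominal_length=200)
        with pytest.warns(UserWarning, match="fewer than 3"):
            assert discover_motifs(pset, DiscoveryParams(),
                                   calibration) == []
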