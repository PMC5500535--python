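"""Cross-signature grouping and the >50% shared-motif rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sigmotif.pwm import Motif, PWM
from sigmotif.shared import call_shared, group_similar, min_gs_required
from sigmotif.simulate import sample_pwm


def _motif(mid, pwm, gs):
    return Motif(id=mid, pwm=pwm, consensus=pwm.consensus(),
                 support=10, source_gs=gs, enrichment_p=1e-6)


def _noisy_copy(pwm, rng, n_sites=25):
    return PWM.from_sites([pwm.sample_site(rng) for _ in range(n_sites)])


class TestMinGsRequired:
    @pytest.mark.parametrize("n_gs,expected", [
        (2, 2), (3, 2), (4, 3), (5, 3), (6, 4), (7, 4), (10, 6),
    ])
    def test_strictly_more_than_half(self, n_gs, expected):
        assert min_gs_required(n_gs) == expected

    def test_rejects_single_signature(self):
        with pytest.raises(ValueError):
            min_gs_required(1)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(2, 60))
    def test_always_majority(self, n_gs):
        need = min_gs_required(n_gs)
        assert need > 0.5 * n_gs
        assert need - 1 <= 0.5 * n_gs


class TestGroupSimilar:
    def test_similar_pair_groups_dissimilar_apart(self, calibration):
        rng = np.random.default_rng(21)
        base = sample_pwm(10, 1.5, rng)
        a = _motif("A", _noisy_copy(base, rng), "GS1")
        b = _motif("B", _noisy_copy(base, rng), "GS2")
        c = _motif("C", sample_pwm(10, 1.5, rng), "GS3")
        groups = group_similar([a, b, c], calibration=calibration)
        members = sorted(frozenset(m.id for m in g.members) for g in groups)
        assert frozenset({"A", "B"}) in members
        assert frozenset({"C"}) in members

    def test_transitive_chain_forms_one_group(self, calibration):
        # A~B and B~C suffice even if A and C are not directly similar
        rng = np.random.default_rng(22)
        base = sample_pwm(10, 1.5, rng)
        a = _motif("A", _noisy_copy(base, rng), "GS1")
        b = _motif("B", _noisy_copy(base, rng), "GS2")
        c = _motif("C", _noisy_copy(base, rng), "GS3")
        groups = group_similar([a, b, c], calibration=calibration)
        assert len(groups) == 1
        assert groups[0].gs_ids == {"GS1", "GS2", "GS3"}

    def test_within_signature_edges_not_created(self, calibration):
        rng = np.random.default_rng(23)
        base = sample_pwm(10, 1.5, rng)
        a = _motif("A", _noisy_copy(base, rng), "GS1")
        b = _motif("B", _noisy_copy(base, rng), "GS1")  # same signature
        groups = group_similar([a, b], calibration=calibration)
        assert len(groups) == 2

    def test_input_order_invariance(self, calibration):
        rng = np.random.default_rng(24)
        base = sample_pwm(10, 1.5, rng)
        motifs = [_motif(f"M{i}", _noisy_copy(base, rng), f"GS{i}")
                  for i in range(4)]
        motifs.append(_motif("X", sample_pwm(10, 1.5, rng), "GS9"))
        g1 = group_similar(motifs, calibration=calibration)
        g2 = group_similar(motifs[::-1], calibration=calibration)
        ids1 = sorted(frozenset(m.id for m in g.members) for g in g1)
        ids2 = sorted(frozenset(m.id for m in g.members) for g in g2)
        assert ids1 == ids2


class TestCallShared:
    def _group_spanning(self, n_span, rng, base=None):
        base = base or sample_pwm(10, 1.5, rng)
        motifs = [_motif(f"M{i}", _noisy_copy(base, rng), f"GS{i}")
                  for i in range(n_span)]
        from sigmotif.shared import MotifGroup
        return MotifGroup(members=motifs), base

    def test_three_of_six_not_shared(self, calibration, rng):
        group, base = self._group_spanning(3, rng)
        db = [("K", base)]
        assert call_shared([group], 6, db, calibration=calibration) == []

    def test_four_of_six_shared(self, calibration, rng):
        group, base = self._group_spanning(4, rng)
        db = [("K", base)]
        shared = call_shared([group], 6, db, calibration=calibration)
        assert len(shared) == 1
        assert shared[0].annotated
        assert shared[0].known_match[0] == "K"

    def test_representative_is_best_known_match(self, calibration):
        rng = np.random.default_rng(31)
        base = sample_pwm(10, 1.6, rng)
        # one member is a near-exact copy of the database entry, the
        # others are noisier: the near-exact one must represent
        close = _motif("close", _noisy_copy(base, rng, n_sites=200), "GS1")
        far1 = _motif("far1", _noisy_copy(base, rng, n_sites=8), "GS2")
        far2 = _motif("far2", _noisy_copy(base, rng, n_sites=8), "GS3")
        far3 = _motif("far3", _noisy_copy(base, rng, n_sites=8), "GS4")
        from sigmotif.shared import MotifGroup
        group = MotifGroup(members=[far1, close, far2, far3])
        shared = call_shared([group], 6, [("K", base)],
                             calibration=calibration)
        assert shared[0].representative.id == "close"

    def test_unannotated_group_flagged(self, calibration):
        rng = np.random.default_rng(32)
        group, _ = self._group_spanning(4, rng)
        decoys = [(f"D{i}", sample_pwm(10, 1.3, np.random.default_rng(900 + i)))
                  for i in range(5)]
        shared = call_shared([group], 6, decoys, calibration=calibration)
        assert len(shared) == 1
        assert not shared[0].annotated
        assert shared[0].known_match is None

    def test_empty_db_falls_back_with_warning(self, calibration, rng):
        group, _ = self._group_spanning(4, rng)
        with pytest.warns(UserWarning, match="empty known-motif"):
            shared = call_shared([group], 6, [], calibration=calibration)
        assert len(shared) == 1 and not shared[0].annotated

    @settings(max_examples=30, deadline=None)
    @given(st.integers(2, 9), st.integers(1, 9))
    def test_majority_rule_property(self, n_gs, n_span):
        """Whatever the composition, every called shared motif spans
        strictly more than half of the signatures."""
        n_span = min(n_span, n_gs)
        rng = np.random.default_rng(n_gs * 100 + n_span)
        base = sample_pwm(8, 1.9, rng)
        motifs = [_motif(f"M{i}", base, f"GS{i}") for i in range(n_span)]
        from sigmotif.shared import MotifGroup
        shared = call_shared([MotifGroup(members=motifs)], n_gs,
                             [("K", base)])
        if n_span > 0.5 * n_gs:
            assert len(shared) == 1
        else:
            assert shared == []
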