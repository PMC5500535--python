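"""Cross-signature motif grouping and shared-motif calling.

Motifs discovered independently in the gene signatures of one cancer
type are joined into groups of mutually similar motifs (connected
components of the similarity graph; only edges between motifs from
*different* signatures are drawn).  A group is called a shared motif
when it contains motifs from strictly more than half of the cancer
type's signatures, and it is represented by the member whose PWM best
matches a known-motif database.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

from .pwm import Motif, PWM
from .similarity import (
    KNOWN_MATCH_E,
    NullCalibration,
    WITHIN_STUDY_E,
    compare_pwms,
)

logger = logging.getLogger(__name__)


@dataclass
class MotifGroup:
    """Mutually similar motifs from different signatures."""

    members: list[Motif]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a group needs at least one member")

    @property
    def gs_ids(self) -> frozenset[str]:
        return frozenset(m.source_gs for m in self.members)


@dataclass
class SharedMotif:
    """A motif group spanning more than half of a cancer type's GSs."""

    group: MotifGroup
    representative: Motif
    cancer_type: str
    known_match: tuple[str, float] | None  # (name, e_value) below 1e-5
    annotated: bool  # False when no known motif matched

    def __post_init__(self) -> None:
        if self.representative not in self.group.members:
            raise ValueError("representative must belong to the group")


def min_gs_required(n_gs: int) -> int:
    """Smallest signature count strictly exceeding half of ``n_gs``."""
    if n_gs < 2:
        raise ValueError(f"need at least 2 signatures, got {n_gs}")
    return math.floor(n_gs / 2) + 1


def group_similar(
    motifs: list[Motif],
    threshold: float = WITHIN_STUDY_E,
    calibration: NullCalibration | None = None,
) -> list[MotifGroup]:
    """Connected components of the cross-signature similarity graph.

    Edges join motifs from different signatures whose comparison
    E-value is strictly below the threshold; motifs from the same
    signature are never linked directly.  The result is invariant to
    the input order.
    """
    motifs = sorted(motifs, key=lambda m: m.id)
    n = len(motifs)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if motifs[i].source_gs == motifs[j].source_gs:
                continue
            try:
                e = compare_pwms(motifs[i].pwm, motifs[j].pwm,
                                 calibration).e_value
            except ValueError:  # lengths admit no alignment
                continue
            if e < threshold:
                parent[find(i)] = find(j)
    comps: dict[int, list[Motif]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(motifs[i])
    return [MotifGroup(members=sorted(ms, key=lambda m: m.id))
            for _, ms in sorted(comps.items())]


def call_shared(
    groups: list[MotifGroup],
    n_gs: int,
    known_db: list[tuple[str, PWM]],
    cancer_type: str = "",
    threshold: float = KNOWN_MATCH_E,
    calibration: NullCalibration | None = None,
) -> list[SharedMotif]:
    """Keep groups spanning > 50% of GSs; pick representatives.

    The representative is the member whose best known-motif comparison
    has the smallest E-value (members without any finite comparison
    rank last); the known match is recorded only when its E-value is
    below the known-match threshold.  With an empty database the
    representative falls back to the member most similar on average to
    its group, and the shared motif is flagged unannotated.
    """
    needed = min_gs_required(n_gs)
    shared: list[SharedMotif] = []
    for group in groups:
        if len(group.gs_ids) < needed:
            continue
        if known_db:
            best_member, best_name, best_e = None, None, float("inf")
            for m in group.members:
                hit = _best_match(m.pwm, known_db, calibration)
                if hit is not None and hit[1] < best_e:
                    best_member, best_name, best_e = m, hit[0], hit[1]
            if best_member is None:
                best_member = group.members[0]
            annotated = best_e < threshold
            shared.append(SharedMotif(
                group=group,
                representative=best_member,
                cancer_type=cancer_type,
                known_match=(best_name, best_e) if annotated else None,
                annotated=annotated,
            ))
        else:
            warnings.warn(
                "empty known-motif database: representatives chosen by "
                "within-group similarity", stacklevel=2)
            best_member, best_score = group.members[0], -float("inf")
            for m in group.members:
                sims = []
                for other in group.members:
                    if other is m:
                        continue
                    try:
                        sims.append(compare_pwms(m.pwm, other.pwm,
                                                 calibration).score)
                    except ValueError:
                        continue
                mean = sum(sims) / len(sims) if sims else -float("inf")
                if mean > best_score:
                    best_member, best_score = m, mean
            shared.append(SharedMotif(
                group=group,
                representative=best_member,
                cancer_type=cancer_type,
                known_match=None,
                annotated=False,
            ))
    return shared


def _best_match(pwm: PWM, known_db: list[tuple[str, PWM]],
                calibration: NullCalibration | None
                ) -> tuple[str, float] | None:
    """(name, e_value) of the minimum-E database entry, unthresholded."""
    best = None
    for name, known in known_db:
        try:
            e = compare_pwms(pwm, known, calibration).e_value
        except ValueError:
            continue
        if best is None or e < best[1]:
            best = (name, e)
    return best
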