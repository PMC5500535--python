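"""PWM target scanning with a max-min normalized segment score.

The score of a DNA segment s_1..s_k under a PWM M = (m_ij) is

    sum_i (m_{i, s_i} - min_j m_ij)  /  sum_i (max_j m_ij - min_j m_ij)

with nucleotides ordered A, C, G, T.  The score lies in [0, 1]: a
segment picking every column's most probable base scores 1, one picking
every least probable base scores 0.  Uniform columns contribute zero to
both sums (the formula's limit); an all-uniform PWM has no defined
score and is rejected.  A gene is a target of a motif when any window
of its promoter — on either strand — scores strictly above the cutoff
(default 0.9).  Windows containing masked or ambiguous bases are
skipped entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import PromoterSet
from .pwm import PWM, encode

DEFAULT_SCORE_CUTOFF = 0.9


@dataclass(frozen=True)
class ScanHit:
    """Best-scoring window of one promoter."""

    gene_id: str
    position: int  # 0-based window start within the promoter (forward)
    strand: str  # '+' or '-'
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0 + 1e-12:
            raise ValueError("score outside [0, 1]")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass
class TargetGeneSet:
    """Genes whose promoter contains a window above the score cutoff."""

    source_id: str
    genes: frozenset[str]
    universe_size: int

    def __post_init__(self) -> None:
        if len(self.genes) > self.universe_size:
            raise ValueError("more targets than scanned genes")


def _score_terms(pwm: PWM) -> tuple[np.ndarray, float]:
    """Per-column numerator lookup and the (positive) denominator."""
    m = pwm.matrix
    mins = m.min(axis=1, keepdims=True)
    denom = float((m.max(axis=1) - m.min(axis=1)).sum())
    if denom <= 0:
        raise ValueError("all PWM columns are uniform; score undefined")
    return m - mins, denom


def segment_score(pwm: PWM, segment: str) -> float:
    """Max-min normalized score of a single k-mer."""
    codes = encode(segment)
    if len(codes) != pwm.length:
        raise ValueError(
            f"segment length {len(codes)} != PWM length {pwm.length}")
    if (codes < 0).any():
        raise ValueError("segment contains masked or ambiguous bases")
    num_lut, denom = _score_terms(pwm)
    return float(num_lut[np.arange(pwm.length), codes].sum() / denom)


def _window_scores(codes: np.ndarray, pwm: PWM) -> np.ndarray:
    """Scores of all valid forward windows; NaN where a window is masked."""
    k = pwm.length
    L = len(codes)
    if L < k:
        return np.empty(0)
    num_lut, denom = _score_terms(pwm)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win >= 0).all(axis=1)
    scores = np.full(len(win), np.nan)
    if valid.any():
        idx = win[valid]
        acc = np.zeros(int(valid.sum()))
        for i in range(k):
            acc += num_lut[i][idx[:, i]]
        scores[valid] = acc / denom
    return scores


def scan_gene(pwm: PWM, promoter: str) -> ScanHit | None:
    """Best window over both strands of one promoter.

    Ties are broken by smaller position, then the forward strand.
    Returns None when no unmasked window exists.
    """
    if not promoter:
        raise ValueError("empty promoter sequence")
    codes = encode(promoter)
    k = pwm.length
    L = len(codes)
    fwd = _window_scores(codes, pwm)
    rc = 3 - codes[::-1]
    rc[rc > 3] = -1
    rev = _window_scores(rc, pwm)
    best: tuple | None = None
    for strand, scores in (("+", fwd), ("-", rev)):
        if len(scores) == 0:
            continue
        finite = ~np.isnan(scores)
        if not finite.any():
            continue
        top = np.nanmax(scores)
        tied = np.flatnonzero(scores == top)
        # ties break toward the smaller forward-strand position, which
        # on the reverse strand is the *last* index in scan order
        i = int(tied[0]) if strand == "+" else int(tied[-1])
        pos = i if strand == "+" else L - k - i
        score = float(scores[i])
        key = (-score, pos, strand != "+")
        if best is None or key < best[0]:
            best = (key, score, pos, strand)
    if best is None:
        return None
    _, score, pos, strand = best
    return ScanHit(gene_id="", position=pos, strand=strand, score=score)


def target_genes(
    pwm: PWM,
    universe: PromoterSet,
    cutoff: float = DEFAULT_SCORE_CUTOFF,
    source_id: str = "",
) -> TargetGeneSet:
    """Genes whose best window scores strictly above the cutoff."""
    hits = []
    for gene, seq in universe.entries.items():
        hit = scan_gene(pwm, seq) if seq else None
        if hit is not None and hit.score > cutoff:
            hits.append(gene)
    return TargetGeneSet(
        source_id=source_id or "pwm",
        genes=frozenset(hits),
        universe_size=len(universe.entries),
    )


def combination_targets(
    member_targets: list[TargetGeneSet],
    source_id: str = "",
) -> TargetGeneSet:
    """Intersection of the member motifs' target sets.

    The combination's targets are genes targeted by every member; all
    member sets must come from the same scanned universe.
    """
    if not member_targets:
        raise ValueError("no member target sets")
    sizes = {t.universe_size for t in member_targets}
    if len(sizes) != 1:
        raise ValueError(f"universe mismatch across members: {sizes}")
    genes = frozenset.intersection(*(t.genes for t in member_targets))
    return TargetGeneSet(
        source_id=source_id or "+".join(t.source_id for t in member_targets),
        genes=genes,
        universe_size=sizes.pop(),
    )
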