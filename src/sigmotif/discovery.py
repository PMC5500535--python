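"""De novo motif and motif-combination discovery in promoter sets.

The finder is a transparent, cross-fitted, word-seeded stand-in for
heavyweight de novo discovery tools:

1. every unmasked k-mer window on both strands is enumerated for each
   requested length k;
2. the sequences are split into ``n_folds`` round-robin folds; per
   rotation (train on all folds but one), seed words are ranked by
   Hamming-ball occurrence count on the training folds (the ball is
   all words within ``max_mismatch`` substitutions) and screened
   against an order-``background_order`` Markov model, with per-length
   quotas so short noisy words cannot crowd out longer seeds; random
   projections (windows hashed on a few random columns) contribute
   collision-bucket seeds, which find diffuse motifs whose sites share
   no exact word;
3. every surviving seed is refined at one common width
   k_eval = max(k_values) + 2 by hybrid ZOOPS EM on the training folds:
   hard rounds (each sequence's best window above a permissive exact
   threshold) lock a sharp pattern, soft rounds with posterior weights
   broaden the site set, and a double hard re-estimation snaps the
   final matrix to concrete sites;
4. the refined PWM is frozen and evaluated on the held-out fold by the
   sum of per-sequence best-window log-likelihood ratios, whose null
   distribution is computed exactly (dynamic programming over PWM
   columns, per-sequence maximum, convolution across sequences);
   candidates from different rotations are grouped around anchors by
   PWM similarity (training-side information only) and the grouped
   folds give one convolution p-value, accepted at
   ``enrichment_alpha``;
5. accepted motifs are re-estimated on the full data (all occurrences,
   both strands, pseudocount 0.25 per cell), trimmed of uninformative
   flank columns, must reach support s = max(2, ceil(T * 5%)), and are
   deduplicated at the within-study similarity threshold.

Motif combinations are co-occurring motif groups: pairs (and triples) of
motifs whose joint sequence support is at least s and whose overlap is
hypergeometrically significant at ``cooccurrence_alpha``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import PromoterSet
from .pwm import Motif, PWM, encode
from .similarity import NullCalibration, WITHIN_STUDY_E, compare_pwms

logger = logging.getLogger(__name__)


def support_threshold(T: int) -> int:
    """Minimum sequence support s = max(2, ceil(T * 5%))."""
    if T <= 0:
        raise ValueError(f"sequence count must be positive, got {T}")
    return max(2, math.ceil(0.05 * T))


@dataclass(frozen=True)
class DiscoveryParams:
    """Tunable parameters of the finder."""

    k_values: tuple[int, ...] = (8, 9, 10, 12)
    s: int | None = None  # None -> support_threshold(T)
    max_mismatch: int = 1
    enrichment_alpha: float = 1e-4
    cooccurrence_alpha: float = 1e-3
    background_order: int = 2
    seed: int = 0
    max_seeds: int = 20  # seeds refined per k and fold rotation
    seed_screen_p: float = 0.01  # permissive word-stage binomial screen
    pwm_hit_p: float = 1e-5  # per-window null tail held during refinement
    refine_rounds: int = 6
    n_folds: int = 4  # cross-fitting folds (train on all but one)
    n_projections: int = 8  # random projections for collision seeding
    projection_len: int = 8  # columns hashed per projection
    buckets_per_projection: int = 2  # collision buckets refined each
    merge_e: float = 1e-2  # cross-fold candidate merge threshold
    max_combination_size: int = 3

    def __post_init__(self) -> None:
        if self.s is not None and self.s < 2:
            raise ValueError("s must be >= 2")
        if any(k < 6 or k > 30 for k in self.k_values):
            raise ValueError("k_values must lie within [6, 30]")
        if self.max_mismatch not in (0, 1, 2):
            raise ValueError("max_mismatch must be 0, 1 or 2")
        if self.refine_rounds < 1:
            raise ValueError("refine_rounds must be >= 1")
        if self.n_folds < 2:
            raise ValueError("cross-fitting needs at least 2 folds")
        if self.max_combination_size < 2:
            raise ValueError("combinations need at least 2 motifs")


@dataclass
class MotifCombination:
    """Motifs that co-occur in the same promoter sequences."""

    id: str
    motif_ids: frozenset[str]
    supporting_sequences: frozenset[str]
    cooccurrence_p: float

    def __post_init__(self) -> None:
        if len(self.motif_ids) < 2:
            raise ValueError("a combination needs at least two motifs")


# ---------------------------------------------------------------------------
# background models


class MarkovBackground:
    """Order-m Markov model fitted on the unmasked input (both strands)."""

    def __init__(self, sequences: list[np.ndarray], order: int = 2) -> None:
        if order < 0 or order > 3:
            raise ValueError("background order must be in [0, 3]")
        self.order = order
        ctx_counts = np.ones((4**order, 4)) if order else np.ones((1, 4))
        init_counts = np.ones(4**order) if order else np.ones(1)
        for codes in sequences:
            rc = 3 - codes[::-1]
            rc[rc > 3] = -1  # masked stays masked
            for strand in (codes, rc):
                valid = strand >= 0
                edges = np.flatnonzero(np.diff(np.concatenate(
                    ([False], valid, [False])).astype(int)))
                for a, b in zip(edges[::2], edges[1::2]):
                    run = strand[a:b]
                    if len(run) <= order:
                        continue
                    if order:
                        ctx = np.zeros(len(run) - order, dtype=np.int64)
                        for j in range(order):
                            ctx = ctx * 4 + run[j : len(run) - order + j]
                        np.add.at(ctx_counts, (ctx, run[order:]), 1)
                        np.add.at(init_counts, ctx, 1)
                    else:
                        np.add.at(ctx_counts, (0, run), 1)
        self.trans = ctx_counts / ctx_counts.sum(axis=1, keepdims=True)
        self.init = init_counts / init_counts.sum()

    def word_prob(self, word: np.ndarray) -> float:
        """Probability of a k-mer under the model."""
        m = self.order
        if m == 0:
            return float(np.prod(self.trans[0, word]))
        if len(word) <= m:
            raise ValueError("word shorter than the model order")
        ctx = 0
        for j in range(m):
            ctx = ctx * 4 + int(word[j])
        p = float(self.init[ctx])
        for j in range(m, len(word)):
            p *= float(self.trans[ctx, int(word[j])])
            ctx = (ctx * 4 + int(word[j])) % (4**m)
        return p

    def base_composition(self) -> np.ndarray:
        """Strand-symmetric order-0 base probabilities."""
        if self.order == 0:
            return self.trans[0].copy()
        probs = self.init.reshape([4] * self.order).sum(
            axis=tuple(range(self.order - 1))
        )
        return probs / probs.sum()


_LLR_STEP = 0.02
TRIM_IC = 0.15  # bits; flank columns below this are trimmed at report
MIN_REPORT_COLS = 6


def _window_llr_dist(pwm_matrix: np.ndarray, q: np.ndarray
                     ) -> tuple[np.ndarray, int]:
    """Exact null distribution of the per-window LLR on a 0.02 grid.

    The per-window log-likelihood ratio sum(log(m_i[b_i]/q[b_i])) has an
    exactly computable null distribution under an order-0 background
    because columns are independent: discretize the per-column values
    and convolve.  Returns (probabilities, grid base index).
    """
    llr = np.log(np.clip(pwm_matrix, 1e-9, 1.0) / q)
    offsets = np.round(llr / _LLR_STEP).astype(int)
    dist = np.array([1.0])
    base = 0
    for i in range(pwm_matrix.shape[0]):
        o = offsets[i]
        new = np.zeros(len(dist) + (o.max() - o.min()))
        for b in range(4):
            new[o[b] - o.min() : o[b] - o.min() + len(dist)] += q[b] * dist
        dist, base = new, base + int(o.min())
    return dist, base


def _llr_threshold(pwm_matrix: np.ndarray, q: np.ndarray,
                   target_p: float) -> tuple[float, float]:
    """Smallest LLR cutoff whose exact null tail is <= target_p."""
    dist, base = _window_llr_dist(pwm_matrix, q)
    tail = np.cumsum(dist[::-1])[::-1]
    idx = int(np.searchsorted(-tail, -target_p))
    if idx >= len(dist):
        idx = len(dist) - 1
    # the threshold sits half a step below the bin centre, so exact
    # scores falling in that bin are included
    tau = (base + idx) * _LLR_STEP - _LLR_STEP / 2
    return float(tau), float(tail[idx])


def _max_sum_pvalue(parts: list[tuple[np.ndarray, int, np.ndarray]],
                    observed: float) -> float:
    """P(sum of per-sequence best-window LLRs >= observed) under the null.

    ``parts`` holds (window distribution, grid base, per-sequence window
    counts) groups; sequences in different parts may be scored under
    different PWMs (cross-fitting scores each held-out fold with its own
    training-fold PWM), and the total statistic is the sum over all
    sequences of all parts.

    Per sequence, the null best-window LLR has cdf F(x)^n (windows
    treated as independent, which is conservative for the upper tail
    because overlapping windows are positively correlated); the per-
    sequence distributions are convolved exactly on a coarsened grid,
    with rebinned mass pushed upward so the tail stays conservative.
    """
    coarse = 5  # 0.02 -> 0.1 grid
    step = _LLR_STEP * coarse
    total = np.array([1.0])
    total_base = 0
    n_seq = 0
    for dist, base, window_counts in parts:
        if len(window_counts) == 0:
            continue
        cdf = np.minimum(np.cumsum(dist), 1.0)
        fine_idx = base + np.arange(len(dist))
        c_idx = -(-fine_idx // coarse)  # ceil: mass pushed up (conservative)
        c_lo = int(c_idx[0])
        span = int(c_idx[-1]) - c_lo + 1
        for n in np.asarray(window_counts):
            n_seq += 1
            pmf = np.diff(np.concatenate(([0.0], cdf ** int(n))))
            cpmf = np.bincount(c_idx - c_lo, weights=pmf, minlength=span)
            cbase = c_lo
            # trim negligible lower mass, lumping it at its retained edge
            csum = np.cumsum(cpmf)
            cut = int(np.searchsorted(csum, 1e-18))
            if cut > 0:
                cpmf = cpmf[cut:].copy()
                cpmf[0] += csum[cut - 1]
                cbase += cut
            total = np.convolve(total, cpmf)
            total_base += cbase
    if n_seq == 0:
        return 1.0
    tail = np.cumsum(total[::-1])[::-1]
    idx = int(math.ceil(observed / step - total_base - 1e-9))
    if idx < 0:
        return 1.0
    if idx >= len(tail):
        return 1e-300
    return float(max(tail[idx], 1e-300))


# ---------------------------------------------------------------------------
# window enumeration


def _windows_both_strands(encoded: dict[str, np.ndarray], k: int):
    """All unmasked k-windows on both strands of every sequence.

    Returns (W, seq_idx, pos, strand) where W holds the window base
    codes row-wise (strand orientation) and pos is the forward-strand
    coordinate of the window start.
    """
    W_l, seqs_l, pos_l, strand_l = [], [], [], []
    for si, codes in enumerate(encoded.values()):
        L = len(codes)
        if L < k:
            continue
        rc = 3 - codes[::-1]
        rc[rc > 3] = -1
        for strand_code, arr in ((0, codes), (1, rc)):
            win = np.lib.stride_tricks.sliding_window_view(arr, k)
            ok = (win >= 0).all(axis=1)
            n = int(ok.sum())
            if n == 0:
                continue
            W_l.append(win[ok])
            seqs_l.append(np.full(n, si, dtype=np.int32))
            p = np.flatnonzero(ok)
            pos_l.append(p if strand_code == 0 else L - k - p)
            strand_l.append(np.full(n, strand_code, dtype=np.int8))
    if not W_l:
        return (np.empty((0, k), dtype=np.int8), np.empty(0, dtype=np.int32),
                np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int8))
    return (np.concatenate(W_l), np.concatenate(seqs_l),
            np.concatenate(pos_l), np.concatenate(strand_l))


def _ball_codes(word: np.ndarray, max_mismatch: int,
                powers: np.ndarray) -> np.ndarray:
    """Integer codes of all words within the Hamming ball of ``word``."""
    base = int((word.astype(np.int64) * powers).sum())
    out = {base}
    k = len(word)
    if max_mismatch >= 1:
        for i in range(k):
            for b in range(4):
                if b != word[i]:
                    out.add(base + (b - int(word[i])) * int(powers[i]))
    if max_mismatch >= 2:
        for i in range(k):
            for j in range(i + 1, k):
                for bi in range(4):
                    if bi == word[i]:
                        continue
                    for bj in range(4):
                        if bj == word[j]:
                            continue
                        out.add(base + (bi - int(word[i])) * int(powers[i])
                                + (bj - int(word[j])) * int(powers[j]))
    return np.fromiter(out, dtype=np.int64)


def _decode_word(code: int, k: int) -> np.ndarray:
    out = np.empty(k, dtype=np.int64)
    for i in range(k - 1, -1, -1):
        out[i] = code % 4
        code //= 4
    return out


def _ball_counts(uniq: np.ndarray, counts: np.ndarray, k: int,
                 powers: np.ndarray) -> np.ndarray:
    """Total Hamming<=1 ball occurrence count for every distinct word.

    Words agreeing everywhere except position i share the same
    position-i-masked pattern, so one grouped sum per position collects
    all Hamming-1 neighbours at once.
    """
    c64 = counts.astype(np.int64)
    total = c64 * (1 - k)  # own count enters each of the k group sums
    for i in range(k):
        digit = (uniq // powers[i]) % 4
        masked = uniq - digit * powers[i]
        grp, inv = np.unique(masked, return_inverse=True)
        gs = np.bincount(inv, weights=counts).astype(np.int64)
        total += gs[inv]
    return total


try:  # numba accelerates the hot window-scoring loop when present
    from numba import njit

    @njit(cache=True)
    def _scan_llr_jit(W, lut):  # pragma: no cover - thin jit wrapper
        n, k = W.shape
        out = np.zeros(n)
        for r in range(n):
            acc = 0.0
            for i in range(k):
                acc += lut[i, W[r, i]]
            out[r] = acc
        return out

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _scan_llr(W: np.ndarray, pmat: np.ndarray, q: np.ndarray) -> np.ndarray:
    lut = np.log(np.clip(pmat, 1e-9, 1.0) / q)
    if _HAVE_NUMBA and len(W) > 5000:
        return _scan_llr_jit(W, lut)
    llr = np.zeros(len(W))
    for i in range(pmat.shape[0]):
        llr += lut[i][W[:, i]]
    return llr


@dataclass
class _Candidate:
    k: int
    fold: int  # held-out fold index
    pmat: np.ndarray
    tau: float
    p_tail: float
    p_fold: float  # held-out sum-of-best-window-LLR p-value
    heldout_support: int
    heldout_T: int
    train_hits: int
    dist: np.ndarray  # exact single-window LLR null distribution
    dist_base: int
    heldout_n_win: np.ndarray  # windows per held-out sequence
    heldout_sum: float  # observed sum of per-sequence best windows
    pwm: PWM = field(init=False)

    def __post_init__(self) -> None:
        self.pwm = PWM(self.pmat)


@dataclass
class _Rotation:
    """Training/held-out window structures for one fold rotation."""

    Wt: np.ndarray
    seq_t: np.ndarray
    Wh: np.ndarray
    seq_h: np.ndarray
    Wt_onehot: np.ndarray
    n_win_t: np.ndarray
    T_test: int


def _run_em_rotation(rot: _Rotation, pmat0: np.ndarray,
                     params: DiscoveryParams, q: np.ndarray,
                     n_genes: int, k_eval: int):
    """Hybrid ZOOPS EM from an initial PWM on a rotation's training fold.

    Two hard rounds (each sequence contributes its best window if it
    clears a permissive exact threshold) lock onto a sharp pattern — a
    fully soft start can diffuse into the flat background attractor —
    then soft rounds with posterior weights broaden the site set, and a
    double hard re-estimation snaps the final matrix to concrete sites.
    """
    Wt, seq_t, n_win_t = rot.Wt, rot.seq_t, rot.n_win_t
    pmat = pmat0
    gamma = 0.5
    hard_rounds = min(2, params.refine_rounds - 1)
    for rnd in range(params.refine_rounds):
        llr_t = _scan_llr(Wt, pmat, q)
        if rnd < hard_rounds:
            tau_h, _ = _llr_threshold(pmat, q, 1e-4)
            cand = np.flatnonzero(llr_t >= tau_h)
            if len(cand) == 0:
                return None
            sel = np.lexsort((llr_t[cand], seq_t[cand]))
            ordered = cand[sel]
            last = np.concatenate([np.diff(seq_t[ordered]) != 0, [True]])
            rows = ordered[last]
            alpha = min(1.0, max(0.25, 0.1 * len(rows)))
            cmat = np.full((k_eval, 4), alpha)
            sites = Wt[rows]
            for r in range(4):
                cmat[:, r] += (sites == r).sum(axis=0)
        else:
            lr = np.exp(np.minimum(llr_t, 50.0))
            prior = gamma / np.maximum(n_win_t[seq_t], 1)
            w = lr * prior
            denom = (1.0 - gamma) + np.bincount(
                seq_t, weights=w, minlength=n_genes)
            resp = w / denom[seq_t]
            n_eff = float(resp.sum())
            if n_eff < 1.0:
                return None
            alpha = min(1.0, max(0.25, 0.05 * n_eff))
            wc = (resp.astype(np.float32) @ rot.Wt_onehot).reshape(k_eval, 4)
            cmat = alpha + wc.astype(float)
        pmat = cmat / cmat.sum(axis=1, keepdims=True)
    for _ in range(2):
        tau_f, _ = _llr_threshold(pmat, q, 5e-4)
        llr_t = _scan_llr(Wt, pmat, q)
        cand = np.flatnonzero(llr_t >= tau_f)
        if len(cand) < 3:
            break
        sel = np.lexsort((llr_t[cand], seq_t[cand]))
        ordered = cand[sel]
        last = np.concatenate([np.diff(seq_t[ordered]) != 0, [True]])
        sites = Wt[ordered[last]]
        cmat = np.full((k_eval, 4), 0.5)
        for r in range(4):
            cmat[:, r] += (sites == r).sum(axis=0)
        pmat = cmat / cmat.sum(axis=1, keepdims=True)
    tau, p_tail = _llr_threshold(pmat, q, params.pwm_hit_p)
    llr_t = _scan_llr(Wt, pmat, q)
    strong = np.flatnonzero(llr_t >= tau)
    train_hits = len(np.unique(seq_t[strong]))
    if train_hits < 2:
        return None
    return train_hits, pmat, float(tau), float(p_tail)


def _heldout_candidate(rot: _Rotation, heldout: int, em_out,
                       q: np.ndarray, k_eval: int,
                       win_e: np.ndarray) -> _Candidate:
    """Evaluate a frozen refined PWM on the rotation's held-out fold."""
    train_hits, pmat, tau, p_tail = em_out
    llr_h = _scan_llr(rot.Wh, pmat, q)
    heldout_support = len(np.unique(rot.seq_h[llr_h >= tau]))
    sel = np.lexsort((llr_h, rot.seq_h))
    last = np.concatenate([np.diff(rot.seq_h[sel]) != 0, [True]])
    seq_max = llr_h[sel][last]
    n_win = win_e[rot.seq_h[sel][last]]
    dist, dbase = _window_llr_dist(pmat, q)
    obs = float(seq_max.sum())
    p_fold = _max_sum_pvalue([(dist, dbase, n_win)], obs)
    return _Candidate(
        k=k_eval, fold=heldout, pmat=pmat, tau=tau, p_tail=p_tail,
        p_fold=p_fold, heldout_support=int(heldout_support),
        heldout_T=rot.T_test, train_hits=train_hits,
        dist=dist, dist_base=dbase, heldout_n_win=n_win, heldout_sum=obs,
    )


# ---------------------------------------------------------------------------
# discovery



def _pairwise_evalues_same_length(mats: np.ndarray,
                                  calibration: NullCalibration | None
                                  ) -> np.ndarray:
    """E-value matrix for n same-length PWMs, computed as one batch.

    Mirrors compare_pwms (best Fisher-z alignment over all offsets and
    orientations against the calibrated Gaussian null) but vectorizes
    the candidate-by-candidate comparisons of the grouping stage.
    """
    from .similarity import _ATANH_CLAMP, _alignments, default_calibration
    n, k, _ = mats.shape
    cal = calibration or default_calibration()
    mu, sd = cal.params(k, k)
    offsets = _alignments(k, k)
    cen = mats - mats.mean(axis=2, keepdims=True)
    norm = (cen**2).sum(axis=2)
    cen_rc = cen[:, ::-1, ::-1]
    norm_rc = norm[:, ::-1]
    best = np.full((n, n), -np.inf)
    for off in offsets:
        sa, sb = max(0, off), max(0, -off)
        m = min(k - sa, k - sb)
        a = cen[:, sa : sa + m]
        na = norm[:, sa : sa + m]
        for bmat, bnorm in ((cen, norm), (cen_rc, norm_rc)):
            b = bmat[:, sb : sb + m]
            nb = bnorm[:, sb : sb + m]
            num = np.einsum("ikb,jkb->ijk", a, b)
            den = np.sqrt(na[:, None, :] * nb[None, :, :])
            r = np.where(den > 1e-12, num / np.maximum(den, 1e-300), 0.0)
            t = np.arctanh(np.clip(r, -_ATANH_CLAMP, _ATANH_CLAMP)).sum(axis=2)
            np.maximum(best, t, out=best)
    n_comp = 2 * len(offsets)
    return n_comp * stats.norm.sf((best - mu) / sd)


def discover_motifs(
    promoters: PromoterSet,
    params: DiscoveryParams = DiscoveryParams(),
    calibration: NullCalibration | None = None,
) -> list[Motif]:
    """Discover enriched motifs in one promoter set."""
    gene_ids = list(promoters.entries)
    encoded = {g: encode(promoters.entries[g]) for g in gene_ids}
    usable = [g for g in gene_ids if (encoded[g] >= 0).any()]
    if not usable:
        warnings.warn(f"{promoters.signature_id}: all sequences fully masked",
                      stacklevel=2)
        return []
    if len(usable) < 3:
        warnings.warn(f"{promoters.signature_id}: fewer than 3 usable "
                      "sequences", stacklevel=2)
        return []
    T = len(gene_ids)
    s = params.s if params.s is not None else support_threshold(T)
    background = MarkovBackground([encoded[g] for g in usable],
                                  params.background_order)
    q = background.base_composition()
    n_folds = min(params.n_folds, T)
    fold_of_seq = np.arange(len(gene_ids)) % n_folds  # round-robin split

    # word enumeration at every seeding length, plus the common
    # evaluation width: refining every seed at k_eval = max(k) + 2
    # keeps all informative columns inside the window even when the
    # alignment phase drifts by a column or two
    k_eval = min(max(params.k_values) + 2, 30)
    per_k: dict[int, tuple] = {}
    for k in sorted(set(params.k_values) | {k_eval}):
        W, seqs, poss, strands = _windows_both_strands(encoded, k)
        if len(W) == 0:
            continue
        powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        words = W.astype(np.int64) @ powers
        per_k[k] = (W, seqs, poss, strands, words, powers)
    if k_eval not in per_k:
        return []
    We, seqs_e, poss_e, strands_e, _, _ = per_k[k_eval]
    win_e = np.bincount(seqs_e, minlength=len(gene_ids))

    candidates: list[_Candidate] = []
    rot_data: dict[int, _Rotation] = {}
    for heldout in range(n_folds):
        T_test = int((fold_of_seq == heldout).sum())
        T_train = len(gene_ids) - T_test
        if T_train < 2 or T_test < 1:
            continue
        # --- seed mining on the training fold, per word length
        seed_pool: list[tuple[float, int, int]] = []  # (screen_p, k, seed)
        seed_sites: dict[tuple[int, int], np.ndarray] = {}
        for k in sorted(params.k_values):
            if k not in per_k:
                continue
            W, seqs, poss, strands, words, powers = per_k[k]
            train_rows = fold_of_seq[seqs] != heldout
            w_train = words[train_rows]
            if len(w_train) == 0:
                continue
            Wt_k = W[train_rows]
            seq_tk = seqs[train_rows]
            order = np.argsort(w_train, kind="stable")
            uniq, starts, counts = np.unique(
                w_train[order], return_index=True, return_counts=True)
            ball_tot = _ball_counts(uniq, counts, k, powers)
            rank = np.argsort(-ball_tot, kind="stable")
            pool = uniq[rank][: 8 * params.max_seeds]
            win_k = np.bincount(seqs, minlength=len(gene_ids))
            mean_win = float(win_k[win_k > 0].mean())
            for seed in pool:
                seed_arr = _decode_word(int(seed), k)
                ball = _ball_codes(seed_arr, params.max_mismatch, powers)
                idx = np.searchsorted(uniq, ball)
                idx[idx >= len(uniq)] = len(uniq) - 1
                present = np.flatnonzero(uniq[idx] == ball)
                if len(present) == 0:
                    continue
                rows_t = np.concatenate([
                    order[starts[i] : starts[i] + counts[i]]
                    for i in idx[present]
                ])
                support0 = len(np.unique(seq_tk[rows_t]))
                if support0 < (3 if T_train >= 20 else 2):
                    continue
                lam_word = sum(
                    background.word_prob(_decode_word(int(w), k))
                    for w in ball
                )
                p_seq0 = -math.expm1(-mean_win * lam_word)
                screen_p = float(stats.binom.sf(support0 - 1, T_train,
                                                min(1.0, p_seq0)))
                if screen_p > params.seed_screen_p:
                    continue
                seed_pool.append((screen_p, k, int(seed)))
                seed_sites[(k, int(seed))] = Wt_k[rows_t]
        if not seed_pool:
            continue
        # per-length quotas: each k keeps its most surprising seeds, so
        # noisy short-word clusters cannot crowd out longer seeds, then
        # remaining slots fill with the best of the rest
        seed_pool.sort()
        quota = max(3, params.max_seeds // max(1, len(params.k_values)))
        taken: list[tuple[float, int, int]] = []
        per_len: dict[int, int] = {}
        rest: list[tuple[float, int, int]] = []
        for item in seed_pool:
            if per_len.get(item[1], 0) < quota:
                taken.append(item)
                per_len[item[1]] = per_len.get(item[1], 0) + 1
            else:
                rest.append(item)
        taken.extend(rest[: max(0, params.max_seeds - len(taken))])
        seed_pool = sorted(taken)
        # --- shared training/held-out structures at the evaluation width
        train_rows_e = fold_of_seq[seqs_e] != heldout
        Wt = We[train_rows_e]
        seq_t = seqs_e[train_rows_e]
        Wh = We[~train_rows_e]
        seq_h = seqs_e[~train_rows_e]
        if len(Wt) == 0 or len(Wh) == 0:
            continue
        Wt_onehot = np.zeros((len(Wt), k_eval * 4), dtype=np.float32)
        for r in range(4):
            Wt_onehot[:, r::4] = Wt == r
        n_win_t = np.bincount(seq_t, minlength=len(gene_ids))
        rot_data[heldout] = _Rotation(Wt, seq_t, Wh, seq_h, Wt_onehot,
                                      n_win_t, T_test)

        def run_em(pmat0: np.ndarray):
            return _run_em_rotation(rot_data[heldout], pmat0, params, q,
                                    len(gene_ids), k_eval)

        # --- random-projection seeding at the evaluation width: hash
        # every training window on a few random columns; windows of the
        # same diffuse motif collide even when no two sites share an
        # exact word, and the bucket consensus averages out the
        # idiosyncratic errors that word seeds freeze in
        proj_inits: list[np.ndarray] = []
        rng = np.random.default_rng(
            (int(params.seed) % (2**31), heldout, 7919))
        p_len = min(params.projection_len, k_eval - 1)
        pow_p = 4 ** np.arange(p_len - 1, -1, -1, dtype=np.int64)
        mean_win_e = float(win_e[win_e > 0].mean())
        for _ in range(params.n_projections):
            cols = np.sort(rng.choice(k_eval, size=p_len, replace=False))
            keys = Wt[:, cols].astype(np.int64) @ pow_p
            korder = np.argsort(keys, kind="stable")
            ks_sorted = keys[korder]
            uk, kstarts, kcounts = np.unique(
                ks_sorted, return_index=True, return_counts=True)
            # distinct-sequence support per bucket, fully vectorized
            pair = keys.astype(np.int64) * len(gene_ids) + seq_t
            upair = np.unique(pair)
            nseq_per_key = np.bincount(
                np.searchsorted(uk, upair // len(gene_ids)),
                minlength=len(uk))
            cand_b = np.flatnonzero(nseq_per_key >= 3)
            if len(cand_b) == 0:
                continue
            # composition-aware screen of the shared gapped pattern
            digits = (uk[cand_b, None] // pow_p[None, :]) % 4
            p_fwd = np.prod(q[digits], axis=1)
            p_rev = np.prod(q[3 - digits[:, ::-1]], axis=1)
            p_seq0 = -np.expm1(-mean_win_e * (p_fwd + p_rev) / 2.0)
            screen = stats.binom.sf(nseq_per_key[cand_b] - 1, T_train,
                                    np.minimum(1.0, p_seq0))
            keep = np.flatnonzero(screen <= params.seed_screen_p)
            for j in keep[np.argsort(screen[keep], kind="stable")][
                    : params.buckets_per_projection]:
                bi = cand_b[j]
                rows_b = korder[kstarts[bi] : kstarts[bi] + kcounts[bi]]
                sites_b = Wt[rows_b[:40]]
                cmat = np.full((k_eval, 4), 0.5)
                for r in range(4):
                    cmat[:, r] += (sites_b == r).sum(axis=0)
                proj_inits.append(cmat / cmat.sum(axis=1, keepdims=True))

        seen_pm: set[bytes] = set()
        inits: list[np.ndarray] = []
        for screen_p, k, seed in seed_pool[: params.max_seeds]:
            sites0 = seed_sites[(k, seed)]
            pad = k_eval - k
            left = pad // 2
            cmat = np.full((k_eval, 4), 0.5)
            for r in range(4):
                cmat[left : left + k, r] += (sites0 == r).sum(axis=0)
            inits.append(cmat / cmat.sum(axis=1, keepdims=True))
        inits.extend(proj_inits)
        seen_init: set[bytes] = set()
        for pmat0 in inits:
            ikey = pmat0.round(4).tobytes()
            if ikey in seen_init:
                continue
            seen_init.add(ikey)
            out = run_em(pmat0)
            if out is None:
                continue
            key = out[1].round(6).tobytes()
            if key in seen_pm:
                continue
            seen_pm.add(key)
            candidates.append(_heldout_candidate(
                rot_data[heldout], heldout, out, q, k_eval, win_e))
    if not candidates:
        return []
    n_cand = len(candidates)
    # anchors: candidates whose own held-out fold shows at least some
    # signal; a group whose every fold is null cannot pass, and a group
    # with signal is found via its strongest member as anchor, so this
    # shortcut skips no discoverable motif (Bonferroni still counts
    # every evaluated candidate)
    anchor_ids = [i for i, c in enumerate(candidates) if c.p_fold <= 0.3]
    sim_matrix = _pairwise_evalues_same_length(
        np.stack([c.pmat for c in candidates]), calibration)

    def similarity(i: int, j: int) -> float:
        return float(sim_matrix[i, j])

    accepted: list[Motif] = []
    for i in anchor_ids:
        anchor = candidates[i]
        # assemble the anchor's cross-fold group: in every other fold,
        # the candidate most similar to the anchor (if similar at all);
        # the choice uses only training-fold information
        group = {anchor.fold: anchor}
        for f in sorted({c.fold for c in candidates}):
            if f == anchor.fold:
                continue
            best_j, best_key = None, None
            for j, c in enumerate(candidates):
                if c.fold != f:
                    continue
                e = similarity(i, j)
                if e >= params.merge_e:
                    continue
                key = (e, -c.train_hits, j)
                if best_key is None or key < best_key:
                    best_j, best_key = j, key
            if best_j is not None:
                group[f] = candidates[best_j]
        # one exact test on the summed held-out statistic: each fold is
        # scored under its own training-fold PWM, folds are disjoint, so
        # the null of the sum is the convolution of the fold nulls
        parts = [(c.dist, c.dist_base, c.heldout_n_win)
                 for c in group.values()]
        observed = sum(c.heldout_sum for c in group.values())
        group_p = _max_sum_pvalue(parts, observed)
        if group_p > params.enrichment_alpha:
            continue
        # full-data polish with the anchor's PWM, then trimming of
        # uninformative flank columns
        rep = anchor
        llr = _scan_llr(We, rep.pmat, q)
        hits = np.flatnonzero(llr >= rep.tau)
        if len(hits) == 0:
            continue
        final_sites = We[hits]
        cmat = np.full((k_eval, 4), 0.25)
        for r in range(4):
            cmat[:, r] += (final_sites == r).sum(axis=0)
        pmat_full = cmat / cmat.sum(axis=1, keepdims=True)
        ic = 2.0 + (np.clip(pmat_full, 1e-12, 1) *
                    np.log2(np.clip(pmat_full, 1e-12, 1))).sum(axis=1)
        lo, hi = 0, k_eval
        while hi - lo > MIN_REPORT_COLS and ic[lo] < TRIM_IC:
            lo += 1
        while hi - lo > MIN_REPORT_COLS and ic[hi - 1] < TRIM_IC:
            hi -= 1
        pwm = PWM(pmat_full[lo:hi] /
                  pmat_full[lo:hi].sum(axis=1, keepdims=True))
        occurrences: dict[str, list[tuple[int, str]]] = {}
        for rr in hits:
            # trimming shifts the occurrence start in motif orientation
            if int(strands_e[rr]) == 0:
                pos = int(poss_e[rr]) + lo
            else:
                pos = int(poss_e[rr]) + (k_eval - hi)
            occurrences.setdefault(gene_ids[int(seqs_e[rr])], []).append(
                (pos, "+-"[int(strands_e[rr])])
            )
        support = len(occurrences)
        if support < s:
            continue
        accepted.append(Motif(
            id=f"{promoters.signature_id}_tmp",
            pwm=pwm,
            consensus=pwm.consensus(),
            support=int(support),
            source_gs=promoters.signature_id,
            enrichment_p=group_p,
            occurrences=occurrences,
        ))
    # deduplicate by PWM similarity, keeping the most significant motif
    accepted.sort(key=lambda m: (m.enrichment_p, -m.support, m.consensus))
    kept: list[Motif] = []
    for mot in accepted:
        if any(
            compare_pwms(mot.pwm, other.pwm, calibration).e_value
            < WITHIN_STUDY_E
            for other in kept
        ):
            continue
        kept.append(mot)
    for i, mot in enumerate(kept, 1):
        mot.id = f"{promoters.signature_id}_m{i}"
    return kept



def build_combinations(
    motifs: list[Motif],
    promoters: PromoterSet,
    params: DiscoveryParams = DiscoveryParams(),
) -> list[MotifCombination]:
    """Significant co-occurring motif pairs (and triples).

    The hypergeometric draw treats the promoter set as the universe,
    the sequences carrying one motif as the drawn sample and those
    carrying the other as successes; the upper tail of the joint
    support is the co-occurrence p-value.
    """
    T = len(promoters.entries)
    s = params.s if params.s is not None else support_threshold(T)
    occ = {m.id: frozenset(m.occurrences) for m in motifs}
    combos: list[MotifCombination] = []
    counter = 0
    motifs_sorted = sorted(motifs, key=lambda m: m.id)
    sig_pairs: list[tuple[Motif, Motif, frozenset[str]]] = []
    for i, a in enumerate(motifs_sorted):
        for b in motifs_sorted[i + 1 :]:
            joint = occ[a.id] & occ[b.id]
            if len(joint) < s:
                continue
            p = float(stats.hypergeom.sf(
                len(joint) - 1, T, len(occ[b.id]), len(occ[a.id])
            ))
            if p <= params.cooccurrence_alpha:
                counter += 1
                combos.append(MotifCombination(
                    id=f"{promoters.signature_id}_c{counter}",
                    motif_ids=frozenset({a.id, b.id}),
                    supporting_sequences=joint,
                    cooccurrence_p=p,
                ))
                sig_pairs.append((a, b, joint))
    if params.max_combination_size >= 3:
        seen: set[frozenset[str]] = {c.motif_ids for c in combos}
        for a, b, joint_ab in sig_pairs:
            for c in motifs_sorted:
                if c.id in (a.id, b.id):
                    continue
                trio = frozenset({a.id, b.id, c.id})
                if trio in seen:
                    continue
                joint = joint_ab & occ[c.id]
                if len(joint) < s:
                    continue
                p = float(stats.hypergeom.sf(
                    len(joint) - 1, T, len(occ[c.id]), len(joint_ab)
                ))
                if p <= params.cooccurrence_alpha:
                    seen.add(trio)
                    counter += 1
                    combos.append(MotifCombination(
                        id=f"{promoters.signature_id}_c{counter}",
                        motif_ids=trio,
                        supporting_sequences=joint,
                        cooccurrence_p=p,
                    ))
    return combos


def permute_sequences(promoters: PromoterSet, seed: int) -> PromoterSet:
    """Shuffle each sequence's characters independently (composition kept).

    Masked characters are permuted along with the rest, so base counts
    and the masked fraction are conserved per sequence.
    """
    rng = np.random.default_rng(seed)
    entries = {}
    for gene, seq in promoters.entries.items():
        arr = np.array(list(seq))
        rng.shuffle(arr)
        entries[gene] = "".join(arr)
    return PromoterSet(
        signature_id=promoters.signature_id,
        entries=entries,
        nominal_length=promoters.nominal_length,
    )
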