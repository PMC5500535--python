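"""PWM-PWM comparison with an empirically calibrated E-value.

Two motifs are compared over every ungapped alignment (all offsets with
sufficient column overlap, both orientations).  Each aligned column pair
contributes its Pearson correlation; the alignment's reported *score* is
the mean column correlation, and its test statistic is the sum of
Fisher z-transformed (atanh) column correlations, which accumulates
evidence across columns instead of averaging it away.  The statistic of
the best alignment is referred to a Gaussian fitted to the best-alignment
statistics of many random PWM pairs of the same length pair, and the
resulting tail probability is multiplied by the number of candidate
alignments, giving a Bonferroni-style E-value per comparison.

The default decision thresholds are E < 1e-8 for calling two motifs from
the same study similar, and E < 1e-5 for matching a motif against an
external known-motif database.  The E-value scale is specific to this
calibration; it is not comparable to other motif-comparison tools.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .pwm import PWM

WITHIN_STUDY_E = 1e-8
KNOWN_MATCH_E = 1e-5

# Cap on |r| before the Fisher z-transform.  Sharp PWM columns sharing a
# dominant base reach |r| ~ 1 by chance, and uncapped atanh would let a
# few such columns dominate the statistic; 0.98 (atanh ~ 2.3) keeps the
# null tail light without costing sensitivity for genuinely similar PWMs.
_ATANH_CLAMP = 0.98


@dataclass(frozen=True)
class SimilarityResult:
    score: float  # mean column correlation of the best alignment
    e_value: float
    offset: int  # position of b's first column relative to a's
    orientation: str  # "forward" or "reverse-complement"
    overlap_columns: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.score <= 1.0 + 1e-9:
            raise ValueError("score outside [-1, 1]")
        if self.e_value < 0:
            raise ValueError("negative e_value")


def min_overlap(k_a: int, k_b: int) -> int:
    """Minimum aligned columns: max(6, ceil(0.75 * shorter length))."""
    return max(6, math.ceil(0.75 * min(k_a, k_b)))


def _column_correlations(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation per aligned column pair; 0 if a column is flat."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = (ac * bc).sum(axis=1)
    den = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
    out = np.zeros(len(num))
    ok = den > 1e-12
    out[ok] = num[ok] / den[ok]
    return np.clip(out, -1.0, 1.0)


def _alignments(k_a: int, k_b: int) -> list[int]:
    """Offsets of b relative to a keeping at least min_overlap columns."""
    lo = -(k_b - min_overlap(k_a, k_b))
    hi = k_a - min_overlap(k_a, k_b)
    return list(range(lo, hi + 1))


def _stat_and_score(a: np.ndarray, b: np.ndarray, offset: int
                    ) -> tuple[float, float, int]:
    """(fisher-z sum, mean correlation, overlap) for one alignment."""
    start_a = max(0, offset)
    start_b = max(0, -offset)
    n = min(a.shape[0] - start_a, b.shape[0] - start_b)
    r = _column_correlations(a[start_a : start_a + n], b[start_b : start_b + n])
    t = float(np.arctanh(np.clip(r, -_ATANH_CLAMP, _ATANH_CLAMP)).sum())
    return t, float(r.mean()), n


def _centered(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = m - m.mean(axis=1, keepdims=True)
    return c, (c**2).sum(axis=1)


def _centered_cached(p: PWM, rc: bool = False) -> tuple[np.ndarray, np.ndarray]:
    attr = "_centered_rc" if rc else "_centered_fwd"
    cached = getattr(p, attr, None)
    if cached is None:
        mat = p.matrix[::-1, ::-1] if rc else p.matrix
        cached = _centered(mat)
        object.__setattr__(p, attr, cached)
    return cached


class NullCalibration:
    """Per-length-pair Gaussian null for the best-alignment statistic.

    For each unordered length pair (k_a, k_b) the calibration draws
    ``n_pairs`` independent PWM pairs (columns sampled from a symmetric
    Dirichlet, concentration ``alpha``, matching the sharpness of motif
    columns estimated from tens of binding sites), records the best
    Fisher-z sum over all alignments of each pair, and fits a Gaussian.
    The fit is seeded and cached, so E-values are reproducible.
    """

    def __init__(self, n_pairs: int = 2000, alpha: float = 0.45,
                 seed: int = 101) -> None:
        if n_pairs < 100:
            raise ValueError("need at least 100 null pairs")
        self.n_pairs = n_pairs
        self.alpha = alpha
        self.seed = seed
        self._cache: dict[tuple[int, int], tuple[float, float]] = {}

    def params(self, k_a: int, k_b: int) -> tuple[float, float]:
        key = (min(k_a, k_b), max(k_a, k_b))
        if key not in self._cache:
            self._cache[key] = self._fit(*key)
        return self._cache[key]

    def _fit(self, k_a: int, k_b: int) -> tuple[float, float]:
        # One stream per length pair so adding pairs never reshuffles others.
        rng = np.random.default_rng((self.seed, k_a, k_b))
        offsets = _alignments(k_a, k_b)
        n = self.n_pairs
        a = rng.dirichlet([self.alpha] * 4, size=(n, k_a))
        b = rng.dirichlet([self.alpha] * 4, size=(n, k_b))
        b_rc = b[:, ::-1, ::-1]
        best = np.full(n, -np.inf)
        for off in offsets:
            sa, sb = max(0, off), max(0, -off)
            m = min(k_a - sa, k_b - sb)
            av = a[:, sa : sa + m]
            ac = av - av.mean(axis=2, keepdims=True)
            na = (ac**2).sum(axis=2)
            for mat in (b, b_rc):
                bv = mat[:, sb : sb + m]
                bc = bv - bv.mean(axis=2, keepdims=True)
                num = (ac * bc).sum(axis=2)
                den = np.sqrt(na * (bc**2).sum(axis=2))
                r = np.where(den > 1e-12, num / np.maximum(den, 1e-300), 0.0)
                t = np.arctanh(np.clip(r, -_ATANH_CLAMP, _ATANH_CLAMP)
                               ).sum(axis=1)
                np.maximum(best, t, out=best)
        # Quantile-based fit (median and q99): the best-over-alignments
        # statistic is right-skewed, and a moment fit underestimates the
        # upper tail that E-values extrapolate into.
        med = float(np.median(best))
        q99 = float(np.quantile(best, 0.99))
        return med, (q99 - med) / 2.3263478740408408

    def save(self, path: str | Path) -> None:
        payload = {
            "n_pairs": self.n_pairs,
            "alpha": self.alpha,
            "seed": self.seed,
            "pairs": {f"{k[0]}x{k[1]}": {"mean": v[0], "sd": v[1]}
                      for k, v in self._cache.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "NullCalibration":
        payload = json.loads(Path(path).read_text())
        cal = cls(n_pairs=payload["n_pairs"], alpha=payload["alpha"],
                  seed=payload["seed"])
        for key, v in payload["pairs"].items():
            ka, kb = (int(x) for x in key.split("x"))
            cal._cache[(ka, kb)] = (v["mean"], v["sd"])
        return cal


_DEFAULT_CALIBRATION: NullCalibration | None = None


def default_calibration() -> NullCalibration:
    """Process-wide calibration with fixed seed (lazily built, cached)."""
    global _DEFAULT_CALIBRATION
    if _DEFAULT_CALIBRATION is None:
        _DEFAULT_CALIBRATION = NullCalibration()
    return _DEFAULT_CALIBRATION


def compare_pwms(a: PWM, b: PWM,
                 calibration: NullCalibration | None = None
                 ) -> SimilarityResult:
    """Best ungapped alignment of two PWMs with its E-value.

    Ties between alignments are broken by larger overlap, then smaller
    |offset|, then forward orientation.
    """
    null = calibration or default_calibration()
    offsets = _alignments(a.length, b.length)
    if not offsets:
        raise ValueError(
            f"no alignment with >= {min_overlap(a.length, b.length)} "
            f"overlapping columns for lengths {a.length}, {b.length}"
        )
    ac, an = _centered_cached(a)
    mats = {"forward": _centered_cached(b),
            "reverse-complement": _centered_cached(b, rc=True)}
    best: tuple | None = None
    for off in offsets:
        sa, sb = max(0, off), max(0, -off)
        n = min(a.length - sa, b.length - sb)
        for orientation, (bc, bn) in mats.items():
            num = (ac[sa : sa + n] * bc[sb : sb + n]).sum(axis=1)
            den = np.sqrt(an[sa : sa + n] * bn[sb : sb + n])
            r = np.where(den > 1e-12, num / np.maximum(den, 1e-300), 0.0)
            r = np.clip(r, -1.0, 1.0)
            t = float(np.arctanh(np.clip(r, -_ATANH_CLAMP, _ATANH_CLAMP)).sum())
            key = (t, n, -abs(off), orientation == "forward")
            if best is None or key > best[0]:
                best = (key, t, float(r.mean()), off, orientation, n)
    _, t, score, off, orientation, n_cols = best
    mu, sd = null.params(a.length, b.length)
    n_comparisons = 2 * len(offsets)
    e_value = float(n_comparisons * stats.norm.sf((t - mu) / sd))
    return SimilarityResult(score=score, e_value=e_value, offset=off,
                            orientation=orientation, overlap_columns=n_cols)


def similar(a: PWM, b: PWM, threshold: float = WITHIN_STUDY_E,
            calibration: NullCalibration | None = None) -> bool:
    """True iff the comparison E-value is strictly below the threshold."""
    return compare_pwms(a, b, calibration).e_value < threshold


def match_known(
    pwm: PWM,
    known_db: list[tuple[str, PWM]],
    threshold: float = KNOWN_MATCH_E,
    calibration: NullCalibration | None = None,
) -> tuple[str, SimilarityResult] | None:
    """Best known-motif match below the threshold, or None."""
    if not known_db:
        raise ValueError("known_db is empty")
    null = calibration or default_calibration()
    best_name, best_res = None, None
    for name, known in known_db:
        res = compare_pwms(pwm, known, null)
        if best_res is None or res.e_value < best_res.e_value:
            best_name, best_res = name, res
    if best_res is not None and best_res.e_value < threshold:
        return best_name, best_res
    return None
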