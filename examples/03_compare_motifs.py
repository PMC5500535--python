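"""PWM similarity: E-values, the 1e-8 study threshold, known-motif match.

Comparison aligns two matrices over all ungapped offsets and both
orientations; the per-column correlations are combined and referred to
a calibrated null, giving an E-value.  Two re-estimates of the same
motif land far below the 1e-8 within-study threshold; unrelated
matrices land near 1.
"""

import numpy as np

from sigmotif import PWM, compare_pwms, match_known, sample_pwm, similar

rng = np.random.default_rng(3)
truth = sample_pwm(10, 1.5, rng)

# two independent 30-site re-estimates of the same motif
a = PWM.from_sites([truth.sample_site(rng) for _ in range(30)])
b = PWM.from_sites([truth.sample_site(rng) for _ in range(30)])
res = compare_pwms(a, b)
print(f"re-estimates of one motif: score={res.score:.3f} "
      f"E={res.e_value:.2e} similar={similar(a, b)}")

unrelated = sample_pwm(10, 1.5, rng)
res = compare_pwms(a, unrelated)
print(f"unrelated motifs:          score={res.score:.3f} "
      f"E={res.e_value:.2e} similar={similar(a, unrelated)}")

# matching a motif against a known-motif database (threshold 1e-5)
db = [(f"DECOY_{i}", sample_pwm(10, 1.3, rng)) for i in range(10)]
db.append(("SP1-like", truth))
hit = match_known(a, db)
print(f"best database match: {hit[0]} (E={hit[1].e_value:.2e})")
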