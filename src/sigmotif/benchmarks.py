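"""Self-contained validation experiments for the analysis pipeline.

Each function generates its own synthetic inputs (seeded), runs the
relevant pipeline stages from scratch and measures an outcome: planted
shared-motif recovery, permutation-control false-positive rates, null
calibration of the miRNA overlap test, designated-miRNA recovery, and
agreement of the scanning and enrichment primitives with brute-force
oracles.  The acceptance script and the acceptance test suite both run
these; problem sizes are documented in the methods note.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .discovery import DiscoveryParams, discover_motifs, permute_sequences
from .enrichment import (
    common_mirnas,
    hypergeom_overlap_test,
    mirna_regulates_gs,
)
from .pwm import PWM, decode, revcomp
from .scan import scan_gene, target_genes
from .shared import call_shared, group_similar
from .similarity import NullCalibration, compare_pwms, default_calibration
from .simulate import (
    PlantedMotifSpec,
    SyntheticStudySpec,
    generate_study,
    sample_pwm,
)

RECOVERY_SPEC = dict(
    cancer_types=(("t", 6, 40),),
    universe_size=300,
    n_mirnas=5,
    n_cancer_sets=5,
)


def _recovery_spec(seed: int, plant_rate: float) -> SyntheticStudySpec:
    """The planted-recovery study: 6 GSs x 40 promoters x 1.5 kb, one
    IC-1.3 PWM planted in 4 of the 6 signatures at the given rate."""
    return SyntheticStudySpec(
        planted_motifs=(PlantedMotifSpec(ic=1.3, plant_rate=plant_rate,
                                         fraction_of_gs=0.67),),
        seed=seed,
        **RECOVERY_SPEC,
    )


def shared_motif_recovery(
    n_seeds: int = 10,
    seed0: int = 1,
    calibration: NullCalibration | None = None,
    with_twin: bool = True,
    n_twins: int | None = None,
) -> dict:
    """Planted-PWM recovery through discovery + shared-motif calling.

    A seed succeeds when at least one called shared motif's
    representative is similar (module threshold, E < 1e-8) to the
    planted PWM; the plant-rate-0 twin must call no shared motif.
    """
    cal = calibration or default_calibration()
    params = DiscoveryParams()
    recovered = 0
    per_seed = []
    for i in range(n_seeds):
        study = generate_study(_recovery_spec(seed0 + 7919 * i, 0.6))
        truth = study.truth.planted_pwms["planted_1"]
        motifs = []
        for sig in study.signatures:
            motifs.extend(discover_motifs(study.promoters[sig.id], params,
                                          cal))
        groups = group_similar(motifs, calibration=cal)
        shared = call_shared(groups, len(study.signatures), study.known_db,
                             cancer_type="t", calibration=cal)
        hit = any(
            compare_pwms(sm.representative.pwm, truth, cal).e_value < 1e-8
            for sm in shared
        )
        recovered += hit
        per_seed.append(bool(hit))
    twin_calls = []
    if with_twin:
        for i in range(n_twins if n_twins is not None else n_seeds):
            study = generate_study(_recovery_spec(seed0 + 7919 * i, 0.0))
            motifs = []
            for sig in study.signatures:
                motifs.extend(discover_motifs(study.promoters[sig.id],
                                              params, cal))
            groups = group_similar(motifs, calibration=cal)
            shared = call_shared(groups, len(study.signatures),
                                 study.known_db, cancer_type="t",
                                 calibration=cal)
            twin_calls.append(len(shared))
    return {
        "n_seeds": n_seeds,
        "recovered": recovered,
        "recovery_rate": recovered / n_seeds,
        "per_seed": per_seed,
        "twin_shared_calls": twin_calls,
        "twin_false_rate": (
            sum(1 for n in twin_calls if n > 0) / len(twin_calls)
            if twin_calls else float("nan")
        ),
    }


def permutation_control(
    n_reps: int = 8,
    seed: int = 1,
    calibration: NullCalibration | None = None,
) -> dict:
    """Shared-motif rate on nucleotide-permuted copies of one study."""
    cal = calibration or default_calibration()
    params = DiscoveryParams()
    study = generate_study(_recovery_spec(seed, 0.6))
    shared_per_rep = []
    motifs_per_rep = []
    for rep in range(n_reps):
        motifs = []
        for i, sig in enumerate(study.signatures):
            perm = permute_sequences(study.promoters[sig.id],
                                     seed * 100003 + rep * 1009 + i)
            motifs.extend(discover_motifs(perm, params, cal))
        groups = group_similar(motifs, calibration=cal)
        shared = call_shared(groups, len(study.signatures), study.known_db,
                             cancer_type="t", calibration=cal)
        motifs_per_rep.append(len(motifs))
        shared_per_rep.append(len(shared))
    rate = sum(1 for n in shared_per_rep if n > 0) / n_reps
    return {
        "n_reps": n_reps,
        "motifs_per_rep": motifs_per_rep,
        "shared_per_rep": shared_per_rep,
        "shared_motif_rate": rate,
    }


def _mirna_study(seed: int, rho: float, ic: float = 1.6,
                 n_mirnas: int = 30) -> SyntheticStudySpec:
    """Study for the miRNA experiments: larger signatures, genome-wide
    universe, designated miRNA overlapping true targets at rate rho."""
    return SyntheticStudySpec(
        cancer_types=(("t", 6, 80),),
        universe_size=1200,
        planted_motifs=(PlantedMotifSpec(ic=ic),),
        n_mirnas=n_mirnas,
        mirna_target_overlap=rho,
        mirna_background=0.1,
        seed=seed,
    )


def _mirna_calls_for_study(study, alpha: float = 0.05) -> dict:
    """Hypergeometric calls per signature using the planted PWM's
    genome-wide target genes (the scanned universe is the test
    universe; discovery quality is a separate experiment)."""
    truth_pwm = study.truth.planted_pwms["planted_1"]
    targets = target_genes(truth_pwm, study.universe_promoters, cutoff=0.9)
    universe = frozenset(study.universe_promoters.entries)
    calls_by_gs = {}
    for sig in study.signatures:
        in_gs = targets.genes & frozenset(sig.genes)
        calls = [
            mirna_regulates_gs(sig.id, {"shared1": in_gs}, name, genes,
                               universe, alpha=alpha)
            for name, genes in sorted(study.mirna_sets.sets.items())
        ]
        calls_by_gs[sig.id] = calls
    return calls_by_gs


def common_mirna_recovery(
    n_seeds: int = 12,
    seed0: int = 1,
    rho: float = 0.5,
) -> dict:
    """How often the designated miRNA is called common at overlap rho."""
    recovered = 0
    for i in range(n_seeds):
        study = generate_study(_mirna_study(seed0 + 104729 * i, rho))
        calls = _mirna_calls_for_study(study)
        designated = study.truth.true_common_mirnas["t"]
        recovered += designated in common_mirnas(calls)
    return {
        "n_seeds": n_seeds,
        "recovered": recovered,
        "recovery_rate": recovered / n_seeds,
    }


def mirna_null_calibration(seed: int = 1, n_mirnas: int = 2200) -> dict:
    """Fraction of null miRNA overlap tests below p = 0.05.

    The study's miRNA sets are drawn independently of the motif's
    target genes (overlap rate equal to the background), so every
    (motif, miRNA) hypergeometric test is null.  The motif's
    genome-wide target set is tested against each miRNA set over the
    scanned universe: at these sizes the discrete test's attainable
    p-levels are dense, so the fraction below the nominal level should
    sit near it (per-signature-restricted tests are markedly more
    conservative; see the methods note).
    """
    study = generate_study(_mirna_study(seed, rho=0.1, n_mirnas=n_mirnas))
    truth_pwm = study.truth.planted_pwms["planted_1"]
    targets = target_genes(truth_pwm, study.universe_promoters, cutoff=0.9)
    universe = frozenset(study.universe_promoters.entries)
    designated = study.truth.true_common_mirnas["t"]
    pvals = []
    for name, genes in sorted(study.mirna_sets.sets.items()):
        if name == designated:
            continue  # constructed differently; not a clean null
        res = hypergeom_overlap_test(targets.genes, genes, universe,
                                     source_id="planted", set_name=name)
        pvals.append(res.p_value)
    pvals = np.asarray(pvals)
    return {
        "n_tests": len(pvals),
        "fraction_below_alpha": float((pvals < 0.05).mean()),
    }


def scan_oracle_agreement(n_pairs: int = 100, seed: int = 1) -> dict:
    """Vectorized scanning vs exhaustive brute force on seeded pairs."""
    rng = np.random.default_rng(seed)
    max_abs = 0.0
    mismatches = 0
    for _ in range(n_pairs):
        pwm = sample_pwm(int(rng.integers(8, 13)), 1.3, rng)
        seq = decode(rng.integers(0, 4, size=1500))
        got = scan_gene(pwm, seq)
        want_score, want_pos, want_strand = _brute_best(pwm.matrix, seq)
        max_abs = max(max_abs, abs(got.score - want_score))
        if (got.position, got.strand) != (want_pos, want_strand):
            mismatches += 1
    return {"n_pairs": n_pairs, "max_abs_diff": max_abs,
            "position_mismatches": mismatches}


def _brute_best(matrix: np.ndarray, promoter: str):
    order = {"A": 0, "C": 1, "G": 2, "T": 3}
    k = len(matrix)
    mins = matrix.min(axis=1)
    denom = float((matrix.max(axis=1) - mins).sum())
    best = None
    for strand, seq in (("+", promoter), ("-", revcomp(promoter))):
        L = len(seq)
        for i in range(L - k + 1):
            num = 0.0
            for j in range(k):
                num += matrix[j][order[seq[i + j]]] - mins[j]
            s = num / denom
            pos = i if strand == "+" else L - k - i
            key = (-s, pos, strand != "+")
            if best is None or key < best[0]:
                best = (key, s, pos, strand)
    return best[1:]


def exact_tail_agreement(seed: int = 1, n_cases: int = 60) -> dict:
    """Binomial and hypergeometric upper tails vs direct enumeration."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cases):
        N = int(rng.integers(3, 21))
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        x = int(rng.integers(0, min(K, n) + 1))
        got_b = float(stats.binom.sf(x - 1, n, K / N))
        want_b = sum(math.comb(n, i) * (K / N) ** i
                     * (1 - K / N) ** (n - i) for i in range(x, n + 1))
        got_h = float(stats.hypergeom.sf(x - 1, N, K, n))
        want_h = sum(
            math.comb(K, i) * math.comb(N - K, n - i)
            for i in range(x, min(K, n) + 1) if n - i <= N - K
        ) / math.comb(N, n)
        for got, want in ((got_b, want_b), (got_h, want_h)):
            if want > 0:
                worst = max(worst, abs(got - want) / want)
    return {"n_cases": n_cases, "max_rel_err": worst}
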