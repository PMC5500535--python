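"""Gene-set and miRNA-target enrichment of motif target genes.

Two exact tests drive the functional analysis:

* binomial: the overlap x between a motif combination's n target genes
  and a cancer-related gene set of size K in a universe of size N is
  referred to Binomial(n, K/N), upper tail P(X >= x);
* hypergeometric: the overlap between a motif's target genes within a
  signature and a miRNA's target set, both restricted to a common
  universe, upper tail of the hypergeometric distribution.

A miRNA is said to regulate a signature when its target set overlaps
(p < alpha, default 0.05) the target genes of strictly more than half
of the shared motifs in that signature, and a miRNA is a common
regulator of a cancer type when it regulates every signature of that
type.  No multiple-testing correction enters these calls (raw
thresholds follow the study design); Benjamini-Hochberg q-values are
reported alongside for transparency only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_MIRNA_ALPHA = 0.05


@dataclass(frozen=True)
class EnrichmentResult:
    target_source_id: str
    gene_set_name: str
    overlap: int
    n_targets: int
    set_size: int
    universe_size: int
    p_value: float

    def __post_init__(self) -> None:
        if self.overlap > min(self.n_targets, self.set_size):
            raise ValueError("overlap exceeds the smaller set")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class MirnaCall:
    mirna_name: str
    gs_id: str
    n_shared_motifs_in_gs: int
    n_significant: int
    regulates: bool

    def __post_init__(self) -> None:
        if self.n_significant > self.n_shared_motifs_in_gs:
            raise ValueError("more significant motifs than motifs")


def binomial_overlap_test(
    targets: frozenset[str] | set[str],
    gene_set: frozenset[str] | set[str],
    universe: frozenset[str] | set[str],
    source_id: str = "targets",
    set_name: str = "set",
) -> EnrichmentResult:
    """Exact binomial upper tail of the target/gene-set overlap.

    With n targets, baseline hit probability p0 = |set| / |universe|
    and overlap x, the p-value is P(X >= x) for X ~ Binomial(n, p0).
    An empty target set gives p = 1.
    """
    if not universe:
        raise ValueError("empty universe")
    if not set(targets) <= set(universe) or not set(gene_set) <= set(universe):
        raise ValueError("targets and gene set must lie within the universe")
    n = len(targets)
    x = len(set(targets) & set(gene_set))
    p0 = len(gene_set) / len(universe)
    p = 1.0 if n == 0 else float(stats.binom.sf(x - 1, n, p0))
    return EnrichmentResult(
        target_source_id=source_id, gene_set_name=set_name,
        overlap=x, n_targets=n, set_size=len(gene_set),
        universe_size=len(universe), p_value=min(1.0, p),
    )


def hypergeom_overlap_test(
    motif_targets: frozenset[str] | set[str],
    mirna_set: frozenset[str] | set[str],
    universe: frozenset[str] | set[str],
    source_id: str = "motif",
    set_name: str = "mirna",
) -> EnrichmentResult:
    """Exact hypergeometric upper tail of the overlap.

    All sets are restricted to the universe first; with N = |universe|,
    K successes (miRNA targets), n draws (motif targets) and overlap x,
    the p-value is P(X >= x) under Hypergeometric(N, K, n).
    """
    if not universe:
        raise ValueError("empty universe")
    uni = set(universe)
    targets = set(motif_targets) & uni
    mirna = set(mirna_set) & uni
    N, K, n = len(uni), len(mirna), len(targets)
    x = len(targets & mirna)
    p = float(stats.hypergeom.sf(x - 1, N, K, n))
    return EnrichmentResult(
        target_source_id=source_id, gene_set_name=set_name,
        overlap=x, n_targets=n, set_size=K,
        universe_size=N, p_value=min(1.0, p),
    )


def random_group_control(
    targets: frozenset[str] | set[str],
    gene_set: frozenset[str] | set[str],
    universe: list[str],
    n_reps: int = 100,
    seed: int = 0,
    source_id: str = "targets",
    set_name: str = "set",
) -> dict:
    """Compare the actual binomial p against random same-size gene groups.

    Each replicate draws |targets| genes uniformly without replacement
    from the universe and recomputes the test against the same gene
    set.  Reports the actual p, the replicate p-values, and the
    fraction of replicates the actual p beats (i.e. is smaller than).
    """
    if n_reps < 1:
        raise ValueError("need at least one replicate")
    if len(targets) > len(universe):
        raise ValueError("more targets than universe genes")
    rng = np.random.default_rng(seed)
    actual = binomial_overlap_test(targets, gene_set, frozenset(universe),
                                   source_id, set_name)
    genes = np.asarray(sorted(universe))
    rep_ps = []
    for _ in range(n_reps):
        draw = frozenset(rng.choice(genes, size=len(targets),
                                    replace=False).tolist())
        rep = binomial_overlap_test(draw, gene_set, frozenset(universe),
                                    "random", set_name)
        rep_ps.append(rep.p_value)
    rep_ps = np.array(rep_ps)
    return {
        "actual_p": actual.p_value,
        "replicate_p": rep_ps,
        "fraction_actual_beats": float((actual.p_value < rep_ps).mean()),
        "replicate_mean_p": float(rep_ps.mean()),
        "replicate_median_p": float(np.median(rep_ps)),
    }


def bh_qvalues(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg q-values (reported, never used for calls)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    if n == 0:
        return []
    order = np.argsort(p)
    q = np.empty(n)
    prev = 1.0
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        val = min(prev, p[i] * n / (rank + 1))
        q[i] = val
        prev = val
    return q.tolist()


def mirna_regulates_gs(
    gs_id: str,
    motif_targets_in_gs: dict[str, frozenset[str]],
    mirna_name: str,
    mirna_set: frozenset[str] | set[str],
    universe: frozenset[str] | set[str],
    alpha: float = DEFAULT_MIRNA_ALPHA,
) -> MirnaCall:
    """Does one miRNA regulate one signature?

    ``motif_targets_in_gs`` maps each shared motif to its target genes
    within the signature.  The call is positive iff the count of shared
    motifs with hypergeometric p < alpha strictly exceeds half of the
    shared motifs present.
    """
    n_motifs = len(motif_targets_in_gs)
    if n_motifs == 0:
        return MirnaCall(mirna_name=mirna_name, gs_id=gs_id,
                         n_shared_motifs_in_gs=0, n_significant=0,
                         regulates=False)
    n_sig = 0
    for motif_id, targets in motif_targets_in_gs.items():
        res = hypergeom_overlap_test(targets, mirna_set, universe,
                                     source_id=motif_id,
                                     set_name=mirna_name)
        if res.p_value < alpha:
            n_sig += 1
    return MirnaCall(
        mirna_name=mirna_name, gs_id=gs_id,
        n_shared_motifs_in_gs=n_motifs, n_significant=n_sig,
        regulates=n_sig > 0.5 * n_motifs,
    )


def common_mirnas(calls_by_gs: dict[str, list[MirnaCall]]) -> list[str]:
    """miRNAs that regulate every signature of the cancer type.

    ``calls_by_gs`` maps each signature id to its per-miRNA calls; a
    miRNA is common iff its call is positive in every signature.
    """
    if not calls_by_gs:
        return []
    per_gs_positive = [
        {c.mirna_name for c in calls if c.regulates}
        for calls in calls_by_gs.values()
    ]
    common = frozenset.intersection(*map(frozenset, per_gs_positive))
    return sorted(common)
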