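"""Enrichment statistics: binomial overlap, hypergeometric miRNA test.

The binomial test asks whether a motif combination's target genes
overlap a cancer-related gene set more than expected from the set's
share of the scanned universe; the hypergeometric test does the same
for a miRNA's target set against one motif's targets.
"""

from sigmotif import (
    binomial_overlap_test,
    hypergeom_overlap_test,
    random_group_control,
)

universe = [f"G{i:04d}" for i in range(1000)]
gene_set = frozenset(universe[:150])          # a cancer-related set
targets = frozenset(universe[100:160])        # 60 targets, 50 inside

res = binomial_overlap_test(targets, gene_set, frozenset(universe),
                            source_id="combo1", set_name="CSET_1")
print(f"binomial: overlap {res.overlap}/{res.n_targets} vs set of "
      f"{res.set_size} in {res.universe_size} genes -> p = {res.p_value:.2e}")

ctrl = random_group_control(targets, gene_set, universe, n_reps=500, seed=1)
print(f"actual p beats {ctrl['fraction_actual_beats']:.0%} of random "
      f"same-size gene groups (median random p = "
      f"{ctrl['replicate_median_p']:.3f})")

mirna = frozenset(universe[120:400])
res = hypergeom_overlap_test(targets, mirna, frozenset(universe),
                             source_id="shared1", set_name="mir-1")
print(f"hypergeometric: overlap {res.overlap} of {res.n_targets} motif "
      f"targets with a {res.set_size}-gene miRNA set -> "
      f"p = {res.p_value:.2e}")
# Small p-values say the overlap is larger than the set's share of the
# universe explains; the random-group control shows how often chance
# gene lists of the same size do as well.
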