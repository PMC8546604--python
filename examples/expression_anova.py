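"""RPKM and two-way ANOVA variance partitioning of a DGC gene set.

Generates a negative-binomial count table for 8 focal genes under 3
conditions (3 replicates) embedded among 50 stable background genes,
computes RPKM, and partitions the total variance into gene, condition,
gene x condition interaction, and residual components, followed by the
Bonferroni-corrected pairwise gene comparisons within each condition.
"""

import numpy as np

from cdgscan.expression import anova_partition, rpkm
from cdgscan.synth import make_counts

rng = np.random.default_rng(42)
n_focal, n_background = 8, 50
gene_fx = np.concatenate([rng.normal(0, 1.0, n_focal), np.zeros(n_background)])
inter = np.zeros((n_focal + n_background, 3))
inter[:n_focal] = [0.0, 0.5, 1.0] + rng.normal(0, 0.4, size=(n_focal, 3))

table, _ = make_counts(rng, gene_fx, np.zeros(3), inter, r=3, dispersion=0.05)
expr = rpkm(table)
focal = list(table.counts.index[:n_focal])
part = anova_partition(expr, table.library_conditions, genes=focal)

print("two-way ANOVA, % of total sum of squares:")
for effect in ("gene", "condition", "interaction", "residual"):
    print(f"  {effect:12s} {part.pct_ss[effect]:6.2f}%")
print(f"  (sum = {sum(part.pct_ss.values()):.4f}%)")
print()
sig = part.pairwise[part.pairwise["p_bonferroni"] < 0.05]
print(f"Bonferroni-significant gene pairs (per-condition families): {len(sig)}"
      f" of {len(part.pairwise)}")
print(sig.head(5).to_string(index=False))

# Gene identity explains most of the variance (planted gene effects),
# condition and interaction contribute the planted shifts, and the
# four %SS components sum to 100 exactly.
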