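"""The headline comparison: MICA vs a correlation/TOM baseline on
gene-by-environment structure.

Simulates the default desk-scale study (200 genes x 100 samples, five
planted modules, one of which couples its genes through two-condition
relationships with near-zero pooled correlation), runs both pipelines,
and reports how much of the GxE module each method keeps together, plus
the Pearson profile of all high-MIC pairs (the nonlinearity census).

Takes a couple of minutes: the MIC matrix over 19,900 pairs dominates.
"""

import warnings

import numpy as np

from mica import (
    default_design,
    mic_matrix,
    nonlinearity_census,
    pearson_matrix,
    run_baseline,
    run_mica,
    simulate_expression,
)

design = default_design(seed=1)
expr, truth = simulate_expression(design)
gxe_genes = truth.genes_of_kind(design, "gxe")
print(f"{expr.n_genes} genes x {expr.n_samples} samples; "
      f"{len(gxe_genes)} genes in the planted GxE module")

assoc = mic_matrix(expr)
result = run_mica(expr, n_modules=len(design.modules), cutoff=0.7,
                  burn_in=2000, sampling_iters=1000, seed=11, assoc=assoc)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    base_part, base_power = run_baseline(expr)

idx = {g: i for i, g in enumerate(expr.gene_ids)}


def coplacement(partition):
    lab = partition.labels()
    sub = np.array([lab[idx[g]] for g in gxe_genes])
    counts = np.bincount(sub[sub > 0], minlength=2)
    return counts.max() / len(gxe_genes)


print(f"\nGxE genes sharing one hardened MICA module:  {coplacement(result.partition):5.0%}")
print(f"GxE genes sharing one baseline module:       {coplacement(base_part):5.0%} "
      f"(baseline soft power {base_power})")

census = nonlinearity_census(expr, mic_cut=0.8, mic=assoc,
                             pearson=pearson_matrix(expr))
print(f"\ncensus: {census.n_high_mic} pairs with MIC > 0.8")
print(f"  fraction with |r| < 0.6 (nonlinear):      {census.frac_low:.3f}")
print(f"  fraction with |r| > 0.9 (strongly linear): {census.frac_high:.3f}")
print(
    "\nThe MIC pipeline keeps the GxE module intact; the correlation"
    "\nbaseline cannot see the condition-dependent relationships and"
    "\nleaves those genes unplaced or scattered."
)
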