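"""Detect fuzzy modules in a small planted network with the full pipeline.

Simulates three 8-gene modules (one pair of genes overlapping two
modules), builds the MIC association matrix, hard-thresholds it into an
unweighted network and runs the ICMg Gibbs sampler. Prints the fuzzy
membership rows of the overlap genes and the hardened partition sizes.
"""

import numpy as np

from mica import ModuleSpec, SimulationDesign, run_mica, simulate_expression

design = SimulationDesign(
    n_samples=60,
    modules=[ModuleSpec(8, 1.0, "linear", 0.2) for _ in range(3)],
    n_overlap_genes=2,
    n_background_genes=4,
    seed=1,
)
expr, truth = simulate_expression(design)

# 0.45 keeps the weaker overlap-gene links (MIC ~ 0.6) while dropping
# background pairs (MIC ~ 0.3)
result = run_mica(expr, n_modules=3, cutoff=0.45, burn_in=1000,
                  sampling_iters=1000, seed=2)
print(f"hard threshold {result.cutoff:.2f} -> {result.edges.n_edges} edges")

print("\nfuzzy memberships of the overlap genes (rows sum to 1):")
for g in expr.gene_ids:
    if g.startswith("OV_"):
        row = result.mm.mm[result.mm.gene_ids.index(g)]
        planted = sorted(truth.module_of[g])
        print(f"  {g}: {np.round(row, 2)}  (planted in modules {planted})")

print("\nhardened module sizes:", result.partition.module_sizes(),
      "| unplaced:", result.partition.n_unplaced)
print(
    "\nOverlap genes split their membership between their two planted"
    "\nmodules instead of being forced into one, which is the point of"
    "\nthe interaction-component model."
)
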