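"""Simulate a triplet multi-omics project and score its gene-sets.

Generates three 1000 x 30 tables with six sample clusters and 5 DE
gene-sets per cluster, integrates them by weighted joint factorization,
reconstructs per-sample gene-set scores from the top five components and
tests their significance.
"""

import numpy as np

from mogsa import (
    SimulationConfig, compute_gss, evaluate_auc, fit_mfa, gss_significance,
    preprocess_block, project_genesets, simulate_project, table_weights,
    variance_explained,
)

project = simulate_project(SimulationConfig(seed=1))
centered = [preprocess_block(b) for b in project.blocks]
weights = table_weights(centered, "mfa")
model = fit_mfa(centered, weights, n_components=5)

ve = variance_explained(model)
print(f"top-5 variance fraction: {ve.top_fraction(5):.3f}")
print("per-table share of the selected components (%):",
      {k: round(v, 1) for k, v in ve.block_shares_percent.items()})

space = project_genesets(model, project.annotations)
result = gss_significance(compute_gss(model, space), model, space)

auc = evaluate_auc(result.Y, project.truth)
print(f"AUC for recovering the planted DE gene-sets: {auc:.3f}")
print(f"significant (set, sample) pairs at BH p<0.05: "
      f"{(result.p_adj < 0.05).sum()} of {result.p_adj.size}")

# the score decomposes additively over tables and components
gap = np.abs(sum(result.by_block.values()) - result.Y).max()
print(f"max additivity error of the per-table decomposition: {gap:.2e}")

# The AUC near 0.8 means the low-rank scores rank truly DE (set, sample)
# pairs above null ones far better than chance (0.5); the three tables
# contribute roughly equal variance by construction.
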