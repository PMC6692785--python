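"""Remove a confounded component from gene-set score computation.

Builds two tables in which a 30-feature set is strongly aligned with a
smooth confounding gradient (think growth rate or doubling time).  The
gradient dominates component 1; excluding that single component from the
score reconstruction removes the set's spurious significance while all
other components stay untouched.
"""

import numpy as np

from mogsa import (
    compute_gss, exclude_components, fit_mfa, gss_significance,
    project_genesets, table_weights,
)
from mogsa.io_formats import AnnotationMatrix, OmicsBlock

rng = np.random.default_rng(7)
p, n = 400, 24
gradient = np.linspace(-1.5, 1.5, n)
target = rng.choice(p, 30, replace=False)

blocks = []
for name in ("rna", "protein"):
    v = rng.normal(size=(p, n))
    v[target] += 2.0 * gradient
    v -= v.mean(1, keepdims=True)
    blocks.append(OmicsBlock(name, [f"f{i}" for i in range(p)],
                             [f"s{j}" for j in range(n)], v))
G = np.zeros((p, 2), dtype=np.int8)
G[target, 0] = 1
G[rng.choice(np.setdiff1d(np.arange(p), target), 30, replace=False), 1] = 1
anns = [AnnotationMatrix(b.name, list(b.feature_ids),
                         ["confounded_set", "background_set"], G)
        for b in blocks]

model = fit_mfa(blocks, table_weights(blocks, "mfa"), n_components=5)
for label, m in (("with component 1", model),
                 ("component 1 excluded", exclude_components(model, [0]))):
    space = project_genesets(m, anns)
    res = gss_significance(compute_gss(m, space), m, space)
    print(f"{label}: min p of confounded set = {res.p[0].min():.2e}")

# With component 1 in, the confounded set is highly significant in the
# gradient-extreme samples; dropping the single confounded component
# leaves it indistinguishable from background.
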