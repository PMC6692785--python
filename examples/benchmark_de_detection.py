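"""Compare low-rank gene-set scores with the naive full-data product.

Simulates projects in a low signal-to-noise condition (DE mean shift
m=0.3) and scores each by (a) the five-component reconstruction and
(b) naive matrix multiplication (NMM) of the annotation with the
concatenated data.  Detection of the planted DE gene-sets is summarized
as the pooled AUC over all (set, sample) pairs.
"""

from mogsa import SimulationConfig, run_benchmark

table = run_benchmark([SimulationConfig(m_signal=0.3)],
                      n_projects=10, seed=7)
print(table[["m_signal", "n_deg", "method", "mean_auc", "sd_auc"]]
      .to_string(index=False))

# The low-rank scores win because the discarded components carry mostly
# feature-level noise: truncation filters it out before the gene-set
# summation, which raises the signal-to-noise of every score.
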