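# Methods

## Model

`mogsa` scores gene-sets per sample by combining three linear steps.

**1. Joint factorization.**  Each omics table X_k (features × samples,
feature-centered) is weighted by w_k and the weighted tables are
column-concatenated sample-wise: Z = [w_1 X_1ᵀ | … | w_K X_Kᵀ], an
n × Σp_k matrix.  Its thin SVD Z = U D Vᵀ gives sample scores P = U·D,
per-table loadings Q_k (the row blocks of V, jointly orthonormal) and
component variances λ_r = d_r².  Table k's contribution to λ_r is
d_r²·‖V_k[:, r]‖², so the per-table variance partition sums exactly to the
eigenvalues.  The default weight w_k = 1/σ₁(X_k) makes every weighted
table's leading eigenvalue 1, equalizing table influence regardless of
feature count or scale (a `weight_on: sigma_squared` switch divides by
σ₁² for users who prefer weighting on the eigenvalue scale; it changes
relative table influence, not the algebra).  STATIS weighting multiplies
the σ₁ weights by the leading eigenvector of the K × K RV-coefficient
matrix of the weighted tables (rescaled to mean 1), down-weighting a table
dissimilar from the consensus; it is applied *on top of* the σ₁ weights so
that scale equalization is never lost.

Component signs are fixed by making the largest-magnitude loading of each
component positive, so results do not depend on the SVD backend.  Nearly
equal eigenvalues make individual components rotationally unstable
(standard PCA behaviour); the per-index component matching used in the
stability analysis is documented as unreliable under such ties.

**2. Gene-set projection.**  A binary annotation matrix G_k marks which
features of table k belong to each gene-set; a feature may belong to
several sets.  Annotation columns are normalized per set by the
mapped-feature count pooled over all tables (`unit-sum`, the default), so
the resulting score is the mean reconstructed abundance of the set's member
features; `unit-norm` (divide by √count) and `none` are available.  The
normalized annotation is projected as supplementary columns,
W_k = G̃_kᵀ Q_k.  Because the loadings already live in the weighted-data
space, the table weight enters exactly once: with all components the score
matrix below reproduces Σ_k G̃_kᵀ (w_k X_k) to machine precision, which is
asserted in the tests against an independently coded naive-product oracle.

**3. Score reconstruction.**  Over a selected component set c,
Y = W[:, c] · P[:, c]ᵀ (gene-sets × samples).  Replacing W by one table's
W_k gives the per-table decomposition; single-column outer products give
the per-component decomposition; both sum exactly to Y.  Components are
selectable non-contiguously, so a component carrying unwanted variance
(a batch effect, culture artifact, or proliferation signal) can be
excluded; the change in Y equals that component's additive term exactly.

## Significance

The null model keeps each set's per-table mapped size g_k fixed and treats
membership as random.  For sample j let R_k = Q_k[:, c] D_c U[:, c]ᵀ be the
reconstruction of the weighted table and μ_kj, σ²_kj the mean and variance
of its column j over features.  A random set's score is a (scaled) simple
random sample sum, so under the normal approximation

    mean  = Σ_k ν g_k μ_kj
    var   = Σ_k ν² g_k σ²_kj (N_k − g_k)/(N_k − 1)

with ν the set's normalization constant and the finite-population factor
optional (`finite_population=False` drops it).  Two-sided p-values come
from the normal tail, which supports arbitrarily small p; an empirical
permutation mode (size-matched random sets, add-one smoothing) is retained
for verification and agrees with the analytic p on test fixtures.
Benjamini–Hochberg correction is applied across gene-sets within each
sample by default (`adjust="global"` pools the whole matrix).

The per-sample analytic null is verified in the tests against the
empirical moments of thousands of size-matched random sets (mean within
Monte-Carlo error, sd within 8%).  One caveat is documented rather than
hidden: pooling all set × sample p-values of a *single* project into one
Kolmogorov–Smirnov test treats them as independent, which they are not
when scores are reconstructed from very few components — samples of the
same cluster then share almost identical scores.  Marginal calibration
holds at any rank; the iid-based KS test applied to strongly rank-reduced
scores rejects in ~28% of null projects purely through this dependence.

## Component count selection

Sample labels of every table are permuted independently B times
(destroying cross-table alignment while preserving each table's marginal
structure) and the model is refit.  A component is significant when its
exact permutation p-value (1 + #{null λ ≥ observed λ})/(B + 1) is ≤ α;
with the defaults B = 20, α = 0.05 this requires beating every replicate.
A `max_null` rule (compare against the per-replicate maximum) is provided
for users who want family-wise control.  Numerically zero components
(feature centering leaves one null direction) are never reported.

## Gene influential score

For a set with g ≥ 2 mapped members, each member i is removed in turn, the
annotation renormalized, and the set's score profile recomputed over the
selected components; Δᵢ = Var(Y_full) − Var(Y_−i) across samples.  Scores
are Δᵢ / max_j Δⱼ, so the most influential gene scores exactly 1 whenever
any removal reduces variance; negative scores (removal increases variance)
are reported as-is.  If every Δ is non-positive, scores are normalized by
max |Δ| instead (all ≤ 0); identical member profiles receive exactly equal
scores by construction.

## Simulator

The generator emulates a matched triplet study.  Defaults: K = 3 tables of
p = 1000 features × n = 30 samples; m = 20 gene-sets of 50 genes; 6 equal
clusters of 5 samples; 5 DE sets per cluster; 10 DE genes per DE set; DE
shift mean m_signal = 0.5; cluster-effect sd s_cluster = 0.5.  Each entry is

    X_ij = α_i + β_{i,l(j)} + γ_ij + ε_ij

with α_i ~ N(0,1) (a per-feature baseline, removed by centering; its
distribution is irrelevant downstream), β_{i,l} ~ N(0, s_cluster) drawn per
(feature, cluster, table), ε ~ N(0,1), and γ_ij ~ N(m_signal, 1) exactly
when feature i is a DE gene of a set that is DE in sample j's cluster.
Drawing β per feature (not one scalar per cluster) is deliberate: a scalar
cluster offset shared by all features would collapse the six-cluster
structure onto a single component, whereas per-feature draws span the five
cluster contrasts — the regime the component-selection analysis assumes.
Non-overlap mode partitions each table's features into the 20 sets (exact
DE counts: 5 × n_deg DE features per table and cluster); overlap mode
samples memberships independently per set so features can belong to
several sets.  Set membership and DE genes are drawn independently per
table; DE set identity per cluster is shared across tables.  γ ≡ 0 is
expressed as `de_sets_per_cluster=0`.

Under these conditions the mean top-5 variance fraction of the joint
factorization is ≈ 24%, 32% and 55% for s_cluster = 0.3, 0.5, 1.0, and the
permutation test selects exactly five components in essentially every
project.  What the simulator does *not* emulate: heavy-tailed and count
distributions, platform-specific missingness, correlated noise between
features, unequal table sizes, or realistic annotation overlap structure —
so passing benchmarks here demonstrates correctness of the machinery and
the intrinsic-denoising effect, not performance on any particular real
platform.

The DE-detection benchmark scores each simulated project with (a) the
five-component reconstruction and (b) the naive full-rank product on the
concatenated, uniformly weighted tables (NMM), and reports the pooled AUC
over all (set, sample) pairs (per-sample averaged AUC as a secondary
column).  Default replicate count in tests and the acceptance script is 20
projects per condition, a deliberate scale-down of the original
100-replicate design that leaves the method ordering stable.

## Numerical choices and degenerate inputs

- All public matrices are features × samples; component indices are
  0-based in the Python API and 1-based on the CLI.
- TSV round-trips are bit-exact: floats are written with 17 significant
  digits and parsed with a correctly-rounded parser.
- Gene-set size filters: a set is kept iff total annotated genes ≤ 500 and
  features mapped across *all* tables ≥ 5 (both configurable); the total
  count governs the upper filter, the mapped count the lower one.
- Duplicate feature ids: configurable (error, or keep the row with the
  higher mean); missing values: error or zero-fill.
- Zero-variance tables, singleton gene-sets (for GIS), empty component
  sets, single-sample inputs and one-class truth matrices all raise
  informative errors rather than returning NaN.
- Ties in λ are returned in backend order after the sign convention.

## Limitations

- Linear method: nonlinear cross-table structure is not captured.
- Requires every sample measured in every table; no missing-sample
  handling.
- Feature-to-set mapping is exact string matching; identifier translation
  (e.g. phospho-site → protein → gene symbol) must be done upstream.
- The analytic significance model assumes member features are
  exchangeable with the table's feature population; sets whose members
  have atypical variance structure inherit the usual limitations of
  competitive gene-set nulls.
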