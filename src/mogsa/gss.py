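"""Gene-set projection and per-sample gene-set scores (GSS).

The binary annotation matrices are projected as supplementary columns into
the fitted latent space: with normalized annotation ``G~_k`` and table
weight ``w_k``, the per-table gene-set space is ``W_k = (w_k G~_k)' Q_k``
(sets x components) and the combined space is ``W = sum_k W_k``.  The
gene-set x sample score matrix is then ``Y = W_c P_c'`` over the selected
components ``c``.  With all components selected this equals the naive
matrix product of the normalized annotation with the weighted centered
data, so component selection is exactly a low-rank denoising of that naive
score.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import AnnotationMatrix
from .mfa import MFAModel

__all__ = [
    "GeneSetSpace",
    "GSSResult",
    "project_genesets",
    "compute_gss",
    "gss_significance",
    "exclude_components",
]


@dataclass
class GeneSetSpace:
    """Projected gene-set coordinates in the component space.

    ``W_blocks[name]`` is sets x R for one table; ``W`` is their sum.
    ``set_sizes[name]`` holds the mapped-feature count of each set within
    that table and ``norm_factors`` the per-set normalization constant
    applied to the annotation columns.
    """

    set_names: list[str]
    W: np.ndarray
    W_blocks: dict[str, np.ndarray]
    set_sizes: dict[str, np.ndarray]
    norm_factors: np.ndarray
    normalization: str


@dataclass
class GSSResult:
    """Gene-set x sample scores with decompositions and significance.

    ``Y`` (m x n) decomposes additively over tables (``by_block``) and over
    the used components (``by_component``).  ``p``/``p_adj`` are two-sided
    p-values and their BH adjustment, filled by :func:`gss_significance`.
    """

    set_names: list[str]
    sample_ids: list[str]
    Y: np.ndarray
    by_block: dict[str, np.ndarray]
    by_component: dict[int, np.ndarray]
    components_used: list[int]
    p: np.ndarray | None = None
    p_adj: np.ndarray | None = None


def project_genesets(model: MFAModel,
                     annotations: Sequence[AnnotationMatrix],
                     normalization: str = "unit-sum") -> GeneSetSpace:
    """Project annotation matrices into the fitted component space.

    Annotation columns are normalized per set by the mapped-feature count
    pooled over all tables: ``unit-sum`` divides by the count (the GSS then
    is a mean reconstructed abundance of member features), ``unit-norm`` by
    its square root, ``none`` leaves the 0/1 entries.
    """
    if normalization not in ("unit-sum", "unit-norm", "none"):
        raise ValueError(f"unknown normalization {normalization!r}")
    by_name = {a.block_name: a for a in annotations}
    if set(by_name) != set(model.block_names):
        raise ValueError("annotations must cover exactly the model's blocks")
    ref = annotations[0].set_names
    for a in annotations[1:]:
        if a.set_names != ref:
            raise ValueError(
                f"annotation for block {a.block_name!r} has a different "
                "gene-set order"
            )
    for nm in model.block_names:
        if by_name[nm].feature_ids != model.feature_ids[nm]:
            raise ValueError(
                f"annotation feature order does not match block {nm!r}"
            )

    sizes = {nm: by_name[nm].set_sizes.astype(float) for nm in model.block_names}
    total = np.sum([sizes[nm] for nm in model.block_names], axis=0)
    if np.any(total == 0):
        j = int(np.flatnonzero(total == 0)[0])
        raise ValueError(
            f"gene-set {ref[j]!r} maps to no feature in any block; "
            "filter it with build_annotation first"
        )
    if normalization == "unit-sum":
        nu = 1.0 / total
    elif normalization == "unit-norm":
        nu = 1.0 / np.sqrt(total)
    else:
        nu = np.ones_like(total)

    # The loadings Q_k already live in the weighted-data space (they are row
    # blocks of V from the SVD of the weighted concatenation), so the table
    # weight enters exactly once: W_k P' reproduces G~' (w_k X_k) at full
    # rank, the naive weighted matrix product.
    W_blocks = {}
    for nm in model.block_names:
        G = by_name[nm].G.astype(float) * nu          # p_k x m, normalized
        W_blocks[nm] = G.T @ model.block_loadings[nm]
    W = np.sum([W_blocks[nm] for nm in model.block_names], axis=0)
    return GeneSetSpace(
        set_names=list(ref), W=W, W_blocks=W_blocks,
        set_sizes={nm: s.astype(int) for nm, s in sizes.items()},
        norm_factors=nu, normalization=normalization,
    )


def compute_gss(model: MFAModel, space: GeneSetSpace,
                components: Sequence[int] | None = None) -> GSSResult:
    """Reconstruct gene-set x sample scores from the selected components.

    ``Y = W_c P_c'`` with ``c`` the used components; ``by_block`` replaces
    ``W`` by each table's ``W_k`` and ``by_component`` is the per-component
    outer product, so both decompositions sum exactly to ``Y``.
    """
    comps = list(model.selected_components if components is None else components)
    if not comps:
        raise ValueError("component set must be non-empty")
    if min(comps) < 0 or max(comps) >= model.n_components:
        raise ValueError("component index out of range")

    P = model.sample_scores
    Y = space.W[:, comps] @ P[:, comps].T
    by_block = {nm: space.W_blocks[nm][:, comps] @ P[:, comps].T
                for nm in model.block_names}
    by_component = {r: np.outer(space.W[:, r], P[:, r]) for r in comps}
    return GSSResult(
        set_names=list(space.set_names),
        sample_ids=list(model.sample_ids),
        Y=Y, by_block=by_block, by_component=by_component,
        components_used=comps,
    )


def _reconstructed_blocks(model: MFAModel, comps: Sequence[int]):
    return {nm: model.reconstruct_block(nm, comps) for nm in model.block_names}


def gss_significance(result: GSSResult, model: MFAModel, space: GeneSetSpace,
                     method: str = "analytic", n_draws: int = 1000,
                     seed: int | np.random.Generator | None = None,
                     finite_population: bool = True,
                     adjust: str = "per_sample") -> GSSResult:
    """Attach two-sided p-values and BH-adjusted p-values to a GSS result.

    The null keeps each set's per-table mapped size fixed and treats the
    membership as random.  ``analytic`` uses the normal approximation for a
    simple random sample of reconstructed feature values: for sample ``j``,
    mean ``sum_k nu g_kj mu_kj`` and variance
    ``sum_k nu^2 g_kj sigma^2_kj (N_k - g_kj)/(N_k - 1)`` where ``mu``,
    ``sigma^2`` are the mean/variance over features of table k's
    reconstructed (weighted) column ``j``; the finite-population factor can
    be dropped with ``finite_population=False``.  The normal tail supports
    arbitrarily small p-values.  ``permutation`` draws ``n_draws``
    size-matched random sets per table instead (empirical two-sided p with
    add-one smoothing).  BH is applied across gene-sets within each sample
    (``adjust="per_sample"``) or over the whole matrix (``"global"``).
    """
    if method not in ("analytic", "permutation"):
        raise ValueError(f"unknown method {method!r}")
    if adjust not in ("per_sample", "global"):
        raise ValueError(f"unknown adjust {adjust!r}")
    comps = result.components_used
    recon = _reconstructed_blocks(model, comps)
    m, n = result.Y.shape
    nu = space.norm_factors

    if method == "analytic":
        mean = np.zeros((m, n))
        var = np.zeros((m, n))
        for nm in model.block_names:
            R = recon[nm]                       # p_k x n
            N = R.shape[0]
            mu = R.mean(axis=0)                 # per sample
            s2 = R.var(axis=0, ddof=0)
            g = space.set_sizes[nm].astype(float)      # per set
            fpc = ((N - g) / (N - 1.0)) if (finite_population and N > 1) \
                else np.ones_like(g)
            mean += np.outer(nu * g, mu)
            var += np.outer(nu ** 2 * g * fpc, s2)
        sd = np.sqrt(var)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, (result.Y - mean) / sd, 0.0)
        p = 2.0 * stats.norm.sf(np.abs(z))
    else:
        if n_draws < 1:
            raise ValueError("n_draws must be >= 1 for permutation")
        rng = np.random.default_rng(seed) if not isinstance(
            seed, np.random.Generator) else seed
        p = np.empty((m, n))
        for s in range(m):
            null = np.zeros((n_draws, n))
            for nm in model.block_names:
                R = recon[nm]
                g = int(space.set_sizes[nm][s])
                if g == 0:
                    continue
                for b in range(n_draws):
                    idx = rng.choice(R.shape[0], g, replace=False)
                    null[b] += nu[s] * R[idx].sum(axis=0)
            center = null.mean(axis=0)
            dev = np.abs(result.Y[s] - center)
            exceed = (np.abs(null - center) >= dev[None, :]).sum(axis=0)
            p[s] = (1.0 + exceed) / (n_draws + 1.0)

    p = np.clip(p, 0.0, 1.0)
    p_adj = np.empty_like(p)
    if adjust == "per_sample":
        for j in range(n):
            p_adj[:, j] = multipletests(p[:, j], method="fdr_bh")[1]
    else:
        p_adj = multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)
    return replace(result, p=p, p_adj=p_adj)


def exclude_components(model: MFAModel, drop: Sequence[int]) -> MFAModel:
    """Return a model with the given components removed from the selection.

    Dropping e.g. a component aligned with a known confounder changes the
    downstream scores by exactly that component's additive contribution.
    ``drop`` must be a proper subset of the current selection.
    """
    drop_set = set(int(r) for r in drop)
    selected = set(model.selected_components)
    if not drop_set <= selected:
        raise ValueError("drop must be a subset of the selected components")
    remaining = sorted(selected - drop_set)
    if not remaining:
        raise ValueError("cannot drop all selected components")
    return model.with_selected(remaining)
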