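"""Per-block transformation/filtering, table weighting and RV coefficients.

A multi-table factorization is only meaningful if no single table dominates
by virtue of having more features or a larger scale.  The default weighting
divides each centered table by its first singular value, so every weighted
table has leading eigenvalue 1.  STATIS weighting additionally down-weights
tables that are dissimilar (by RV coefficient) from the consensus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import OmicsBlock

__all__ = ["TableWeighting", "preprocess_block", "rv_coefficient", "table_weights"]


@dataclass
class TableWeighting:
    """Positive per-table weights.

    ``method`` is one of ``mfa`` (1 / first singular value), ``statis``
    (RV-consensus weights applied on top of the mfa weights) or ``uniform``.
    """

    method: str
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("table weights must be positive")

    def weight_of(self, block_name: str) -> float:
        return self.weights[block_name]


def preprocess_block(block: OmicsBlock,
                     log_base: float | None = None,
                     offset: float = 0.0,
                     min_mean: float | None = None,
                     min_mad: float | None = None,
                     center: bool = True,
                     scale: bool = False) -> OmicsBlock:
    """Transform and filter one block.

    Steps are applied in a fixed order: log transform, feature filters
    (mean then MAD), per-feature centering across samples, optional
    unit-variance scaling.  Each applied step is appended to the block's
    provenance.

    Parameters
    ----------
    log_base
        If given, replace values by ``log(x + offset) / log(log_base)``.
        All ``x + offset`` must be positive.
    min_mean
        Keep features with mean (across samples) >= ``min_mean``.
    min_mad
        Keep features with (unscaled) median absolute deviation >
        ``min_mad``.
    center
        Subtract each feature's mean across samples (required before
        factorization).
    scale
        Additionally divide each feature by its standard deviation.
    """
    X = block.values.copy()
    features = list(block.feature_ids)
    steps: list[str] = []

    if log_base is not None:
        shifted = X + offset
        if np.any(shifted <= 0):
            raise ValueError(
                f"block {block.name!r}: log transform of non-positive value "
                f"(min {shifted.min():g} after offset {offset:g})"
            )
        X = np.log(shifted) / np.log(log_base)
        steps.append(f"log(base={log_base:g}, offset={offset:g})")

    keep = np.ones(X.shape[0], dtype=bool)
    if min_mean is not None:
        keep &= X.mean(axis=1) >= min_mean
        steps.append(f"filter(min_mean={min_mean:g})")
    if min_mad is not None:
        mad = stats.median_abs_deviation(X, axis=1, scale=1.0)
        keep &= mad > min_mad
        steps.append(f"filter(min_mad={min_mad:g})")
    if not keep.all():
        if not keep.any():
            raise ValueError(f"block {block.name!r}: filters removed all features")
        X = X[keep]
        features = [f for f, k in zip(features, keep) if k]

    if center:
        X = X - X.mean(axis=1, keepdims=True)
        steps.append("center")
    if scale:
        sd = X.std(axis=1, ddof=0, keepdims=True)
        if np.any(sd == 0):
            raise ValueError(
                f"block {block.name!r}: zero-variance feature cannot be scaled"
            )
        X = X / sd
        steps.append("scale")

    out = block.with_values(X, step="; ".join(steps) if steps else "identity",
                            feature_ids=features)
    return out


def _centered(values: np.ndarray) -> np.ndarray:
    return values - values.mean(axis=1, keepdims=True)


def rv_coefficient(A: OmicsBlock, B: OmicsBlock) -> float:
    """Matrix correlation between two sample-matched tables, in [0, 1].

    RV = trace(S_A S_B) / sqrt(trace(S_A^2) trace(S_B^2)) where ``S_X`` is
    the n x n sample cross-product of the feature-centered table.  RV(A, A)
    is 1; orthogonal sample profiles give 0.  Symmetric in its arguments and
    invariant to feature permutation and orthogonal rotation of features.
    """
    if A.sample_ids != B.sample_ids:
        raise ValueError("rv_coefficient requires identical sample_ids")
    Sa = _centered(A.values).T @ _centered(A.values)
    Sb = _centered(B.values).T @ _centered(B.values)
    den = np.sqrt(np.sum(Sa * Sa) * np.sum(Sb * Sb))
    if den == 0:
        raise ValueError("rv_coefficient undefined for a zero-variance block")
    return float(np.sum(Sa * Sb) / den)


def rv_matrix(blocks: Sequence[OmicsBlock]) -> np.ndarray:
    """Pairwise RV coefficients, K x K (diagonal = 1)."""
    K = len(blocks)
    R = np.eye(K)
    for i in range(K):
        for j in range(i + 1, K):
            R[i, j] = R[j, i] = rv_coefficient(blocks[i], blocks[j])
    return R


def table_weights(blocks: Sequence[OmicsBlock], method: str = "mfa",
                  weight_on: str = "sigma") -> TableWeighting:
    """Compute per-table weights for the joint factorization.

    ``mfa`` sets weight_k = 1 / sigma1(X_k) (first singular value of the
    centered table), so each weighted table has leading eigenvalue 1;
    ``weight_on="sigma_squared"`` divides by sigma1^2 instead.  ``statis``
    multiplies the mfa weights by factors proportional to the leading
    eigenvector of the K x K RV matrix (rescaled to mean 1), down-weighting
    a table dissimilar from the consensus.  ``uniform`` returns all 1.
    """
    if not blocks:
        raise ValueError("at least one block required")
    if method not in ("mfa", "statis", "uniform"):
        raise ValueError(f"unknown weighting method {method!r}")
    if weight_on not in ("sigma", "sigma_squared"):
        raise ValueError(f"unknown weight_on {weight_on!r}")

    names = [b.name for b in blocks]
    if method == "uniform":
        return TableWeighting("uniform", dict.fromkeys(names, 1.0))

    mfa_w = {}
    for b in blocks:
        sigma1 = np.linalg.svd(_centered(b.values), compute_uv=False)[0]
        if sigma1 == 0:
            raise ValueError(f"block {b.name!r} is constant; weight undefined")
        mfa_w[b.name] = 1.0 / (sigma1 if weight_on == "sigma" else sigma1 ** 2)
    if method == "mfa":
        return TableWeighting("mfa", mfa_w)

    # statis: leading eigenvector of the RV matrix of the mfa-weighted tables
    weighted = [b.with_values(b.values * mfa_w[b.name], step="mfa-weight")
                for b in blocks]
    R = rv_matrix(weighted)
    vals, vecs = np.linalg.eigh(R)
    lead = np.abs(vecs[:, -1])          # Perron vector, nonnegative
    lead = lead / lead.mean()           # rescale to mean 1
    return TableWeighting(
        "statis", {n: mfa_w[n] * f for n, f in zip(names, lead)}
    )
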