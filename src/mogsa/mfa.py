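"""Joint factorization of weighted tables (multiple factor analysis).

MFA is PCA of the column-concatenated, per-table weighted data
``Z = [w_1 X_1' | ... | w_K X_K']`` (samples x total features).  The thin
SVD ``Z = U D V'`` yields sample scores ``P = U D``, per-table feature
loadings ``Q_k`` (row blocks of ``V``) and component variances
``lambda_r = d_r^2``.  Component indices are 0-based throughout the Python
API.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import OmicsBlock
from .preprocess import TableWeighting, table_weights

__all__ = [
    "MFAModel",
    "fit_mfa",
    "permutation_component_test",
    "PermutationTestResult",
    "variance_explained",
    "VarianceExplained",
    "stability_analysis",
    "save_model",
    "load_model",
]


@dataclass
class MFAModel:
    """Result of a joint factorization.

    Attributes
    ----------
    sample_scores
        ``P = U D``, shape (n, R).
    block_loadings
        Map block name -> its row block of ``V`` (p_k x R); the concatenated
        loadings have orthonormal columns.
    singular_values
        ``d``, length R, non-increasing.
    per_block_variance
        (K, R); entry [k, r] is table k's contribution to eigenvalue
        ``lambda_r = d_r^2``; columns sum to the eigenvalues.
    selected_components
        0-based component indices used for downstream scoring.
    """

    sample_ids: list[str]
    block_names: list[str]
    feature_ids: dict[str, list[str]]
    sample_scores: np.ndarray
    block_loadings: dict[str, np.ndarray]
    singular_values: np.ndarray
    block_weights: TableWeighting
    selected_components: list[int]
    per_block_variance: np.ndarray

    @property
    def eigenvalues(self) -> np.ndarray:
        """Component variances lambda = d^2."""
        return self.singular_values ** 2

    @property
    def n_components(self) -> int:
        return len(self.singular_values)

    @property
    def left_vectors(self) -> np.ndarray:
        """``U`` recovered from P = U D (zero where d == 0)."""
        d = self.singular_values
        U = np.zeros_like(self.sample_scores)
        nz = d > 0
        U[:, nz] = self.sample_scores[:, nz] / d[nz]
        return U

    def reconstruct_block(self, name: str,
                          components: Sequence[int] | None = None) -> np.ndarray:
        """Low-rank reconstruction of the *weighted, centered* table.

        Returns ``w_k X_k`` restricted to the given components
        (default: the model's selected components), shape (p_k, n).
        """
        comps = list(self.selected_components if components is None
                     else components)
        Q = self.block_loadings[name][:, comps]
        d = self.singular_values[comps]
        U = self.left_vectors[:, comps]
        return (Q * d) @ U.T

    def with_selected(self, components: Sequence[int]) -> "MFAModel":
        comps = sorted(set(int(c) for c in components))
        if not comps:
            raise ValueError("selected_components must be non-empty")
        if comps[0] < 0 or comps[-1] >= self.n_components:
            raise ValueError("component index out of range")
        return replace(self, selected_components=comps)


def _check_aligned(blocks: Sequence[OmicsBlock]) -> None:
    ref = blocks[0].sample_ids
    for b in blocks[1:]:
        if b.sample_ids != ref:
            raise ValueError(
                f"block {b.name!r} sample ids differ from block "
                f"{blocks[0].name!r}; all tables must share samples in order"
            )


def fit_mfa(blocks: Sequence[OmicsBlock],
            weighting: TableWeighting | None = None,
            n_components: int | None = None) -> MFAModel:
    """Fit the joint factorization of weighted, centered tables.

    Parameters
    ----------
    blocks
        Feature-centered tables sharing ``sample_ids`` in identical order.
    weighting
        Per-table weights; default computes mfa weights (1 / sigma1).
    n_components
        Number of leading components to mark selected for downstream
        scoring; default ``min(n - 1, total features)``.  The full spectrum
        is always stored.
    """
    if not blocks:
        raise ValueError("at least one block required")
    _check_aligned(blocks)
    n = blocks[0].n_samples
    if n < 2:
        raise ValueError("at least two samples required for factorization")
    if weighting is None:
        weighting = table_weights(blocks, "mfa")

    names = [b.name for b in blocks]
    w = [weighting.weight_of(nm) for nm in names]
    Z = np.concatenate([(wk * b.values).T for wk, b in zip(w, blocks)], axis=1)
    total_p = Z.shape[1]
    max_rank = min(n - 1, total_p)
    if n_components is not None and not (1 <= n_components <= max_rank):
        raise ValueError(
            f"n_components must be in [1, {max_rank}] (= min(n-1, total features))"
        )

    U, d, Vt = np.linalg.svd(Z, full_matrices=False)
    V = Vt.T
    # sign convention: largest-magnitude loading of each component positive
    flip = np.sign(V[np.abs(V).argmax(axis=0), np.arange(V.shape[1])])
    flip[flip == 0] = 1.0
    V *= flip
    U *= flip

    P = U * d
    sizes = [b.n_features for b in blocks]
    offsets = np.cumsum([0] + sizes)
    loadings = {nm: V[offsets[k]:offsets[k + 1]]
                for k, nm in enumerate(names)}
    pbv = np.stack([
        (d ** 2) * np.sum(loadings[nm] ** 2, axis=0) for nm in names
    ])

    n_sel = n_components if n_components is not None else max_rank
    return MFAModel(
        sample_ids=list(blocks[0].sample_ids),
        block_names=names,
        feature_ids={b.name: list(b.feature_ids) for b in blocks},
        sample_scores=P,
        block_loadings=loadings,
        singular_values=d,
        block_weights=weighting,
        selected_components=list(range(n_sel)),
        per_block_variance=pbv,
    )


@dataclass
class PermutationTestResult:
    observed: np.ndarray          # eigenvalues, length R
    null: np.ndarray              # (B, R) eigenvalues under permutation
    significant: list[int]        # 0-based indices with observed > null quantile
    alpha: float


def permutation_component_test(blocks: Sequence[OmicsBlock],
                               weighting: TableWeighting | None = None,
                               B: int = 20,
                               alpha: float = 0.05,
                               rule: str = "per_component",
                               seed: int | np.random.Generator | None = None,
                               ) -> PermutationTestResult:
    """Sample-permutation null for the number of informative components.

    Each replicate independently permutes the sample order of every table,
    destroying the cross-table correlation while preserving each table's
    marginal structure, then refits.  A component is significant when its
    exact permutation p-value, ``(1 + #{null >= observed}) / (B + 1)``, is
    at most ``alpha`` — against its own null (``rule="per_component"``) or
    against the per-replicate maximum (``rule="max_null"``).  With B=20 and
    alpha=0.05 this requires the observed variance to exceed every null
    replicate.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if rule not in ("per_component", "max_null"):
        raise ValueError(f"unknown rule {rule!r}")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    if weighting is None:
        weighting = table_weights(blocks, "mfa")

    observed = fit_mfa(blocks, weighting).eigenvalues
    null = np.empty((B, len(observed)))
    n = blocks[0].n_samples
    for b in range(B):
        permuted = []
        for blk in blocks:
            perm = rng.permutation(n)
            permuted.append(OmicsBlock(
                name=blk.name,
                feature_ids=list(blk.feature_ids),
                sample_ids=list(blk.sample_ids),  # labels kept, values shuffled
                values=blk.values[:, perm],
                provenance=blk.provenance + ["permute_samples"],
            ))
        lam = fit_mfa(permuted, weighting).eigenvalues
        null[b, : len(lam)] = lam[: null.shape[1]]

    ref = null if rule == "per_component" else \
        np.broadcast_to(null.max(axis=1)[:, None], null.shape)
    p = (1.0 + (ref >= observed[None, :]).sum(axis=0)) / (B + 1.0)
    # ignore numerically-zero components (centering leaves one null direction)
    nonzero = observed > 1e-12 * observed[0]
    significant = [int(r) for r in np.flatnonzero((p <= alpha) & nonzero)]
    return PermutationTestResult(observed, null, significant, alpha)


@dataclass
class VarianceExplained:
    fractions: np.ndarray          # lambda_r / sum(lambda), full spectrum
    block_shares_percent: dict[str, float]  # over the selected components
    components: list[int]

    def top_fraction(self, r: int) -> float:
        return float(self.fractions[:r].sum())


def variance_explained(model: MFAModel) -> VarianceExplained:
    """Per-component variance fractions and per-table shares.

    Fractions are over the full stored spectrum; table shares are the
    percentage each table contributes to the total variance of the model's
    selected components.
    """
    lam = model.eigenvalues
    fractions = lam / lam.sum()
    comps = model.selected_components
    sub = model.per_block_variance[:, comps]
    total = sub.sum()
    shares = {nm: float(100.0 * sub[k].sum() / total)
              for k, nm in enumerate(model.block_names)}
    return VarianceExplained(fractions, shares, list(comps))


def stability_analysis(blocks: Sequence[OmicsBlock],
                       weighting_method: str = "mfa",
                       mode: str = "drop_features",
                       fraction: float = 0.1,
                       B: int = 10,
                       n_components: int = 5,
                       seed: int | np.random.Generator | None = None,
                       ) -> np.ndarray:
    """Robustness of components to data perturbation.

    ``leave_one_sample_out`` refits once per left-out sample;
    ``drop_features`` refits ``B`` times with ``fraction`` of each table's
    features removed at random.  Components are matched by index and the
    mean absolute Pearson correlation of sample scores (on the shared
    samples) with the full-data model is returned, one value per component.
    """
    if mode not in ("leave_one_sample_out", "drop_features"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "drop_features" and not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed

    full = fit_mfa(blocks, table_weights(blocks, weighting_method))
    if n_components > full.n_components:
        raise ValueError("n_components exceeds the rank of the full model")
    P_full = full.sample_scores[:, :n_components]
    n = len(full.sample_ids)

    def refit_scores(sub_blocks, sample_idx):
        model = fit_mfa(sub_blocks, table_weights(sub_blocks, weighting_method))
        if n_components > model.n_components:
            raise ValueError("n_components exceeds the perturbed model rank")
        return model.sample_scores[:, :n_components], sample_idx

    replicates = []
    if mode == "leave_one_sample_out":
        for j in range(n):
            keep = [i for i in range(n) if i != j]
            subs = [OmicsBlock(b.name, list(b.feature_ids),
                               [b.sample_ids[i] for i in keep],
                               b.values[:, keep], list(b.provenance))
                    for b in blocks]
            replicates.append(refit_scores(subs, keep))
    else:
        for _ in range(B):
            subs = []
            for b in blocks:
                p = b.n_features
                n_drop = int(round(fraction * p))
                keep_f = np.sort(rng.choice(p, p - n_drop, replace=False))
                subs.append(OmicsBlock(
                    b.name, [b.feature_ids[i] for i in keep_f],
                    list(b.sample_ids), b.values[keep_f], list(b.provenance)))
            replicates.append(refit_scores(subs, list(range(n))))

    corr = np.zeros((len(replicates), n_components))
    for i, (P_sub, idx) in enumerate(replicates):
        ref = P_full[idx]
        for r in range(n_components):
            a, bvec = ref[:, r], P_sub[:, r]
            sa, sb = a.std(), bvec.std()
            corr[i, r] = 1.0 if sa == 0 and sb == 0 else abs(
                np.corrcoef(a, bvec)[0, 1]) if sa > 0 and sb > 0 else 0.0
    return corr.mean(axis=0)


_SCHEMA_VERSION = 1


def save_model(model: MFAModel, path: str | Path) -> None:
    """Serialize a model to a single ``.npz`` archive with a JSON manifest."""
    manifest = {
        "schema_version": _SCHEMA_VERSION,
        "sample_ids": model.sample_ids,
        "block_names": model.block_names,
        "feature_ids": model.feature_ids,
        "selected_components": model.selected_components,
        "weighting_method": model.block_weights.method,
        "weights": model.block_weights.weights,
    }
    arrays = {
        "sample_scores": model.sample_scores,
        "singular_values": model.singular_values,
        "per_block_variance": model.per_block_variance,
    }
    for nm in model.block_names:
        arrays[f"loadings::{nm}"] = model.block_loadings[nm]
    np.savez(path, manifest=np.frombuffer(
        json.dumps(manifest).encode(), dtype=np.uint8), **arrays)


def load_model(path: str | Path) -> MFAModel:
    with np.load(path) as npz:
        manifest = json.loads(bytes(npz["manifest"]).decode())
        if manifest["schema_version"] != _SCHEMA_VERSION:
            raise ValueError("unsupported model schema version")
        loadings = {nm: npz[f"loadings::{nm}"]
                    for nm in manifest["block_names"]}
        return MFAModel(
            sample_ids=manifest["sample_ids"],
            block_names=manifest["block_names"],
            feature_ids=manifest["feature_ids"],
            sample_scores=npz["sample_scores"],
            block_loadings=loadings,
            singular_values=npz["singular_values"],
            block_weights=TableWeighting(manifest["weighting_method"],
                                         manifest["weights"]),
            selected_components=list(manifest["selected_components"]),
            per_block_variance=npz["per_block_variance"],
        )
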