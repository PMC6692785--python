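"""Gene influential score (GIS): leave-one-out importance of set members.

For each mapped member feature of a gene-set the set's score profile is
recomputed with that feature removed (annotation renormalized), and the
drop in across-sample variance of the profile is recorded.  Normalizing by
the largest drop gives scores with maximum exactly 1; a negative score
means removing the feature *increases* the profile variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import AnnotationMatrix
from .mfa import MFAModel

__all__ = ["GISResult", "gene_influential_score"]


@dataclass
class GISResult:
    """Per-gene influence on one gene-set's score profile.

    ``table`` has one row per mapped member (columns: gene, block,
    delta_var, score), sorted by score descending with lexicographic
    tie-break.
    """

    set_name: str
    table: pd.DataFrame

    @property
    def scores(self) -> pd.Series:
        return self.table.set_index("gene")["score"]


def gene_influential_score(model: MFAModel,
                           annotations: Sequence[AnnotationMatrix],
                           set_name: str,
                           normalization: str = "unit-sum",
                           components: Sequence[int] | None = None,
                           ) -> GISResult:
    """Leave-one-out influence of each member feature of ``set_name``.

    The set's score profile uses the model's selected components (or
    ``components``) and the given annotation normalization, consistent with
    :func:`mogsa.gss.compute_gss`.  Requires at least two mapped features.
    """
    if normalization not in ("unit-sum", "unit-norm", "none"):
        raise ValueError(f"unknown normalization {normalization!r}")
    comps = list(model.selected_components if components is None else components)

    # per-member reconstructed profile rows: (feature, block, w_k x_hat row)
    members: list[tuple[str, str, np.ndarray]] = []
    for ann in annotations:
        if ann.block_name not in model.block_names:
            raise ValueError(f"unknown block {ann.block_name!r}")
        if set_name not in ann.set_names:
            raise ValueError(f"gene-set {set_name!r} not in the annotation")
        j = ann.set_names.index(set_name)
        rows = np.flatnonzero(ann.G[:, j])
        if rows.size:
            R = model.reconstruct_block(ann.block_name, comps)
            for i in rows:
                members.append((ann.feature_ids[i], ann.block_name, R[i]))
    g_total = len(members)
    if g_total < 2:
        raise ValueError(
            f"gene-set {set_name!r} has {g_total} mapped feature(s); "
            "leave-one-out requires at least 2"
        )

    def norm_factor(count: int) -> float:
        if normalization == "unit-sum":
            return 1.0 / count
        if normalization == "unit-norm":
            return 1.0 / np.sqrt(count)
        return 1.0

    total = np.sum([row for _, _, row in members], axis=0)
    y_full = norm_factor(g_total) * total
    var_full = y_full.var()

    delta = np.empty(g_total)
    for idx, (_, _, row) in enumerate(members):
        y_loo = norm_factor(g_total - 1) * (total - row)
        delta[idx] = var_full - y_loo.var()

    dmax = delta.max()
    if dmax > 0:
        score = delta / dmax
    elif np.any(delta != 0):
        score = delta / np.abs(delta).max()
    else:
        score = np.zeros_like(delta)

    table = pd.DataFrame({
        "gene": [g for g, _, _ in members],
        "block": [b for _, b, _ in members],
        "delta_var": delta,
        "score": score,
    }).sort_values(["score", "gene"], ascending=[False, True],
                   kind="stable").reset_index(drop=True)
    return GISResult(set_name=set_name, table=table)
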