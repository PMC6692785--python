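"""Reading and writing omics matrices and gene-set collections.

All matrix files are tab-separated text, features in rows and samples in
columns: the first column holds feature identifiers under the header
``feature_id``, the remaining header cells are sample identifiers.  The same
orientation (features x samples) is used for every in-memory matrix in this
package unless a docstring says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OmicsBlock",
    "GeneSetCollection",
    "AnnotationMatrix",
    "read_matrix",
    "write_matrix",
    "read_gmt",
    "write_gmt",
    "build_annotation",
]


@dataclass
class OmicsBlock:
    """One named omics data table (features x samples).

    Parameters
    ----------
    name
        Label for the table (e.g. ``"rna"``, ``"protein"``).
    feature_ids
        Ordered, unique feature identifiers; length ``p``.
    sample_ids
        Ordered, unique sample identifiers; length ``n``.
    values
        Dense float matrix of shape ``(p, n)``; all entries finite.
    provenance
        Ordered log of the processing steps already applied.
    """

    name: str
    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"block {self.name!r}: values must be 2-D")
        p, n = self.values.shape
        if p != len(self.feature_ids) or n != len(self.sample_ids):
            raise ValueError(
                f"block {self.name!r}: shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != p:
            raise ValueError(f"block {self.name!r}: duplicate feature ids")
        if len(set(self.sample_ids)) != n:
            raise ValueError(f"block {self.name!r}: duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"block {self.name!r}: non-finite values present")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    def with_values(self, values: np.ndarray, step: str,
                    feature_ids: Sequence[str] | None = None) -> "OmicsBlock":
        """Return a copy with new values and a provenance entry appended."""
        return OmicsBlock(
            name=self.name,
            feature_ids=list(feature_ids) if feature_ids is not None
            else list(self.feature_ids),
            sample_ids=list(self.sample_ids),
            values=values,
            provenance=self.provenance + [step],
        )


@dataclass
class GeneSetCollection:
    """A named collection of gene sets (GMT semantics).

    ``sets`` maps set name -> ordered unique member gene identifiers.
    """

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            seen: dict[str, None] = {}
            for g in members:
                seen.setdefault(str(g), None)
            self.sets[name] = list(seen)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets


@dataclass
class AnnotationMatrix:
    """Binary feature x gene-set incidence matrix for one block.

    ``G[i, j] == 1`` iff feature ``i`` of the block is a member of retained
    gene-set ``j``.  A feature may belong to several sets, so row sums may
    exceed 1.  ``set_names`` has identical order across the annotation
    matrices of one analysis.
    """

    block_name: str
    feature_ids: list[str]
    set_names: list[str]
    G: np.ndarray
    normalization: str = "none"

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G)
        if self.G.shape != (len(self.feature_ids), len(self.set_names)):
            raise ValueError(
                f"annotation for block {self.block_name!r}: G shape "
                f"{self.G.shape} != ({len(self.feature_ids)}, {len(self.set_names)})"
            )
        if not np.isin(self.G, (0, 1)).all():
            raise ValueError("annotation entries must be 0/1")
        if self.normalization not in ("unit-sum", "unit-norm", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @property
    def set_sizes(self) -> np.ndarray:
        """Mapped-feature count per set within this block."""
        return self.G.sum(axis=0)


def read_matrix(path: str | Path, dedup_policy: str = "error",
                missing: str = "error") -> OmicsBlock:
    """Read a features x samples TSV matrix into an :class:`OmicsBlock`.

    Parameters
    ----------
    path
        Tab-separated file; first column feature ids, header row sample ids.
    dedup_policy
        ``"error"`` raises on duplicated feature ids; ``"keep_higher_mean"``
        keeps, for each duplicated id, the row with the highest mean (the
        usual convention when a gene symbol maps to several probes).
    missing
        ``"error"`` (default) rejects empty/NA cells; ``"zero"`` replaces
        them with 0.
    """
    if dedup_policy not in ("error", "keep_higher_mean"):
        raise ValueError(f"unknown dedup_policy {dedup_policy!r}")
    if missing not in ("error", "zero"):
        raise ValueError(f"unknown missing policy {missing!r}")
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                      keep_default_na=False)
    raw = raw.mask(raw.isin(["", "NA", "NaN", "nan"]))
    numeric = raw.apply(pd.to_numeric, errors="coerce")

    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path.name}: non-numeric value {raw.iat[i, j]!r} at "
            f"feature {raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    miss = numeric.isna().to_numpy()
    if miss.any():
        if missing == "error":
            i, j = np.argwhere(miss)[0]
            raise ValueError(
                f"{path.name}: missing value at feature {raw.index[i]!r}, "
                f"sample {raw.columns[j]!r} (set missing='zero' to zero-fill)"
            )
    # final conversion through numpy's correctly-rounded string parser, so
    # that write_matrix -> read_matrix is bit-exact
    cells = raw.to_numpy(dtype=object)
    cells[miss] = "0"
    numeric = pd.DataFrame(cells.astype(np.float64), index=raw.index,
                           columns=raw.columns)

    if numeric.index.duplicated().any():
        if dedup_policy == "error":
            dups = numeric.index[numeric.index.duplicated()].unique().tolist()
            raise ValueError(f"{path.name}: duplicated feature ids {dups[:5]}")
        # keep the duplicate row with the highest mean value
        means = numeric.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        numeric = numeric.iloc[order]
        numeric = numeric[~numeric.index.duplicated(keep="first")]

    steps = [f"read_matrix({path.name}, dedup_policy={dedup_policy}, "
             f"missing={missing})"]
    return OmicsBlock(
        name=path.stem,
        feature_ids=list(numeric.index),
        sample_ids=list(numeric.columns),
        values=numeric.to_numpy(dtype=float),
        provenance=steps,
    )


def write_matrix(block: OmicsBlock, path: str | Path) -> None:
    """Write a block as TSV (round-trips exactly through :func:`read_matrix`).

    Floats are written with 17 significant digits, enough to reproduce any
    double exactly on re-parse.
    """
    block.to_frame().to_csv(path, sep="\t", index_label="feature_id",
                            float_format="%.17g")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name TAB description TAB gene*``."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path.name}:{lineno}: expected at least "
                    f"'name<TAB>description', got {len(fields)} field(s)"
                )
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            sets[name] = [g for g in members if g]
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def build_annotation(collection: GeneSetCollection,
                     blocks: Sequence[OmicsBlock],
                     min_mapped: int = 5,
                     max_size: int = 500) -> list[AnnotationMatrix]:
    """Construct per-block binary annotation matrices with size filtering.

    A gene set is retained iff its total number of annotated genes is at most
    ``max_size`` and the number of its genes that map to features, counted
    over the concatenated features of *all* blocks, is at least
    ``min_mapped``.  Mapping is exact string match between feature ids and
    gene identifiers.  The retained-set order is shared across blocks and
    independent of block order.
    """
    if min_mapped < 1:
        raise ValueError("min_mapped must be >= 1")
    if not blocks:
        raise ValueError("at least one block required")

    feature_sets = [set(b.feature_ids) for b in blocks]
    retained: list[str] = []
    for name, members in collection.sets.items():
        if len(members) > max_size:
            continue
        mapped = sum(sum(g in fs for g in members) for fs in feature_sets)
        if mapped >= min_mapped:
            retained.append(name)
    if not retained:
        raise ValueError(
            "no gene-set passed the size filters; consider lowering "
            f"min_mapped (={min_mapped}) or raising max_size (={max_size})"
        )

    out = []
    for block in blocks:
        index = {f: i for i, f in enumerate(block.feature_ids)}
        G = np.zeros((block.n_features, len(retained)), dtype=np.int8)
        for j, name in enumerate(retained):
            for g in collection.sets[name]:
                i = index.get(g)
                if i is not None:
                    G[i, j] = 1
        out.append(AnnotationMatrix(
            block_name=block.name,
            feature_ids=list(block.feature_ids),
            set_names=list(retained),
            G=G,
        ))
    return out
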