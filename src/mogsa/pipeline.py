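"""End-to-end orchestration: read, preprocess, weight, fit, score, write.

A single :class:`AnalysisConfig` (loadable from YAML) drives the whole
analysis; every source of randomness flows through one seeded generator
and a JSON manifest records versions, the seed, the selected components
and every threshold, so a rerun with identical config and seed reproduces
the outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .io_formats import build_annotation, read_gmt, read_matrix
from .preprocess import preprocess_block, table_weights
from .mfa import fit_mfa, permutation_component_test, save_model, variance_explained
from .gss import compute_gss, exclude_components, gss_significance, project_genesets

logger = logging.getLogger("mogsa")

__all__ = ["AnalysisConfig", "run_pipeline"]


@dataclass
class AnalysisConfig:
    """Validated configuration for one full analysis run."""

    blocks: list[dict[str, Any]]            # each: {name, path, preprocess:{}}
    gmt: str
    out_dir: str
    weighting: str = "mfa"
    n_components: int | str = "auto"        # int or "auto"
    auto_B: int = 20
    auto_alpha: float = 0.05
    drop_components: list[int] = field(default_factory=list)  # 0-based
    min_mapped: int = 5
    max_size: int = 500
    normalization: str = "unit-sum"
    significance: str = "analytic"
    n_draws: int = 1000
    dedup_policy: str = "error"
    missing: str = "error"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        if not self.blocks:
            raise ValueError("config: at least one block required")
        for spec in self.blocks:
            if "path" not in spec or "name" not in spec:
                raise ValueError("config: each block needs 'name' and 'path'")
            if not Path(spec["path"]).exists():
                raise FileNotFoundError(f"block file not found: {spec['path']}")
        if not Path(self.gmt).exists():
            raise FileNotFoundError(f"GMT file not found: {self.gmt}")
        if self.n_components != "auto" and int(self.n_components) < 1:
            raise ValueError("config: n_components must be 'auto' or >= 1")


def _write_tsv(matrix: np.ndarray, rows, cols, path: Path) -> None:
    pd.DataFrame(matrix, index=rows, columns=cols).to_csv(
        path, sep="\t", index_label="feature_id")


def run_pipeline(config: AnalysisConfig) -> Path:
    """Execute the full analysis; returns the output directory.

    Stages: read -> preprocess -> table weights -> factorization ->
    (permutation component selection when ``n_components='auto'``) ->
    component exclusion -> annotation -> projection -> scores ->
    significance -> write.  Any stage failure is re-raised with the stage
    name prefixed.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    stage = "read"
    try:
        blocks = []
        for spec in config.blocks:
            b = read_matrix(spec["path"], dedup_policy=config.dedup_policy,
                            missing=config.missing)
            b.name = spec["name"]
            blocks.append(b)
            logger.info("read block %s: %d features x %d samples",
                        b.name, b.n_features, b.n_samples)

        stage = "preprocess"
        blocks = [preprocess_block(b, **spec.get("preprocess", {}))
                  for b, spec in zip(blocks, config.blocks)]

        stage = "weighting"
        weighting = table_weights(blocks, config.weighting)
        logger.info("table weights (%s): %s", weighting.method,
                    {k: round(v, 6) for k, v in weighting.weights.items()})

        stage = "fit"
        if config.n_components == "auto":
            test = permutation_component_test(
                blocks, weighting, B=config.auto_B, alpha=config.auto_alpha,
                seed=rng)
            model = fit_mfa(blocks, weighting)
            if not test.significant:
                raise ValueError(
                    "permutation test found no significant component; "
                    "set n_components explicitly"
                )
            model = model.with_selected(test.significant)
            logger.info("auto-selected components: %s", test.significant)
        else:
            model = fit_mfa(blocks, weighting,
                            n_components=int(config.n_components))
        if config.drop_components:
            model = exclude_components(model, config.drop_components)

        stage = "annotate"
        collection = read_gmt(config.gmt)
        annotations = build_annotation(
            collection, blocks, min_mapped=config.min_mapped,
            max_size=config.max_size)

        stage = "score"
        space = project_genesets(model, annotations,
                                 normalization=config.normalization)
        result = compute_gss(model, space)

        stage = "significance"
        result = gss_significance(
            result, model, space, method=config.significance,
            n_draws=config.n_draws, seed=rng)

        stage = "write"
        save_model(model, out / "model.npz")
        ve = variance_explained(model)
        pd.DataFrame({
            "component": np.arange(1, model.n_components + 1),
            "eigenvalue": model.eigenvalues,
            "fraction": ve.fractions,
        }).to_csv(out / "scree.tsv", sep="\t", index=False)
        sets, samples = result.set_names, result.sample_ids
        _write_tsv(result.Y, sets, samples, out / "Y.tsv")
        _write_tsv(result.p, sets, samples, out / "p.tsv")
        _write_tsv(result.p_adj, sets, samples, out / "p_adj.tsv")
        (out / "by_block").mkdir(exist_ok=True)
        for nm, mat in result.by_block.items():
            _write_tsv(mat, sets, samples, out / "by_block" / f"{nm}.tsv")
        (out / "by_component").mkdir(exist_ok=True)
        for r, mat in result.by_component.items():
            _write_tsv(mat, sets, samples,
                       out / "by_component" / f"component_{r + 1}.tsv")
        from . import __version__ as pkg_version
        manifest = {
            "version": pkg_version,
            "seed": config.seed,
            "weighting": weighting.method,
            "weights": weighting.weights,
            "selected_components": model.selected_components,
            "dropped_components": list(config.drop_components),
            "n_gene_sets": len(sets),
            "annotation_filters": {"min_mapped": config.min_mapped,
                                   "max_size": config.max_size},
            "normalization": config.normalization,
            "significance": {"method": config.significance,
                             "n_draws": config.n_draws},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    logger.info("pipeline finished; outputs in %s", out)
    return out
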