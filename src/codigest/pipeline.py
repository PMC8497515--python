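"""End-to-end pipeline: characterize -> predict -> aggregate -> compare -> advise.

A :class:`RunConfig` names every input and output path plus thresholds,
constants overrides and a seed.  :func:`run_pipeline` executes the stages in
order, writes every artifact, and records a manifest (SHA-256 of inputs and
outputs, constants, thresholds, seed, package version) so identical
configurations produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from . import __version__
from .advisor import (
    ADPathwayAnnotation,
    flag_ad_relevant,
    recommend,
)
from .bmp import BMPConstants, DEFAULT_CONSTANTS, characterize
from .differential import lefse_screen
from .errors import CodigestError, ValidationError
from .io import (
    read_feature_table,
    read_gene_content,
    read_hierarchy,
    read_sample_metadata,
    read_substrates,
    write_characterization,
    write_differential_results,
    write_feature_table,
    write_plan,
)
from .prediction import aggregate_pathways, copy_number_normalize, predict_metagenome

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    substrates: str
    otu_table: str
    gene_content: str
    hierarchy: str
    metadata: str
    out_dir: str
    level: int = 3
    alpha: float = 0.05
    lda_threshold: float = 2.0
    correction: str = "none"
    base_model: str = "b"
    seed: int = 0
    annotations: str | None = None
    constants: Mapping[str, float] | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.lda_threshold <= 0:
            raise ValidationError(f"lda_threshold must be positive, got {self.lda_threshold}")
        if self.level not in (2, 3):
            raise ValidationError(f"level must be 2 or 3, got {self.level}")
        if self.base_model not in ("f", "b", "d"):
            raise ValidationError(f"base_model must be one of f, b, d, got {self.base_model!r}")
        for path_field in ("substrates", "otu_table", "gene_content", "hierarchy", "metadata"):
            value = getattr(self, path_field)
            if not value:
                raise ValidationError(f"config field {path_field!r} is required")
            if not Path(value).exists():
                raise ValidationError(f"config field {path_field!r}: no such file {value!r}")

    @classmethod
    def from_mapping(cls, payload: Mapping[str, object]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**payload)  # type: ignore[arg-type]

    def bmp_constants(self) -> BMPConstants:
        if not self.constants:
            return DEFAULT_CONSTANTS
        return dataclasses.replace(DEFAULT_CONSTANTS, **dict(self.constants))


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and return the manifest dictionary.

    Stage failures are re-raised as :class:`CodigestError` naming the stage.
    Outputs land in ``cfg.out_dir``: characterization.tsv, ko_table.tsv,
    pathway_table.tsv, differential.tsv, plan.json, plan.txt, manifest.json.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    constants = cfg.bmp_constants()
    stage = "characterize"
    try:
        substrates = read_substrates(cfg.substrates)
        bmp_results = {ua.name: characterize(ua, constants) for ua in substrates}
        write_characterization(list(bmp_results.values()), out_dir / "characterization.tsv", constants)

        stage = "predict"
        otu = read_feature_table(cfg.otu_table, kind="otu")
        classes = read_sample_metadata(cfg.metadata)
        otu = otu.with_classes(classes.loc[otu.sample_ids])
        gene_content = read_gene_content(cfg.gene_content)
        normalized = copy_number_normalize(otu, gene_content)
        ko_table = predict_metagenome(normalized, gene_content)
        write_feature_table(ko_table, out_dir / "ko_table.tsv")

        stage = "aggregate"
        hierarchy = read_hierarchy(cfg.hierarchy)
        pathway_table = aggregate_pathways(ko_table, hierarchy, level=cfg.level)
        write_feature_table(pathway_table, out_dir / "pathway_table.tsv")

        stage = "compare"
        results = lefse_screen(
            pathway_table, alpha=cfg.alpha, lda_threshold=cfg.lda_threshold
        )
        write_differential_results(results, out_dir / "differential.tsv")

        stage = "advise"
        annotation = (
            ADPathwayAnnotation.from_tsv(cfg.annotations)
            if cfg.annotations
            else ADPathwayAnnotation.load_default()
        )
        tally = flag_ad_relevant(results, annotation)
        plan = recommend(bmp_results, tally.counts, base_model=cfg.base_model)
        write_plan(plan, out_dir / "plan.json", out_dir / "plan.txt")
    except CodigestError as exc:
        raise CodigestError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "constants": constants.as_provenance(),
        "thresholds": {
            "alpha": cfg.alpha,
            "lda_threshold": cfg.lda_threshold,
            "level": cfg.level,
            "base_model": cfg.base_model,
            "correction": cfg.correction,
        },
        "inputs": {
            name: _sha256(Path(getattr(cfg, name)))
            for name in ("substrates", "otu_table", "gene_content", "hierarchy", "metadata")
        },
        "outputs": {
            name: _sha256(out_dir / name)
            for name in (
                "characterization.tsv",
                "ko_table.tsv",
                "pathway_table.tsv",
                "differential.tsv",
                "plan.json",
            )
        },
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
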