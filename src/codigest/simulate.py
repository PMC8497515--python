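"""Synthetic data generation for every pipeline stage.

The generators emulate the study design the package targets: three manure
classes (cow, pig, horse) with three biological replicates each.

* :func:`simulate_ultimate_analysis` draws noisy replicate compositions
  around a substrate's reported means with truncated-at-zero normal noise,
  honoring the mean/SD parameterization in which such measurements are
  reported.
* :func:`simulate_feature_table` produces class-structured count tables with
  Dirichlet-multinomial overdispersion: a base community composition is
  drawn once from a symmetric Dirichlet, class-specific effects are planted
  on the proportion scale (so the truth is well defined at any sequencing
  depth), each sample's composition is drawn from a Dirichlet centred on its
  class base, and counts are multinomial at the configured depth.  Classes
  are exchangeable when nothing is planted, which makes the generator a
  valid null for false-positive-rate studies.
* :func:`simulate_gene_content` draws a sparse small-integer KO copy-count
  reference with 16S copy numbers uniform on 1..15.
* :func:`make_reference_fixture` bundles the three reference manure compositions
  with a seeded 3x3 synthetic microbiome carrying four horse-enriched
  pathway features, plus matched OTU/gene-content/hierarchy inputs for
  end-to-end runs.

All randomness flows through ``numpy.random.default_rng`` seeded from the
configuration, so outputs are byte-identical for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bmp import UltimateAnalysis, validate_ultimate_analysis
from .errors import SimulationError
from .tables import FeatureTable, GeneContentTable, PathwayHierarchy

#: Reported composition of the three manures: mean and SD on the percent
#: scales of standard substrate characterization (TS % of wet mass, VS % of
#: TS, elements % of TS); n = 3 biological replicates each.
REFERENCE_MANURES: dict[str, dict[str, tuple[float, float]]] = {
    "cow": {
        "ts": (14.5, 1.7), "vs": (88.7, 2.1), "c": (25.7, 8.3), "h": (3.8, 0.8),
        "n": (4.9, 1.6), "s": (0.2, 0.1), "o": (54.0, 7.8),
    },
    "pig": {
        "ts": (20.4, 2.4), "vs": (82.8, 2.8), "c": (27.2, 6.0), "h": (4.1, 0.4),
        "n": (2.1, 1.0), "s": (0.2, 0.0), "o": (49.2, 8.4),
    },
    "horse": {
        "ts": (21.8, 0.8), "vs": (86.8, 2.4), "c": (30.6, 5.7), "h": (4.2, 0.4),
        "n": (1.5, 0.4), "s": (0.2, 0.1), "o": (50.3, 6.7),
    },
}

#: The four pathway features treated as horse-enriched throughout the package.
SIGNIFICANT_PATHWAYS: tuple[str, ...] = (
    "Fructose and mannose metabolism",
    "Amino acid and nucleotide sugar metabolism",
    "Phosphotransferase system (PTS)",
    "Starch and sucrose metabolism",
)

_BACKGROUND_PATHWAYS: tuple[str, ...] = (
    "Glycolysis / Gluconeogenesis",
    "Oxidative phosphorylation",
    "Pyruvate metabolism",
    "Butanoate metabolism",
    "Glyoxylate and dicarboxylate metabolism",
    "Riboflavin metabolism",
    "Selenocompound metabolism",
    "Phenylalanine metabolism",
)

#: Expected base composition of the fixture's pathway community: the four
#: target pathways are minor (0.2% each) so the planted shifts dominate
#: them; the background holds the bulk of the functional mass.
_FIXTURE_BASE: tuple[float, ...] = (
    0.002, 0.002, 0.002, 0.002,  # the four target pathways
    0.20, 0.17, 0.15, 0.13, 0.12, 0.09, 0.07, 0.062,
)

_LEVEL2_PARENT: dict[str, str] = {
    "Fructose and mannose metabolism": "Carbohydrate metabolism",
    "Amino acid and nucleotide sugar metabolism": "Carbohydrate metabolism",
    "Phosphotransferase system (PTS)": "Membrane transport",
    "Starch and sucrose metabolism": "Carbohydrate metabolism",
    "Glycolysis / Gluconeogenesis": "Carbohydrate metabolism",
    "Pyruvate metabolism": "Carbohydrate metabolism",
    "Glyoxylate and dicarboxylate metabolism": "Carbohydrate metabolism",
    "Riboflavin metabolism": "Metabolism of cofactors and vitamins",
    "Selenocompound metabolism": "Metabolism of other amino acids",
    "Phenylalanine metabolism": "Amino acid metabolism",
    "Glycine, serine and threonine metabolism": "Amino acid metabolism",
    "Butanoate metabolism": "Carbohydrate metabolism",
    "Propanoate metabolism": "Carbohydrate metabolism",
    "Oxidative phosphorylation": "Energy metabolism",
    "Aminobenzoate degradation": "Xenobiotics biodegradation and metabolism",
    "Naphthalene degradation": "Xenobiotics biodegradation and metabolism",
}


def reference_ultimate_analyses() -> dict[str, UltimateAnalysis]:
    """Validated :class:`UltimateAnalysis` objects for the reference manures."""
    out = {}
    for name, fields in REFERENCE_MANURES.items():
        row: dict[str, object] = {"name": name}
        for key, (mean, sd) in fields.items():
            col = "ts_pct" if key == "ts" else "vs_pct_ts" if key == "vs" else f"{key}_pct"
            row[col] = mean
            row[col + "_sd"] = sd
        out[name] = validate_ultimate_analysis(row)
    return out


def simulate_ultimate_analysis(
    name: str,
    means: Mapping[str, float] | None = None,
    sds: Mapping[str, float] | None = None,
    n_replicates: int = 3,
    rng: np.random.Generator | int | None = None,
    max_attempts: int = 1000,
) -> tuple[list[UltimateAnalysis], UltimateAnalysis]:
    """Draw replicate ultimate analyses and their mean row.

    ``means``/``sds`` are on the percent reporting scales with keys
    ``ts, vs, c, h, n, s, o``; defaults are the reference values for
    ``name`` when it is one of the reference manures.  Each field is drawn
    from a normal truncated at zero; whole replicates are rejected and
    redrawn while the elemental sum exceeds 100% of TS.  Raises
    :class:`SimulationError` when no feasible replicate is found within
    ``max_attempts`` draws.
    """
    if means is None or sds is None:
        if name not in REFERENCE_MANURES:
            raise SimulationError(
                f"no reference composition for {name!r}; pass means and sds explicitly"
            )
        ref = REFERENCE_MANURES[name]
        means = means or {k: v[0] for k, v in ref.items()}
        sds = sds or {k: v[1] for k, v in ref.items()}
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    keys = ("ts", "vs", "c", "h", "n", "s", "o")
    for key in keys:
        if key not in means or key not in sds:
            raise SimulationError(f"means/sds missing key {key!r}")
        if sds[key] < 0:
            raise SimulationError(f"negative SD for {key!r}")

    def draw_field(mean: float, sd: float) -> float:
        if sd == 0:
            if mean < 0:
                raise SimulationError("negative mean with zero SD is infeasible")
            return mean
        for _ in range(max_attempts):
            value = rng.normal(mean, sd)
            if value >= 0:
                return value
        raise SimulationError(f"could not draw a non-negative value for mean={mean}, sd={sd}")

    replicates: list[UltimateAnalysis] = []
    for rep in range(n_replicates):
        for _ in range(max_attempts):
            draws = {k: draw_field(means[k], sds[k]) for k in keys}
            elemental = sum(draws[k] for k in ("c", "h", "n", "s", "o"))
            if elemental <= 100 and 0 < draws["ts"] <= 100 and 0 < draws["vs"] <= 100:
                break
        else:
            raise SimulationError(
                f"{name}: no feasible replicate within {max_attempts} draws"
            )
        replicates.append(
            UltimateAnalysis(
                name=f"{name}_rep{rep + 1}",
                ts=draws["ts"] / 100,
                vs_of_ts=draws["vs"] / 100,
                c=draws["c"] / 100,
                h=draws["h"] / 100,
                n=draws["n"] / 100,
                s=draws["s"] / 100,
                o=draws["o"] / 100,
            )
        )
    mean_row = UltimateAnalysis(
        name=name,
        ts=float(np.mean([r.ts for r in replicates])),
        vs_of_ts=float(np.mean([r.vs_of_ts for r in replicates])),
        c=float(np.mean([r.c for r in replicates])),
        h=float(np.mean([r.h for r in replicates])),
        n=float(np.mean([r.n for r in replicates])),
        s=float(np.mean([r.s for r in replicates])),
        o=float(np.mean([r.o for r in replicates])),
    )
    return replicates, mean_row


@dataclass(frozen=True)
class PlantedEffect:
    """A class-specific abundance effect planted on the proportion scale.

    Exactly one of ``ppm_shift`` (additive, per-million units) or
    ``fold_change`` (multiplicative, > 0) must be given; the class base
    composition is modified and renormalized before sampling.
    """

    target_class: str
    features: tuple[str, ...]
    ppm_shift: float | None = None
    fold_change: float | None = None

    def __post_init__(self) -> None:
        if (self.ppm_shift is None) == (self.fold_change is None):
            raise SimulationError("specify exactly one of ppm_shift or fold_change")
        if self.fold_change is not None and self.fold_change <= 0:
            raise SimulationError("fold_change must be positive")
        if self.ppm_shift is not None and self.ppm_shift <= 0:
            raise SimulationError("ppm_shift must be positive")


@dataclass
class SimulationConfig:
    """Configuration of the class-structured count-table generator.

    ``dirichlet_concentration`` sets replicate overdispersion: each sample's
    composition is Dirichlet with parameter
    ``concentration * n_features * class_base``, i.e. the concentration is
    on the per-feature scale (a uniform base with the default of 50 gives a
    symmetric Dirichlet(50)).  ``depth_dispersion`` is the coefficient of
    variation of the per-sample sequencing depth (0 = every sample exactly
    at ``depth_mean``).  ``base_alpha`` is the symmetric Dirichlet parameter
    for the base community composition (larger = more even community).
    """

    seed: int = 0
    class_names: tuple[str, ...] = ("cow", "pig", "horse")
    n_samples_per_class: int = 3
    n_features: int = 200
    feature_kind: str = "otu"
    feature_names: tuple[str, ...] | None = None
    depth_mean: int = 50_000
    depth_dispersion: float = 0.0
    dirichlet_concentration: float = 50.0
    base_alpha: float = 10.0
    base_proportions: tuple[float, ...] | None = None
    planted: tuple[PlantedEffect, ...] = ()

    def __post_init__(self) -> None:
        if self.depth_mean <= 0:
            raise SimulationError("sequencing depth must be positive")
        if self.depth_dispersion < 0:
            raise SimulationError("depth dispersion must be non-negative")
        if self.dirichlet_concentration <= 0 or self.base_alpha <= 0:
            raise SimulationError("Dirichlet concentrations must be positive")
        if self.n_samples_per_class < 1 or self.n_features < 2:
            raise SimulationError("need >= 1 sample per class and >= 2 features")
        if len(set(self.class_names)) < 2:
            raise SimulationError("need at least two distinct classes")
        if self.feature_names is not None and len(self.feature_names) != self.n_features:
            raise SimulationError("feature_names length must equal n_features")
        if self.base_proportions is not None:
            props = tuple(float(v) for v in self.base_proportions)
            if len(props) != self.n_features:
                raise SimulationError("base_proportions length must equal n_features")
            if any(v <= 0 for v in props) or abs(sum(props) - 1.0) > 1e-6:
                raise SimulationError("base_proportions must be positive and sum to 1")
            self.base_proportions = props
        self.planted = tuple(self.planted)


def _feature_names(cfg: SimulationConfig) -> list[str]:
    if cfg.feature_names is not None:
        return list(cfg.feature_names)
    width = max(4, len(str(cfg.n_features)))
    prefix = cfg.feature_kind.upper() if cfg.feature_kind == "otu" else cfg.feature_kind
    return [f"{prefix}_{i:0{width}d}" for i in range(cfg.n_features)]


def simulate_feature_table(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[FeatureTable, dict]:
    """Generate a class-structured count table plus its planted-truth record.

    Returns the table (with class labels attached) and a JSON-serializable
    dictionary recording the base composition, the per-class expected
    proportions after planting, and the planted effects.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    names = _feature_names(cfg)
    name_index = {n: i for i, n in enumerate(names)}
    if cfg.base_proportions is not None:
        base = np.asarray(cfg.base_proportions, dtype=float)
    else:
        base = rng.dirichlet(np.full(cfg.n_features, cfg.base_alpha))
    class_bases: dict[str, np.ndarray] = {}
    for cls in cfg.class_names:
        p = base.copy()
        for effect in cfg.planted:
            if effect.target_class != cls:
                continue
            for feat in effect.features:
                if feat not in name_index:
                    raise SimulationError(f"planted effect on unknown feature {feat!r}")
                i = name_index[feat]
                if effect.fold_change is not None:
                    p[i] = base[i] * effect.fold_change
                else:
                    p[i] = base[i] + effect.ppm_shift / 1e6
        class_bases[cls] = p / p.sum()

    sample_ids: list[str] = []
    labels: list[str] = []
    counts = np.zeros((len(cfg.class_names) * cfg.n_samples_per_class, cfg.n_features), dtype=np.int64)
    row = 0
    alpha_scale = cfg.dirichlet_concentration * cfg.n_features
    for cls in cfg.class_names:
        for rep in range(cfg.n_samples_per_class):
            sample_ids.append(f"{cls}_{rep + 1}")
            labels.append(cls)
            if cfg.depth_dispersion > 0:
                cv2 = cfg.depth_dispersion**2
                depth = max(1, int(round(rng.gamma(1.0 / cv2, cfg.depth_mean * cv2))))
            else:
                depth = cfg.depth_mean
            composition = rng.dirichlet(alpha_scale * class_bases[cls])
            counts[row] = rng.multinomial(depth, composition)
            row += 1

    data = pd.DataFrame(counts, index=sample_ids, columns=names)
    table = FeatureTable(
        data=data,
        kind=cfg.feature_kind,
        classes=pd.Series(labels, index=sample_ids),
    )
    truth = {
        "base": {n: float(v) for n, v in zip(names, base)},
        "class_expected_proportions": {
            cls: {n: float(v) for n, v in zip(names, p)} for cls, p in class_bases.items()
        },
        "planted": [
            {
                "target_class": e.target_class,
                "features": list(e.features),
                "ppm_shift": e.ppm_shift,
                "fold_change": e.fold_change,
            }
            for e in cfg.planted
        ],
    }
    return table, truth


def simulate_gene_content(
    n_otus: int,
    n_kos: int,
    density: float = 0.2,
    max_copies: int = 5,
    rng: np.random.Generator | int | None = None,
    otu_ids: Sequence[str] | None = None,
    ko_ids: Sequence[str] | None = None,
) -> GeneContentTable:
    """Sparse random KO copy-count reference with 16S copy numbers in [1, 15]."""
    if not 0 < density <= 1:
        raise SimulationError("density must be in (0, 1]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    otus = list(otu_ids) if otu_ids is not None else [f"OTU_{i:04d}" for i in range(n_otus)]
    kos = list(ko_ids) if ko_ids is not None else [f"K{i:05d}" for i in range(1, n_kos + 1)]
    present = rng.random((n_otus, n_kos)) < density
    copies = rng.integers(1, max_copies + 1, size=(n_otus, n_kos))
    data = pd.DataFrame(np.where(present, copies, 0), index=otus, columns=kos)
    rrna = pd.Series(rng.integers(1, 16, size=n_otus), index=otus)
    return GeneContentTable(data=data, rrna_copies=rrna)


@dataclass
class ReferenceFixture:
    """Seeded bundle reproducing the three-manure reference design end to end."""

    substrates: dict[str, UltimateAnalysis]
    microbiome: FeatureTable  # pathway-level, 3 classes x 3 replicates
    truth: dict
    otu_table: FeatureTable
    gene_content: GeneContentTable
    hierarchy: PathwayHierarchy


def fixture_config(seed: int = 0) -> SimulationConfig:
    """Configuration of the pathway-level fixture microbiome.

    The four target pathways are planted as a three-level gradient — horse
    +10,000 ppm, pig +5,000 ppm, cow at base — because a three-group rank
    test on 3 replicates per group can only reach p < 0.05 reliably when all
    three groups separate; the real manure communities likewise differ
    between all three hosts.  Pathway-level profiles aggregate many gene
    families, so replicate variability is far lower than for OTU profiles;
    the per-feature concentration of 450 reflects that.
    """
    pathways = tuple(SIGNIFICANT_PATHWAYS) + tuple(_BACKGROUND_PATHWAYS)
    return SimulationConfig(
        seed=seed,
        n_features=len(pathways),
        feature_kind="pathway",
        feature_names=pathways,
        depth_mean=50_000,
        depth_dispersion=0.0,
        dirichlet_concentration=450.0,
        base_proportions=_FIXTURE_BASE,
        planted=(
            PlantedEffect(
                target_class="horse", features=SIGNIFICANT_PATHWAYS, ppm_shift=10_000.0
            ),
            PlantedEffect(
                target_class="pig", features=SIGNIFICANT_PATHWAYS, ppm_shift=5_000.0
            ),
        ),
    )


def make_reference_fixture(seed: int = 0) -> ReferenceFixture:
    """Reference-manure compositions plus a seeded synthetic microbiome.

    The pathway-level table has 12 features — the four horse-enriched
    reference pathways planted per :func:`fixture_config`, plus
    eight background pathways — over the 3-class x 3-replicate design.
    Matched OTU-level inputs (40 OTUs, 48 KOs, a 4-KOs-per-pathway
    hierarchy and a gene-content reference in which eight horse-associated
    OTUs carry the KOs of the planted pathways) support full-pipeline runs.
    """
    rng = np.random.default_rng(seed)
    pathways = list(SIGNIFICANT_PATHWAYS) + list(_BACKGROUND_PATHWAYS)
    cfg = fixture_config(seed)
    microbiome, truth = simulate_feature_table(cfg, rng=np.random.default_rng(rng.integers(2**31)))

    # hierarchy: 4 KOs per pathway, 64 KOs total
    kos = [f"K{i:05d}" for i in range(1, 4 * len(pathways) + 1)]
    records = []
    for i, ko in enumerate(kos):
        pathway = pathways[i // 4]
        records.append(
            {"ko_id": ko, "level3_name": pathway, "level2_name": _LEVEL2_PARENT[pathway]}
        )
    hierarchy = PathwayHierarchy.from_frame(pd.DataFrame.from_records(records))

    # gene content: horse-associated OTUs carry KOs of the planted pathways
    n_otus = 40
    otus = [f"OTU_{i:04d}" for i in range(n_otus)]
    horse_otus = otus[:8]
    planted_kos = kos[: 4 * len(SIGNIFICANT_PATHWAYS)]
    background_kos = kos[4 * len(SIGNIFICANT_PATHWAYS):]
    gc_rng = np.random.default_rng(rng.integers(2**31))
    copies = np.zeros((n_otus, len(kos)), dtype=np.int64)
    ko_index = {k: j for j, k in enumerate(kos)}
    for i, otu in enumerate(otus):
        own = planted_kos if otu in horse_otus else background_kos
        chosen = gc_rng.choice(len(own), size=max(3, len(own) // 4), replace=False)
        for j in chosen:
            copies[i, ko_index[own[j]]] = gc_rng.integers(1, 6)
    gene_content = GeneContentTable(
        data=pd.DataFrame(copies, index=otus, columns=kos),
        rrna_copies=pd.Series(gc_rng.integers(1, 16, size=n_otus), index=otus),
    )

    otu_cfg = SimulationConfig(
        seed=seed,
        n_features=n_otus,
        feature_kind="otu",
        feature_names=tuple(otus),
        depth_mean=50_000,
        depth_dispersion=0.1,
        dirichlet_concentration=50.0,
        base_alpha=10.0,
        planted=(
            PlantedEffect(target_class="horse", features=tuple(horse_otus), fold_change=8.0),
        ),
    )
    otu_table, _ = simulate_feature_table(otu_cfg, rng=np.random.default_rng(rng.integers(2**31)))

    return ReferenceFixture(
        substrates=reference_ultimate_analyses(),
        microbiome=microbiome,
        truth=truth,
        otu_table=otu_table,
        gene_content=gene_content,
        hierarchy=hierarchy,
    )
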