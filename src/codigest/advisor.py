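"""Rule-based co-digestion advisor.

Combines theoretical BMP characterization with differential-pathway results
into an explicit, reproducible recommendation: substrates are ranked by BMP,
each substrate's count of significant anaerobic-digestion-relevant pathway
enrichments is tallied against a packaged annotation list, and emphasis
weights are computed by a transparent heuristic::

    weight_i  proportional to  BMP_i * (1 + tally_i / max(1, sum of tallies))

normalized to sum to 1.  The rule is configuration, not science: it is
monotone (raising a substrate's BMP or its enrichment tally never lowers its
weight) and scale-invariant in the BMPs, and the emitted plan text labels it
as a heuristic.

The packaged annotations — pathway-to-AD-stage tags and genus-to-role tags —
are editable TSV resources curated from the anaerobic-digestion literature
on these manure communities; they are explicitly partial and can be replaced
by the user.  Name matching is case-insensitive after whitespace
normalization, never fuzzy.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .bmp import BMPResult
from .differential import DifferentialResult
from .errors import ValidationError
from .prediction import to_relative_proportions
from .tables import FeatureTable

AD_PATHWAY_TAGS = frozenset(
    {"hydrolysis", "acidogenesis_acetogenesis", "growth_support", "none"}
)
GENUS_ROLE_TAGS = frozenset(
    {"growth_metabolism", "lignocellulose", "acidogenesis_acetogenesis", "pathogenic"}
)
UNCLASSIFIED_ROLE = "unclassified"


def _normalize_name(name: str) -> str:
    return " ".join(str(name).lower().split())


def _packaged(filename: str):
    return resources.files("codigest") / "data" / filename


@dataclass(frozen=True)
class ADPathwayAnnotation:
    """Pathway name -> anaerobic-digestion relevance tag (normalized names)."""

    tags: Mapping[str, str]

    def __post_init__(self) -> None:
        for name, tag in self.tags.items():
            if tag not in AD_PATHWAY_TAGS:
                raise ValidationError(
                    f"pathway {name!r} has unknown tag {tag!r}; expected {sorted(AD_PATHWAY_TAGS)}"
                )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ADPathwayAnnotation":
        if frame["pathway"].map(_normalize_name).duplicated().any():
            raise ValidationError("duplicate pathway names in annotation")
        return cls(
            {_normalize_name(r.pathway): str(r.tag) for r in frame.itertuples(index=False)}
        )

    @classmethod
    def from_tsv(cls, path) -> "ADPathwayAnnotation":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    @classmethod
    def load_default(cls) -> "ADPathwayAnnotation":
        with resources.as_file(_packaged("ad_pathways.tsv")) as path:
            return cls.from_tsv(path)

    def tag_for(self, pathway_name: str) -> str | None:
        return self.tags.get(_normalize_name(pathway_name))


@dataclass(frozen=True)
class GenusRoleAnnotation:
    """Genus name -> set of functional role tags (normalized names)."""

    roles: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for genus, tags in self.roles.items():
            if not tags:
                raise ValidationError(f"genus {genus!r} has no role tags")
            unknown = set(tags) - GENUS_ROLE_TAGS
            if unknown:
                raise ValidationError(f"genus {genus!r} has unknown tags {sorted(unknown)}")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GenusRoleAnnotation":
        if frame["genus"].map(_normalize_name).duplicated().any():
            raise ValidationError("duplicate genus names in annotation")
        return cls(
            {
                _normalize_name(r.genus): frozenset(
                    t.strip() for t in str(r.roles).split(",") if t.strip()
                )
                for r in frame.itertuples(index=False)
            }
        )

    @classmethod
    def from_tsv(cls, path) -> "GenusRoleAnnotation":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    @classmethod
    def load_default(cls) -> "GenusRoleAnnotation":
        with resources.as_file(_packaged("genus_roles.tsv")) as path:
            return cls.from_tsv(path)

    def roles_for(self, genus: str) -> frozenset[str] | None:
        return self.roles.get(_normalize_name(genus))


@dataclass(frozen=True)
class ADTally:
    """Per-class counts of significant AD-relevant pathway enrichments."""

    counts: dict[str, int]
    matched: dict[str, list[str]]
    unmatched: list[str]


def flag_ad_relevant(
    results: Iterable[DifferentialResult],
    annotation: ADPathwayAnnotation | None = None,
) -> ADTally:
    """Tally significant features whose pathway carries an AD-relevance tag.

    Features tagged ``none`` or absent from the annotation are excluded from
    the tallies; names not found in the annotation are reported in
    ``unmatched``.
    """
    annotation = annotation or ADPathwayAnnotation.load_default()
    counts: dict[str, int] = {}
    matched: dict[str, list[str]] = {}
    unmatched: list[str] = []
    for result in results:
        counts.setdefault(result.assigned_class, 0)
        if not result.significant:
            continue
        tag = annotation.tag_for(result.feature_id)
        if tag is None:
            unmatched.append(result.feature_id)
        elif tag != "none":
            counts[result.assigned_class] += 1
            matched.setdefault(result.assigned_class, []).append(result.feature_id)
    return ADTally(counts=counts, matched=matched, unmatched=unmatched)


@dataclass(frozen=True)
class GenusRoleSummary:
    """Per-class mean relative abundance per role, plus pathogen alerts."""

    coverage: pd.DataFrame  # classes x roles
    pathogen_alerts: dict[str, list[str]]


def genus_role_summary(
    table: FeatureTable,
    annotation: GenusRoleAnnotation | None = None,
    classes: pd.Series | None = None,
) -> GenusRoleSummary:
    """Summarize a genus-level table by annotated functional roles.

    A genus tagged with several roles contributes its full abundance to each
    role; genera absent from the annotation are counted under
    ``unclassified``.  Pathogen alerts list, per class, the genera tagged
    pathogenic with a non-zero class mean.
    """
    if table.kind != "genus":
        raise ValidationError(f"expected a genus table, got kind {table.kind!r}")
    annotation = annotation or GenusRoleAnnotation.load_default()
    labels = classes if classes is not None else table.class_labels()
    labels = pd.Series(labels).loc[table.data.index]
    rel = to_relative_proportions(table, scale=1.0)
    class_means = rel.data.groupby(labels).mean().sort_index()
    roles = sorted(GENUS_ROLE_TAGS) + [UNCLASSIFIED_ROLE]
    coverage = pd.DataFrame(0.0, index=class_means.index, columns=roles)
    alerts: dict[str, list[str]] = {cls: [] for cls in class_means.index}
    for genus in class_means.columns:
        tags = annotation.roles_for(genus)
        if tags is None:
            coverage[UNCLASSIFIED_ROLE] += class_means[genus]
            continue
        for tag in tags:
            coverage[tag] += class_means[genus]
        if "pathogenic" in tags:
            for cls in class_means.index:
                if class_means.loc[cls, genus] > 0:
                    alerts[cls].append(str(genus))
    for cls in alerts:
        alerts[cls].sort()
    return GenusRoleSummary(coverage=coverage, pathogen_alerts=alerts)


@dataclass
class CodigestionPlan:
    """Serializable co-digestion recommendation."""

    base_model: str
    ranking: list[str]  # substrates by descending BMP
    bmp_values: dict[str, float]
    ad_tallies: dict[str, int]
    weights: dict[str, float]
    expected_mixture_bmp: float
    pathogen_alerts: dict[str, list[str]]
    rationale: list[str]

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    @classmethod
    def from_dict(cls, payload: Mapping) -> "CodigestionPlan":
        return cls(**payload)

    @classmethod
    def from_json(cls, text: str) -> "CodigestionPlan":
        return cls.from_dict(json.loads(text))

    def to_text(self) -> str:
        lines = [
            f"Co-digestion plan (BMP model: {self.base_model.upper()})",
            "Ranking by mono-digestion BMP: " + " > ".join(self.ranking),
            "Recommended VS-mass emphasis weights:",
        ]
        for name in self.ranking:
            lines.append(
                f"  {name}: weight {self.weights[name]:.3f} "
                f"(BMP {self.bmp_values[name]:.1f} mL CH4/gVS, "
                f"{self.ad_tallies.get(name, 0)} AD-relevant enrichments)"
            )
        lines.append(
            f"Expected additive mixture BMP at these weights: "
            f"{self.expected_mixture_bmp:.1f} mL CH4/gVS"
        )
        for cls, genera in sorted(self.pathogen_alerts.items()):
            if genera:
                lines.append(f"Pathogen alert ({cls}): " + ", ".join(genera))
        lines.extend(self.rationale)
        return "\n".join(lines)


def recommend(
    bmps: Mapping[str, BMPResult],
    tallies: Mapping[str, int],
    base_model: str = "b",
    pathogen_alerts: Mapping[str, Sequence[str]] | None = None,
) -> CodigestionPlan:
    """Deterministic co-digestion recommendation.

    ``bmps`` maps substrate name to its characterization; ``tallies`` maps
    substrate (class) name to its count of significant AD-relevant pathway
    enrichments (missing substrates count 0).  Weights follow the documented
    heuristic and sum to 1; the expected mixture BMP is the additive model
    evaluated at the recommended weights.
    """
    if not bmps:
        raise ValidationError("recommend requires at least one substrate")
    values = {name: res.bmp(base_model) for name, res in bmps.items()}
    total_tally = sum(max(0, tallies.get(name, 0)) for name in bmps)
    raw = {
        name: values[name] * (1.0 + tallies.get(name, 0) / max(1, total_tally))
        for name in bmps
    }
    norm = sum(raw.values())
    if norm <= 0:
        raise ValidationError("all substrate BMPs are zero; cannot form weights")
    weights = {name: raw[name] / norm for name in bmps}
    ranking = sorted(bmps, key=lambda name: (-values[name], name))
    expected = sum(weights[name] * values[name] for name in bmps)
    rationale = [
        "Rule: weight_i is proportional to BMP_i * (1 + tally_i / max(1, total tallies));"
        " this is a documented heuristic, not a fitted model.",
        f"Top-ranked substrate: {ranking[0]} "
        f"(highest {base_model.upper()}-model BMP"
        + (
            f" and {tallies.get(ranking[0], 0)} AD-relevant pathway enrichments)."
            if tallies.get(ranking[0], 0)
            else ")."
        ),
        "Emphasize higher-weight substrates when composing the feed mixture.",
    ]
    return CodigestionPlan(
        base_model=base_model,
        ranking=ranking,
        bmp_values=values,
        ad_tallies={name: int(tallies.get(name, 0)) for name in bmps},
        weights=weights,
        expected_mixture_bmp=expected,
        pathogen_alerts={k: sorted(v) for k, v in (pathogen_alerts or {}).items()},
        rationale=rationale,
    )
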