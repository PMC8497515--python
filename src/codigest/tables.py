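"""In-memory containers for feature tables, gene-content references and the
KEGG-style pathway hierarchy.

A :class:`FeatureTable` holds a samples-by-features matrix of non-negative
counts or abundances together with an optional sample-to-class map.  Feature
kinds are tagged (``otu``, ``ko``, ``pathway``, ``genus``) so downstream
stages can assert they are fed the right level.  Tables are dense pandas
DataFrames; the intended scale (hundreds to a few thousand features) does
not warrant sparse storage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

FEATURE_KINDS = ("otu", "ko", "pathway", "genus")


@dataclass
class FeatureTable:
    """Samples x features abundance matrix with optional class labels.

    ``data`` is indexed by sample id with feature ids as columns.
    ``classes`` maps every sample to a class label when present.
    ``taxonomy`` optionally carries a per-feature annotation string parsed
    from classic OTU-table files (kept aside, never used numerically).
    """

    data: pd.DataFrame
    kind: str = "otu"
    classes: pd.Series | None = None
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(
                f"unknown feature kind {self.kind!r}; expected one of {FEATURE_KINDS}"
            )
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample ids in feature table")
        if self.data.columns.has_duplicates:
            raise ValidationError("duplicate feature ids in feature table")
        values = self.data.to_numpy(dtype=float)
        if values.size and np.nanmin(values) < 0:
            raise ValidationError("feature table contains negative entries")
        if np.isnan(values).any():
            raise ValidationError("feature table contains missing values")
        if self.classes is not None:
            self.classes = pd.Series(self.classes)
            missing = self.data.index.difference(self.classes.index)
            if len(missing):
                raise ValidationError(
                    f"class map does not cover samples: {list(missing)[:5]}"
                )
            self.classes = self.classes.loc[self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def class_labels(self) -> pd.Series:
        if self.classes is None:
            raise ValidationError("feature table has no sample classes attached")
        return self.classes

    def with_data(self, data: pd.DataFrame, kind: str | None = None) -> "FeatureTable":
        """New table with replaced matrix; classes carry over when the new
        sample index is still covered by the class map."""
        classes = None
        if self.classes is not None and data.index.isin(self.classes.index).all():
            classes = self.classes.loc[data.index].copy()
        return FeatureTable(data=data, kind=kind or self.kind, classes=classes, taxonomy=None)

    def with_classes(self, classes: Mapping[str, str] | pd.Series) -> "FeatureTable":
        return FeatureTable(
            data=self.data.copy(),
            kind=self.kind,
            classes=pd.Series(classes),
            taxonomy=None if self.taxonomy is None else self.taxonomy.copy(),
        )


@dataclass
class GeneContentTable:
    """Per-OTU genome annotation: KO copy counts plus 16S rRNA copy number.

    ``data`` is OTUs x KOs with non-negative integer copy counts;
    ``rrna_copies`` gives the 16S gene copies per OTU genome (at least 1),
    used to correct observed 16S abundances for copy-number bias.
    """

    data: pd.DataFrame
    rrna_copies: pd.Series

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate OTU ids in gene-content table")
        if self.data.columns.has_duplicates:
            raise ValidationError("duplicate KO ids in gene-content table")
        values = self.data.to_numpy(dtype=float)
        if values.size and values.min() < 0:
            raise ValidationError("gene-content table contains negative copy counts")
        self.rrna_copies = pd.Series(self.rrna_copies)
        missing = self.data.index.difference(self.rrna_copies.index)
        if len(missing):
            raise ValidationError(
                f"rrna_copies missing for OTUs: {list(missing)[:5]}"
            )
        self.rrna_copies = self.rrna_copies.loc[self.data.index].astype(float)
        if (self.rrna_copies < 1).any():
            raise ValidationError("16S copy numbers must be >= 1 for every OTU")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def ko_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class PathwayHierarchy:
    """Map from KO id to its (level-3 pathway, level-2 category) memberships.

    A KO may belong to several pathways; every mapping must carry non-empty
    names at both levels.
    """

    mapping: dict[str, tuple[tuple[str, str], ...]]

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ValidationError("pathway hierarchy is empty")
        for ko, entries in self.mapping.items():
            if not entries:
                raise ValidationError(f"KO {ko!r} has no pathway memberships")
            for level3, level2 in entries:
                if not level3 or not level2:
                    raise ValidationError(f"KO {ko!r} has an empty pathway name")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PathwayHierarchy":
        """Build from a long-form frame with columns ko_id, level3_name, level2_name."""
        required = {"ko_id", "level3_name", "level2_name"}
        if not required.issubset(frame.columns):
            raise ValidationError(
                f"hierarchy frame must have columns {sorted(required)}"
            )
        mapping: dict[str, list[tuple[str, str]]] = {}
        for row in frame.itertuples(index=False):
            entry = (str(row.level3_name), str(row.level2_name))
            mapping.setdefault(str(row.ko_id), []).append(entry)
        return cls({ko: tuple(dict.fromkeys(v)) for ko, v in mapping.items()})

    def to_frame(self) -> pd.DataFrame:
        records = [
            {"ko_id": ko, "level3_name": l3, "level2_name": l2}
            for ko, entries in self.mapping.items()
            for l3, l2 in entries
        ]
        return pd.DataFrame.from_records(records)

    def pathways_for(self, ko: str, level: int) -> tuple[str, ...]:
        """Distinct pathway names for one KO at hierarchy level 2 or 3."""
        if level not in (2, 3):
            raise ValidationError(f"hierarchy level must be 2 or 3, got {level}")
        entries = self.mapping.get(ko)
        if entries is None:
            return ()
        idx = 0 if level == 3 else 1
        return tuple(dict.fromkeys(entry[idx] for entry in entries))
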