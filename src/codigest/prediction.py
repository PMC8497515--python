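"""PICRUSt-style functional prediction from a 16S feature table.

The procedure mirrors the classic prediction pipeline: correct observed OTU
abundances for 16S copy number, multiply by the per-genome KO copy counts of
a gene-content reference to obtain a predicted metagenome, and aggregate KO
abundances to KEGG pathway levels.  Ancestral-state reconstruction over a
reference phylogeny (how precomputed gene-content references are built) is
out of scope; the reference is an input.
"""

from __future__ import annotations

import logging


import pandas as pd

from .errors import ValidationError
from .tables import FeatureTable, GeneContentTable, PathwayHierarchy

logger = logging.getLogger(__name__)

UNCLASSIFIED = "Unclassified"


def copy_number_normalize(
    table: FeatureTable, gene_content: GeneContentTable, missing: str = "drop"
) -> FeatureTable:
    """Divide each OTU's abundance by its 16S copy number.

    OTUs absent from the reference are dropped with a logged estimate of the
    discarded abundance fraction (``missing="drop"``, the default) or cause a
    hard failure (``missing="error"``).
    """
    if table.kind != "otu":
        raise ValidationError(f"expected an OTU table, got kind {table.kind!r}")
    if missing not in ("drop", "error"):
        raise ValidationError(f"missing policy must be 'drop' or 'error', got {missing!r}")
    known = [f for f in table.feature_ids if f in gene_content.rrna_copies.index]
    absent = [f for f in table.feature_ids if f not in gene_content.rrna_copies.index]
    if absent:
        if missing == "error":
            raise ValidationError(
                f"{len(absent)} OTUs missing from gene-content reference, e.g. {absent[:5]}"
            )
        total = float(table.data.to_numpy().sum())
        lost = float(table.data[absent].to_numpy().sum())
        logger.warning(
            "dropping %d OTUs missing from the reference (%.2f%% of total abundance)",
            len(absent),
            100.0 * lost / total if total else 0.0,
        )
    data = table.data[known].astype(float) / gene_content.rrna_copies.loc[known]
    return table.with_data(data, kind="otu")


def predict_metagenome(
    table_norm: FeatureTable, gene_content: GeneContentTable
) -> FeatureTable:
    """Predicted KO abundances: M[s, k] = sum_o abundance[s, o] * copies[o, k].

    Expects a copy-number-normalized OTU table whose OTUs are all present in
    the reference.
    """
    if table_norm.kind != "otu":
        raise ValidationError(f"expected an OTU table, got kind {table_norm.kind!r}")
    missing = [f for f in table_norm.feature_ids if f not in gene_content.data.index]
    if missing:
        raise ValidationError(
            f"OTUs absent from gene-content reference: {missing[:5]} "
            "(run copy_number_normalize first)"
        )
    genes = gene_content.data.loc[table_norm.feature_ids].astype(float)
    predicted = pd.DataFrame(
        table_norm.data.to_numpy(dtype=float) @ genes.to_numpy(),
        index=table_norm.data.index,
        columns=genes.columns,
    )
    return table_norm.with_data(predicted, kind="ko")


def aggregate_pathways(
    table: FeatureTable, hierarchy: PathwayHierarchy, level: int = 3
) -> FeatureTable:
    """Sum KO abundances into pathway features at hierarchy level 2 or 3.

    A KO mapped to several pathways contributes its full abundance to each
    (the KEGG convention), so column totals can exceed the KO total.  KOs
    with no mapping are collected under ``"Unclassified"``.
    """
    if table.kind != "ko":
        raise ValidationError(f"expected a KO table, got kind {table.kind!r}")
    if level not in (2, 3):
        raise ValidationError(f"hierarchy level must be 2 or 3, got {level}")
    groups: dict[str, list[str]] = {}
    for ko in table.feature_ids:
        names = hierarchy.pathways_for(ko, level) or (UNCLASSIFIED,)
        for name in names:
            groups.setdefault(name, []).append(ko)
    aggregated = pd.DataFrame(
        {name: table.data[kos].sum(axis=1) for name, kos in sorted(groups.items())},
        index=table.data.index,
    )
    return table.with_data(aggregated, kind="pathway")


def to_relative_proportions(table: FeatureTable, scale: float = 1.0) -> FeatureTable:
    """Scale every sample's feature vector to a fixed total (1 by default,
    1e6 for the per-million convention)."""
    totals = table.data.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValidationError(
            f"cannot normalize sample(s) with zero total: {list(zero.index)[:5]}"
        )
    return table.with_data(table.data.div(totals, axis=0) * scale)
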