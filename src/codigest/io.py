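"""Readers and writers for the package's tab-separated interchange formats.

Feature tables use the classic OTU-table orientation: features as rows,
samples as columns, an optional leading ``#`` comment block, a header whose
first cell may be ``#OTU ID``, and an optional trailing ``taxonomy`` column
(parsed and kept aside).  All files are UTF-8, tab-separated, with
deterministic row ordering.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .advisor import CodigestionPlan
from .bmp import BMPConstants, BMPResult, DEFAULT_CONSTANTS, UltimateAnalysis, validate_ultimate_analysis
from .differential import DifferentialResult, TwoGroupResult
from .errors import ParseError, ValidationError
from .tables import FeatureTable, GeneContentTable, PathwayHierarchy

_TAXONOMY_NAMES = {"taxonomy", "taxon", "consensus lineage", "consensuslineage"}


def read_feature_table(path, kind: str = "otu") -> FeatureTable:
    """Parse a classic tab-separated feature table.

    Tolerates leading ``#`` comment lines, a ``#OTU ID`` header cell and a
    trailing taxonomy column.  Raises :class:`ParseError` with a line number
    for ragged rows, and :class:`ValidationError` for duplicate ids or
    negative entries.
    """
    path = Path(path)
    header: list[str] | None = None
    feature_ids: list[str] = []
    rows: list[list[float]] = []
    taxonomy: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if header is None:
                if line.startswith("#") and not line.lower().startswith("#otu id"):
                    continue  # comment block before the header
                if len(fields) < 2:
                    raise ParseError(f"{path}:{lineno}: header has no sample columns")
                header = fields
                continue
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: ragged row ({len(fields)} fields, header has {len(header)})"
                )
            feature_ids.append(fields[0])
            rows.append(fields[1:])
    if header is None or not feature_ids:
        raise ParseError(f"{path}: no features found")
    sample_ids = header[1:]
    tax_col = None
    if sample_ids and sample_ids[-1].strip().lower() in _TAXONOMY_NAMES:
        tax_col = sample_ids[-1]
        sample_ids = sample_ids[:-1]
        taxonomy = {fid: row[-1] for fid, row in zip(feature_ids, rows)}
        rows = [row[:-1] for row in rows]
    if not sample_ids:
        raise ParseError(f"{path}: no sample columns")
    try:
        values = np.array([[float(v) for v in row] for row in rows])
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric abundance value ({exc})") from exc
    data = pd.DataFrame(values.T, index=sample_ids, columns=feature_ids)
    return FeatureTable(
        data=data,
        kind=kind,
        taxonomy=pd.Series(taxonomy) if tax_col else None,
    )


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a feature table in classic orientation (features as rows)."""
    frame = table.data.T.rename_axis("#OTU ID")
    if table.taxonomy is not None:
        frame = frame.assign(taxonomy=table.taxonomy.reindex(frame.index).fillna(""))
    frame.to_csv(path, sep="\t")


def read_sample_metadata(path) -> pd.Series:
    """Read a two-column sample metadata TSV (sample_id, class)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    frame.columns = [c.lstrip("#").strip().lower() for c in frame.columns]
    renames = {"sampleid": "sample_id", "sample-id": "sample_id"}
    frame = frame.rename(columns=renames)
    if not {"sample_id", "class"}.issubset(frame.columns):
        raise ParseError(f"{path}: metadata needs columns sample_id and class")
    if frame["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample ids in metadata")
    return pd.Series(frame["class"].to_numpy(), index=frame["sample_id"].to_numpy())


def write_sample_metadata(classes: pd.Series, path) -> None:
    pd.DataFrame({"sample_id": classes.index, "class": classes.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_gene_content(path) -> GeneContentTable:
    """Read an OTU x KO copy-count TSV with an ``rrna_copies`` column."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if "rrna_copies" not in frame.columns:
        raise ParseError(f"{path}: gene-content table needs an 'rrna_copies' column")
    rrna = frame.pop("rrna_copies")
    frame = frame.rename_axis(None)
    return GeneContentTable(data=frame, rrna_copies=rrna.rename_axis(None))


def write_gene_content(gc: GeneContentTable, path) -> None:
    frame = gc.data.copy()
    frame["rrna_copies"] = gc.rrna_copies.astype(int)
    frame.index.name = "otu_id"
    frame.to_csv(path, sep="\t")


def read_hierarchy(path) -> PathwayHierarchy:
    """Read a flat KO -> pathway map (columns ko_id, level3_name, level2_name)."""
    return PathwayHierarchy.from_frame(pd.read_csv(path, sep="\t"))


def write_hierarchy(hierarchy: PathwayHierarchy, path) -> None:
    hierarchy.to_frame().to_csv(path, sep="\t", index=False)


def read_substrates(path) -> list[UltimateAnalysis]:
    """Read a substrate characterization table (CSV or TSV by sniffing).

    Requires columns name, ts_pct, vs_pct_ts, c_pct, h_pct, n_pct, s_pct,
    o_pct on the conventional percent scales; optional ``*_sd`` columns.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    frame = pd.read_csv(_io.StringIO(text), sep=delimiter)
    required = {"name", "ts_pct", "vs_pct_ts", "c_pct", "h_pct", "n_pct", "s_pct", "o_pct"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing substrate columns {sorted(missing)}")
    return [validate_ultimate_analysis(row._asdict()) for row in frame.itertuples(index=False)]


def write_substrates(rows: Iterable[UltimateAnalysis], path) -> None:
    records = []
    for ua in rows:
        records.append(
            {
                "name": ua.name,
                "ts_pct": ua.ts * 100,
                "vs_pct_ts": ua.vs_of_ts * 100,
                "c_pct": ua.c * 100,
                "h_pct": ua.h * 100,
                "n_pct": ua.n * 100,
                "s_pct": ua.s * 100,
                "o_pct": ua.o * 100,
            }
        )
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def write_characterization(
    results: Sequence[BMPResult], path, constants: BMPConstants = DEFAULT_CONSTANTS
) -> None:
    """Write per-substrate derived quantities with a constants provenance column."""
    provenance = constants.as_provenance()
    records = [
        {
            "name": r.name,
            "empirical_formula": str(r.formula),
            "thod_gO2_per_gVS": round(r.thod, 6),
            "hhv_MJ_per_t": round(r.hhv, 6),
            "bmp_f_mL_per_gVS": round(r.bmp_f, 6),
            "bmp_b_mL_per_gVS": round(r.bmp_b, 6),
            "bmp_d_mL_per_gVS": round(r.bmp_d, 6),
            "constants": provenance,
        }
        for r in results
    ]
    pd.DataFrame.from_records(records).to_csv(path, sep="\t", index=False)


def write_differential_results(results: Sequence[DifferentialResult], path) -> None:
    records = []
    for r in results:
        row = {
            "feature_id": r.feature_id,
            "kw_h": round(r.kw_h, 6),
            "p_value": r.p_value,
            "effect_size": round(r.effect_size, 6),
            "assigned_class": r.assigned_class,
            "significant": r.significant,
        }
        for cls, mean in sorted(r.class_means.items()):
            row[f"mean_{cls}_ppm"] = round(mean, 6)
        records.append(row)
    pd.DataFrame.from_records(records).to_csv(path, sep="\t", index=False)


def read_differential_results(path) -> list[DifferentialResult]:
    frame = pd.read_csv(path, sep="\t")
    mean_cols = [c for c in frame.columns if c.startswith("mean_") and c.endswith("_ppm")]
    out = []
    for row in frame.itertuples(index=False):
        means = {c[len("mean_"):-len("_ppm")]: float(getattr(row, c)) for c in mean_cols}
        out.append(
            DifferentialResult(
                feature_id=str(row.feature_id),
                class_means=means,
                kw_h=float(row.kw_h),
                p_value=float(row.p_value),
                effect_size=float(row.effect_size),
                assigned_class=str(row.assigned_class),
                significant=bool(row.significant),
            )
        )
    return out


def write_two_group_results(results: Sequence[TwoGroupResult], path) -> None:
    pd.DataFrame.from_records(
        [
            {
                "feature_id": r.feature_id,
                "mean_a_pct": r.mean_a,
                "mean_b_pct": r.mean_b,
                "difference_pct": r.difference,
                "ci95_low": r.ci_low,
                "ci95_high": r.ci_high,
                "welch_t": r.welch_t,
                "welch_df": r.welch_df,
                "p_value": r.p_value,
                "significant": r.significant,
                "degenerate": r.degenerate,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False)


def write_plan(plan: CodigestionPlan, json_path, text_path=None) -> None:
    Path(json_path).write_text(plan.to_json() + "\n", encoding="utf-8")
    if text_path is not None:
        Path(text_path).write_text(plan.to_text() + "\n", encoding="utf-8")


def read_plan(json_path) -> CodigestionPlan:
    return CodigestionPlan.from_json(Path(json_path).read_text(encoding="utf-8"))
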