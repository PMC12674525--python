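"""Delimited-text readers and writers for consumer and source tables.

Layouts mirror typical supplementary isotope tables: one measurement per
row, header-bearing CSV or TSV (autodetected), configurable column-name
mapping. Unicode minus signs and thin/no-break spaces are normalized to
ASCII before numeric parsing.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .records import (
    TRACERS,
    AgeCategoryScheme,
    ConsumerRecord,
    QCCriteria,
    SourceSpec,
    StudyDataset,
    assign_age_category,
    default_age_scheme,
    qc_filter,
)

__all__ = [
    "SchemaError",
    "DuplicateKeyError",
    "read_consumer_table",
    "write_consumer_table",
    "read_source_table",
    "write_source_table",
    "build_study_dataset",
]


class SchemaError(ValueError):
    """A table lacks mandatory columns or has malformed structure."""


class DuplicateKeyError(ValueError):
    """Two rows share (individual_id, tissue, slice_index)."""


_UNICODE_CLEANUP = str.maketrans(
    {
        "−": "-",  # minus sign
        "–": "-",  # en dash used as minus in some exports
        " ": "",  # thin space
        " ": "",  # narrow no-break space
        " ": " ",  # no-break space
    }
)

_CONSUMER_COLUMNS = {
    "individual_id",
    "tissue",
    "d13c",
    "d15n",
}
_OPTIONAL_CONSUMER_COLUMNS = {
    "subgroup",
    "site",
    "slice_index",
    "pct_c",
    "pct_n",
    "cn_ratio",
    "collagen_yield",
    "tooth_type",
    "segment",
    "age_years",
}


def _read_clean_table(path, column_map: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
    text = Path(path).read_text(encoding="utf-8").translate(_UNICODE_CLEANUP)
    df = pd.read_csv(_io.StringIO(text), sep=None, engine="python")
    df.columns = [str(c).strip().lower() for c in df.columns]
    if column_map:
        df = df.rename(columns={k.lower(): v for k, v in column_map.items()})
    return df


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        return float("nan")


def read_consumer_table(
    path,
    column_map: Optional[Mapping[str, str]] = None,
) -> list[ConsumerRecord]:
    """Read one-measurement-per-row consumer records.

    Mandatory columns: individual_id, tissue, d13c, d15n. Dentine rows
    additionally require slice_index. Subgroup may be given directly or
    derived later by :func:`build_study_dataset` from tooth anatomy
    (tooth_type, segment) or bone age_years.
    """
    df = _read_clean_table(path, column_map)
    missing = sorted(_CONSUMER_COLUMNS - set(df.columns))
    if missing:
        raise SchemaError(f"consumer table missing columns: {missing}")
    records: list[ConsumerRecord] = []
    seen: set[tuple] = set()
    for _, row in df.iterrows():
        tissue = str(row["tissue"]).strip().lower()
        slice_index = None
        if "slice_index" in df.columns:
            si = _opt_float(row.get("slice_index"))
            if si is not None and not np.isnan(si):
                slice_index = int(si)
        key = (str(row["individual_id"]), tissue, slice_index)
        if key in seen:
            raise DuplicateKeyError(f"duplicate record key {key}")
        seen.add(key)
        rec = ConsumerRecord(
            individual_id=str(row["individual_id"]),
            subgroup=str(row["subgroup"]) if "subgroup" in df.columns and pd.notna(row.get("subgroup")) else "",
            tissue=tissue,
            slice_index=slice_index if tissue == "dentine" else None,
            d13c=float(row["d13c"]),
            d15n=float(row["d15n"]),
            pct_c=_opt_float(row.get("pct_c")),
            pct_n=_opt_float(row.get("pct_n")),
            cn_ratio=_opt_float(row.get("cn_ratio")),
            collagen_yield=_opt_float(row.get("collagen_yield")),
            site=str(row["site"]) if "site" in df.columns and pd.notna(row.get("site")) else "",
        )
        # carry anatomy / age columns for later subgroup assignment
        extra = {}
        for c in ("tooth_type", "segment", "age_years"):
            if c in df.columns and pd.notna(row.get(c)):
                extra[c] = row[c]
        if extra:
            object.__setattr__(rec, "_anatomy", extra)
        records.append(rec)
    return records


def write_consumer_table(records: Sequence[ConsumerRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "individual_id": r.individual_id,
                "site": r.site,
                "subgroup": r.subgroup,
                "tissue": r.tissue,
                "slice_index": r.slice_index,
                "d13c": r.d13c,
                "d15n": r.d15n,
                "pct_c": r.pct_c,
                "pct_n": r.pct_n,
                "cn_ratio": r.cn_ratio,
                "collagen_yield": r.collagen_yield,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_source_table(
    path,
    tef: Optional[Mapping[str, Mapping[str, tuple[float, float]]]] = None,
    conc: Optional[Mapping[str, Mapping[str, float]]] = None,
    column_map: Optional[Mapping[str, str]] = None,
    default_tef: Mapping[str, tuple[float, float]] = None,
) -> list[SourceSpec]:
    """Read a long-format source sample table (columns: source, d13c, d15n).

    TEFs and concentrations are configuration, not sample data; supply them
    per source name via ``tef`` / ``conc`` (or a shared ``default_tef``).
    """
    df = _read_clean_table(path, column_map)
    needed = {"source", "d13c", "d15n"}
    missing = sorted(needed - set(df.columns))
    if missing:
        raise SchemaError(f"source table missing columns: {missing}")
    if default_tef is None:
        default_tef = {"d13c": (1.0, 0.0), "d15n": (3.0, 0.0)}
    tef = tef or {}
    conc = conc or {}
    sources: list[SourceSpec] = []
    for name, grp in df.groupby("source", sort=False):
        sources.append(
            SourceSpec(
                name=str(name),
                samples={t: grp[t].astype(float).to_numpy() for t in TRACERS},
                tef=dict(tef.get(str(name), default_tef)),
                conc=dict(conc.get(str(name), {"C": 0.45, "N": 0.13})),
            )
        )
    return sources


def write_source_table(sources: Sequence[SourceSpec], path) -> None:
    rows = []
    for s in sources:
        n = max(s.n_samples(t) for t in s.samples)
        for i in range(n):
            row = {"source": s.name}
            for t, v in s.samples.items():
                row[t] = float(v[i]) if i < v.size else np.nan
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _assign_subgroup(rec: ConsumerRecord, scheme: AgeCategoryScheme) -> str:
    """Resolve a record's age category from explicit label, anatomy or age."""
    if rec.subgroup:
        return rec.subgroup
    anatomy = getattr(rec, "_anatomy", {})
    if "age_years" in anatomy:
        return scheme.category_of_age(float(anatomy["age_years"]))
    if "tooth_type" in anatomy and "segment" in anatomy:
        return assign_age_category(
            str(anatomy["tooth_type"]).strip().lower(),
            str(anatomy["segment"]).strip().lower(),
            scheme,
        )
    raise SchemaError(
        f"record {rec.individual_id!r} has no subgroup and no anatomy/age columns"
    )


def build_study_dataset(
    consumers: Sequence[ConsumerRecord],
    sources: Sequence[SourceSpec],
    *,
    qc: QCCriteria = QCCriteria(),
    scheme: Optional[AgeCategoryScheme] = None,
    subgroups: Optional[Sequence[str]] = None,
    tracers: tuple[str, ...] = TRACERS,
    apply_qc: bool = True,
) -> StudyDataset:
    """Validate, QC-filter and age-assign raw records into model input.

    Applies, in order: quality filtering, subgroup (age-category)
    assignment where not explicit, and the under-age exclusion (records in
    categories entirely below ``scheme.exclusion_age`` are dropped, both
    dentine and bone).
    """
    scheme = scheme or default_age_scheme()
    if apply_qc:
        kept, rejected = qc_filter(list(consumers), qc)
    else:
        kept, rejected = list(consumers), []
    labeled: list[ConsumerRecord] = []
    for rec in kept:
        sub = _assign_subgroup(rec, scheme)
        if sub != rec.subgroup:
            rec = ConsumerRecord(
                individual_id=rec.individual_id,
                subgroup=sub,
                tissue=rec.tissue,
                slice_index=rec.slice_index,
                d13c=rec.d13c,
                d15n=rec.d15n,
                pct_c=rec.pct_c,
                pct_n=rec.pct_n,
                cn_ratio=rec.cn_ratio,
                collagen_yield=rec.collagen_yield,
                site=rec.site,
            )
        labeled.append(rec)
    dropped_labels = scheme.excluded_categories()
    excluded = [r for r in labeled if r.subgroup in dropped_labels]
    retained = [r for r in labeled if r.subgroup not in dropped_labels]
    return StudyDataset(
        consumers=retained,
        sources=list(sources),
        tracers=tracers,
        subgroups=tuple(subgroups) if subgroups else (),
        qc_rejected=rejected,
        excluded=excluded,
    )
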