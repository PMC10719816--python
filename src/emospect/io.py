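"""Reading and writing review tables and result tables.

Review column dictionary (CSV and JSONL share it): review_id, source,
drug, text, age, age_band, duration_months, duration_band, rating_year,
satisfaction_raw, satisfaction_scale.  Bands are recomputed from age /
duration_months when those are present; explicit band columns cover
records (e.g. synthetic ones) that carry only the band.
"""

from __future__ import annotations

import json
from typing import Optional, Sequence

import pandas as pd

from .preprocess import ReviewRecord, band_age, band_duration
from .stats import standardize_satisfaction

__all__ = [
    "read_reviews",
    "write_reviews_csv",
    "write_reviews_jsonl",
    "records_to_frame",
    "write_annotations_tsv",
]

_COLUMNS = [
    "review_id", "source", "drug", "text", "age", "age_band",
    "duration_months", "duration_band", "rating_year",
    "satisfaction_raw", "satisfaction_scale",
]


def _record_from_row(row: dict) -> ReviewRecord:
    def _get(key):
        v = row.get(key)
        if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
            return None
        return v

    age = _get("age")
    age = int(age) if age is not None else None
    months = _get("duration_months")
    months = float(months) if months is not None else None
    age_band = band_age(age) if age is not None else _get("age_band")
    dur_band = band_duration(months) if months is not None else _get("duration_band")
    raw = _get("satisfaction_raw")
    raw = int(raw) if raw is not None else None
    scale = int(_get("satisfaction_scale") or 5)
    sat5 = float(standardize_satisfaction(raw, scale)) if raw is not None else None
    year = _get("rating_year")
    return ReviewRecord(
        review_id=str(row["review_id"]),
        source=str(_get("source") or "synthetic"),
        drug=str(row["drug"]),
        text=str(_get("text") or ""),
        age=age,
        age_band=age_band,
        duration_months=months,
        duration_band=dur_band,
        rating_year=int(year) if year is not None else None,
        satisfaction_raw=raw,
        satisfaction_scale=scale,
        satisfaction_5=sat5,
    )


def read_reviews(path) -> list[ReviewRecord]:
    """Load a review table from .csv or .jsonl by extension."""
    path = str(path)
    if path.endswith(".jsonl"):
        rows = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    rows.append(json.loads(line))
    else:
        rows = pd.read_csv(path).to_dict("records")
    return [_record_from_row(r) for r in rows]


def records_to_frame(records: Sequence[ReviewRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "review_id": r.review_id,
                "source": r.source,
                "drug": r.drug,
                "text": r.text,
                "age": r.age,
                "age_band": r.age_band,
                "duration_months": r.duration_months,
                "duration_band": r.duration_band,
                "rating_year": r.rating_year,
                "satisfaction_raw": r.satisfaction_raw,
                "satisfaction_scale": r.satisfaction_scale,
            }
            for r in records
        ],
        columns=_COLUMNS,
    )


def write_annotations_tsv(annotations, path) -> None:
    """Annotation dump: one matched term per line with its class lineage."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("review_id\tspan_start\tspan_end\tmatched_term\ttertiary\tsecondary\tprimary\n")
        for a in annotations:
            fh.write(
                f"{a.review_id}\t{a.span[0]}\t{a.span[1]}\t{a.matched_term}\t"
                f"{a.tertiary_class}\t{a.secondary_class}\t{a.primary_class}\n"
            )


def write_reviews_csv(records: Sequence[ReviewRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def write_reviews_jsonl(records: Sequence[ReviewRecord], path) -> None:
    df = records_to_frame(records)
    with open(path, "w", encoding="utf-8") as fh:
        for row in df.to_dict("records"):
            clean_row = {k: (None if pd.isna(v) else v) for k, v in row.items()} if any(
                isinstance(v, float) for v in row.values()
            ) else row
            fh.write(json.dumps(clean_row) + "\n")
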