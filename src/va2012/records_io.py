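"""Record CSV/JSON dialect.

CSV: one row per decedent; columns ``record_id, age_group, sex`` then one
column per indicator_id with values Y/N/DK/NA (empty = not asked).
The JSON mirror uses the same vocabulary with full response words.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .questionnaire import VARecord

__all__ = ["records_to_frame", "frame_to_records", "write_records_csv",
           "read_records_csv", "write_records_json", "read_records_json"]

_TO_SYMBOL = {"yes": "Y", "no": "N", "dont_know": "DK", "not_applicable": "NA"}
_FROM_SYMBOL = {v: k for k, v in _TO_SYMBOL.items()}

META_COLUMNS = ("record_id", "age_group", "sex")


def records_to_frame(
    records: Iterable[VARecord], indicator_order: Sequence[str] | None = None
) -> pd.DataFrame:
    records = list(records)
    if indicator_order is None:
        seen: dict[str, None] = {}
        for rec in records:
            for iid in rec.responses:
                seen.setdefault(iid)
        indicator_order = list(seen)
    rows = []
    for rec in records:
        row = {"record_id": rec.record_id, "age_group": rec.age_group, "sex": rec.sex}
        for iid in indicator_order:
            resp = rec.responses.get(iid)
            row[iid] = "" if resp is None else _TO_SYMBOL[resp]
        rows.append(row)
    return pd.DataFrame(rows, columns=list(META_COLUMNS) + list(indicator_order))


def frame_to_records(frame: pd.DataFrame) -> list[VARecord]:
    indicator_cols = [c for c in frame.columns if c not in META_COLUMNS]
    records = []
    for _, row in frame.iterrows():
        responses = {}
        for iid in indicator_cols:
            val = row[iid]
            if pd.isna(val) or val == "":
                continue
            sym = str(val).strip().upper()
            if sym not in _FROM_SYMBOL:
                raise ValueError(
                    f"record {row['record_id']!r}, indicator {iid}: "
                    f"bad response symbol {val!r}"
                )
            responses[iid] = _FROM_SYMBOL[sym]
        records.append(
            VARecord(
                record_id=str(row["record_id"]),
                age_group=str(row["age_group"]),
                sex=str(row["sex"]),
                responses=responses,
            )
        )
    return records


def write_records_csv(
    records: Iterable[VARecord],
    path: str | Path,
    indicator_order: Sequence[str] | None = None,
) -> None:
    records_to_frame(records, indicator_order).to_csv(path, index=False)


def read_records_csv(path: str | Path) -> list[VARecord]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return frame_to_records(frame)


def write_records_json(records: Iterable[VARecord], path: str | Path) -> None:
    payload = [
        {
            "record_id": r.record_id,
            "age_group": r.age_group,
            "sex": r.sex,
            "responses": dict(r.responses),
        }
        for r in records
    ]
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_records_json(path: str | Path) -> list[VARecord]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return [
        VARecord(
            record_id=str(r["record_id"]),
            age_group=r["age_group"],
            sex=r.get("sex", "unknown"),
            responses=dict(r.get("responses", {})),
        )
        for r in payload
    ]
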