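"""Readers and writers for observation records, schemes, and schedules.

Observation records travel as CSV with columns ``colony_id,
interval_index, interval_months, height_start_cm, height_end_cm``; an empty
cell or the sentinel ``DEAD`` in ``height_end_cm`` marks death.  Schemes,
survival schedules, and matrices round-trip through JSON.
"""

from __future__ import annotations

import json
from typing import Iterable

import numpy as np
import pandas as pd

from .scheme import DEAD, HeightRecord, SizeClassScheme

__all__ = [
    "read_records_csv",
    "write_records_csv",
    "read_scheme_json",
    "write_scheme_json",
    "read_survival_json",
    "write_survival_json",
]

RECORD_COLUMNS = [
    "colony_id",
    "interval_index",
    "interval_months",
    "height_start_cm",
    "height_end_cm",
]


def write_records_csv(records: Iterable[HeightRecord], path) -> None:
    rows = [
        {
            "colony_id": r.colony_id,
            "interval_index": r.interval_index,
            "interval_months": r.interval_length_mo,
            "height_start_cm": r.height_start_cm,
            "height_end_cm": DEAD if r.died else r.height_end_cm,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False)


def read_records_csv(path) -> list[HeightRecord]:
    df = pd.read_csv(path, dtype={"colony_id": str, "height_end_cm": str})
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records CSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        end_raw = row.height_end_cm
        dead = (
            end_raw is None
            or (isinstance(end_raw, float) and np.isnan(end_raw))
            or str(end_raw).strip() in ("", DEAD)
        )
        records.append(
            HeightRecord(
                colony_id=str(row.colony_id),
                interval_index=int(row.interval_index),
                interval_length_mo=float(row.interval_months),
                height_start_cm=float(row.height_start_cm),
                height_end_cm=None if dead else float(end_raw),
            )
        )
    return records


def write_scheme_json(scheme: SizeClassScheme, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "classes": [list(c) for c in scheme.classes],
                "absorbing_label": scheme.absorbing_label,
                "resolution_cm": scheme.resolution_cm,
            },
            fh,
            indent=1,
        )


def read_scheme_json(path) -> SizeClassScheme:
    with open(path) as fh:
        d = json.load(fh)
    return SizeClassScheme(
        classes=tuple(tuple(c) for c in d["classes"]),
        absorbing_label=d["absorbing_label"],
        resolution_cm=d.get("resolution_cm", 0.1),
    )


def write_survival_json(survival: dict[str, float], path) -> None:
    with open(path, "w") as fh:
        json.dump(survival, fh, indent=1)


def read_survival_json(path) -> dict[str, float]:
    with open(path) as fh:
        return {str(k): float(v) for k, v in json.load(fh).items()}
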