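"""Reading and writing record tables, weight tables and statistics.

All tabular artifacts are plain UTF-8 TSV; statistics are JSON.  Reals are
serialized with ``repr`` so that a write/read round-trip is exact.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd

from .records import QuasiSmilesRecord, SET_LABELS

__all__ = [
    "read_records",
    "write_records",
    "write_weights",
    "read_weights",
    "write_stats",
    "read_stats",
]


def read_records(source) -> list[QuasiSmilesRecord]:
    """Read records from a TSV/CSV file (or file-like / DataFrame).

    Required columns: ``id``, ``quasi_smiles``, ``endpoint``; optional
    ``set_label``.  Delimiter is sniffed from the extension (``.csv`` →
    comma, otherwise tab).  Duplicate ids and non-numeric endpoints are
    rejected with the offending row named.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        sep = "," if str(source).endswith(".csv") else "\t"
        df = pd.read_csv(source, sep=sep, dtype=str)
    missing = {"id", "quasi_smiles", "endpoint"} - set(df.columns)
    if missing:
        raise ValueError(f"missing required column(s): {sorted(missing)}")

    dup = df["id"][df["id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate record id(s): {sorted(dup.unique())}")

    records = []
    for _, row in df.iterrows():
        try:
            endpoint = float(row["endpoint"])
        except (TypeError, ValueError):
            raise ValueError(
                f"non-numeric endpoint {row['endpoint']!r} in row id={row['id']}"
            ) from None
        if pd.isna(row["endpoint"]):
            raise ValueError(f"missing endpoint in row id={row['id']}")
        label = row.get("set_label")
        if label is not None and (pd.isna(label) or label == ""):
            label = None
        records.append(
            QuasiSmilesRecord(
                id=int(row["id"]),
                quasi_smiles=str(row["quasi_smiles"]),
                endpoint=endpoint,
                set_label=label,
            )
        )
    return records


def write_records(records: Iterable[QuasiSmilesRecord], path) -> None:
    """Write records as TSV with columns id, quasi_smiles, endpoint, set_label."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("id\tquasi_smiles\tendpoint\tset_label\n")
        for rec in records:
            label = rec.set_label or ""
            fh.write(f"{rec.id}\t{rec.quasi_smiles}\t{rec.endpoint!r}\t{label}\n")


def write_weights(weight_table, path) -> None:
    """Write a weight table as TSV: code, weight, rare flag (0/1)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("code\tweight\trare\n")
        for code in sorted(weight_table.weights):
            rare = 1 if code in weight_table.rare_codes else 0
            fh.write(f"{code}\t{weight_table.weights[code]!r}\t{rare}\n")


def read_weights(path):
    """Read a weight TSV back into a :class:`~quasicw.descriptor.WeightTable`."""
    from .descriptor import WeightTable

    df = pd.read_csv(path, sep="\t", dtype={"code": str})
    weights = dict(zip(df["code"], df["weight"].astype(float)))
    rare = set(df.loc[df["rare"] == 1, "code"])
    return WeightTable(weights=weights, rare_codes=rare)


def write_stats(stats_by_set: dict, path) -> None:
    """Serialize per-set statistics (Table-style columns) to JSON.

    ``stats_by_set`` maps a set label to a :class:`SetStatistics` or a
    plain dict of its fields.
    """
    payload = {}
    for label, stats in stats_by_set.items():
        if hasattr(stats, "as_dict"):
            payload[label] = stats.as_dict()
        else:
            payload[label] = dict(stats)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_stats(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
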