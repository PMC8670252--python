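"""Generic tabular I/O for stage outputs and small annotation tables."""

from __future__ import annotations

from dataclasses import asdict, is_dataclass
from typing import Mapping

import pandas as pd

from .errors import ValidationError


def records_to_frame(records) -> pd.DataFrame:
    """Coerce a homogeneous record collection to a DataFrame.

    Accepts a DataFrame, a list of dataclasses, or a list of mappings; all
    records must share a schema.
    """
    if isinstance(records, pd.DataFrame):
        return records
    rows = list(records)
    if not rows:
        return pd.DataFrame()
    dicts = []
    for r in rows:
        if is_dataclass(r) and not isinstance(r, type):
            dicts.append(asdict(r))
        elif isinstance(r, Mapping):
            dicts.append(dict(r))
        else:
            raise ValidationError(f"cannot serialize record of type {type(r).__name__}")
    schema = tuple(dicts[0].keys())
    for d in dicts[1:]:
        if tuple(d.keys()) != schema:
            raise ValidationError(
                f"heterogeneous record schemas: {schema} vs {tuple(d.keys())}"
            )
    return pd.DataFrame(dicts, columns=list(schema))


def write_table(records, path, float_digits: int = 6) -> None:
    """Write records as UTF-8 TSV: one header row, deterministic column order,
    floats at *float_digits* significant digits."""
    frame = records_to_frame(records)
    frame.to_csv(path, sep="\t", index=False, float_format=f"%.{float_digits}g",
                 encoding="utf-8")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_probe_map(path) -> pd.DataFrame:
    """Probe-to-feature map TSV with columns probe_id, feature_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"probe_id", "feature_id"} - set(df.columns)
    if missing:
        raise ValidationError(f"probe map {path} lacks columns {sorted(missing)}")
    return df[["probe_id", "feature_id"]]


def read_ko_annotation(path) -> pd.DataFrame:
    """KO-term annotation TSV with columns gene_id, ko_term (one term per row)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene_id", "ko_term"} - set(df.columns)
    if missing:
        raise ValidationError(f"KO annotation {path} lacks columns {sorted(missing)}")
    return df[["gene_id", "ko_term"]]
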