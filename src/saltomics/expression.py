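"""Experiment design and expression matrices.

An :class:`ExpressionTable` wraps a pandas DataFrame whose columns are a
``(timepoint, replicate)`` MultiIndex.  Replicated tables (log2 signals or
per-replicate log2 fold changes) carry integer replicate labels; replicate-
mean tables use the single replicate label ``"mean"``.  Missing values are
NaN, never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DesignError, ParseError, ValidationError

MEAN = "mean"


@dataclass(frozen=True)
class ExperimentDesign:
    """Sampling scheme: ordered time points (hours), reference first."""

    timepoints: tuple[float, ...] = (0.0, 0.5, 2.0, 24.0)
    replicates_per_timepoint: int = 2

    def __post_init__(self) -> None:
        tps = tuple(float(t) for t in self.timepoints)
        object.__setattr__(self, "timepoints", tps)
        if len(tps) < 2:
            raise ValidationError("design needs >= 2 timepoints")
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValidationError("timepoints must be strictly increasing")
        if self.replicates_per_timepoint < 1:
            raise ValidationError("replicates_per_timepoint must be >= 1")

    @property
    def reference(self) -> float:
        return self.timepoints[0]

    @property
    def treated_timepoints(self) -> tuple[float, ...]:
        return self.timepoints[1:]

    def columns(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_tuples(
            [
                (tp, rep)
                for tp in self.timepoints
                for rep in range(1, self.replicates_per_timepoint + 1)
            ],
            names=["timepoint", "replicate"],
        )


def format_timepoint(tp: float) -> str:
    return f"{tp:g}"


def _column_label(tp: float, rep) -> str:
    if rep == MEAN:
        return f"{format_timepoint(tp)}h"
    return f"{format_timepoint(tp)}h_r{rep}"


def _parse_column_label(label: str):
    """Invert :func:`_column_label`; raises ParseError on unparseable labels."""
    if "_r" in label:
        tp_part, rep_part = label.rsplit("_r", 1)
        try:
            rep = int(rep_part)
        except ValueError:
            raise ParseError(f"bad replicate in column label {label!r}") from None
    else:
        tp_part, rep = label, MEAN
    if not tp_part.endswith("h"):
        raise ParseError(f"column label {label!r} lacks the 'h' unit suffix")
    try:
        tp = float(tp_part[:-1])
    except ValueError:
        raise ParseError(f"bad timepoint in column label {label!r}") from None
    return tp, rep


@dataclass
class ExpressionTable:
    """Feature (or probe) x (timepoint, replicate) matrix of log2 values."""

    data: pd.DataFrame
    value_kind: str = "signal"  # "signal" | "log2fc"

    def __post_init__(self) -> None:
        if self.value_kind not in ("signal", "log2fc"):
            raise ValidationError(f"bad value_kind {self.value_kind!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate row id {dup!r}")
        if not isinstance(self.data.columns, pd.MultiIndex):
            raise ValidationError("columns must be a (timepoint, replicate) MultiIndex")

    @property
    def row_ids(self) -> pd.Index:
        return self.data.index

    @property
    def timepoints(self) -> tuple[float, ...]:
        return tuple(dict.fromkeys(self.data.columns.get_level_values(0)))

    def validate_against(self, design: ExperimentDesign) -> None:
        """Check column labels match the design (reference optional for log2fc)."""
        tps = set(self.data.columns.get_level_values(0))
        expected = set(design.timepoints)
        allowed = (
            expected if self.value_kind == "signal" else expected | set(design.treated_timepoints)
        )
        if self.value_kind == "signal" and tps != expected:
            raise DesignError(
                f"table timepoints {sorted(tps)} != design timepoints {sorted(expected)}"
            )
        if not tps <= allowed:
            raise DesignError(f"table timepoints {sorted(tps)} not in design {sorted(expected)}")
        reps = set(self.data.columns.get_level_values(1))
        if reps != {MEAN}:
            bad = {r for r in reps if r != MEAN and not (1 <= int(r) <= design.replicates_per_timepoint)}
            if bad:
                raise DesignError(f"replicate labels {sorted(map(str, bad))} exceed design")

    def replicate_means(self) -> pd.DataFrame:
        """Per-timepoint replicate means (NaN-aware), columns = timepoints."""
        return self.data.T.groupby(level="timepoint").mean().T


def read_expression(path, design: ExperimentDesign | None = None,
                    value_kind: str = "signal") -> ExpressionTable:
    """Read a TSV expression matrix; header labels like ``0.5h_r1`` or ``24h``."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    columns = [_parse_column_label(c) for c in df.columns]
    body = np.empty(df.shape, dtype=float)
    values = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = values[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
                body[i, j] = np.nan
                continue
            try:
                body[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {cell!r} at row "
                    f"{df.index[i]!r}, column {df.columns[j]!r}"
                ) from None
    out = pd.DataFrame(
        body,
        index=df.index,
        columns=pd.MultiIndex.from_tuples(columns, names=["timepoint", "replicate"]),
    )
    table = ExpressionTable(out, value_kind=value_kind)
    if design is not None:
        table.validate_against(design)
    return table


def write_expression(table: ExpressionTable, path) -> None:
    """Write an :class:`ExpressionTable` as TSV with flat column labels."""
    flat = table.data.copy()
    flat.columns = [_column_label(tp, rep) for tp, rep in table.data.columns]
    flat.index.name = "feature_id"
    # no float_format: repr round-trips exactly
    flat.to_csv(path, sep="\t")
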