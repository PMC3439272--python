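"""Experimental data tables and their conversion to per-condition node weights.

A :class:`DataSet` is a thin wrapper over a pandas DataFrame: one designated
identifier column plus named numeric condition columns (missing values are
NaN; ``NA`` and the empty string are missing on input).  The walk engine
needs strictly positive multiplicative weights, so log2-ratio data is mapped
through ``2**x`` (up-analysis) or ``2**(-x)`` (down-analysis); genes without
a measurement get the neutral weight 1 and behave exactly as in the uniform
baseline walk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("edgeflux")

MISSING_MARKERS = ["", "NA"]
_FLOAT_MAX = float(np.finfo(np.float64).max)

__all__ = [
    "DataSet",
    "MappingReport",
    "read_data_table",
    "read_alias_table",
    "average_replicates",
    "normalize_to_baseline",
    "map_identifiers",
    "to_weights",
]


@dataclass
class DataSet:
    frame: pd.DataFrame
    id_column: str

    def __post_init__(self):
        if self.id_column not in self.frame.columns:
            raise ValueError(
                f"identifier column {self.id_column!r} not in table "
                f"(columns: {list(self.frame.columns)})")
        if self.frame.columns.duplicated().any():
            dupes = self.frame.columns[self.frame.columns.duplicated()]
            raise ValueError(f"duplicate column names: {list(dupes)}")

    @property
    def value_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c != self.id_column]

    @property
    def identifiers(self) -> pd.Series:
        return self.frame[self.id_column]

    def column(self, name: str) -> pd.Series:
        if name not in self.frame.columns:
            raise KeyError(f"no column {name!r} in dataset")
        return pd.to_numeric(self.frame[name], errors="coerce")

    def copy(self) -> "DataSet":
        return DataSet(self.frame.copy(), self.id_column)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_data_table(path, id_column: str | int = 0) -> DataSet:
    """Read a TSV data table with a header row.

    ``id_column`` may be a column name or a 0-based index.
    """
    frame = pd.read_csv(path, sep="\t", na_values=MISSING_MARKERS,
                        keep_default_na=False, comment="#", dtype={0: str})
    if isinstance(id_column, int):
        id_column = frame.columns[id_column]
    frame[id_column] = frame[id_column].astype(str)
    return DataSet(frame, id_column)


def read_alias_table(path) -> dict[str, str]:
    """Two-column TSV alias -> canonical symbol."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(f"{path}: malformed alias line {lineno}: {line!r}")
            out[fields[0].strip()] = fields[1].strip()
    return out


def average_replicates(dataset: DataSet,
                       groups: Mapping[str, Sequence[str]]) -> DataSet:
    """Collapse replicate columns to their arithmetic means.

    Each entry of ``groups`` maps a new column name to its member columns;
    missing values are skipped, an all-missing row stays missing.  The
    result has the identifier column plus one column per group.
    """
    data = {dataset.id_column: dataset.identifiers}
    for new_col, members in groups.items():
        members = list(members)
        if not members:
            raise ValueError(f"replicate group {new_col!r} is empty")
        for m in members:
            if m not in dataset.frame.columns:
                raise KeyError(f"replicate group {new_col!r}: no column {m!r}")
        block = pd.concat([dataset.column(m) for m in members], axis=1)
        data[new_col] = block.mean(axis=1, skipna=True)
    return DataSet(pd.DataFrame(data), dataset.id_column)


def normalize_to_baseline(dataset: DataSet, baseline_column: str,
                          mode: str = "ratio") -> DataSet:
    """Divide every condition by the baseline column (fold change).

    ``mode='ratio'`` gives value/baseline, ``'log2-ratio'`` its log2.  Rows
    whose baseline is zero, negative or missing cannot be normalized: their
    outputs become missing with a warning.  The baseline column itself
    becomes all 1 (ratio) or all 0 (log2-ratio).
    """
    if mode not in ("ratio", "log2-ratio"):
        raise ValueError(f"mode must be 'ratio' or 'log2-ratio', got {mode!r}")
    if baseline_column not in dataset.frame.columns:
        raise KeyError(f"no baseline column {baseline_column!r}")
    base = dataset.column(baseline_column)
    bad = ~(base > 0)  # includes NaN
    if bad.any():
        logger.warning(
            "normalize_to_baseline: %d row(s) have nonpositive or missing "
            "baseline; outputs set to missing", int(bad.sum()))
    data = {dataset.id_column: dataset.identifiers}
    for col in dataset.value_columns:
        vals = dataset.column(col) / base
        vals[bad] = np.nan
        if mode == "log2-ratio":
            with np.errstate(divide="ignore", invalid="ignore"):
                vals = np.log2(vals.where(vals > 0))
        data[col] = vals
    return DataSet(pd.DataFrame(data), dataset.id_column)


@dataclass
class MappingReport:
    unmapped: list[str] = field(default_factory=list)
    collapsed: dict[str, int] = field(default_factory=dict)

    @property
    def n_unmapped(self) -> int:
        return len(self.unmapped)


def map_identifiers(dataset: DataSet, alias_table: Mapping[str, str],
                    collapse: str = "absmax") -> tuple[DataSet, MappingReport]:
    """Rewrite identifiers to canonical symbols and collapse duplicates.

    Unmapped identifiers pass through unchanged and are listed in the
    report.  Rows mapping to the same symbol collapse per column: the value
    of largest magnitude (``collapse='absmax'``, sign kept — the most
    extreme signal wins) or the mean (``'mean'``).
    """
    if collapse not in ("absmax", "mean"):
        raise ValueError(f"collapse must be 'absmax' or 'mean', got {collapse!r}")
    report = MappingReport()
    ids = dataset.identifiers.astype(str)
    mapped = ids.map(lambda x: alias_table.get(x, x))
    report.unmapped = sorted(set(ids[~ids.isin(alias_table)]))
    frame = dataset.frame.copy()
    frame[dataset.id_column] = mapped.values
    value_cols = dataset.value_columns
    counts = frame[dataset.id_column].value_counts()
    report.collapsed = {
        sym: int(n) for sym, n in counts.items() if n > 1}

    def _absmax(s: pd.Series):
        s = pd.to_numeric(s, errors="coerce").dropna()
        if s.empty:
            return np.nan
        return s.iloc[int(np.argmax(np.abs(s.to_numpy())))]

    agg = _absmax if collapse == "absmax" else "mean"
    numeric = frame[value_cols].apply(pd.to_numeric, errors="coerce")
    numeric[dataset.id_column] = frame[dataset.id_column]
    collapsed = numeric.groupby(dataset.id_column, sort=True).agg(agg)
    collapsed = collapsed.reset_index()
    return DataSet(collapsed, dataset.id_column), report


def to_weights(dataset: DataSet, column: str, transform: str = "up",
               missing_fill: float = 1.0, floor: float = 1e-8,
               nodes: Iterable[str] | None = None) -> dict[str, float]:
    """Turn one data column into strictly positive node weights.

    ``identity`` uses the values as-is (they must be positive up to floor
    repair); ``up`` maps a log2-ratio x to 2**x, ``down`` to 2**(-x) so the
    two directions are reciprocal.  Genes absent from the column, and
    missing cells, get ``missing_fill``; everything is floored at ``floor``.
    If ``nodes`` is given, the output covers exactly those genes.
    """
    if transform not in ("identity", "up", "down"):
        raise ValueError(
            f"transform must be 'identity', 'up' or 'down', got {transform!r}")
    vals = dataset.column(column)
    ids = dataset.identifiers.astype(str)
    raw: dict[str, float] = {}
    for gene, x in zip(ids, vals):
        if not np.isfinite(x):
            continue
        if transform == "identity":
            if x <= 0:
                raise ValueError(
                    f"identity transform: column {column!r} has nonpositive "
                    f"value {x} for {gene!r}; use the 'up' or 'down' "
                    "transform for log-ratio data")
            raw[gene] = float(x)
        elif transform == "up":
            # exp2 may overflow to inf; clamp to keep weights finite
            with np.errstate(over="ignore"):
                raw[gene] = float(min(np.exp2(x), _FLOAT_MAX))
        else:
            with np.errstate(over="ignore"):
                raw[gene] = float(min(np.exp2(-x), _FLOAT_MAX))
    target = set(nodes) if nodes is not None else set(ids)
    out: dict[str, float] = {}
    for gene in target:
        w = raw.get(gene, missing_fill)
        if not np.isfinite(w):
            w = missing_fill
        out[gene] = max(w, floor)
    return out
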