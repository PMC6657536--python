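"""Long-format aggregometry dataset container and CSV I/O.

The interchange format is a plain CSV (UTF-8, "." decimal separator) with
header columns ``subject_id, dose, group, time_min, aggregation_pct`` —
one row per observation, one trace per (subject, dose, group).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["AggregationDataset", "read_dataset", "write_dataset", "COLUMNS"]

log = logging.getLogger(__name__)

COLUMNS = ("subject_id", "dose", "group", "time_min", "aggregation_pct")

#: Percent-aggregation values outside this range are physiologically
#: implausible and trigger a warning (not rejection: noise can overshoot).
PLAUSIBLE_RANGE = (-20.0, 120.0)


@dataclass
class AggregationDataset:
    """Validated long-format table of aggregometry traces."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset is missing required column(s): {missing}")
        if len(df) == 0:
            raise ValueError("dataset is empty")
        for col in ("time_min", "aggregation_pct"):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"column {col!r} has an unparseable numeric value at row {row}"
                )
            if vals.isna().any():
                row = int(np.flatnonzero(vals.isna().to_numpy())[0])
                raise ValueError(f"column {col!r} has a missing value at row {row}")
            df[col] = vals.astype(float)
        if not np.all(np.isfinite(df["aggregation_pct"])):
            raise ValueError("aggregation_pct contains non-finite values")
        if df["time_min"].min() < 0:
            raise ValueError("time_min must be >= 0")
        lo, hi = PLAUSIBLE_RANGE
        n_out = int(((df["aggregation_pct"] < lo) | (df["aggregation_pct"] > hi)).sum())
        if n_out:
            warnings.warn(
                f"{n_out} aggregation values fall outside the plausible range "
                f"[{lo:g}, {hi:g}]",
                stacklevel=2,
            )
        # times must increase within each trace; sort (with a warning) if not
        key = ["subject_id", "dose", "group"]
        fixed = []
        needs_sort = False
        for _, g in df.groupby(key, sort=False):
            t = g["time_min"].to_numpy()
            if np.any(np.diff(t) < 0):
                needs_sort = True
                g = g.sort_values("time_min", kind="stable")
            fixed.append(g)
        if needs_sort:
            log.warning("non-monotone trace times found; traces were re-sorted by time")
            df = pd.concat(fixed, ignore_index=True)
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def doses(self) -> list[float]:
        return sorted(self.df["dose"].unique().tolist())

    @property
    def groups(self) -> list[str]:
        return sorted(self.df["group"].unique().tolist())

    def conditions(self) -> list[tuple[float, str]]:
        """All (dose, group) cells, agonist-only first, doses ascending."""
        cells = self.df[["dose", "group"]].drop_duplicates()
        return sorted(
            map(tuple, cells.to_numpy().tolist()), key=lambda c: (c[1], c[0])
        )

    def condition(self, dose: float, group: str) -> pd.DataFrame:
        """Rows of one dose x group cell (all replicate traces pooled)."""
        sel = (self.df["dose"] == dose) & (self.df["group"] == group)
        sub = self.df[sel]
        if len(sub) == 0:
            raise KeyError(f"no data for dose={dose!r}, group={group!r}")
        return sub.reset_index(drop=True)


def read_dataset(path: str | Path) -> AggregationDataset:
    """Read and validate a long-format aggregometry CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"dataset file is empty: {path}") from None
    if len(df) == 0:
        raise ValueError(f"dataset file has a header but no rows: {path}")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path} is missing required column(s): {missing}")
    return AggregationDataset(df[list(COLUMNS)].copy())


def write_dataset(dataset: AggregationDataset, path: str | Path) -> Path:
    """Write the dataset as CSV; round-trips through :func:`read_dataset`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dataset.df.to_csv(path, index=False)
    return path
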