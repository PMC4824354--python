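"""Separation-performance metrics from fraction count tables.

A count table records, per replicate disk, how many cells of each class
were recovered from each lane section.  The metrics quantify how well a
target class was banked into a chosen section:

* retention  — % of the target class recovered in the target section,
* exclusion  — % of a contaminant class kept OUT of the target section,
* enrichment — fold-change of the target:contaminant ratio in the
  section relative to the whole lane.

Denominators are the class totals over the sections actually present in
the table, so tables that sampled a representative middle section (rather
than every section) keep their own denominator convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "SeparationMetrics",
    "partition_metrics",
    "summarize_disks",
    "class_fraction_by_section",
]

_COLUMNS = ("disk", "section", "cell_class", "count")


@dataclass(frozen=True)
class CountTable:
    """Long-format (disk, section, cell_class, count) table of recovered
    cells; counts are non-negative integers and keys are unique."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"count table is missing columns: {missing}")
        df = df.loc[:, list(_COLUMNS)].reset_index(drop=True)
        counts = df["count"]
        if not np.issubdtype(counts.dtype, np.integer):
            as_float = counts.astype(float)
            if not np.all(as_float == np.floor(as_float)):
                bad = df.index[as_float != np.floor(as_float)].tolist()
                raise ValueError(f"non-integer counts at rows {bad}")
            df["count"] = as_float.astype(np.int64)
        if (df["count"] < 0).any():
            bad = df.index[df["count"] < 0].tolist()
            raise ValueError(f"negative counts at rows {bad}")
        dup = df.duplicated(subset=["disk", "section", "cell_class"])
        if dup.any():
            keys = df.loc[dup, ["disk", "section", "cell_class"]].to_records(index=False).tolist()
            raise ValueError(f"duplicate (disk, section, cell_class) keys: {keys}")
        object.__setattr__(self, "frame", df)

    @classmethod
    def from_records(
        cls, rows: Iterable[tuple[object, str, str, int]]
    ) -> "CountTable":
        """Build from (disk, section, cell_class, count) tuples."""
        return cls(pd.DataFrame(rows, columns=list(_COLUMNS)))

    @property
    def disks(self) -> list:
        return sorted(self.frame["disk"].unique().tolist())

    @property
    def sections(self) -> list[str]:
        return sorted(self.frame["section"].unique().tolist())

    @property
    def cell_classes(self) -> list[str]:
        return sorted(self.frame["cell_class"].unique().tolist())

    def disk_counts(self, disk) -> pd.DataFrame:
        """Section x class pivot of one disk's counts (missing cells 0)."""
        sub = self.frame[self.frame["disk"] == disk]
        if sub.empty:
            raise KeyError(f"no rows for disk {disk!r}")
        return sub.pivot_table(
            index="section", columns="cell_class", values="count",
            aggfunc="sum", fill_value=0,
        )


@dataclass(frozen=True)
class SeparationMetrics:
    """Per-disk separation outcome; a metric whose denominator is zero is
    None (undefined), never 0 or 100."""

    retention_pct: float | None
    exclusion_pct: float | None
    enrichment_fold: float | None

    def __post_init__(self) -> None:
        for name in ("retention_pct", "exclusion_pct"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} must lie in [0, 100], got {v}")
        if self.enrichment_fold is not None and self.enrichment_fold < 0:
            raise ValueError(f"enrichment_fold must be >= 0, got {self.enrichment_fold}")


def _metrics_for_pivot(
    pivot: pd.DataFrame, target_class: str, contaminant_class: str, target_section: str
) -> SeparationMetrics:
    if target_section not in pivot.index:
        raise KeyError(f"target section {target_section!r} absent from the table")

    def col(cls: str) -> pd.Series:
        if cls not in pivot.columns:
            raise KeyError(f"cell class {cls!r} absent from the table")
        return pivot[cls]

    t = col(target_class)
    c = col(contaminant_class)
    t_total, c_total = int(t.sum()), int(c.sum())
    t_sec, c_sec = int(t.loc[target_section]), int(c.loc[target_section])

    retention = 100.0 * t_sec / t_total if t_total > 0 else None
    exclusion = 100.0 * (1.0 - c_sec / c_total) if c_total > 0 else None
    if t_total == 0 or c_total == 0 or t_sec == 0 and c_sec == 0:
        enrichment = None
    elif c_sec == 0:
        enrichment = math.inf
    else:
        enrichment = (t_sec / c_sec) / (t_total / c_total)
    return SeparationMetrics(retention, exclusion, enrichment)


def partition_metrics(
    table: CountTable,
    target_class: str,
    contaminant_class: str,
    target_section: str,
) -> dict[object, SeparationMetrics]:
    """Retention / exclusion / enrichment of `target_class` vs
    `contaminant_class` in `target_section`, per disk."""
    return {
        disk: _metrics_for_pivot(
            table.disk_counts(disk), target_class, contaminant_class, target_section
        )
        for disk in table.disks
    }


def class_fraction_by_section(table: CountTable, cell_class: str, disk) -> pd.Series:
    """Percentage of one class recovered in each section of one disk
    (sums to 100 when the class total is nonzero)."""
    pivot = table.disk_counts(disk)
    if cell_class not in pivot.columns:
        raise KeyError(f"cell class {cell_class!r} absent from the table")
    counts = pivot[cell_class]
    total = counts.sum()
    if total == 0:
        raise ValueError(f"class {cell_class!r} has zero total on disk {disk!r}")
    return 100.0 * counts / total


def summarize_disks(
    table: CountTable,
    target_class: str,
    contaminant_class: str,
    target_section: str,
) -> pd.DataFrame:
    """Across-disk mean and sample standard deviation of each metric.

    Returns a frame indexed by metric name with columns ``mean``, ``sd``
    and ``n_disks``; with a single disk the dispersion is reported
    missing (NaN), and disks where a metric is undefined are dropped from
    that metric's summary.
    """
    per_disk = partition_metrics(table, target_class, contaminant_class, target_section)
    rows = {}
    for name in ("retention_pct", "exclusion_pct", "enrichment_fold"):
        vals = [getattr(m, name) for m in per_disk.values()]
        vals = [v for v in vals if v is not None and math.isfinite(v)]
        n = len(vals)
        mean = float(np.mean(vals)) if n else float("nan")
        sd = float(np.std(vals, ddof=1)) if n >= 2 else float("nan")
        rows[name] = {"mean": mean, "sd": sd, "n_disks": n}
    return pd.DataFrame.from_dict(rows, orient="index")
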