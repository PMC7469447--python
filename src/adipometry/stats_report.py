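"""Summaries, size histograms, two-method comparison statistics, and export.

The comparison statistics mirror a spreadsheet linear-regression check
between two analysis methods run on the same image: Pearson correlation of
the per-bin cell-count vectors and of the per-bin summed-area vectors, with
two-sided p-values from the t distribution on n - 2 degrees of freedom, plus
percent differences against the first table as reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .segmentation import CellPopulation

__all__ = [
    "HistogramSpec",
    "BinnedTable",
    "ComparisonStats",
    "totals",
    "histogram",
    "percent_difference",
    "compare_methods",
    "export_table",
    "read_binned_csv",
    "save_histogram_png",
]


@dataclass(frozen=True)
class HistogramSpec:
    """Ascending bin edges in square microns.

    Edges ``e_0 .. e_{k-1}`` define half-open bins ``[e_i, e_{i+1})`` plus a
    final open-ended bin ``[e_{k-1}, inf)``. Cells below ``e_0`` are counted
    in a separate underflow row.
    """

    bin_edges: tuple[float, ...]

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.bin_edges)
        if len(edges) < 1:
            raise ValueError("at least one bin edge is required")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError(f"bin edges must be strictly ascending, got {edges}")
        object.__setattr__(self, "bin_edges", edges)

    @property
    def labels(self) -> tuple[str, ...]:
        edges = self.bin_edges
        inner = [f"{lo:g}-{hi:g}" for lo, hi in zip(edges, edges[1:])]
        return tuple(inner + [f"{edges[-1]:g}+"])


@dataclass
class BinnedTable:
    """Per-size-bin cell counts and summed areas, with totals."""

    labels: tuple[str, ...]
    counts: tuple[int, ...]
    areas: tuple[float, ...]
    underflow_count: int = 0
    underflow_area: float = 0.0

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.counts) == len(self.areas)):
            raise ValueError("labels, counts and areas must have equal length")
        self.labels = tuple(self.labels)
        self.counts = tuple(int(c) for c in self.counts)
        self.areas = tuple(float(a) for a in self.areas)

    @property
    def total_count(self) -> int:
        return sum(self.counts)

    @property
    def total_area(self) -> float:
        return float(sum(self.areas))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"bin_label": lb, "count": ct, "area_um2": ar}
            for lb, ct, ar in zip(self.labels, self.counts, self.areas)
        ]
        if self.underflow_count:
            rows.append(
                {
                    "bin_label": "UNDERFLOW",
                    "count": self.underflow_count,
                    "area_um2": self.underflow_area,
                }
            )
        rows.append({"bin_label": "TOTAL", "count": self.total_count, "area_um2": self.total_area})
        return pd.DataFrame(rows, columns=["bin_label", "count", "area_um2"])


def totals(pop: CellPopulation) -> tuple[int, float]:
    """Count and summed area (square microns) over included cells only."""
    included = pop.included_cells
    return len(included), float(sum(c.area_um2 for c in included))


def histogram(pop: CellPopulation, spec: HistogramSpec) -> BinnedTable:
    """Bin the included cells by physical area.

    Each cell lands in exactly one bin (half-open convention, final bin
    open-ended); bin counts plus the underflow row conserve the population
    totals.
    """
    edges = spec.bin_edges
    n_bins = len(edges)
    counts = [0] * n_bins
    areas = [0.0] * n_bins
    under_n, under_a = 0, 0.0
    for cell in pop.included_cells:
        a = cell.area_um2
        if a < edges[0]:
            under_n += 1
            under_a += a
            continue
        # last edge whose value is <= a
        idx = int(np.searchsorted(edges, a, side="right")) - 1
        counts[idx] += 1
        areas[idx] += a
    return BinnedTable(
        labels=spec.labels,
        counts=tuple(counts),
        areas=tuple(areas),
        underflow_count=under_n,
        underflow_area=under_a,
    )


def percent_difference(a: float, b: float) -> float:
    """``|b - a| / a * 100`` with ``a`` the reference; NaN when ``a`` is 0."""
    if a == 0:
        return math.nan
    return abs(b - a) / abs(a) * 100.0


def _pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r and its two-sided p-value (t test, n - 2 dof)."""
    xa = np.asarray(x, dtype=np.float64)
    ya = np.asarray(y, dtype=np.float64)
    n = xa.size
    xd = xa - xa.mean()
    yd = ya - ya.mean()
    sx = math.sqrt(float(xd @ xd))
    sy = math.sqrt(float(yd @ yd))
    if sx == 0.0 or sy == 0.0:
        return math.nan, math.nan
    if np.array_equal(xa, ya):
        return 1.0, 0.0
    r = float(xd @ yd) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    from scipy.stats import t as t_dist

    t_stat = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(t_dist.sf(abs(t_stat), n - 2))
    return r, p


@dataclass
class ComparisonStats:
    """Correlation and percent-difference summary of two binned tables."""

    r_count: float
    p_count: float
    r_area: float
    p_area: float
    per_bin_area_pct_diff: tuple[float, ...]
    total_area_pct_diff: float
    total_count_pct_diff: float
    n_bins: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"statistic": "r_count", "value": self.r_count},
            {"statistic": "p_count", "value": self.p_count},
            {"statistic": "r_area", "value": self.r_area},
            {"statistic": "p_area", "value": self.p_area},
            {"statistic": "total_area_pct_diff", "value": self.total_area_pct_diff},
            {"statistic": "total_count_pct_diff", "value": self.total_count_pct_diff},
        ]
        rows.extend(
            {"statistic": f"bin{i + 1}_area_pct_diff", "value": v}
            for i, v in enumerate(self.per_bin_area_pct_diff)
        )
        return pd.DataFrame(rows, columns=["statistic", "value"])


def compare_methods(table_a: BinnedTable, table_b: BinnedTable) -> ComparisonStats:
    """Compare two methods' binned results; ``table_a`` is the reference.

    Requires identical bin structure and at least 3 bins (for the p-value's
    n - 2 degrees of freedom). Zero-variance vectors yield NaN correlations.
    """
    if table_a.labels != table_b.labels:
        raise ValueError(
            f"bin structures differ: {table_a.labels} vs {table_b.labels}"
        )
    n = len(table_a.labels)
    if n < 3:
        raise ValueError(f"need at least 3 bins for comparison statistics, got {n}")
    r_count, p_count = _pearson(table_a.counts, table_b.counts)
    r_area, p_area = _pearson(table_a.areas, table_b.areas)
    per_bin = tuple(percent_difference(a, b) for a, b in zip(table_a.areas, table_b.areas))
    return ComparisonStats(
        r_count=r_count,
        p_count=p_count,
        r_area=r_area,
        p_area=p_area,
        per_bin_area_pct_diff=per_bin,
        total_area_pct_diff=percent_difference(table_a.total_area, table_b.total_area),
        total_count_pct_diff=percent_difference(table_a.total_count, table_b.total_count),
        n_bins=n,
    )


def _population_frame(pop: CellPopulation) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": c.id,
                "area_px": c.area_px,
                "area_um2": c.area_um2,
                "included": c.included,
                "exclusion_reason": c.exclusion_reason or "",
            }
            for c in pop.cells
        ],
        columns=["id", "area_px", "area_um2", "included", "exclusion_reason"],
    )


def export_table(
    obj: CellPopulation | BinnedTable | ComparisonStats,
    path: str | Path,
    format: str = "csv",
) -> Path:
    """Write a per-cell sheet, bin table, or comparison summary to disk.

    CSV is the canonical bit-exact format; ``format="xlsx"`` writes the same
    frame through openpyxl as a convenience mirror.
    """
    if isinstance(obj, CellPopulation):
        frame = _population_frame(obj)
    elif isinstance(obj, (BinnedTable, ComparisonStats)):
        frame = obj.to_frame()
    else:
        raise TypeError(f"cannot export object of type {type(obj).__name__}")
    p = Path(path)
    if format == "csv":
        frame.to_csv(p, index=False)
    elif format == "xlsx":
        frame.to_excel(p, index=False)
    else:
        raise ValueError(f"unknown export format {format!r} (use csv or xlsx)")
    return p


def read_binned_csv(path: str | Path) -> BinnedTable:
    """Load a bin table written by :func:`export_table` (TOTAL/UNDERFLOW aware)."""
    frame = pd.read_csv(path)
    required = {"bin_label", "count", "area_um2"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    under = frame[frame["bin_label"] == "UNDERFLOW"]
    bins = frame[~frame["bin_label"].isin(["TOTAL", "UNDERFLOW"])]
    return BinnedTable(
        labels=tuple(str(x) for x in bins["bin_label"]),
        counts=tuple(int(x) for x in bins["count"]),
        areas=tuple(float(x) for x in bins["area_um2"]),
        underflow_count=int(under["count"].iloc[0]) if len(under) else 0,
        underflow_area=float(under["area_um2"].iloc[0]) if len(under) else 0.0,
    )


def save_histogram_png(table: BinnedTable, path: str | Path, title: str = "Cell size distribution") -> Path:
    """Bar-chart rendering of a binned table (counts per size bin)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(range(len(table.labels)), table.counts, color="#4477aa")
    ax.set_xticks(range(len(table.labels)))
    ax.set_xticklabels(table.labels, rotation=45, ha="right")
    ax.set_xlabel("area bin (µm²)")
    ax.set_ylabel("number of cells")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)
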