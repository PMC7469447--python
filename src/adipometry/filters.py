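"""Reversible cell exclusion: area limits, border cells, and point toggling.

Filters only flip inclusion flags; geometry and measurements are never
altered, so any sequence of filter operations can be undone without
re-running detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .segmentation import CellPopulation, Point

__all__ = [
    "FilterSpec",
    "filter_by_area",
    "exclude_border_cells",
    "toggle_at_point",
    "apply_filters",
]


@dataclass(frozen=True)
class FilterSpec:
    """Declarative filter configuration, applied size -> border -> manual."""

    min_area_um2: float = 0.0
    max_area_um2: float = math.inf
    exclude_border: bool = False
    manual_points: tuple[Point, ...] = ()

    def __post_init__(self) -> None:
        if self.min_area_um2 < 0:
            raise ValueError(f"min_area_um2 must be >= 0, got {self.min_area_um2}")
        if self.min_area_um2 > self.max_area_um2:
            raise ValueError(
                f"min_area_um2 {self.min_area_um2} exceeds max_area_um2 {self.max_area_um2}"
            )


def filter_by_area(
    pop: CellPopulation, min_area_um2: float, max_area_um2: float = math.inf
) -> CellPopulation:
    """Exclude cells outside the closed interval [min, max] square microns.

    Cells back inside the interval have their size exclusion lifted; border
    and manual states are untouched.
    """
    if min_area_um2 > max_area_um2:
        raise ValueError(f"min area {min_area_um2} exceeds max area {max_area_um2}")
    out = pop.copy()
    for cell in out.cells:
        in_range = min_area_um2 <= cell.area_um2 <= max_area_um2
        if not in_range:
            if cell.auto_reason is None:
                cell.auto_reason = "size"
        elif cell.auto_reason == "size":
            cell.auto_reason = None
    return out


def exclude_border_cells(pop: CellPopulation, on: bool = True) -> CellPopulation:
    """Exclude (or re-admit) cells whose contour touches the image frame."""
    out = pop.copy()
    for cell in out.cells:
        if on:
            if cell.contour.touches_frame and cell.auto_reason is None:
                cell.auto_reason = "border"
        elif cell.auto_reason == "border":
            cell.auto_reason = None
    return out


def toggle_at_point(pop: CellPopulation, point: Point) -> tuple[CellPopulation, int | None]:
    """Flip the manual inclusion state of the cell under ``point``.

    A click on an included cell manually excludes it; a click on any excluded
    cell brings it back; a second click undoes the first. Returns the new
    population and the id of the hit cell, or ``None`` for a background miss
    (the population is then returned unchanged).

    Raises
    ------
    ValueError
        If ``point`` lies outside the image bounds.
    """
    out = pop.copy()
    cell = out.cell_at(point)  # raises on out-of-bounds
    if cell is None:
        return out, None
    if cell.manual_state is not None:
        cell.manual_state = None
    elif cell.included:
        cell.manual_state = "exclude"
    else:
        cell.manual_state = "include"
    return out, cell.id


def apply_filters(pop: CellPopulation, spec: FilterSpec) -> CellPopulation:
    """Apply a full filter spec to a pristine view of the population.

    All flags are reset first, then the area filter, border exclusion, and
    manual toggles are applied in that order (manual clicks win last).
    Re-applying the same spec is therefore idempotent, and the original
    population object is never mutated.
    """
    base = pop.copy()
    for cell in base.cells:
        cell.auto_reason = None
        cell.manual_state = None
    out = filter_by_area(base, spec.min_area_um2, spec.max_area_um2)
    out = exclude_border_cells(out, spec.exclude_border)
    for point in spec.manual_points:
        out, _ = toggle_at_point(out, point)
    return out
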