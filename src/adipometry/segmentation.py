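"""External contour tracing and calibrated cell measurement.

Objects are 8-connected foreground components of a binary mask. Only the
outermost boundary of each component is traced (interior holes never create
objects); the boundary chain is compressed by replacing maximal collinear
pixel runs with their two endpoints, and the object's size is the count of
its foreground pixels (boundary included, holes excluded).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .io_calibration import Calibration, RasterImage
from . import preprocess
from .preprocess import PreprocessParams

__all__ = [
    "Contour",
    "CellRecord",
    "CellPopulation",
    "trace_external_contours",
    "compress_chain",
    "decompress_chain",
    "contour_pixel_area",
    "detect_cells",
]

Point = tuple[int, int]

# Moore neighborhood in clockwise screen order starting due north
_NBRS: tuple[Point, ...] = (
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
)
_W_IDX = 6  # index of the west neighbor


@dataclass
class Contour:
    """Compressed closed boundary chain of one external object."""

    vertices: list[Point]
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)
    pixel_count: int
    touches_frame: bool

    @property
    def start(self) -> Point:
        return self.vertices[0]


def _moore_trace(mask: np.ndarray, start: Point) -> list[Point]:
    """Follow the outer boundary from ``start``, returning the pixel chain.

    ``start`` must be the first pixel of its component in raster order (its
    west neighbor is background or out of frame). Termination uses Jacob's
    criterion: stop when the initial move from the start pixel repeats.
    """
    h, w = mask.shape
    chain: list[Point] = [start]
    p = start
    b_idx = _W_IDX
    first_move: tuple[Point, Point] | None = None
    limit = 4 * mask.size + 8
    for _ in range(limit):
        nxt: Point | None = None
        scan = 0
        for i in range(1, 9):
            idx = (b_idx + i) % 8
            r = p[0] + _NBRS[idx][0]
            c = p[1] + _NBRS[idx][1]
            if 0 <= r < h and 0 <= c < w and mask[r, c]:
                nxt = (r, c)
                scan = i
                break
        if nxt is None:  # isolated pixel
            break
        move = (p, nxt)
        if first_move is None:
            first_move = move
        elif move == first_move:
            break
        chain.append(nxt)
        prev_idx = (b_idx + scan - 1) % 8
        back = (p[0] + _NBRS[prev_idx][0], p[1] + _NBRS[prev_idx][1])
        b_idx = _NBRS.index((back[0] - nxt[0], back[1] - nxt[1]))
        p = nxt
    else:  # pragma: no cover - safety net
        raise RuntimeError("boundary trace did not terminate")
    while len(chain) > 1 and chain[-1] == chain[0]:
        chain.pop()
    return chain


def _flood_component(
    mask: np.ndarray, labels: np.ndarray, start: Point, label: int
) -> tuple[int, tuple[int, int, int, int], bool]:
    """Label the 8-connected component containing ``start``; return
    (pixel count, bbox, touches_frame)."""
    h, w = mask.shape
    stack = deque([start])
    labels[start] = label
    count = 0
    min_r, min_c, max_r, max_c = start[0], start[1], start[0], start[1]
    touches = False
    while stack:
        r, c = stack.pop()
        count += 1
        if r < min_r:
            min_r = r
        if r > max_r:
            max_r = r
        if c < min_c:
            min_c = c
        if c > max_c:
            max_c = c
        if r == 0 or r == h - 1 or c == 0 or c == w - 1:
            touches = True
        for dr, dc in _NBRS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and labels[rr, cc] == 0:
                labels[rr, cc] = label
                stack.append((rr, cc))
    return count, (min_r, min_c, max_r, max_c), touches


def trace_external_contours(
    mask: np.ndarray, return_labels: bool = False
) -> list[Contour] | tuple[list[Contour], np.ndarray]:
    """Trace the external contour of every 8-connected foreground component.

    Components are reported in raster-scan order of their first boundary
    pixel. Interior holes are ignored (spaces between cells never become
    contours) and are excluded from the pixel count.

    When ``return_labels`` is true, also returns an int32 label map in which
    component ``k`` (1-based, matching list order) fills its pixels.
    """
    mask = np.ascontiguousarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    contours: list[Contour] = []
    rows, cols = np.nonzero(mask)
    for r, c in zip(rows.tolist(), cols.tolist()):
        if labels[r, c]:
            continue
        label = len(contours) + 1
        chain = _moore_trace(mask, (r, c))
        count, bbox, touches = _flood_component(mask, labels, (r, c), label)
        contours.append(
            Contour(
                vertices=compress_chain(chain),
                bbox=bbox,
                pixel_count=count,
                touches_frame=touches,
            )
        )
    if return_labels:
        return contours, labels
    return contours


def compress_chain(boundary: Sequence[Point]) -> list[Point]:
    """Collapse maximal collinear runs of a closed pixel chain to endpoints.

    Consecutive boundary pixels differ by one of the 8 unit steps, so a
    collinear run is a maximal run of identical steps; only its first and
    last point are kept. Reconstruction with :func:`decompress_chain` yields
    the original point set exactly.
    """
    pts = list(boundary)
    n = len(pts)
    if n <= 2:
        return pts
    steps = [(pts[(i + 1) % n][0] - pts[i][0], pts[(i + 1) % n][1] - pts[i][1]) for i in range(n)]
    # rotate so position 0 sits at a direction change (incoming != outgoing)
    pivot = next((i for i in range(n) if steps[i - 1] != steps[i]), None)
    if pivot is None:  # cannot happen for a closed chain of n > 2 distinct steps
        return [pts[0], pts[-1]]
    pts = pts[pivot:] + pts[:pivot]
    steps = steps[pivot:] + steps[:pivot]
    verts = [pts[0]]
    for i in range(1, n):
        if steps[i - 1] != steps[i]:
            verts.append(pts[i])
    return verts


def decompress_chain(vertices: Sequence[Point]) -> list[Point]:
    """Rasterize compressed vertices back into the full boundary pixel chain."""
    verts = list(vertices)
    n = len(verts)
    if n <= 1:
        return verts
    chain: list[Point] = []
    for i in range(n):
        r0, c0 = verts[i]
        r1, c1 = verts[(i + 1) % n]
        dr, dc = r1 - r0, c1 - c0
        k = max(abs(dr), abs(dc))
        if k == 0:
            chain.append((r0, c0))
            continue
        sr = (dr > 0) - (dr < 0)
        sc = (dc > 0) - (dc < 0)
        if dr != sr * k or dc != sc * k:
            raise ValueError(f"segment {verts[i]}->{verts[(i + 1) % n]} is not a unit-step run")
        for j in range(k):
            chain.append((r0 + sr * j, c0 + sc * j))
    return chain


def contour_pixel_area(contour: Contour, mask: np.ndarray) -> int:
    """Count the foreground pixels of the contour's component.

    Boundary pixels are included; interior holes are not foreground and are
    therefore excluded. The result is cached on the contour.
    """
    labels = np.zeros(mask.shape, dtype=np.int32)
    count, _, _ = _flood_component(np.asarray(mask, dtype=bool), labels, contour.start, 1)
    contour.pixel_count = count
    return count


@dataclass
class CellRecord:
    """One detected cell with its measurements and inclusion state.

    ``included`` and ``exclusion_reason`` are derived from the automatic
    filter reason (size/border) and the manual click override, so repeated
    toggling is always reversible.
    """

    id: int
    contour: Contour
    area_px: int
    area_um2: float
    auto_reason: str | None = None  # "size" | "border"
    manual_state: str | None = None  # "exclude" | "include"

    @property
    def included(self) -> bool:
        if self.manual_state == "include":
            return True
        if self.manual_state == "exclude":
            return False
        return self.auto_reason is None

    @property
    def exclusion_reason(self) -> str | None:
        if self.included:
            return None
        if self.manual_state == "exclude":
            return "manual"
        return self.auto_reason


@dataclass
class CellPopulation:
    """All detected cells of one calibrated image."""

    cells: list[CellRecord]
    calibration: Calibration
    image_shape: tuple[int, int]
    label_map: np.ndarray | None = None

    @property
    def included_cells(self) -> list[CellRecord]:
        return [c for c in self.cells if c.included]

    def copy(self) -> "CellPopulation":
        return CellPopulation(
            cells=[replace(c) for c in self.cells],
            calibration=self.calibration,
            image_shape=self.image_shape,
            label_map=self.label_map,
        )

    def cell_at(self, point: Point) -> CellRecord | None:
        """The cell whose component contains ``point``, or ``None``."""
        if self.label_map is None:
            raise RuntimeError("population carries no label map; rerun detect_cells")
        r, c = int(point[0]), int(point[1])
        h, w = self.image_shape
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"point {point} outside image of shape {self.image_shape}")
        label = int(self.label_map[r, c])
        return self.cells[label - 1] if label else None


def detect_cells(
    img: RasterImage,
    cal: Calibration,
    params: PreprocessParams | None = None,
) -> CellPopulation:
    """Run the full detection pipeline on a calibrated image.

    Grayscale conversion, haze removal, median denoising, thresholding and
    border thickening, then external contour tracing; every traced object
    becomes an initially-included cell with pixel and physical areas.
    """
    params = params or PreprocessParams()
    gray = preprocess.to_grayscale(img)
    if params.dehaze_strength > 0:
        gray = preprocess.dehaze(gray, params.dehaze_strength)
    if params.denoise_radius > 0:
        gray = preprocess.denoise(gray, params.denoise_radius)
    mask = preprocess.binarize(gray, params.threshold, params.invert)
    mask = preprocess.thicken_borders(mask, params.border_thickness)
    contours, labels = trace_external_contours(mask, return_labels=True)
    cells = [
        CellRecord(
            id=i + 1,
            contour=ct,
            area_px=ct.pixel_count,
            area_um2=ct.pixel_count * cal.area_factor,
        )
        for i, ct in enumerate(contours)
    ]
    return CellPopulation(cells=cells, calibration=cal, image_shape=mask.shape, label_map=labels)
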