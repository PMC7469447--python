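"""Synthetic adipose-tissue-like images with exact ground truth.

Every generator is fully deterministic under its seed and records, per cell,
the interior pixel count, frame contact and centroid, plus a registry of any
injected defects (haze fraction, dust speck centres, scratch coordinates).
This makes every pipeline stage testable without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .io_calibration import Calibration, RasterImage

__all__ = [
    "FixtureParams",
    "FixtureError",
    "CellTruth",
    "GroundTruth",
    "make_grid_cells",
    "make_voronoi_tissue",
    "add_artifacts",
    "make_fluorescent_overlay",
    "write_fixture",
]


class FixtureError(ValueError):
    """Raised when fixture parameters cannot be realized."""


@dataclass(frozen=True)
class FixtureParams:
    """Parameters shared by the tissue generators.

    ``gap_fraction`` controls how much of the membrane network is punched
    open to simulate faint/broken cell borders; ``haze``, ``n_dust`` and
    ``scratch`` configure :func:`add_artifacts`. A single ``rng_seed`` drives
    all randomness.
    """

    shape: tuple[int, int] = (256, 256)
    n_cells: int = 50
    membrane_width: int = 3
    gap_fraction: float = 0.0
    haze: float = 0.0
    n_dust: int = 0
    scratch: bool = False
    interior_mean: int = 230
    interior_jitter: int = 10
    membrane_mean: int = 40
    membrane_jitter: int = 10
    mpp: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gap_fraction", "haze"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise FixtureError(f"{name} must lie in [0, 1], got {v}")
        if self.n_cells < 1:
            raise FixtureError("n_cells must be >= 1")
        if self.mpp <= 0:
            raise FixtureError("mpp must be > 0")


@dataclass
class CellTruth:
    pixel_count: int
    touches_frame: bool
    centroid: tuple[float, float]


@dataclass
class GroundTruth:
    """Exact per-cell and defect bookkeeping for one generated image."""

    n_cells: int
    cells: list[CellTruth]
    mpp: float
    labels: np.ndarray  # 0 = membrane/background, k = cell k (1-based)
    haze_fraction: float = 0.0
    dust_points: list[tuple[int, int]] = field(default_factory=list)
    scratch_points: list[tuple[int, int]] = field(default_factory=list)

    @property
    def total_interior_pixels(self) -> int:
        return sum(c.pixel_count for c in self.cells)

    def probe_point(self, cell_index: int) -> tuple[int, int]:
        """An interior pixel of cell ``cell_index`` (0-based), nearest its centroid."""
        rows, cols = np.nonzero(self.labels == cell_index + 1)
        cr, cc = self.cells[cell_index].centroid
        d2 = (rows - cr) ** 2 + (cols - cc) ** 2
        i = int(np.argmin(d2))
        return int(rows[i]), int(cols[i])


def _truths_from_labels(labels: np.ndarray, n_cells: int) -> list[CellTruth]:
    h, w = labels.shape
    cells = []
    for k in range(1, n_cells + 1):
        rows, cols = np.nonzero(labels == k)
        if rows.size == 0:
            raise FixtureError(f"cell {k} has no interior pixels; loosen parameters")
        touches = bool(
            (rows == 0).any() or (rows == h - 1).any() or (cols == 0).any() or (cols == w - 1).any()
        )
        cells.append(
            CellTruth(
                pixel_count=int(rows.size),
                touches_frame=touches,
                centroid=(float(rows.mean()), float(cols.mean())),
            )
        )
    return cells


def _render(labels: np.ndarray, params: FixtureParams, rng: np.random.Generator) -> np.ndarray:
    """Paint interiors bright and membranes/background dark, with jitter,
    replicated into 3 identical channels."""
    interior = labels > 0
    img = rng.integers(
        params.membrane_mean - params.membrane_jitter,
        params.membrane_mean + params.membrane_jitter + 1,
        size=labels.shape,
    )
    bright = rng.integers(
        params.interior_mean - params.interior_jitter,
        params.interior_mean + params.interior_jitter + 1,
        size=labels.shape,
    )
    img[interior] = bright[interior]
    img = np.clip(img, 0, 255).astype(np.uint8)
    return np.repeat(img[:, :, None], 3, axis=2)


def make_grid_cells(
    rows: int, cols: int, radius_px: int, params: FixtureParams | None = None
) -> tuple[RasterImage, GroundTruth]:
    """Regular grid of bright discs on a dark background.

    Ground-truth pixel counts are the exact rasterized disc sizes (clipped at
    the frame, which sets the frame-touching flag). Overlapping discs are a
    parameter error.
    """
    params = params or FixtureParams()
    h, w = params.shape
    rng = np.random.default_rng(params.rng_seed)
    pitch_r = h / rows
    pitch_c = w / cols
    if (rows > 1 and 2 * radius_px >= pitch_r) or (cols > 1 and 2 * radius_px >= pitch_c):
        raise FixtureError(
            f"discs of radius {radius_px} overlap at pitch ({pitch_r:.1f}, {pitch_c:.1f})"
        )
    labels = np.zeros((h, w), dtype=np.int32)
    rr, cc = np.mgrid[0:h, 0:w]
    k = 0
    for i in range(rows):
        for j in range(cols):
            k += 1
            cr = (i + 0.5) * pitch_r
            ccol = (j + 0.5) * pitch_c
            disc = (rr - cr) ** 2 + (cc - ccol) ** 2 <= radius_px**2
            labels[disc] = k
    truths = _truths_from_labels(labels, k)
    img = RasterImage(_render(labels, params, rng))
    gt = GroundTruth(n_cells=k, cells=truths, mpp=params.mpp, labels=labels)
    return img, gt


def make_voronoi_tissue(params: FixtureParams) -> tuple[RasterImage, GroundTruth]:
    """Voronoi mosaic of bright polygonal cells separated by dark membranes.

    Sites are dart-thrown with a minimum separation so every cell keeps an
    interior after the membrane band is removed. ``gap_fraction`` > 0 punches
    interior-coloured holes through random membrane locations, merging
    neighbouring cells until the borders are thickened back shut.
    """
    h, w = params.shape
    rng = np.random.default_rng(params.rng_seed)
    min_sep = max(4 * params.membrane_width, 12)
    sites: list[tuple[float, float]] = []
    for _ in range(20000):
        if len(sites) == params.n_cells:
            break
        cand = (rng.uniform(0, h), rng.uniform(0, w))
        if all((cand[0] - s[0]) ** 2 + (cand[1] - s[1]) ** 2 >= min_sep**2 for s in sites):
            sites.append(cand)
    if len(sites) < params.n_cells:
        raise FixtureError(
            f"could not place {params.n_cells} sites with separation {min_sep} in {params.shape}"
        )
    tree = cKDTree(np.asarray(sites))
    rr, cc = np.mgrid[0:h, 0:w]
    pts = np.column_stack([rr.ravel(), cc.ravel()])
    dists, idx = tree.query(pts, k=2)
    nearest = idx[:, 0].reshape(h, w).astype(np.int32) + 1
    margin = (dists[:, 1] - dists[:, 0]).reshape(h, w)
    membrane = margin < params.membrane_width
    labels = np.where(membrane, 0, nearest)

    gap_points: list[tuple[int, int]] = []
    if params.gap_fraction > 0:
        mem_rows, mem_cols = np.nonzero(membrane)
        n_gaps = int(round(params.gap_fraction * 3 * params.n_cells))
        order = rng.permutation(mem_rows.size)
        # narrow punch: bridge stays removable by erosion of radius ~membrane_width
        gap_r = max(1, params.membrane_width - 1)
        taken: list[tuple[int, int]] = []
        for oi in order:
            if len(gap_points) >= n_gaps:
                break
            r, c = int(mem_rows[oi]), int(mem_cols[oi])
            # keep gaps apart so merged bridges stay narrow
            if any((r - tr) ** 2 + (c - tc) ** 2 < (6 * gap_r) ** 2 for tr, tc in taken):
                continue
            gap_points.append((r, c))
            taken.append((r, c))
        for r, c in gap_points:
            disc = (rr - r) ** 2 + (cc - c) ** 2 <= gap_r**2
            labels[disc & membrane] = -1  # gap: painted bright, owned by no cell

    truths = _truths_from_labels(np.where(labels > 0, labels, 0), params.n_cells)
    paint_labels = np.where(labels != 0, np.abs(labels), 0)
    img = RasterImage(_render(paint_labels, params, rng))
    gt = GroundTruth(
        n_cells=params.n_cells,
        cells=truths,
        mpp=params.mpp,
        labels=np.where(labels > 0, labels, 0),
    )
    return img, gt


def add_artifacts(
    img: RasterImage, gt: GroundTruth, params: FixtureParams
) -> tuple[RasterImage, GroundTruth]:
    """Blend haze and stamp dust specks and/or a scratch onto a fixture.

    Dust specks are bright radius-1 discs placed on open background, well
    clear of cell interiors and of each other, so each becomes one spurious
    detectable object removable by median denoising. The scratch is a long
    2-px-wide bright horizontal line through the clearest background band,
    detectable as exactly one extra object. Haze is a convex blend with
    white. The defect registry on the returned ground truth is updated;
    per-cell truth is unchanged.
    """
    arr = img.pixels.astype(np.float64)
    h, w = gt.labels.shape
    interior = gt.labels > 0
    clearance = ndimage.distance_transform_edt(~interior)
    rng = np.random.default_rng(params.rng_seed + 1)
    bright = float(params.interior_mean)

    scratch_points: list[tuple[int, int]] = []
    if params.scratch:
        # width 3 so the scratch survives a radius-2 median filter (unlike dust);
        # away from the frame so it is not a border object
        margin = 5
        row_clear = clearance[:, 2 : w - 2].min(axis=1)
        row_clear[:margin] = -1.0
        row_clear[h - margin - 3 :] = -1.0
        r0 = int(np.argmax(row_clear))
        if row_clear[r0] < 5.0:
            raise FixtureError("no background band clear enough for a scratch")
        for r in (r0, r0 + 1, r0 + 2):
            for c in range(2, w - 2):
                arr[r, c] = bright
                scratch_points.append((r, c))
        interior_or_defect = interior.copy()
        for r, c in scratch_points:
            interior_or_defect[r, c] = True
        clearance = ndimage.distance_transform_edt(~interior_or_defect)

    dust_points: list[tuple[int, int]] = []
    if params.n_dust > 0:
        allowed = clearance >= 4.0
        cand_r, cand_c = np.nonzero(allowed)
        if cand_r.size == 0:
            raise FixtureError("no open background available for dust specks")
        order = rng.permutation(cand_r.size)
        for oi in order:
            if len(dust_points) >= params.n_dust:
                break
            r, c = int(cand_r[oi]), int(cand_c[oi])
            if any((r - pr) ** 2 + (c - pc) ** 2 < 8**2 for pr, pc in dust_points):
                continue
            dust_points.append((r, c))
        if len(dust_points) < params.n_dust:
            raise FixtureError(
                f"placed only {len(dust_points)} of {params.n_dust} dust specks"
            )
        rr, cc = np.mgrid[0:h, 0:w]
        for r, c in dust_points:
            arr[(rr - r) ** 2 + (cc - c) ** 2 <= 1] = bright

    if params.haze > 0:
        arr = (1.0 - params.haze) * arr + params.haze * 255.0

    out_gt = GroundTruth(
        n_cells=gt.n_cells,
        cells=list(gt.cells),
        mpp=gt.mpp,
        labels=gt.labels,
        haze_fraction=params.haze,
        dust_points=dust_points,
        scratch_points=scratch_points,
    )
    return RasterImage(np.clip(np.round(arr), 0, 255).astype(np.uint8)), out_gt


def make_fluorescent_overlay(
    params: FixtureParams, blob_radius: int = 6, channel_value: int = 200
) -> tuple[RasterImage, GroundTruth]:
    """Disjoint red/green/blue blobs on black, with exact per-channel counts.

    ``n_cells`` blobs are assigned round-robin to the three channels. The
    ground-truth label map stores the blob index; per-channel pixel counts
    are recoverable from the blob colours via ``channel_counts``.
    """
    h, w = params.shape
    rng = np.random.default_rng(params.rng_seed)
    centers: list[tuple[float, float]] = []
    min_sep = 2 * blob_radius + 3
    for _ in range(20000):
        if len(centers) == params.n_cells:
            break
        cand = (rng.uniform(blob_radius, h - blob_radius), rng.uniform(blob_radius, w - blob_radius))
        if all((cand[0] - s[0]) ** 2 + (cand[1] - s[1]) ** 2 >= min_sep**2 for s in centers):
            centers.append(cand)
    if len(centers) < params.n_cells:
        raise FixtureError(f"could not place {params.n_cells} disjoint blobs in {params.shape}")
    labels = np.zeros((h, w), dtype=np.int32)
    arr = np.zeros((h, w, 3), dtype=np.uint8)
    rr, cc = np.mgrid[0:h, 0:w]
    truths = []
    for k, (cr, ccol) in enumerate(centers, start=1):
        disc = (rr - cr) ** 2 + (cc - ccol) ** 2 <= blob_radius**2
        labels[disc] = k
        arr[:, :, (k - 1) % 3][disc] = channel_value
        rows, cols = np.nonzero(disc)
        truths.append(
            CellTruth(
                pixel_count=int(rows.size),
                touches_frame=bool((rows == 0).any() or (rows == h - 1).any()
                                   or (cols == 0).any() or (cols == w - 1).any()),
                centroid=(float(rows.mean()), float(cols.mean())),
            )
        )
    img = RasterImage(arr)
    gt = GroundTruth(n_cells=len(centers), cells=truths, mpp=params.mpp, labels=labels)
    return img, gt


def channel_counts(gt: GroundTruth) -> dict[str, int]:
    """Per-channel foreground pixel counts for a fluorescent fixture."""
    names = ("red", "green", "blue")
    out = {n: 0 for n in names}
    for k, cell in enumerate(gt.cells, start=1):
        out[names[(k - 1) % 3]] += cell.pixel_count
    return out


def write_fixture(
    img: RasterImage, gt: GroundTruth, outdir: str | Path, stem: str = "fixture"
) -> dict[str, Path]:
    """Persist a fixture: calibrated TIFF, ground-truth CSV, and label PNG."""
    import pandas as pd
    import tifffile
    from PIL import Image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tif = outdir / f"{stem}.tif"
    # unitless resolution tags carry pixels per micron; description repeats it
    tifffile.imwrite(
        tif,
        img.pixels,
        resolution=(1.0 / gt.mpp, 1.0 / gt.mpp),
        resolutionunit=1,  # unitless: pixels per micron by microscopy convention
        description=f"microns per pixel: {gt.mpp}",
    )
    csv = outdir / f"{stem}_truth.csv"
    pd.DataFrame(
        [
            {
                "cell": i + 1,
                "pixel_count": c.pixel_count,
                "touches_frame": c.touches_frame,
                "centroid_row": c.centroid[0],
                "centroid_col": c.centroid[1],
            }
            for i, c in enumerate(gt.cells)
        ]
    ).to_csv(csv, index=False)
    png = outdir / f"{stem}_labels.png"
    Image.fromarray(gt.labels.astype(np.uint16)).save(png)
    return {"image": tif, "truth": csv, "labels": png}
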