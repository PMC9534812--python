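"""Region-of-interest and cluster-exclusion masks.

Correlation and colocalization estimates of *single* pentamers are easily
corrupted by bright receptor clusters, so every downstream computation is
restricted to a boolean inclusion mask. Two mask sources are combined:

* a freehand/polygon ROI selecting the cell (:func:`polygon_roi`), and
* automatic cluster exclusion (:func:`cluster_mask`): a pixel is excluded
  when the boxcar mean of its ~5×5 neighborhood is at least ``k`` (default
  3) times the mean intensity of all currently included pixels of the
  preprocessed series. Because bright clusters inflate that reference
  mean, the exclusion is iterated to convergence. The resulting grid is
  smoothed with a 3×3 median (majority) filter.

``dynamic`` mode thresholds each frame separately (one grid per frame);
``static`` mode applies the rule once to the time-averaged image.
Per-frame stacks are reduced to a single grid with
:func:`intersect_masks` (a pixel survives only if included in every
frame).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core_io import ImageSeries

__all__ = ["MaskStack", "polygon_roi", "cluster_mask", "intersect_masks",
           "write_mask", "read_mask"]


@dataclass
class MaskStack:
    """Boolean inclusion grid(s) aligned to an :class:`ImageSeries`.

    ``grids`` has shape (ny, nx) for a static mask or (n_frames, ny, nx)
    for a per-frame (dynamic) mask. ``provenance`` records how the mask
    was built.
    """

    grids: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grids = np.asarray(self.grids, dtype=bool)
        if self.grids.ndim not in (2, 3):
            raise ValueError("mask grids must be 2D (static) or 3D (per frame)")

    @property
    def is_static(self) -> bool:
        return self.grids.ndim == 2

    @property
    def is_empty(self) -> bool:
        return not bool(self.grids.any()) or (
            not self.is_static and bool((~self.grids.any(axis=(1, 2))).any()))

    def static_grid(self) -> np.ndarray:
        """The static grid, intersecting frames if the stack is per-frame."""
        return self.grids if self.is_static else self.grids.all(axis=0)

    def frame(self, f: int) -> np.ndarray:
        return self.grids if self.is_static else self.grids[f]

    def check_shape(self, series: ImageSeries) -> None:
        if self.grids.shape[-2:] != series.frame_shape:
            raise ValueError("mask shape does not match series frames")
        if not self.is_static and self.grids.shape[0] != series.n_frames:
            raise ValueError("per-frame mask must have one grid per frame")


# ---------------------------------------------------------------------------
# Polygon ROI
# ---------------------------------------------------------------------------


def _points_in_polygon(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Even-odd rule point-in-polygon test, vectorized over points.

    A point is inside when a ray cast in +x direction crosses the polygon
    boundary an odd number of times.
    """
    x, y = points[:, 1], points[:, 0]
    vy, vx = vertices[:, 0], vertices[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    n = len(vertices)
    j = n - 1
    for i in range(n):
        yi, xi = vy[i], vx[i]
        yj, xj = vy[j], vx[j]
        with np.errstate(divide="ignore", invalid="ignore"):
            crosses = ((yi > y) != (yj > y)) & (
                x < (xj - xi) * (y - yi) / (yj - yi) + xi)
        inside ^= crosses
        j = i
    return inside


def polygon_roi(series: ImageSeries, vertices) -> MaskStack:
    """Static mask of pixels whose centers fall inside a closed polygon.

    ``vertices`` is an ordered list of (row, col) coordinates in pixel
    units; the polygon is closed implicitly. Inclusion follows the even-odd
    rule. An all-false result is allowed but flagged via ``is_empty``.
    """
    vertices = np.asarray(vertices, dtype=float)
    if vertices.ndim != 2 or vertices.shape[0] < 3 or vertices.shape[1] != 2:
        raise ValueError("polygon needs at least 3 (row, col) vertices")
    # shoelace area; degenerate polygons have zero area
    r, c = vertices[:, 0], vertices[:, 1]
    area = 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))
    if area == 0:
        raise ValueError("degenerate polygon with zero area")
    ny, nx = series.frame_shape
    rr, cc = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    mask = _points_in_polygon(pts, vertices).reshape(ny, nx)
    return MaskStack(grids=mask, provenance={
        "mode": "polygon", "vertices": vertices.tolist()})


# ---------------------------------------------------------------------------
# Cluster exclusion
# ---------------------------------------------------------------------------


def _boxcar_mean(img: np.ndarray, size: int) -> np.ndarray:
    """Neighborhood boxcar mean with shrinking windows at the borders."""
    num = ndimage.uniform_filter(img, size=size, mode="constant", cval=0.0)
    cnt = ndimage.uniform_filter(np.ones_like(img), size=size,
                                 mode="constant", cval=0.0)
    return num / cnt


def _majority_smooth(grid: np.ndarray) -> np.ndarray:
    """3×3 median filter on a boolean grid (majority of the 9 samples)."""
    return ndimage.median_filter(grid.astype(np.uint8), size=3,
                                 mode="nearest").astype(bool)


def cluster_mask(series: ImageSeries, mode: str = "dynamic", k: float = 3.0,
                 neighborhood: int = 5, roi: MaskStack | None = None,
                 channel: int = 0, max_iter: int = 10) -> MaskStack:
    """Exclude bright clusters by iterative neighborhood thresholding.

    A pixel is excluded when the boxcar mean over its ``neighborhood`` ×
    ``neighborhood`` surroundings is ≥ ``k`` × the mean intensity over all
    currently included pixels of the whole (preprocessed) series. Because
    the reference mean drops as clusters are removed, the rule is iterated
    until the excluded set is stable (at most ``max_iter`` passes). Each
    resulting grid is then smoothed with a 3×3 median filter.

    ``mode="dynamic"`` applies the rule per frame (one grid per frame);
    ``mode="static"`` applies it once to the time-averaged image. An
    initial ROI mask, when given, is intersected throughout.
    """
    if k <= 1:
        raise ValueError("threshold factor k must exceed 1")
    if neighborhood < 1 or neighborhood % 2 == 0:
        raise ValueError("neighborhood must be a positive odd integer")
    if mode not in ("dynamic", "static"):
        raise ValueError("mode must be 'dynamic' or 'static'")
    stack = series.channel(channel)
    ny, nx = series.frame_shape
    base = np.ones((ny, nx), dtype=bool) if roi is None else roi.static_grid()

    if mode == "static":
        imgs = stack.mean(axis=0)[None]
    else:
        imgs = stack
    box = np.stack([_boxcar_mean(img, neighborhood) for img in imgs])

    included = np.broadcast_to(base, imgs.shape).copy()
    for _ in range(max_iter):
        # reference: mean intensity of all currently included pixels of the
        # whole preprocessed series (per-frame inclusion in dynamic mode)
        ref_vals = imgs[0][included[0]] if mode == "static" else stack[included]
        if ref_vals.size == 0:
            break
        ref = ref_vals.mean()
        new = base & (box < k * ref)
        if np.array_equal(new, included):
            break
        included = new

    smoothed = np.stack([_majority_smooth(g) & base for g in included])
    grids = smoothed[0] if mode == "static" else smoothed
    return MaskStack(grids=grids, provenance={
        "mode": mode, "k": k, "neighborhood": neighborhood,
        "smoothing": "3x3 median", "iterative": True})


def intersect_masks(stack: MaskStack) -> MaskStack:
    """Reduce a per-frame stack to the single grid included in every frame."""
    grid = stack.static_grid()
    prov = dict(stack.provenance)
    prov["intersected"] = True
    return MaskStack(grids=grid, provenance=prov)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def write_mask(mask: MaskStack, path: str | Path) -> Path:
    """Write mask grids as a 1-bit multi-page TIFF plus a provenance JSON."""
    import tifffile

    path = Path(path)
    grids = mask.grids if not mask.is_static else mask.grids[None]
    tifffile.imwrite(path, grids.astype(np.uint8) * 255, photometric="minisblack")
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump({"static": mask.is_static, **mask.provenance}, fh, indent=2)
    return path


def read_mask(path: str | Path) -> MaskStack:
    import tifffile

    path = Path(path)
    grids = np.asarray(tifffile.imread(path)) > 0
    prov: dict = {}
    meta = path.with_suffix(".json")
    static = grids.ndim == 2 or grids.shape[0] == 1
    if meta.exists():
        with open(meta) as fh:
            prov = json.load(fh)
        static = prov.pop("static", static)
    if grids.ndim == 3 and static:
        grids = grids[0]
    return MaskStack(grids=grids, provenance=prov)
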