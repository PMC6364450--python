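"""Cultivation-box region-of-interest detection in RGB images.

The cultivation boxes have gray rims; ROI detection finds "gray" edge
pixels (similar R, G, B values, mid brightness, high gradient) and fits
an axis-aligned rectangle with one of two procedures:

* edge-density fit — each side is placed at the 1D density peak of the
  detected point rows/cols; robust to outliers but needs many rim points,
  i.e. early growth stages with open canopy;
* maximum empty rectangle — the largest rectangle containing no edge
  point; works with very few visible rim points (late, closed canopy)
  but is sensitive to stray "gray" detections inside the box.

Interactive correction is replaced by a CSV override file keyed by box id
and date.
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path

import numpy as np
from scipy import ndimage

METHOD_EDGE_DENSITY = "edge-density"
METHOD_MAX_EMPTY_RECT = "max-empty-rect"
METHOD_OVERRIDE = "override"


@dataclasses.dataclass(frozen=True)
class ROI:
    """Axis-aligned rectangle, 0-based half-open pixel coordinates."""

    top: int
    left: int
    bottom: int
    right: int
    method: str = METHOD_OVERRIDE

    def __post_init__(self) -> None:
        if not (self.top < self.bottom and self.left < self.right):
            raise ValueError("ROI requires top < bottom and left < right")
        if self.top < 0 or self.left < 0:
            raise ValueError("ROI must lie within image bounds")

    def validate_bounds(self, shape: tuple[int, int]) -> "ROI":
        if self.bottom > shape[0] or self.right > shape[1]:
            raise ValueError(f"ROI {self.rect} exceeds image bounds {shape}")
        return self

    @property
    def rect(self) -> tuple[int, int, int, int]:
        return (self.top, self.left, self.bottom, self.right)

    @property
    def area(self) -> int:
        return (self.bottom - self.top) * (self.right - self.left)

    def contains_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points).reshape(-1, 2)
        return ((pts[:, 0] >= self.top) & (pts[:, 0] < self.bottom)
                & (pts[:, 1] >= self.left) & (pts[:, 1] < self.right))

    def iou(self, other: "ROI") -> float:
        t, l = max(self.top, other.top), max(self.left, other.left)
        b, r = min(self.bottom, other.bottom), min(self.right, other.right)
        inter = max(0, b - t) * max(0, r - l)
        union = self.area + other.area - inter
        return inter / union if union else 0.0


@dataclasses.dataclass
class EdgePointSet:
    """Detected gray edge pixels, (row, col) coordinates."""

    points: np.ndarray
    grayness_tol: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=int).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.points)


def detect_edge_points(rgb: np.ndarray, grayness_tol: float = 0.08,
                       brightness_range: tuple[float, float] = (0.2, 0.8),
                       gradient_percentile: float = 90.0) -> EdgePointSet:
    """Gray, mid-brightness pixels lying on strong intensity edges.

    A pixel qualifies when its largest pairwise channel difference is at
    most ``grayness_tol``, its channel mean lies in ``brightness_range``,
    and its gradient magnitude exceeds the image's ``gradient_percentile``
    level (the edge-response mask).
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    spread = rgb.max(axis=-1) - rgb.min(axis=-1)
    brightness = rgb.mean(axis=-1)
    gray = (spread <= grayness_tol) & (brightness >= brightness_range[0]) \
        & (brightness <= brightness_range[1])
    gx = ndimage.sobel(brightness, axis=1, mode="nearest")
    gy = ndimage.sobel(brightness, axis=0, mode="nearest")
    gmag = np.hypot(gx, gy)
    edges = gmag > np.percentile(gmag, gradient_percentile)
    rows, cols = np.nonzero(gray & edges)
    return EdgePointSet(points=np.column_stack([rows, cols]), grayness_tol=grayness_tol)


def fit_box_edge_density(points: EdgePointSet, bounds: tuple[int, int],
                         smooth_sigma: float = 2.0) -> ROI:
    """Place each box side at the density peak of edge-point rows/cols.

    The top (bottom) side is the row maximizing a smoothed histogram of
    point rows in the upper (lower) image half, and analogously for
    left/right with columns.  The detected rim coordinates are returned
    as a half-open rectangle (bottom/right exclusive bounds are the rim
    coordinate + 1).
    """
    H, W = bounds
    pts = points.points
    if len(pts) < 4:
        raise ValueError("edge-density fit needs at least 4 points")

    def peak(coords: np.ndarray, size: int) -> int | None:
        if coords.size == 0:
            return None
        hist = np.bincount(coords, minlength=size).astype(float)
        hist = ndimage.gaussian_filter1d(hist, smooth_sigma)
        return int(np.argmax(hist))

    rows, cols = pts[:, 0], pts[:, 1]
    top = peak(rows[rows < H / 2], H)
    bottom = peak(rows[rows >= H / 2], H)
    left = peak(cols[cols < W / 2], W)
    right = peak(cols[cols >= W / 2], W)
    if None in (top, bottom, left, right) or top >= bottom or left >= right:
        raise ValueError("edge-density fit failed")
    return ROI(top=top, left=left, bottom=bottom + 1, right=right + 1,
               method=METHOD_EDGE_DENSITY)


def max_empty_rectangle(points: EdgePointSet, bounds: tuple[int, int]) -> ROI:
    """Largest axis-aligned rectangle containing no edge-point pixel.

    Operates on the discrete pixel grid: a half-open rectangle is empty
    iff none of its pixels is an edge point, and the search (largest
    all-clear rectangle via the histogram-stack scan) is optimal on that
    grid.  Ties are broken by the lexicographically smallest
    (top, left, bottom, right).
    """
    H, W = bounds
    blocked = np.zeros((H, W), dtype=bool)
    if len(points):
        pts = points.points
        if (pts < 0).any() or (pts[:, 0] >= H).any() or (pts[:, 1] >= W).any():
            raise ValueError("edge points outside image bounds")
        blocked[pts[:, 0], pts[:, 1]] = True

    best = None  # (-area, top, left, bottom, right)
    heights = np.zeros(W, dtype=int)
    for r in range(H):
        heights = np.where(blocked[r], 0, heights + 1)
        # histogram-stack scan: every maximal rectangle with bottom row r
        stack: list[tuple[int, int]] = []  # (start col, bar height), increasing
        for c in range(W + 1):
            h = int(heights[c]) if c < W else 0
            start = c
            while stack and stack[-1][1] >= h:
                sc, sh = stack.pop()
                cand = (-(sh * (c - sc)), r + 1 - sh, sc, r + 1, c)
                if best is None or cand < best:
                    best = cand
                start = sc
            if h > 0 and (not stack or stack[-1][1] < h):
                stack.append((start, h))
    if best is None:
        raise ValueError("image is fully covered by edge points")
    _, top, left, bottom, right = best
    return ROI(top=top, left=left, bottom=bottom, right=right,
               method=METHOD_MAX_EMPTY_RECT)


def detect_roi(rgb: np.ndarray, grayness_tol: float = 0.08,
               brightness_range: tuple[float, float] = (0.2, 0.8),
               density_min_points: int = 200) -> ROI:
    """Full automatic box detection with the stated method-selection rule.

    Edge-density fitting needs many rim points and is used when at least
    ``density_min_points`` survive detection (early growth stages);
    otherwise the maximum-empty-rectangle procedure is used (closed
    canopy).  Falls back to the other procedure if the preferred one
    degenerates.
    """
    bounds = rgb.shape[:2]
    pts = detect_edge_points(rgb, grayness_tol, brightness_range)
    if len(pts) >= density_min_points:
        try:
            return fit_box_edge_density(pts, bounds)
        except ValueError:
            pass
    return max_empty_rectangle(pts, bounds)


# ---------------------------------------------------------------------------
# Manual override (replaces interactive correction)
# ---------------------------------------------------------------------------


def load_overrides(path: str | Path) -> dict[tuple[str, str], ROI]:
    """Read a ROI override CSV: box_id, date, top, left, bottom, right."""
    overrides: dict[tuple[str, str], ROI] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            key = (str(row["box_id"]), str(row["date"]))
            try:
                overrides[key] = ROI(top=int(row["top"]), left=int(row["left"]),
                                     bottom=int(row["bottom"]), right=int(row["right"]),
                                     method=METHOD_OVERRIDE)
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"malformed ROI override for {key}: {exc}") from exc
    return overrides


def resolve_roi(auto: ROI, overrides: dict[tuple[str, str], ROI] | None,
                box_id: str | None = None, date: str | None = None,
                bounds: tuple[int, int] | None = None) -> ROI:
    """Return the override ROI when present, otherwise the automatic one."""
    chosen = auto
    if overrides:
        key = (str(box_id), str(date))
        if key in overrides:
            chosen = overrides[key]
    if bounds is not None:
        chosen.validate_bounds(bounds)
    return chosen
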