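"""Raster and contour geometry plus segmentation evaluation metrics.

Conventions
-----------
Coordinates are ``(row, col)``, 0-based, with row increasing downward.
Masks are 2-D binary arrays; contours are ordered integer point lists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import line as _draw_line
from skimage.draw import polygon as _draw_polygon


@dataclass
class Contour:
    """Ordered boundary points, open while being traced.

    ``points`` is an (N, 2) integer array of (row, col) coordinates.
    """

    points: np.ndarray
    closed: bool = False

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.points))
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.shape[1] != 2:
            raise ValueError(f"contour points must be (N, 2), got {pts.shape}")
        self.points = pts.astype(np.int64)

    def __len__(self) -> int:
        return len(self.points)


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")


def mask_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """Exact integer (|a∩b|, |a only|, |b only|) pixel counts."""
    _check_same_shape(a, b)
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    inter = int(np.count_nonzero(a & b))
    return inter, int(np.count_nonzero(a)) - inter, int(np.count_nonzero(b)) - inter


def compute_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary masks; 0 when both are empty."""
    inter, a_only, b_only = mask_counts(a, b)
    union = inter + a_only + b_only
    if union == 0:
        return 0.0
    return inter / union


def rasterize_contour(contour: Contour, shape: tuple[int, int]) -> np.ndarray:
    """Fill the polygon obtained by joining consecutive points and closing it.

    Boundary pixels (8-connected digital lines between consecutive points)
    are always included; a single point yields a one-pixel mask.
    """
    pts = contour.points
    if len(pts) == 0:
        raise ValueError("cannot rasterize an empty contour")
    h, w = shape
    if pts[:, 0].min() < 0 or pts[:, 1].min() < 0 or pts[:, 0].max() >= h or pts[:, 1].max() >= w:
        raise ValueError(f"contour point outside image bounds {shape}")
    mask = np.zeros(shape, dtype=np.uint8)
    if len(pts) >= 3:
        rr, cc = _draw_polygon(pts[:, 0], pts[:, 1], shape=shape)
        mask[rr, cc] = 1
    for i in range(len(pts)):
        r0, c0 = pts[i]
        r1, c1 = pts[(i + 1) % len(pts)]
        rr, cc = _draw_line(int(r0), int(c0), int(r1), int(c1))
        mask[rr, cc] = 1
    return mask


def min_edge_distance(p: tuple[int, int], gt: Contour) -> float:
    """Euclidean distance from ``p`` to the nearest ground-truth contour point."""
    if len(gt) == 0:
        raise ValueError("ground-truth contour is empty")
    d = gt.points - np.asarray(p, dtype=np.float64)
    return float(np.sqrt((d**2).sum(axis=1)).min())


def average_perpendicular_distance(pred: Contour, gt: Contour) -> float:
    """Mean over predicted points of the distance to the nearest gt point."""
    if len(pred) == 0 or len(gt) == 0:
        raise ValueError("contours must be nonempty")
    diff = pred.points[:, None, :].astype(np.float64) - gt.points[None, :, :]
    dists = np.sqrt((diff**2).sum(axis=2)).min(axis=1)
    return float(dists.mean())


def precision_recall_fmeasure(pred: np.ndarray, gt: np.ndarray) -> tuple[float, float, float]:
    """Pixelwise precision, recall and F-measure.

    Zero-denominator conventions: empty prediction gives precision 0,
    empty ground truth gives recall 0, and F is 0 when P = R = 0.
    """
    tp, fp, fn = mask_counts(pred, gt)
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return precision, recall, f


def sobel_edge_map(img: np.ndarray) -> np.ndarray:
    """Gradient magnitude from the 3x3 Sobel pair with reflect borders."""
    img = np.asarray(img, dtype=np.float64)
    gr = ndimage.sobel(img, axis=0, mode="reflect")
    gc = ndimage.sobel(img, axis=1, mode="reflect")
    return np.hypot(gr, gc)


def normalize_symmetric(img: np.ndarray) -> np.ndarray:
    """Linearly map an array onto [-1, 1]; a constant array maps to zeros."""
    img = np.asarray(img, dtype=np.float64)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    return 2.0 * (img - lo) / (hi - lo) - 1.0
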