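"""Wing isolation, orientation normalization and size measurement."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import label

from mothwing.synthetic_wings import ConeCatchImage, _BACKGROUND

__all__ = ["WingSize", "segment_wing", "orient_wing", "wing_size"]


@dataclass(frozen=True)
class WingSize:
    """Wing area and the side lengths of its minimum-area bounding box."""

    area: float  # cm^2
    length: float  # cm, major side
    breadth: float  # cm, minor side

    def __post_init__(self) -> None:
        if not (self.length >= self.breadth > 0 and self.area > 0):
            raise ValueError("require length >= breadth > 0 and area > 0")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.area, self.length, self.breadth)


def segment_wing(
    image: np.ndarray | ConeCatchImage,
    background_threshold: float = 0.05,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Largest connected foreground component, or a supplied mask unchanged.

    The background level is estimated from the image border (median); pixels
    whose intensity differs from it by more than ``background_threshold`` are
    foreground, so both bright-on-dark and dark-on-bright subjects work.
    """
    if mask is not None:
        return np.asarray(mask, dtype=bool)
    if isinstance(image, ConeCatchImage):
        img = image.q.mean(axis=0)
    else:
        img = np.asarray(image, dtype=float)
        if img.ndim == 3:
            img = img.mean(axis=0)
    border = np.concatenate([img[0], img[-1], img[:, 0], img[:, -1]])
    bg = float(np.median(border))
    fg = np.abs(img - bg) > background_threshold
    if not fg.any():
        raise ValueError("no foreground found (all pixels at background level)")
    labels = label(fg)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(counts.argmax())


def _major_axis_angle(mask: np.ndarray) -> float:
    """Orientation (radians, in (-pi/2, pi/2]) of the mask's principal axis,
    measured from the +x (column) direction."""
    ys, xs = np.nonzero(mask)
    if len(xs) < 3:
        raise ValueError("degenerate mask: fewer than 3 pixels")
    x = xs - xs.mean()
    y = ys - ys.mean()
    mu20, mu02, mu11 = (x * x).mean(), (y * y).mean(), (x * y).mean()
    if mu20 == mu02 and mu11 == 0:
        return 0.0
    return 0.5 * np.arctan2(2 * mu11, mu20 - mu02)


def orient_wing(
    image: ConeCatchImage,
) -> ConeCatchImage:
    """Rotate so the wing's longest dimension is horizontal, apex to the right.

    The principal-axis angle comes from the mask's second central moments;
    the apex convention flips the image 180 deg when the mass-heavier (basal)
    side faces right, making the orientation sign deterministic.
    """
    angle = _major_axis_angle(image.mask)
    deg = np.rad2deg(angle)
    # ndimage.rotate with positive angle turns axes so that a feature at
    # +angle from the x axis becomes horizontal when rotated by `deg`
    q = np.stack(
        [
            ndimage.rotate(c, deg, reshape=True, order=1, mode="constant", cval=_BACKGROUND)
            for c in image.q
        ]
    )
    mask = ndimage.rotate(
        image.mask.astype(float), deg, reshape=True, order=0, mode="constant", cval=0.0
    ) > 0.5
    if not mask.any():
        raise ValueError("mask vanished during rotation")
    ys, xs = np.nonzero(mask)
    xc = xs - xs.mean()
    skew = float((xc**3).mean())
    if skew < 0:  # long tail (apex) to the left -> flip 180 deg
        q = q[:, ::-1, ::-1].copy()
        mask = mask[::-1, ::-1].copy()
    return ConeCatchImage(q=np.clip(q, 1e-6, 1.0), mask=mask, px_per_cm=image.px_per_cm)


def _min_area_box(points: np.ndarray) -> tuple[float, float]:
    """(major, minor) side lengths of the minimum-area rectangle enclosing
    2-D points, by rotating calipers over convex-hull edges."""
    hull = points[ConvexHull(points).vertices]
    edges = np.diff(np.vstack([hull, hull[:1]]), axis=0)
    angles = np.unique(np.mod(np.arctan2(edges[:, 1], edges[:, 0]), np.pi))
    best = None
    for a in angles:
        c, s = np.cos(a), np.sin(a)
        rot = points @ np.array([[c, -s], [s, c]])
        w = rot[:, 0].max() - rot[:, 0].min()
        h = rot[:, 1].max() - rot[:, 1].min()
        if best is None or w * h < best[0]:
            best = (w * h, max(w, h), min(w, h))
    return best[1], best[2]


def wing_size(mask: np.ndarray, px_per_cm: float) -> WingSize:
    """Area and minimum-area bounding-box side lengths of the mask, in cm.

    Pixels are treated as unit squares (their corners bound the box), so a
    filled 200 x 100 px rectangle at 100 px/cm measures exactly 2 x 1 cm.
    """
    if px_per_cm <= 0:
        raise ValueError("px_per_cm must be positive")
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    area = n / px_per_cm**2
    centers = np.argwhere(mask).astype(float)  # (row, col)
    pts = centers[:, ::-1]  # (x, y)
    try:
        hull_pts = pts[ConvexHull(pts).vertices] if len(pts) >= 3 else pts
        offsets = np.array([[0.5, 0.5], [0.5, -0.5], [-0.5, 0.5], [-0.5, -0.5]])
        corners = (hull_pts[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
        major_px, minor_px = _min_area_box(corners)
    except QhullError:  # collinear pixels: a 1-px-wide strip
        span = pts.max(axis=0) - pts.min(axis=0)
        major_px = float(np.hypot(*span)) + 1.0
        minor_px = 1.0
    return WingSize(
        area=area, length=major_px / px_per_cm, breadth=max(minor_px, 1.0) / px_per_cm
    )
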