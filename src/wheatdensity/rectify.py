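"""Projective calibration and orthorectification.

Oblique field images (camera at ~45 deg) show a spatial resolution that
varies with distance.  A chessboard placed on the soil calibrates a 3x3
projective transform from image pixels to a metric ground plane; images
are then remapped onto a regular ground grid ("orthoimage") so one pixel
covers a constant ground area.

Point coordinates are (x, y) = (column, row), 0-based, origin at the
top-left pixel; ground coordinates are millimetres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2gray
from skimage.feature import corner_peaks, corner_subpix
from skimage.transform import ProjectiveTransform, warp

from .errors import DetectionError, FitError, GeometryError

__all__ = [
    "Homography",
    "CornerGrid",
    "detect_chessboard",
    "fit_homography",
    "rectify_image",
    "RectifiedRaster",
]


@dataclass
class Homography:
    """3x3 projective map, defined up to scale.

    ``matrix`` maps homogeneous ``src_frame`` coordinates to
    ``dst_frame`` coordinates.  Normalized so the bottom-right entry is
    1 whenever it is nonzero.
    """

    matrix: np.ndarray
    src_frame: str = "image pixels"
    dst_frame: str = "ground mm"
    residual_px: float = 0.0

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise FitError(f"homography matrix must be 3x3, got {m.shape}")
        if abs(np.linalg.det(m)) < 1e-12:
            raise FitError("homography matrix is singular")
        if abs(m[2, 2]) > 1e-12:
            m = m / m[2, 2]
        self.matrix = m

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 2) points through the homography."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ph = np.column_stack([pts, np.ones(len(pts))]) @ self.matrix.T
        return ph[:, :2] / ph[:, 2:3]

    def inverse(self) -> "Homography":
        return Homography(
            np.linalg.inv(self.matrix),
            src_frame=self.dst_frame,
            dst_frame=self.src_frame,
            residual_px=self.residual_px,
        )

    @classmethod
    def identity(cls, **kw) -> "Homography":
        return cls(np.eye(3), **kw)

    def to_json(self, path=None) -> str:
        payload = {
            "matrix": self.matrix.tolist(),
            "src_frame": self.src_frame,
            "dst_frame": self.dst_frame,
            "residual_px": self.residual_px,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "Homography":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            np.array(payload["matrix"]),
            src_frame=payload.get("src_frame", "image pixels"),
            dst_frame=payload.get("dst_frame", "ground mm"),
            residual_px=payload.get("residual_px", 0.0),
        )


@dataclass
class CornerGrid:
    """Interior chessboard corners, row-major, with the square edge length."""

    points: np.ndarray            # (rows*cols, 2) pixel (x, y), row-major
    shape: tuple[int, int]        # (pattern_rows, pattern_cols)
    square_size_mm: float = 1.0

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        r, c = self.shape
        if r < 2 or c < 2:
            raise DetectionError("corner grid must be at least 2x2")
        if len(self.points) != r * c:
            raise DetectionError(
                f"expected {r * c} corners for a {r}x{c} grid, got {len(self.points)}"
            )

    def ground_points(self) -> np.ndarray:
        """Metric (x, y) ground coordinates of the lattice, row-major, mm."""
        r, c = self.shape
        jj, ii = np.meshgrid(np.arange(c), np.arange(r))
        return np.column_stack([jj.ravel(), ii.ravel()]) * self.square_size_mm


def _order_outer_corners(points: np.ndarray) -> np.ndarray:
    """Return the TL, TR, BR, BL extreme points of a corner cloud."""
    s = points.sum(axis=1)
    d = points[:, 0] - points[:, 1]
    return np.array(
        [
            points[np.argmin(s)],   # top-left
            points[np.argmax(d)],   # top-right
            points[np.argmax(s)],   # bottom-right
            points[np.argmin(d)],   # bottom-left
        ]
    )


def _xcorner_response(gray: np.ndarray) -> np.ndarray:
    """Chessboard X-corner saliency.

    At an interior corner the two diagonal quadrant pairs differ in
    sign, so |A + D - B - C| is large while |A - D| and |B - C| stay
    small; plain L-corners (board boundary, specks) are penalized by
    the latter terms.  Summed over two scales for robustness.
    """
    g = ndi.gaussian_filter(gray, 1.2)
    resp = np.zeros_like(g)
    for d in (3, 5):
        A = np.roll(g, (d, d), axis=(0, 1))
        D = np.roll(g, (-d, -d), axis=(0, 1))
        B = np.roll(g, (d, -d), axis=(0, 1))
        C = np.roll(g, (-d, d), axis=(0, 1))
        resp += np.abs(A + D - B - C) - np.abs(A - D) - np.abs(B - C)
    resp[resp < 0] = 0
    resp[:8, :] = resp[-8:, :] = 0
    resp[:, :8] = resp[:, -8:] = 0
    return resp


def detect_chessboard(
    image: np.ndarray,
    pattern_rows: int,
    pattern_cols: int,
    square_size_mm: float = 1.0,
) -> CornerGrid:
    """Locate the interior corners of a chessboard, sub-pixel, row-major.

    X-corner saliency peaks are detected, the four outermost anchor an
    initial lattice homography, every lattice node is matched to its
    nearest detection, and matched corners are refined to sub-pixel
    accuracy.

    Raises
    ------
    DetectionError
        If the expected ``pattern_rows x pattern_cols`` corner grid
        cannot be located.
    """
    n_expected = pattern_rows * pattern_cols
    gray = rgb2gray(image) if image.ndim == 3 else np.asarray(image, dtype=float)
    response = _xcorner_response(gray)
    cand = corner_peaks(
        response, min_distance=7, threshold_rel=0.15, num_peaks=n_expected
    )
    if len(cand) < n_expected:
        raise DetectionError(
            f"found {len(cand)} candidate corners, need {n_expected}"
        )
    pts = cand[:, ::-1].astype(float)  # (row, col) -> (x, y)

    # Anchor homography: unit lattice corners -> extreme detections.
    unit = np.array(
        [[0, 0], [pattern_cols - 1, 0], [pattern_cols - 1, pattern_rows - 1],
         [0, pattern_rows - 1]],
        dtype=float,
    )
    anchor = fit_homography(unit, _order_outer_corners(pts))
    jj, ii = np.meshgrid(np.arange(pattern_cols), np.arange(pattern_rows))
    lattice = np.column_stack([jj.ravel(), ii.ravel()]).astype(float)

    # Two matching passes: the second re-fits with all matched corners.
    matched = None
    for _ in range(2):
        pred = anchor.apply(lattice)
        d2 = ((pred[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        nearest = np.argmin(d2, axis=1)
        if len(np.unique(nearest)) != n_expected:
            raise DetectionError("corner lattice matching is not one-to-one")
        matched = pts[nearest]
        anchor = fit_homography(lattice, matched)

    refined = corner_subpix(
        gray, matched[:, ::-1], window_size=11, alpha=0.9
    )
    bad = np.isnan(refined).any(axis=1)
    refined[bad] = matched[:, ::-1][bad]
    return CornerGrid(
        refined[:, ::-1], (pattern_rows, pattern_cols), square_size_mm
    )


def fit_homography(src, dst) -> Homography:
    """Least-squares projective fit (normalized DLT) from correspondences.

    Requires at least 4 point pairs in general position.  The mean
    reprojection error over the correspondences is stored as
    ``residual_px``.
    """
    src = np.atleast_2d(np.asarray(src, dtype=float))
    dst = np.atleast_2d(np.asarray(dst, dtype=float))
    if src.shape != dst.shape or src.shape[0] < 4 or src.shape[1] != 2:
        raise FitError(
            f"need >= 4 matched 2-D points, got {src.shape} vs {dst.shape}"
        )
    tform = ProjectiveTransform.from_estimate(src, dst)
    if not tform:
        raise FitError("projective fit failed (degenerate correspondences)")
    m = tform.params
    if not np.all(np.isfinite(m)) or abs(np.linalg.det(m)) < 1e-12:
        raise FitError("projective fit is rank deficient")
    resid = float(np.mean(np.linalg.norm(tform(src) - dst, axis=1)))
    return Homography(m, residual_px=resid)


@dataclass
class RectifiedRaster:
    """A raster resampled onto a regular ground-plane grid.

    ``origin_mm`` is the ground (x, y) of pixel (0, 0); pixel pitch is
    ``resolution_mm`` in both axes.  ``valid`` is False where the output
    pixel falls outside the source image.
    """

    values: np.ndarray
    valid: np.ndarray
    origin_mm: tuple[float, float]
    resolution_mm: float

    def ground_to_pixel(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (pts - np.asarray(self.origin_mm)) / self.resolution_mm


def rectify_image(
    raster: np.ndarray,
    H: Homography,
    out_resolution_mm: float,
    is_mask: bool = False,
    bounds_mm: tuple | None = None,
) -> RectifiedRaster:
    """Remap a raster to a constant-resolution orthoimage of the ground.

    ``H`` maps image pixels to ground millimetres.  RGB/gray rasters are
    resampled bilinearly; masks and label rasters use nearest-neighbour
    (``is_mask=True``).  The output window defaults to the bounding box
    of the mapped source corners; pass ``bounds_mm`` as
    ``(xmin, ymin, xmax, ymax)`` to override.
    """
    if out_resolution_mm <= 0:
        raise GeometryError("output resolution must be positive")
    raster = np.asarray(raster)
    h, w = raster.shape[:2]
    if bounds_mm is None:
        corners = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]], float)
        g = H.apply(corners)
        xmin, ymin = g.min(axis=0)
        xmax, ymax = g.max(axis=0)
    else:
        xmin, ymin, xmax, ymax = bounds_mm
    out_w = int(np.floor((xmax - xmin) / out_resolution_mm)) + 1
    out_h = int(np.floor((ymax - ymin) / out_resolution_mm)) + 1
    if out_w < 1 or out_h < 1:
        raise GeometryError("empty rectification window")
    if out_w * out_h > 6e7:
        raise GeometryError(
            f"rectification window {out_h}x{out_w} px is implausibly large; "
            "check homography units and output resolution"
        )

    # output px -> ground mm -> source px, as one projective matrix
    T = np.array(
        [[out_resolution_mm, 0, xmin], [0, out_resolution_mm, ymin], [0, 0, 1]]
    )
    inv_map = ProjectiveTransform(np.linalg.inv(H.matrix) @ T)

    order = 0 if is_mask else 1
    if raster.dtype == bool:
        values = warp(
            raster.astype(np.uint8), inv_map, output_shape=(out_h, out_w),
            order=0, cval=0, preserve_range=True,
        ).astype(bool)
    else:
        values = warp(
            raster.astype(float), inv_map, output_shape=(out_h, out_w),
            order=order, cval=0.0, preserve_range=True,
        )
        if np.issubdtype(raster.dtype, np.integer):
            values = np.rint(values).astype(raster.dtype)
    valid = warp(
        np.ones((h, w)), inv_map, output_shape=(out_h, out_w),
        order=0, cval=0.0, preserve_range=True,
    ) > 0.5
    return RectifiedRaster(values, valid, (float(xmin), float(ymin)),
                           float(out_resolution_mm))
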