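"""Crop-row detection with an edge-point Hough transform.

Rows are modelled as parallel lines ``rho = x*cos(theta) + y*sin(theta)``
with x = column and y = row index.  ``theta_row = +/-90 deg`` means
horizontal rows, the nominal acquisition geometry.  The dominant
orientation is the theta column whose vote histogram over rho has the
largest variance (votes from parallel rows pile into a few rho bins),
and individual rows are the prominent peaks of that column.

The accumulator axes follow the acquisition protocol: theta in
[-90, 90) deg in 0.1 deg steps and rho in (-3000, 3000) px in 1 px
steps.  On a binary mask, edge thinning before voting reduces to exact
morphological boundary extraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import NoRowsError, OrientationUndetectableError, RangeError

__all__ = [
    "default_theta_axis",
    "default_rho_axis",
    "edge_points",
    "hough_accumulate",
    "HoughAccumulator",
    "row_orientation",
    "row_positions",
    "locate_rows",
    "rotation_to_horizontal",
    "rotate_rows_horizontal",
    "assign_objects_to_rows",
    "RowModel",
]

THETA_STEP_DEG = 0.1
RHO_STEP_PX = 1.0
RHO_LIMIT_PX = 3000.0


def default_theta_axis() -> np.ndarray:
    """Theta bin centres in degrees: [-90, 90) in 0.1 deg steps."""
    return -90.0 + THETA_STEP_DEG * np.arange(1800)


def default_rho_axis() -> np.ndarray:
    """Rho bin centres in pixels: -2999 ... 2999 in 1 px steps."""
    return np.arange(-RHO_LIMIT_PX + 1, RHO_LIMIT_PX)


@dataclass
class HoughAccumulator:
    """Vote counts indexed by (theta bin, rho bin)."""

    counts: np.ndarray
    theta_deg: np.ndarray
    rho_px: np.ndarray
    n_points: int

    def theta_index(self, theta: float) -> int:
        return int(np.argmin(np.abs(self.theta_deg - theta)))


def edge_points(mask: np.ndarray) -> np.ndarray:
    """Boundary pixels of the foreground as (N, 2) (x, y) coordinates.

    A foreground pixel is a boundary pixel when at least one of its 8
    neighbours (pixels outside the image count as background) is False.
    Identical to the erosion difference mask AND NOT erode(mask).
    """
    mask = np.asarray(mask, dtype=bool)
    eroded = ndi.binary_erosion(mask, structure=np.ones((3, 3)), border_value=0)
    rr, cc = np.nonzero(mask & ~eroded)
    return np.column_stack([cc, rr]).astype(float)


def hough_accumulate(
    points: np.ndarray,
    theta_deg: np.ndarray | None = None,
    rho_px: np.ndarray | None = None,
) -> HoughAccumulator:
    """Vote each point into every theta column at its rounded rho.

    Each point contributes exactly one vote per theta bin, so every
    column of the accumulator sums to the number of points.

    Raises
    ------
    RangeError
        If some point's rho falls outside the rho axis for any theta
        (crop the mask or recentre coordinates).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        raise RangeError("no points to accumulate")
    theta_deg = default_theta_axis() if theta_deg is None else np.asarray(theta_deg)
    rho_px = default_rho_axis() if rho_px is None else np.asarray(rho_px)
    rho0 = rho_px[0]
    rho_step = rho_px[1] - rho_px[0] if len(rho_px) > 1 else 1.0
    n_rho = len(rho_px)

    t = np.deg2rad(theta_deg)
    counts = np.zeros((len(theta_deg), n_rho), dtype=np.int32)
    # chunk over theta to bound the (N x T) distance matrix
    chunk = max(1, int(4e6 / max(len(points), 1)))
    for s in range(0, len(t), chunk):
        block = t[s:s + chunk]
        rho = points @ np.vstack([np.cos(block), np.sin(block)])
        idx = np.rint((rho - rho0) / rho_step).astype(np.int64)
        if idx.min() < 0 or idx.max() >= n_rho:
            raise RangeError(
                "point radius outside the rho axis; crop the image so all "
                f"pixels satisfy |rho| < {rho_px[-1] + rho_step:g} px"
            )
        for j in range(idx.shape[1]):
            counts[s + j] = np.bincount(idx[:, j], minlength=n_rho)
    return HoughAccumulator(counts, theta_deg, rho_px, len(points))


def row_orientation(
    acc: HoughAccumulator,
    smooth_sigma_px: float = 0.0,
    refine_window_deg: float | None = None,
) -> float:
    """Dominant orientation: the theta maximizing the variance of rho votes.

    Ties are broken toward |theta| closest to 90 deg (rows are close to
    horizontal by acquisition design), then toward negative theta.

    With ``smooth_sigma_px`` > 0 the vote columns are blurred along rho
    before the variance is taken: crop rows concentrate votes in a band
    as wide as the plants, whereas spurious orientations (parallel leaf
    edges) make narrow spikes, so band-scale smoothing selects rows
    robustly at low plant density.  ``refine_window_deg`` then re-runs
    the unsmoothed criterion within that window of the coarse optimum
    to recover the precise bin.
    """
    if acc.n_points < 2:
        raise OrientationUndetectableError("need at least 2 points")

    def _argmax(var: np.ndarray, sel: np.ndarray | None = None) -> int:
        idx = np.arange(len(var)) if sel is None else np.nonzero(sel)[0]
        best = var[idx].max()
        ties = idx[var[idx] == best]
        return min(
            ties, key=lambda i: (-abs(acc.theta_deg[i]), acc.theta_deg[i])
        )

    var_raw = acc.counts.var(axis=1)
    if var_raw.max() <= 0:
        raise OrientationUndetectableError("flat accumulator")
    if smooth_sigma_px <= 0:
        return float(acc.theta_deg[_argmax(var_raw)])

    smoothed = ndi.gaussian_filter1d(
        acc.counts.astype(float), smooth_sigma_px / RHO_STEP_PX, axis=1
    )
    coarse = acc.theta_deg[_argmax(smoothed.var(axis=1))]
    if refine_window_deg is None or refine_window_deg <= 0:
        return float(coarse)
    d = np.abs(acc.theta_deg - coarse)
    d = np.minimum(d, 180.0 - d)  # orientation is periodic mod 180
    return float(acc.theta_deg[_argmax(var_raw, d <= refine_window_deg)])


def row_positions(
    acc: HoughAccumulator,
    theta_row: float,
    min_separation_px: float,
    prominence_frac: float = 0.3,
    smooth_sigma_px: float = 2.0,
) -> np.ndarray:
    """Rho offsets of the rows: prominent peaks of the theta_row column.

    The column is lightly smoothed, candidate bins above
    ``prominence_frac * max`` are accepted greedily in decreasing height
    subject to a mutual distance of ``min_separation_px``, and the
    accepted rho values are returned in increasing order.
    """
    col = acc.counts[acc.theta_index(theta_row)].astype(float)
    if smooth_sigma_px > 0:
        col = ndi.gaussian_filter1d(col, smooth_sigma_px / RHO_STEP_PX)
    threshold = prominence_frac * col.max()
    cand = np.nonzero(col > max(threshold, 0))[0]
    if cand.size == 0:
        raise NoRowsError("no rho peak above the prominence threshold")
    cand = cand[np.argsort(-col[cand], kind="stable")]
    accepted: list[int] = []
    min_sep_bins = min_separation_px / RHO_STEP_PX
    for b in cand:
        if all(abs(b - a) >= min_sep_bins for a in accepted):
            accepted.append(int(b))
    return np.sort(acc.rho_px[np.array(accepted)])


@dataclass
class RowModel:
    """Detected row geometry: shared orientation plus per-row offsets."""

    theta_row: float
    rho_rows: np.ndarray
    row_spacing_px: float = float("nan")

    def __post_init__(self):
        self.rho_rows = np.sort(np.asarray(self.rho_rows, dtype=float))
        if len(self.rho_rows) > 1 and np.isnan(self.row_spacing_px):
            self.row_spacing_px = float(np.median(np.diff(self.rho_rows)))

    @property
    def n_rows(self) -> int:
        return len(self.rho_rows)

    def to_json(self, path=None) -> str:
        payload = {
            "theta_row_deg": self.theta_row,
            "rho_rows_px": self.rho_rows.tolist(),
            "spacing_px": self.row_spacing_px,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RowModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            payload["theta_row_deg"],
            np.array(payload["rho_rows_px"]),
            payload.get("spacing_px", float("nan")),
        )


def locate_rows(
    points: np.ndarray,
    min_separation_px: float,
    prominence_frac: float = 0.3,
    peak_smooth_px: float = 2.0,
    orientation_smooth_px: float = 10.0,
    refine_window_deg: float = 1.5,
) -> RowModel:
    """Detect orientation and row offsets from edge points in one call.

    Points are recentred about their centroid before voting so large
    frames stay inside the accumulator's rho range; the returned row
    offsets are shifted back to the original coordinates.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    center = points.mean(axis=0)
    acc = hough_accumulate(points - center)
    theta = row_orientation(acc, smooth_sigma_px=orientation_smooth_px,
                            refine_window_deg=refine_window_deg)
    rho = row_positions(acc, theta, min_separation_px,
                        prominence_frac=prominence_frac,
                        smooth_sigma_px=peak_smooth_px)
    t = np.deg2rad(theta)
    rho_shift = center @ np.array([np.cos(t), np.sin(t)])
    return RowModel(theta, rho + rho_shift)


def rotation_to_horizontal(theta_row: float) -> float:
    """Rotation angle (deg) bringing rows at ``theta_row`` horizontal.

    The result is ``(90 - theta_row) mod 180`` mapped into (-90, 90].
    """
    phi = (90.0 - theta_row) % 180.0
    if phi > 90.0:
        phi -= 180.0
    return phi


def rotate_rows_horizontal(
    raster: np.ndarray, theta_row: float, is_mask: bool = False
) -> np.ndarray:
    """Rotate a raster about its centre so rows become horizontal.

    Masks and label rasters are resampled nearest-neighbour; continuous
    rasters bilinearly.  The canvas grows to hold the rotated frame.
    """
    phi = rotation_to_horizontal(theta_row)
    raster = np.asarray(raster)
    if phi == 0.0:
        return raster.copy()
    order = 0 if is_mask else 1
    if raster.dtype == bool:
        out = ndi.rotate(raster.astype(np.uint8), -phi, reshape=True, order=0,
                         prefilter=False, cval=0)
        return out.astype(bool)
    out = ndi.rotate(raster.astype(float), -phi, reshape=True, order=order,
                     prefilter=False, cval=0)
    if np.issubdtype(raster.dtype, np.integer):
        out = np.rint(out).astype(raster.dtype)
    return out


def assign_objects_to_rows(centroids_xy: np.ndarray, rows: RowModel):
    """Assign each centroid to the nearest row line.

    Returns ``(row_index, distance_px)`` arrays; ties go to the lower
    row index.
    """
    if rows.n_rows < 1:
        raise NoRowsError("row model holds no rows")
    pts = np.atleast_2d(np.asarray(centroids_xy, dtype=float))
    t = np.deg2rad(rows.theta_row)
    rho = pts @ np.array([np.cos(t), np.sin(t)])
    d = np.abs(rho[:, None] - rows.rho_rows[None, :])
    idx = np.argmin(d, axis=1)
    return idx, d[np.arange(len(pts)), idx]
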