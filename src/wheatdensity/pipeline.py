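"""Per-image orchestration: mask -> rectify -> rows -> rotated objects.

``process_image`` runs the geometric half of the pipeline and returns
everything the counting stage needs: the rotated mask, the detected row
model (in the rotated frame, where rows are horizontal), the feature-
complete object list, and any auxiliary label raster transformed through
the identical geometry (used to join synthetic ground truth to objects).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import yaml

from . import rows as rows_mod
from .errors import NoRowsError, WheatDensityError
from .objects import extract_objects
from .rectify import Homography, rectify_image
from .segmentation import segment_green

__all__ = ["PipelineConfig", "ProcessResult", "process_image"]


@dataclass
class PipelineConfig:
    """Tunable pipeline parameters.

    ``resolution_mm`` is the orthoimage sampling step; the row spacing
    comes from the sowing protocol and drives both the Hough peak
    separation and the density denominator.
    """

    resolution_mm: float = 0.5
    row_spacing_mm: float = 175.0
    segment_length_mm: float | None = None   # None: full mask width
    rows_counted: int | str = "all"
    peak_prominence: float = 0.15
    peak_smooth_px: float = 8.0
    min_separation_frac: float = 0.6         # x expected spacing, Hough peaks
    max_hough_points: int = 25000
    min_area_px: int = 4
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {k: v for k, v in payload.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass
class ProcessResult:
    """Geometric-pipeline output for one image (rotated frame)."""

    mask: np.ndarray
    objects: list
    object_labels: np.ndarray
    row_model: rows_mod.RowModel
    theta_row_detected: float
    resolution_mm: float
    aux_label: np.ndarray | None = None


def _stage(name, fn, *args, **kw):
    try:
        return fn(*args, **kw)
    except WheatDensityError as err:
        err.args = (f"[{name}] {err.args[0] if err.args else ''}",) + err.args[1:]
        raise


def _subsample(points: np.ndarray, max_points: int) -> np.ndarray:
    if len(points) <= max_points:
        return points
    stride = int(np.ceil(len(points) / max_points))
    return points[::stride]


def process_image(
    image: np.ndarray,
    config: PipelineConfig | None = None,
    calib: Homography | None = None,
    aux_label: np.ndarray | None = None,
    resolution_mm: float | None = None,
) -> ProcessResult:
    """Segment, rectify, orient and objectify one image.

    Parameters
    ----------
    image : RGB raster.
    calib : image-px -> ground-mm homography; omit if the image is
        already an orthoimage.
    aux_label : optional integer raster (e.g. synthetic plant ids)
        carried through the same rectification and rotation with
        nearest-neighbour sampling.
    resolution_mm : ground resolution of the *input* when no calibration
        is given; defaults to ``config.resolution_mm``.
    """
    config = config or PipelineConfig()
    mask = _stage("segmentation", segment_green, image)

    if calib is not None:
        rect = _stage("rectify", rectify_image, mask, calib,
                      config.resolution_mm, True)
        mask = rect.values & rect.valid
        if aux_label is not None:
            rect_aux = rectify_image(aux_label, calib, config.resolution_mm,
                                     is_mask=True,
                                     bounds_mm=(rect.origin_mm[0],
                                                rect.origin_mm[1],
                                                rect.origin_mm[0]
                                                + rect.resolution_mm
                                                * (rect.values.shape[1] - 1),
                                                rect.origin_mm[1]
                                                + rect.resolution_mm
                                                * (rect.values.shape[0] - 1)))
            aux_label = rect_aux.values
        res_mm = config.resolution_mm
    else:
        res_mm = resolution_mm if resolution_mm is not None else config.resolution_mm

    edges = _stage("rows", rows_mod.edge_points, mask)
    if len(edges) == 0:
        raise NoRowsError("[rows] empty mask, nothing to detect")
    sub = _subsample(edges, config.max_hough_points)
    min_sep = config.min_separation_frac * config.row_spacing_mm / res_mm
    coarse = _stage("rows", rows_mod.locate_rows, sub, min_sep,
                    config.peak_prominence, config.peak_smooth_px)
    theta = coarse.theta_row

    mask_rot = rows_mod.rotate_rows_horizontal(mask, theta, is_mask=True)
    aux_rot = None
    if aux_label is not None:
        aux_rot = rows_mod.rotate_rows_horizontal(
            np.asarray(aux_label), theta, is_mask=True
        )

    # rows are horizontal now: re-locate offsets with a single-column vote
    edges2 = _subsample(rows_mod.edge_points(mask_rot), config.max_hough_points)
    center2 = edges2.mean(axis=0)
    acc2 = rows_mod.hough_accumulate(edges2 - center2,
                                     theta_deg=np.array([90.0]))
    rho = _stage("rows", rows_mod.row_positions, acc2, 90.0, min_sep,
                 config.peak_prominence, config.peak_smooth_px)
    row_model = rows_mod.RowModel(90.0, rho + center2[1])

    objects, labels = _stage("objects", extract_objects, mask_rot,
                             config.min_area_px)
    if objects:
        cents = np.array([o.centroid_xy for o in objects])
        idx, dist = rows_mod.assign_objects_to_rows(cents, row_model)
        for o, i, d in zip(objects, idx, dist):
            o.row_index = int(i)
            o.row_distance_px = float(d)

    return ProcessResult(
        mask=mask_rot,
        objects=objects,
        object_labels=labels,
        row_model=row_model,
        theta_row_detected=theta,
        resolution_mm=res_mm,
        aux_label=aux_rot,
    )
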