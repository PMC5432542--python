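"""Aggregation of per-object counts into plants per square metre.

Density over a row-segment window is the sum of the (continuous)
per-object plant counts on the counted rows divided by the window area,
the product of segment length and row spacing times the number of rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .countmodel import CountModel, predict_counts
from .errors import ConfigError, WheatDensityError
from .objects import FEATURE_NAMES, objects_to_frame
from .pipeline import PipelineConfig, ProcessResult, process_image
from .rectify import Homography

__all__ = [
    "DensityEstimate",
    "aggregate_density",
    "relative_error",
    "run_pipeline",
]


@dataclass
class DensityEstimate:
    """Plant density over a counted row-segment window."""

    plants_per_m2: float
    segment_length_m: float
    row_spacing_m: float
    n_rows_counted: int
    n_objects: int
    sum_counts: float
    per_row: dict = field(default_factory=dict)  # row idx -> (n_obj, sum)


def _counted_rows(n_rows: int, rows_counted) -> np.ndarray:
    """Indices of the counted rows; an int k keeps the k central rows."""
    if rows_counted in ("all", None):
        return np.arange(n_rows)
    k = int(rows_counted)
    if not 0 < k <= n_rows:
        raise ConfigError(f"cannot count {k} of {n_rows} detected rows")
    first = (n_rows - k) // 2
    return np.arange(first, first + k)


def aggregate_density(
    table: pd.DataFrame,
    config: PipelineConfig,
    segment_length_mm: float | None = None,
    segment_bounds_mm: tuple[float, float] | None = None,
    n_rows: int | None = None,
) -> DensityEstimate:
    """Sum per-object counts over the counting window and divide by area.

    ``table`` needs columns ``pred_count``, ``row_index`` and
    ``centroid_x_mm``.  Objects whose centroid falls outside
    ``segment_bounds_mm`` (along-row) or off the counted rows are
    excluded — the centroid decides, not the pixel footprint.  Pass
    ``n_rows`` (the detected row count) so rows without objects still
    contribute window area; otherwise rows are inferred from the table.
    """
    for col in ("pred_count", "row_index", "centroid_x_mm"):
        if col not in table.columns:
            raise WheatDensityError(f"aggregation needs column '{col}'")
    seg_mm = segment_length_mm or config.segment_length_mm
    if seg_mm is None or seg_mm <= 0 or config.row_spacing_mm <= 0:
        raise ConfigError("segment length and row spacing must be positive")

    if n_rows is not None:
        row_ids = np.arange(n_rows)
    else:
        row_ids = np.sort(table["row_index"].unique())
    counted = row_ids[_counted_rows(len(row_ids), config.rows_counted)]
    sel = table["row_index"].isin(counted)
    if segment_bounds_mm is not None:
        x0, x1 = segment_bounds_mm
        sel &= (table["centroid_x_mm"] >= x0) & (table["centroid_x_mm"] <= x1)
    sub = table[sel]

    area_m2 = (seg_mm / 1000.0) * (config.row_spacing_mm / 1000.0) * len(counted)
    if area_m2 <= 0:
        raise ConfigError("zero-area counting window")
    total = float(sub["pred_count"].sum())
    per_row = {
        int(r): (int((sub["row_index"] == r).sum()),
                 float(sub.loc[sub["row_index"] == r, "pred_count"].sum()))
        for r in counted
    }
    return DensityEstimate(
        plants_per_m2=total / area_m2,
        segment_length_m=seg_mm / 1000.0,
        row_spacing_m=config.row_spacing_mm / 1000.0,
        n_rows_counted=len(counted),
        n_objects=int(len(sub)),
        sum_counts=total,
        per_row=per_row,
    )


def relative_error(estimated: float, reference: float) -> float:
    """Unsigned relative error in percent: 100 |est - ref| / ref."""
    if reference <= 0:
        raise WheatDensityError("reference density must be positive")
    return 100.0 * abs(estimated - reference) / reference


def run_pipeline(
    image: np.ndarray,
    model: CountModel,
    config: PipelineConfig | None = None,
    calib: Homography | None = None,
    resolution_mm: float | None = None,
    image_id: str = "",
):
    """Full chain: segment, rectify, rows, objects, count, aggregate.

    Returns ``(DensityEstimate, table, ProcessResult)`` where the table
    is the per-object feature frame with a ``pred_count`` column.
    """
    config = config or PipelineConfig()
    res: ProcessResult = process_image(
        image, config, calib=calib, resolution_mm=resolution_mm
    )
    table = objects_to_frame(res.objects, image_id=image_id,
                             resolution_mm=res.resolution_mm)
    if len(table):
        table["pred_count"] = predict_counts(model, table)
    else:
        table["pred_count"] = np.nan
    seg_mm = config.segment_length_mm
    if seg_mm is None:
        seg_mm = res.mask.shape[1] * res.resolution_mm
    est = aggregate_density(table, config, segment_length_mm=seg_mm,
                            n_rows=res.row_model.n_rows)
    return est, table, res
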