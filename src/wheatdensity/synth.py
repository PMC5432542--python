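"""Ground-truthed synthetic wheat scenes for testing every pipeline stage.

The generator emulates nadir-equivalent (orthorectified) RGB views of
wheat at the 1-2 leaf stage: parallel sowing rows, plants placed along
each row as a homogeneous Poisson process, each plant rendered as 1-2
erect, slightly curved tapering leaves in jittered green, on a textured
brown soil background.  Plant overlap — the phenomenon that makes
per-object counting necessary — emerges naturally as sowing density
rises.  Greenish distractor blobs (residue, stones) are injected so a
realistic fraction of segmented objects contains no plant at all.

Every scene carries exact truth: a per-pixel plant-id raster, the row
geometry, and the rendered plant count, so density bookkeeping is exact
down to machine precision.  A chessboard renderer under a known
homography exercises the calibration path end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.transform import ProjectiveTransform, warp

from .errors import GeometryError
from .rectify import CornerGrid, Homography

__all__ = [
    "SceneSpec",
    "SceneTruth",
    "generate_scene",
    "generate_chessboard",
    "generate_training_set",
    "batch_specs",
]

# plant-appearance defaults: wheat at Haun stage 1.5-2 seen obliquely
LEAF_LENGTH_MM = (20.0, 60.0)
LEAF_WIDTH_MM = (1.5, 3.0)
LEAF_ANGLE_MEAN_DEG = 15.0   # unsigned tilt of a leaf from "up"
LEAF_ANGLE_SD_DEG = 10.0
P_TWO_LEAVES = 0.6
GREEN_BASE = np.array([60.0, 110.0, 50.0])
SOIL_BASE = np.array([125.0, 92.0, 62.0])
DISTRACTOR_BASE = np.array([95.0, 120.0, 85.0])
PLANT_FOOTPRINT_MM = 12.0    # typical along-row extent, for object-count math


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene (the study conditions)."""

    sowing_density_seeds_m2: float = 300.0
    row_spacing_mm: float = 175.0
    row_angle_deg: float = 90.0          # theta convention: +/-90 = horizontal
    n_rows: int = 5
    segment_length_mm: float = 500.0
    margin_mm: float = 80.0
    resolution_mm: float = 0.5
    image_size_px: tuple[int, int] | None = None   # (H, W); derived if None
    emergence_rate: float = 0.9
    null_object_rate: float = 0.15
    hard_mode: bool = False
    perspective: Homography | None = None  # image px -> ground mm, if oblique
    seed: int = 0

    def __post_init__(self):
        if min(self.row_spacing_mm, self.segment_length_mm,
               self.resolution_mm) <= 0 or self.n_rows < 1:
            raise ValueError("physical dimensions must be positive")
        if not (0 <= self.emergence_rate <= 1 and 0 <= self.null_object_rate < 1):
            raise ValueError("rates must lie in [0, 1]")

    def canvas_shape(self) -> tuple[int, int]:
        """(H, W) of the flat canvas holding the rotated row block."""
        if self.image_size_px is not None:
            return tuple(self.image_size_px)
        t = np.deg2rad(self.row_angle_deg)
        L = self.segment_length_mm / self.resolution_mm
        S = (self.n_rows * self.row_spacing_mm + 2 * self.margin_mm) \
            / self.resolution_mm
        w = abs(np.sin(t)) * L + abs(np.cos(t)) * S
        h = abs(np.cos(t)) * L + abs(np.sin(t)) * S
        return int(np.ceil(h)), int(np.ceil(w))


@dataclass
class SceneTruth:
    """Exact bookkeeping for one rendered scene (flat ground frame)."""

    label: np.ndarray              # int32 plant-id raster, 0 = background
    distractor_mask: np.ndarray
    n_plants: int                  # plants with at least one rendered pixel
    plant_row: dict                # plant id -> row index
    theta_row: float               # deg, in [-90, 90)
    rho_rows_px: np.ndarray
    row_spacing_px: float
    resolution_mm: float
    area_m2: float                 # n_rows * spacing * segment length
    spec: SceneSpec | None = None
    perspective: Homography | None = None
    oblique_label: np.ndarray | None = None  # label raster in the oblique frame

    @property
    def density_true(self) -> float:
        """Rendered plants per square metre of the row block."""
        return self.n_plants / self.area_m2


def _stroke_leaf(label, plant_id, base_xy, direction, length_px, width_px, rng):
    """Paint one tapered, curved leaf onto the label raster."""
    h, w = label.shape
    tip = base_xy + direction * length_px
    perp = np.array([-direction[1], direction[0]])
    ctrl = base_xy + direction * (0.5 * length_px) \
        + perp * rng.normal(0.0, 0.12 * length_px)
    n_samp = max(8, int(length_px * 0.9))
    ts = np.linspace(0.0, 1.0, n_samp)
    pts = ((1 - ts) ** 2)[:, None] * base_xy + \
        (2 * ts * (1 - ts))[:, None] * ctrl + (ts ** 2)[:, None] * tip
    radii = np.maximum(0.5 * width_px * (1.0 - 0.8 * ts), 0.7)
    for (x, y), r in zip(pts, radii):
        rr, cc = draw_disk((y, x), r + 0.3, shape=(h, w))
        label[rr, cc] = plant_id


def _paint_blob(mask, center_xy, axes_px, angle, rng):
    """Paint a rough ellipse blob (distractor) onto a boolean raster."""
    h, w = mask.shape
    a, b = axes_px
    n = max(6, int(2 * a))
    ts = np.linspace(0, 2 * np.pi, n, endpoint=False)
    ca, sa = np.cos(angle), np.sin(angle)
    for t in ts:
        ex, ey = 0.7 * a * np.cos(t), 0.7 * b * np.sin(t)
        x = center_xy[0] + ex * ca - ey * sa
        y = center_xy[1] + ex * sa + ey * ca
        rr, cc = draw_disk((y, x), max(0.3 * b, 1.0) * rng.uniform(0.8, 1.2),
                           shape=(h, w))
        mask[rr, cc] = True


def _soil_background(shape, rng):
    """Brown soil: smooth mottling + grain + a few bright stones."""
    h, w = shape
    img = np.empty((h, w, 3))
    mottle = ndi.gaussian_filter(rng.normal(0, 1, (h, w)), 18)
    mottle = mottle / (mottle.std() + 1e-9)
    for k in range(3):
        img[:, :, k] = SOIL_BASE[k] + 9.0 * mottle
    stones = np.zeros((h, w), bool)
    for _ in range(rng.poisson(h * w / 3.5e5)):
        c = rng.uniform([0, 0], [w, h])
        _paint_blob(stones, c, (rng.uniform(4, 10), rng.uniform(3, 7)),
                    rng.uniform(0, np.pi), rng)
    img[stones] = np.array([185.0, 168.0, 148.0]) + rng.normal(0, 5, 3)
    return img, stones


def generate_scene(spec: SceneSpec):
    """Render one scene; returns (rgb_uint8, SceneTruth).

    Deterministic for a given spec (same spec + seed gives identical
    bytes).  If ``spec.perspective`` is set, the returned image is the
    oblique view and the truth keeps the flat-frame geometry plus the
    homography needed to undo it.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.canvas_shape()
    res = spec.resolution_mm
    theta = ((spec.row_angle_deg + 90.0) % 180.0) - 90.0  # wrap to [-90, 90)
    t = np.deg2rad(theta)
    normal = np.array([np.cos(t), np.sin(t)])
    along = np.array([-np.sin(t), np.cos(t)])
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])

    spacing_px = spec.row_spacing_mm / res
    rho_c = center @ normal
    offsets = (np.arange(spec.n_rows) - (spec.n_rows - 1) / 2.0) * spacing_px
    rho_rows = rho_c + offsets

    img, _ = _soil_background((h, w), rng)
    label = np.zeros((h, w), np.int32)

    # plants: Poisson along each row at the emerged linear density
    lam_per_mm = spec.sowing_density_seeds_m2 * spec.emergence_rate \
        * spec.row_spacing_mm / 1e6
    seg_px = spec.segment_length_mm / res
    plant_id = 0
    plant_row: dict[int, int] = {}
    plant_colors: dict[int, np.ndarray] = {}
    for i, rho in enumerate(rho_rows):
        row_center = center + (rho - rho_c) * normal
        n_i = rng.poisson(lam_per_mm * spec.segment_length_mm)
        ts_along = rng.uniform(-seg_px / 2.0, seg_px / 2.0, n_i)
        for t_along in np.sort(ts_along):
            plant_id += 1
            base = row_center + t_along * along \
                + normal * rng.normal(0.0, 2.0 / res)
            n_leaves = 2 if rng.uniform() < P_TWO_LEAVES else 1
            up = -normal if normal[1] > 0 else normal  # image-up leaf habit
            for _ in range(n_leaves):
                ang = np.deg2rad(
                    rng.choice([-1, 1])
                    * abs(rng.normal(LEAF_ANGLE_MEAN_DEG, LEAF_ANGLE_SD_DEG))
                )
                ca, sa = np.cos(ang), np.sin(ang)
                d = np.array([up[0] * ca - up[1] * sa,
                              up[0] * sa + up[1] * ca])
                length = rng.uniform(*LEAF_LENGTH_MM) / res
                width = rng.uniform(*LEAF_WIDTH_MM) / res
                _stroke_leaf(label, plant_id, base, d, length, width, rng)
            plant_row[plant_id] = i
            bright = rng.normal(0.0, 13.0)
            tint = rng.normal(0.0, 4.0, 3)
            color = GREEN_BASE + bright + tint
            if spec.hard_mode:
                color = 0.75 * color + 0.25 * SOIL_BASE
            plant_colors[plant_id] = np.clip(color, 0, 255)

    # distractors sized to the target null-object fraction
    expected_plants = lam_per_mm * spec.segment_length_mm * spec.n_rows
    p_isolated = np.exp(-lam_per_mm * PLANT_FOOTPRINT_MM)
    expected_objects = max(expected_plants * p_isolated, 1.0)
    rate = spec.null_object_rate
    n_distr = rng.poisson(expected_objects * rate / (1.0 - rate)) if rate > 0 else 0
    distractors = np.zeros((h, w), bool)
    for _ in range(n_distr):
        c = rng.uniform([3, 3], [w - 3, h - 3])
        axes = (rng.uniform(2.5, 6.0) / res * 0.5, rng.uniform(2.0, 4.5) / res * 0.5)
        _paint_blob(distractors, c, (max(axes), min(axes)),
                    rng.uniform(0, np.pi), rng)
    distractors &= label == 0   # never erase plant pixels

    # compose (plant colors via a lookup table, one pass over the raster)
    present = np.unique(label)
    present = present[present > 0]
    if len(present):
        lut = np.zeros((int(label.max()) + 1, 3))
        for pid in present:
            lut[pid] = plant_colors[int(pid)]
        sel = label > 0
        img[sel] = lut[label[sel]]
    dr = np.nonzero(distractors)
    if len(dr[0]):
        img[dr] = DISTRACTOR_BASE + rng.normal(0, 5, (len(dr[0]), 3))
    img += rng.normal(0.0, 4.0, img.shape)
    rgb = np.clip(img, 0, 255).astype(np.uint8)

    area_m2 = spec.n_rows * spec.row_spacing_mm * spec.segment_length_mm / 1e6
    truth = SceneTruth(
        label=label,
        distractor_mask=distractors,
        n_plants=len(present),
        plant_row={int(p): plant_row[int(p)] for p in present},
        theta_row=theta,
        rho_rows_px=rho_rows,
        row_spacing_px=spacing_px,
        resolution_mm=res,
        area_m2=area_m2,
        spec=spec,
        perspective=spec.perspective,
    )
    if spec.perspective is not None:
        rgb, truth = _apply_perspective(rgb, truth, spec.perspective)
    return rgb, truth


def _apply_perspective(rgb, truth: SceneTruth, H: Homography):
    """Warp the flat scene to an oblique camera view.

    ``H`` maps oblique image pixels to ground millimetres (the same
    object the calibration stage estimates); the flat canvas lives on
    the ground plane at the scene resolution.
    """
    res = truth.resolution_mm
    ground_to_flatpx = np.diag([1.0 / res, 1.0 / res, 1.0])
    M = ground_to_flatpx @ H.matrix     # image px -> flat canvas px
    h, w = truth.label.shape
    # choose an output frame covering the flat canvas
    inv = np.linalg.inv(M)
    corners = np.array([[0, 0, 1], [w - 1, 0, 1], [w - 1, h - 1, 1],
                        [0, h - 1, 1]], float) @ inv.T
    corners = corners[:, :2] / corners[:, 2:3]
    lo = np.floor(corners.min(axis=0)).astype(int)
    hi = np.ceil(corners.max(axis=0)).astype(int)
    out_w, out_h = hi - lo + 1
    if out_w < 2 or out_h < 2 or out_w * out_h > 4e7:
        raise GeometryError("perspective places the scene outside a usable frame")
    shift = np.array([[1, 0, lo[0]], [0, 1, lo[1]], [0, 0, 1]], float)
    tform = ProjectiveTransform(M @ shift)
    rgb_w = warp(rgb.astype(float), tform, output_shape=(out_h, out_w),
                 order=1, cval=0, preserve_range=True)
    lab_w = warp(truth.label.astype(float), tform, output_shape=(out_h, out_w),
                 order=0, cval=0, preserve_range=True).astype(np.int32)
    # the calibration usable by the pipeline absorbs the frame shift
    H_shifted = Homography(H.matrix @ shift)
    truth = replace(truth, perspective=H_shifted)
    truth.oblique_label = lab_w
    return np.clip(rgb_w, 0, 255).astype(np.uint8), truth


def generate_chessboard(
    square_size_mm: float,
    pattern_rows: int,
    pattern_cols: int,
    camera: Homography | None = None,
    image_shape: tuple[int, int] = (600, 800),
    noise_sd: float = 0.0,
    seed: int = 0,
    supersample: int = 3,
):
    """Render a chessboard seen through ``camera`` (ground mm -> image px).

    Returns ``(rgb_uint8, CornerGrid)`` where the grid holds the *true*
    image-pixel coordinates of the interior corners, row-major.

    Raises
    ------
    GeometryError
        If the board maps outside the frame or collapses.
    """
    rng = np.random.default_rng(seed)
    if camera is None:
        camera = Homography(np.eye(3), src_frame="ground mm",
                            dst_frame="image pixels")
    n_sq_r, n_sq_c = pattern_rows + 1, pattern_cols + 1
    board_w = n_sq_c * square_size_mm
    board_h = n_sq_r * square_size_mm

    jj, ii = np.meshgrid(np.arange(1, pattern_cols + 1),
                         np.arange(1, pattern_rows + 1))
    lattice_mm = np.column_stack([jj.ravel(), ii.ravel()]) * square_size_mm
    corners_px = camera.apply(lattice_mm)
    h, w = image_shape
    if (corners_px.min() < 5 or corners_px[:, 0].max() > w - 5
            or corners_px[:, 1].max() > h - 5):
        raise GeometryError("chessboard corners fall outside the frame")
    spread = corners_px.std(axis=0)
    if min(spread) < pattern_rows:  # collapsed below ~1 px per corner
        raise GeometryError("camera homography collapses the board")

    s = supersample
    yy, xx = np.mgrid[0:h * s, 0:w * s]
    # sample sub-pixel centres so pixel (0,0) is centred on coordinate 0
    pts = np.column_stack([(xx.ravel() + 0.5) / s - 0.5,
                           (yy.ravel() + 0.5) / s - 0.5])
    g = camera.inverse().apply(pts)
    inside = (g[:, 0] >= 0) & (g[:, 0] < board_w) & \
             (g[:, 1] >= 0) & (g[:, 1] < board_h)
    parity = (np.floor(g[:, 0] / square_size_mm)
              + np.floor(g[:, 1] / square_size_mm)) % 2
    vals = np.full(len(pts), 128.0)
    vals[inside] = np.where(parity[inside] == 0, 235.0, 25.0)
    img = vals.reshape(h * s, w * s)
    img = img.reshape(h, s, w, s).mean(axis=(1, 3))
    if noise_sd > 0:
        img = img + rng.normal(0, noise_sd, img.shape)
    rgb = np.clip(img, 0, 255).astype(np.uint8)[..., None].repeat(3, axis=2)
    grid = CornerGrid(corners_px, (pattern_rows, pattern_cols), square_size_mm)
    return rgb, grid


def batch_specs(
    densities, seeds, angle_jitter_deg: float = 1.5, **overrides
) -> list[SceneSpec]:
    """One SceneSpec per (density, seed) pair, cycling densities.

    Row orientation is jittered around horizontal (theta_row = 90) by a
    normal deviation of ``angle_jitter_deg``, mirroring the small camera
    misalignment seen in the field.
    """
    densities = list(densities)
    specs = []
    for k, seed in enumerate(seeds):
        rng = np.random.default_rng(int(seed) + 987_654)
        angle = 90.0 + rng.normal(0.0, angle_jitter_deg)
        specs.append(
            SceneSpec(
                sowing_density_seeds_m2=float(densities[k % len(densities)]),
                row_angle_deg=angle,
                seed=int(seed),
                **overrides,
            )
        )
    return specs


def generate_training_set(specs, config=None):
    """Run scenes through the pipeline and label objects with true counts.

    For each scene the image is segmented, rotated and split into
    objects exactly as in production; each rendered plant is then
    assigned to the object holding the majority of its pixels, so the
    object table carries exact plants-per-object labels (distractor-only
    objects get 0).  Returns ``(table, scene_records)`` where the table
    is the standard feature-table format and each scene record carries
    the truth density and any lost plants.
    """
    from .pipeline import PipelineConfig, process_image

    if config is None:
        config = PipelineConfig()
    frames = []
    records = []
    for k, spec in enumerate(specs):
        rgb, truth = generate_scene(spec)
        aux = truth.label if spec.perspective is None else truth.oblique_label
        calib = truth.perspective
        res = process_image(
            rgb, config, calib=calib, aux_label=aux,
            resolution_mm=spec.resolution_mm,
        )
        counts, lost = match_counts(res.aux_label, res.object_labels)
        for obj in res.objects:
            obj.true_count = counts.get(obj.object_id, 0)
        from .objects import objects_to_frame

        image_id = f"scene{k:03d}_seed{spec.seed}"
        frames.append(objects_to_frame(res.objects, image_id=image_id,
                                       resolution_mm=res.resolution_mm))
        records.append(
            {
                "image_id": image_id,
                "seed": spec.seed,
                "sowing_density": spec.sowing_density_seeds_m2,
                "n_plants": truth.n_plants,
                "density_true": truth.density_true,
                "area_m2": truth.area_m2,
                "n_lost_plants": lost,
                "result": res,
                "truth": truth,
            }
        )
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return table, records


def match_counts(plant_label: np.ndarray, object_label: np.ndarray):
    """Assign each plant to the object holding most of its pixels.

    Returns ``(counts, n_lost)``: a dict object id -> plant count, and
    the number of plants whose pixels hit no object at all.
    """
    sel = plant_label > 0
    pids = plant_label[sel].astype(np.int64)
    oids = object_label[sel].astype(np.int64)
    if len(pids) == 0:
        return {}, 0
    n_obj = int(object_label.max()) + 1
    key = pids * n_obj + oids
    uniq, cnt = np.unique(key, return_counts=True)
    pair_p = uniq // n_obj
    pair_o = uniq % n_obj
    best: dict[int, tuple[int, int]] = {}
    for p, o, c in zip(pair_p, pair_o, cnt):
        if o == 0:
            continue
        if p not in best or c > best[p][1]:
            best[int(p)] = (int(o), int(c))
    counts: dict[int, int] = {}
    for p, (o, _) in best.items():
        counts[o] = counts.get(o, 0) + 1
    n_lost = len(np.unique(pair_p)) - len(best)
    return counts, n_lost
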