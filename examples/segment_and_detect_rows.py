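"""Segment a synthetic wheat scene and detect its crop rows.

Renders a ground-truthed scene, classifies green pixels on the CIELab
a* channel with Otsu thresholding, then finds the row orientation and
positions with the edge-point Hough transform.
"""

import numpy as np

from wheatdensity import SceneSpec, generate_scene, segment_green
from wheatdensity.rows import edge_points, locate_rows

spec = SceneSpec(sowing_density_seeds_m2=300.0, row_angle_deg=88.5, seed=3)
rgb, truth = generate_scene(spec)
print(f"scene: {rgb.shape[1]}x{rgb.shape[0]} px at "
      f"{truth.resolution_mm} mm/px, {truth.n_plants} plants rendered")

mask = segment_green(rgb)
plant = truth.label > 0
f1 = 2 * np.sum(mask & plant) / (mask.sum() + plant.sum())
print(f"vegetation mask: {mask.sum()} px, pixelwise F1 vs truth = {f1:.3f}")

pts = edge_points(mask)
model = locate_rows(pts[:: max(1, len(pts) // 25000)],
                    min_separation_px=0.6 * truth.row_spacing_px)
print(f"theta_row = {model.theta_row:.1f} deg (true {truth.theta_row:.1f}; "
      "+/-90 deg means horizontal rows)")
print(f"{model.n_rows} rows at rho = {np.round(model.rho_rows, 1)} px "
      f"(true {np.round(np.sort(truth.rho_rows_px), 1)})")
print("detected spacing:", round(model.row_spacing_px, 1), "px; sown at",
      truth.row_spacing_px, "px")
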