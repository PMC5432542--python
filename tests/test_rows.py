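"""Hough row detection: voting, orientation, peaks, rotation, assignment."""

import numpy as np
import pytest

from wheatdensity.errors import (
    NoRowsError,
    OrientationUndetectableError,
    RangeError,
)
from wheatdensity.rows import (
    RowModel,
    assign_objects_to_rows,
    default_theta_axis,
    edge_points,
    hough_accumulate,
    locate_rows,
    rotate_rows_horizontal,
    rotation_to_horizontal,
    row_orientation,
    row_positions,
)


def _line_points(theta_deg, rho, n=200, span=400.0, jitter=0.0, rng=None):
    """n points on the line x cos(t) + y sin(t) = rho, centred at origin."""
    t = np.deg2rad(theta_deg)
    normal = np.array([np.cos(t), np.sin(t)])
    along = np.array([-np.sin(t), np.cos(t)])
    s = np.linspace(-span / 2, span / 2, n)
    pts = rho * normal + s[:, None] * along
    if jitter and rng is not None:
        pts = pts + rng.normal(0, jitter, pts.shape)
    return pts


class TestEdgePoints:
    def test_solid_square_perimeter(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        assert len(edge_points(mask)) == 36

    def test_single_pixel_is_its_own_boundary(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 3] = True
        np.testing.assert_array_equal(edge_points(mask), [[3, 2]])

    def test_empty_mask_gives_empty_list(self):
        assert len(edge_points(np.zeros((5, 5), bool))) == 0

    def test_matches_neighbourhood_definition(self, rng):
        # oracle: foreground pixel with >= 1 background 8-neighbour
        # (image border counts as background), checked by direct loops
        mask = rng.uniform(size=(25, 25)) < 0.4
        got = {tuple(p) for p in edge_points(mask).astype(int)}
        want = set()
        h, w = mask.shape
        for r in range(h):
            for c in range(w):
                if not mask[r, c]:
                    continue
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                            want.add((c, r))
        assert got == want


class TestHoughAccumulate:
    def test_single_point_votes_once_per_theta(self):
        acc = hough_accumulate(np.array([[10.0, 20.0]]))
        nonzero_per_col = (acc.counts > 0).sum(axis=1)
        np.testing.assert_array_equal(nonzero_per_col, 1)
        assert acc.counts.max() == 1

    def test_horizontal_line_concentrates_at_90deg(self):
        # y = 5: at theta = -90 every point votes rho = -5 (the +90
        # column is the same line with rho negated; the axis is [-90, 90))
        pts = np.column_stack([np.arange(100.0), np.full(100, 5.0)])
        acc = hough_accumulate(pts)
        col = acc.counts[acc.theta_index(-90.0)]
        assert col[int(-5 - acc.rho_px[0])] == 100
        assert (col > 0).sum() == 1

    def test_column_sums_conserved(self, rng):
        pts = rng.uniform(-500, 500, (137, 2))
        acc = hough_accumulate(pts)
        np.testing.assert_array_equal(acc.counts.sum(axis=1), 137)

    def test_matches_bruteforce_double_loop(self, rng):
        pts = rng.uniform(-100, 100, (20, 2))
        acc = hough_accumulate(pts)
        want = np.zeros_like(acc.counts)
        for x, y in pts:
            for i, th in enumerate(acc.theta_deg):
                t = np.deg2rad(th)
                rho = x * np.cos(t) + y * np.sin(t)
                want[i, int(np.rint(rho - acc.rho_px[0]))] += 1
        np.testing.assert_array_equal(acc.counts, want)

    def test_out_of_range_point_raises(self):
        with pytest.raises(RangeError):
            hough_accumulate(np.array([[4000.0, 0.0]]))


class TestRowOrientation:
    def test_three_horizontal_point_rows(self):
        pts = np.vstack([_line_points(-90, r, n=80) for r in (0, -50, -100)])
        acc = hough_accumulate(pts)
        assert abs(row_orientation(acc)) == 90.0

    def test_exact_bin_recovery_at_minus_88_2(self, rng):
        pts = np.vstack([_line_points(-88.2, r, n=150, jitter=0.3, rng=rng)
                         for r in (-200, 0, 200)])
        acc = hough_accumulate(pts)
        assert row_orientation(acc) == pytest.approx(-88.2, abs=1e-9)

    @pytest.mark.parametrize("theta", [-89.0, -45.0, 0.0, 45.0, 89.0])
    def test_recovery_across_angle_grid(self, theta, rng):
        pts = np.vstack([_line_points(theta, r, n=150, jitter=0.3, rng=rng)
                         for r in (-300, 0, 300)])
        acc = hough_accumulate(pts)
        assert row_orientation(acc) == pytest.approx(theta, abs=0.1)

    def test_single_point_raises(self):
        acc = hough_accumulate(np.array([[1.0, 2.0]]))
        with pytest.raises(OrientationUndetectableError):
            row_orientation(acc)

    def test_isotropic_cloud_has_no_strong_maximum(self, rng):
        pts = rng.uniform(-400, 400, (2000, 2))
        acc = hough_accumulate(pts)
        var = acc.counts.var(axis=1)
        # no orientation may dominate: spread of the criterion stays small
        assert var.max() < 1.3 * np.median(var)


class TestRowPositions:
    def test_five_rows_recovered_at_offsets(self):
        offsets = [-700.0, -350.0, 0.0, 350.0, 700.0]
        pts = np.vstack([_line_points(-90, r, n=300, span=900) for r in offsets])
        acc = hough_accumulate(pts)
        theta = row_orientation(acc)
        rho = row_positions(acc, theta, min_separation_px=210)
        assert len(rho) == 5
        np.testing.assert_allclose(np.sort(rho), sorted(offsets), atol=2)

    def test_single_row(self):
        pts = _line_points(-90, -42.0, n=200)
        acc = hough_accumulate(pts)
        rho = row_positions(acc, -90.0, min_separation_px=100)
        assert len(rho) == 1
        assert rho[0] == pytest.approx(-42, abs=2)

    def test_close_rows_merge_under_min_separation(self):
        pts = np.vstack([_line_points(-90, r, n=200) for r in (0.0, -30.0)])
        acc = hough_accumulate(pts)
        rho = row_positions(acc, -90.0, min_separation_px=100)
        assert len(rho) == 1

    def test_no_peak_raises(self):
        acc = hough_accumulate(np.array([[1.0, 2.0]]))
        acc.counts[:] = 0
        with pytest.raises(NoRowsError):
            row_positions(acc, 0.0, min_separation_px=10)


class TestRotation:
    def test_theta_90_is_identity(self):
        mask = np.zeros((20, 30), bool)
        mask[4:9, 2:25] = True
        out = rotate_rows_horizontal(mask, 90.0, is_mask=True)
        np.testing.assert_array_equal(out, mask)

    def test_rotation_angle_convention(self):
        assert rotation_to_horizontal(90.0) == 0.0
        assert rotation_to_horizontal(-88.2) == pytest.approx(-1.8)
        assert rotation_to_horizontal(0.0) == 90.0
        assert rotation_to_horizontal(-90.0) == 0.0

    @pytest.mark.parametrize("theta", [-88.2, -45.0, 30.0])
    def test_rows_become_horizontal(self, theta):
        h = w = 401
        mask = np.zeros((h, w), bool)
        t = np.deg2rad(theta)
        yy, xx = np.mgrid[0:h, 0:w]
        rho = xx * np.cos(t) + yy * np.sin(t)
        c = 200 * (np.cos(t) + np.sin(t))
        for off in (-80, 0, 80):
            mask |= np.abs(rho - (c + off)) < 2
        rot = rotate_rows_horizontal(mask, theta, is_mask=True)
        acc = hough_accumulate(edge_points(rot)[::3] - [200, 200])
        assert abs(row_orientation(acc)) == pytest.approx(90.0, abs=0.2)

    def test_double_rotation_roundtrip_preserves_foreground(self):
        mask = np.zeros((200, 200), bool)
        mask[60:140, 40:160] = True
        alpha = 7.0
        once = rotate_rows_horizontal(mask, 90.0 - alpha, is_mask=True)
        back = rotate_rows_horizontal(once, 90.0 + alpha, is_mask=True)
        assert abs(int(back.sum()) - int(mask.sum())) < 0.01 * mask.sum()


class TestAssignment:
    MODEL = RowModel(90.0, np.array([100.0, 200.0, 300.0]))

    def test_centred_object_distance_zero(self):
        idx, d = assign_objects_to_rows(np.array([[50.0, 200.0]]), self.MODEL)
        assert idx[0] == 1 and d[0] == 0.0

    def test_equidistant_tie_goes_to_lower_index(self):
        idx, _ = assign_objects_to_rows(np.array([[10.0, 150.0]]), self.MODEL)
        assert idx[0] == 0

    def test_empty_row_model_raises(self):
        with pytest.raises(NoRowsError):
            assign_objects_to_rows(np.array([[0.0, 0.0]]),
                                   RowModel(90.0, np.array([])))

    def test_scene_objects_assigned_to_generating_row(self, processed300):
        res = processed300["result"]
        truth = processed300["truth"]
        assert res.row_model.n_rows == truth.spec.n_rows
        # objects holding plants must sit on a detected row line well
        # within half the row spacing
        for obj in res.objects:
            if obj.true_count and obj.true_count > 0:
                assert obj.row_distance_px < truth.row_spacing_px / 2


class TestLocateRows:
    def test_recentring_handles_large_frames(self):
        # content far from the origin would overflow the rho axis without
        # the internal recentring
        pts = np.vstack([_line_points(-90, r, n=200, span=800)
                         for r in (4000.0, 4350.0)]) + [2500.0, 0.0]
        model = locate_rows(pts, min_separation_px=210)
        assert model.n_rows == 2
        np.testing.assert_allclose(np.sort(model.rho_rows), [4000, 4350],
                                   atol=2)

    def test_axis_definition(self):
        ax = default_theta_axis()
        assert len(ax) == 1800
        assert ax[0] == -90.0
        assert ax[-1] == pytest.approx(89.9)
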