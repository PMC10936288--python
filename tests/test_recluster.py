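"""Corner points, tubular orientation, collinear merging, plausibility."""

import numpy as np
import pytest

from pennatrack import (
    Cluster,
    MergeParams,
    PixelSet,
    cluster_angle,
    connection_angle,
    corner_points,
    merge_pass,
    plausibility_filter,
)
from pennatrack.synthetic import strip_coverage


def cluster_from_coords(coords, intensity=200, cid=0):
    coords = np.asarray(list(coords), dtype=np.int64)
    inten = np.full(len(coords), intensity, dtype=np.int64)
    return Cluster(cid, PixelSet(coords[:, 0], coords[:, 1], inten))


def aa_strip_cluster(angle_deg, length, thickness, center=(100.0, 100.0), cid=0,
                     shape=(200, 220)):
    """Cluster from an anti-aliased strip raster (intensity-carrying pixels)."""
    cov = strip_coverage(shape, center, angle_deg, length, thickness)
    inten = np.round(cov * 200).astype(np.int64)
    rows, cols = np.nonzero(inten > 0)
    return Cluster(cid, PixelSet(cols, rows, inten[rows, cols]))


class TestCornerPoints:
    def test_single_pixel_all_corners_equal(self):
        c = cluster_from_coords([(4, 9)])
        assert set(corner_points(c).values()) == {(4, 9)}

    def test_axis_aligned_rectangle(self):
        coords = [(cc, rr) for rr in range(3) for cc in range(5)]
        corners = corner_points(cluster_from_coords(coords))
        assert corners == {"LU": (0, 0), "RD": (4, 2), "RU": (4, 0), "LD": (0, 2)}

    def test_rotated_rectangle_corners_near_vertices(self):
        th = np.deg2rad(20.0)
        L, T, ctr = 60.0, 5.0, np.array([100.0, 100.0])  # (col, row) center
        u = np.array([np.cos(th), -np.sin(th)])
        v = np.array([np.sin(th), np.cos(th)])
        cols, rows = np.meshgrid(np.arange(200), np.arange(200))
        P = np.stack([cols.ravel(), rows.ravel()], 1) - ctr
        mask = (np.abs(P @ u) <= L / 2) & (np.abs(P @ v) <= T / 2)
        c = cluster_from_coords(np.stack([cols.ravel()[mask], rows.ravel()[mask]], 1))
        corners = corner_points(c)
        verts = [ctr + su * (L / 2) * u + sv * (T / 2) * v for su in (-1, 1) for sv in (-1, 1)]
        for name in ("LU", "LD", "RU", "RD"):
            d = min(np.hypot(*(np.array(corners[name]) - vt)) for vt in verts)
            assert d <= 1.5

    def test_corners_are_members(self):
        rng = np.random.default_rng(0)
        coords = np.unique(rng.integers(0, 40, (60, 2)), axis=0)
        c = cluster_from_coords(coords)
        members = set(map(tuple, coords))
        assert set(corner_points(c).values()) <= members


class TestClusterAngle:
    def test_horizontal_strip_zero(self):
        oc = cluster_angle(cluster_from_coords([(i, 5) for i in range(20)]))
        assert oc.alpha1_deg == pytest.approx(0.0)
        assert oc.alpha2_deg == pytest.approx(0.0)
        assert oc.cluster_angle_deg == pytest.approx(0.0)

    def test_descending_strip_sign_convention(self):
        # 3-px-thick strip along the ideal line row = 0.3*col, length ~60
        coords = []
        for cc in range(60):
            r0 = 0.3 * cc
            coords += [(cc, int(round(r0 + k))) for k in (0, 1, 2)]
        oc = cluster_angle(cluster_from_coords(set(coords)))
        assert oc.cluster_angle_deg == pytest.approx(-16.699, abs=0.5)

    def test_perfect_diagonal_45(self):
        oc = cluster_angle(cluster_from_coords([(i, 10 - i) for i in range(11)]))
        assert oc.cluster_angle_deg == pytest.approx(45.0)

    def test_mean_of_diagonal_angles_identity(self):
        oc = cluster_angle(aa_strip_cluster(17.5, 60, 4))
        assert oc.cluster_angle_deg == pytest.approx(
            0.5 * (oc.alpha1_deg + oc.alpha2_deg)
        )
        assert abs(oc.cluster_angle_deg) <= 90

    @pytest.mark.parametrize("angle", np.arange(0.0, 30.01, 2.5))
    def test_rotated_rectangle_recovery_half_degree(self, angle):
        for L, T in [(40, 6), (60, 4), (80, 3)]:
            oc = cluster_angle(aa_strip_cluster(angle, L, T, center=(100.3, 100.7)))
            assert oc.cluster_angle_deg == pytest.approx(angle, abs=0.5)

    def test_degenerate_single_pixel(self):
        oc = cluster_angle(cluster_from_coords([(3, 3)]))
        assert oc.degenerate and oc.cluster_angle_deg == 0.0


class TestConnectionAngle:
    def test_collinear_segments_45(self):
        left = cluster_angle(cluster_from_coords([(i, 30 - i) for i in range(10)], cid=0))
        right = cluster_angle(cluster_from_coords([(i, 30 - i) for i in range(12, 22)], cid=1))
        beta = connection_angle(left, right)
        assert beta == pytest.approx(45.0)
        assert left.cluster_angle_deg == pytest.approx(45.0)

    def test_direct_arctangent(self):
        left = cluster_angle(cluster_from_coords([(c, 10) for c in range(5, 11)], cid=0))
        right = cluster_angle(cluster_from_coords([(c, 5) for c in range(20, 26)], cid=1))
        assert connection_angle(left, right) == pytest.approx(
            np.degrees(np.arctan2(5, 10)), abs=1e-9
        )

    def test_overlapping_clusters_not_candidates(self):
        a = cluster_angle(cluster_from_coords([(c, 5) for c in range(10)], cid=0))
        b = cluster_angle(cluster_from_coords([(c, 8) for c in range(5, 15)], cid=1))
        assert connection_angle(a, b) is None


class TestMergePass:
    params = MergeParams(angle_tol_deg=5.0, connect_tol_deg=5.0, max_gap_px=20.0)

    def collinear_fragments(self, angle, n, gap=8.0, length=90.0):
        frag = (length - (n - 1) * gap) / n
        th = np.deg2rad(angle)
        u = np.array([np.cos(th), -np.sin(th)])
        out = []
        for i in range(n):
            off = (i - (n - 1) / 2) * (frag + gap)
            ctr = (100.0 + off * u[1], 100.0 + off * u[0])
            out.append(cluster_angle(aa_strip_cluster(angle, frag, 4, center=ctr, cid=i)))
        return out

    def test_single_cluster_fixpoint(self):
        ocs = [cluster_angle(aa_strip_cluster(12.0, 50, 4))]
        assert merge_pass(ocs, self.params) == ocs

    def test_collinear_12deg_segments_merge(self):
        merged = merge_pass(self.collinear_fragments(12.0, 2), self.params)
        assert len(merged) == 1
        assert merged[0].cluster_angle_deg == pytest.approx(12.0, abs=1.0)

    def test_angle_mismatch_blocks_merge(self):
        a = cluster_angle(aa_strip_cluster(10.0, 40, 4, center=(120.0, 70.0), cid=0))
        b = cluster_angle(aa_strip_cluster(40.0, 40, 4, center=(100.0, 130.0), cid=1))
        assert len(merge_pass([a, b], self.params)) == 2

    @pytest.mark.parametrize("angle", [5.0, 12.5, 20.0, 30.0])
    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_fragment_recovery_sweep(self, angle, n):
        merged = merge_pass(self.collinear_fragments(angle, n), self.params)
        assert len(merged) == 1
        assert merged[0].cluster_angle_deg == pytest.approx(angle, abs=1.0)

    def test_idempotent_and_conserves_pixels(self):
        frags = self.collinear_fragments(15.0, 3)
        total = sum(len(oc) for oc in frags)
        once = merge_pass(frags, self.params)
        assert sum(len(oc) for oc in once) == total
        twice = merge_pass(once, self.params)
        assert [len(oc) for oc in twice] == [len(oc) for oc in once]
        assert [oc.cluster_angle_deg for oc in twice] == [
            oc.cluster_angle_deg for oc in once
        ]


class TestPlausibility:
    def oc(self, p_left_row, p_right_row, cid=0):
        coords = [(0, p_left_row), (50, p_right_row)]
        mid = [(c, int(round(p_left_row + (p_right_row - p_left_row) * c / 50)))
               for c in range(1, 50)]
        return cluster_angle(cluster_from_coords(coords + mid, cid=cid))

    def test_mirrored_orientation_left_higher_kept(self):
        # under the mirrored probe orientation the left endpoint is shallower
        kept = plausibility_filter([self.oc(5, 20)], "top", fascicle_rises_right=False)
        assert len(kept) == 1

    def test_mirrored_orientation_opposite_slope_discarded(self):
        kept = plausibility_filter([self.oc(20, 5)], "top", fascicle_rises_right=False)
        assert kept == []

    def test_default_keeps_rising_right(self):
        assert len(plausibility_filter([self.oc(20, 5)], "top")) == 1
        assert plausibility_filter([self.oc(5, 20)], "top") == []

    def test_bottom_roi_angle_bound(self):
        steep = cluster_angle(
            cluster_from_coords([(i, 50 - i) for i in range(30)], cid=0)
        )  # 45 degrees
        flat = cluster_angle(cluster_from_coords([(i, 10) for i in range(30)], cid=1))
        kept = plausibility_filter([steep, flat], "bottom", apo_max_abs_deg=15.0)
        assert kept == [flat]
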