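"""Tests for clustering, principal-axis alignment and outlier removal."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import silhouette_score

import flowrosetta as fr
from flowrosetta.generator import LabeledEvents
from flowrosetta.preprocessing import (
    ClusterTransform,
    DirectionUndefinedError,
    RosettaConfig,
    apply_inverse,
    axis_to_rotation,
    find_optimal_clusters,
    outlier_window,
    principal_angle,
    remove_outliers,
    rotate_to_axis,
    silhouette_coefficient,
)


class TestSilhouette:
    def test_matches_sklearn_oracle(self, rng):
        pts = np.vstack([rng.normal(0, 1, (300, 2)), rng.normal((4, 0), 1, (200, 2)),
                         rng.normal((0, 5), 1.5, (150, 2))])
        labels = np.r_[np.zeros(300, int), np.ones(200, int), np.full(150, 2)]
        ours = silhouette_coefficient(pts, labels)
        theirs = silhouette_score(pts, labels)
        assert ours == pytest.approx(theirs, abs=1e-9)

    def test_well_separated_blobs_score_high(self, rng):
        pts = np.vstack([rng.normal(0, 1, (1000, 2)), rng.normal((50, 0), 1, (1000, 2))])
        ev = LabeledEvents(pts, np.r_[np.zeros(1000, int), np.ones(1000, int)])
        labels, k, sil = find_optimal_clusters(ev, RosettaConfig(max_clusters=4), seed=0)
        assert k == 2
        assert sil > 0.95

    def test_benchmark_selects_two_clusters(self, benchmark_analysis):
        assert benchmark_analysis.n_clusters == 2
        assert benchmark_analysis.silhouette == pytest.approx(0.83, abs=0.02)

    def test_use_cluster_id_passthrough(self, rng):
        pts = rng.normal(0, 1, (400, 2))
        labels = rng.integers(0, 2, 400)
        ev = LabeledEvents(pts, labels)
        out, k, sil = find_optimal_clusters(ev, RosettaConfig(use_cluster_id=True), seed=0)
        np.testing.assert_array_equal(out, labels)
        assert k == 2

    def test_reproducible_under_fixed_seed(self, benchmark_events):
        l1, k1, s1 = find_optimal_clusters(benchmark_events, RosettaConfig(), seed=42)
        l2, k2, s2 = find_optimal_clusters(benchmark_events, RosettaConfig(), seed=42)
        np.testing.assert_array_equal(l1, l2)
        assert (k1, s1) == (k2, s2)

    def test_too_few_events_raise(self):
        ev = LabeledEvents(np.zeros((3, 2)), np.full(3, -1))
        with pytest.raises(ValueError):
            find_optimal_clusters(ev, RosettaConfig(min_clusters=2), seed=0)


class TestPrincipalAngle:
    def test_exact_diagonal_line(self):
        t = np.linspace(-1, 1, 50)
        pts = np.column_stack([t, t])  # the (1,1) direction
        assert principal_angle(pts, outer_percent=0) == pytest.approx(45.0, abs=1e-9)

    def test_anisotropic_gaussian_at_30_degrees(self, rng):
        # major axis along the direction 30 deg clockwise from vertical
        th = np.radians(30.0)
        d = np.array([np.sin(th), np.cos(th)])
        d_perp = np.array([d[1], -d[0]])
        t = rng.normal(0, 400, 10_000)
        u = rng.normal(0, 100, 10_000)
        pts = np.outer(t, d) + np.outer(u, d_perp)
        assert principal_angle(pts) == pytest.approx(30.0, abs=1.0)

    def test_trimming_shields_against_outliers(self, rng):
        pts = rng.normal(0, 1, (5000, 2)) * [1, 5]
        clean = principal_angle(pts, outer_percent=2)
        spiked = np.vstack([pts, np.column_stack([np.full(50, 20.0), np.zeros(50)])])
        assert abs(principal_angle(spiked, outer_percent=2) - clean) < 0.5

    def test_isotropic_flagged(self):
        # points on a circle: exactly equal eigenvalues, no direction
        th = np.linspace(0, 2 * np.pi, 721)[:-1]
        pts = np.column_stack([np.cos(th), np.sin(th)])
        with pytest.raises(DirectionUndefinedError):
            principal_angle(pts, outer_percent=0)

    def test_axis_reporting_convention(self):
        assert axis_to_rotation(145.0) == 325.0
        assert axis_to_rotation(170.0) == 350.0
        assert axis_to_rotation(45.0) == 45.0
        assert axis_to_rotation(0.0) == 0.0


class TestRotateToAxis:
    def test_vertical_alignment_diagonalizes(self, rng):
        pts = rng.normal((5, -3), (2, 7), (20_000, 2)) @ np.array([[0.9, 0.3], [-0.3, 0.9]])
        rot, tr = rotate_to_axis(pts, "vertical")
        cov = np.cov(rot.T)
        assert abs(cov[0, 1]) / np.sqrt(cov[0, 0] * cov[1, 1]) < 0.02
        assert cov[1, 1] >= cov[0, 0]
        np.testing.assert_allclose(rot.mean(axis=0), 0, atol=1e-9)

    def test_horizontal_is_vertical_rotated_90(self, rng):
        pts = rng.normal(0, 1, (5000, 2)) * [1, 4]
        v, _ = rotate_to_axis(pts, "vertical")
        h, _ = rotate_to_axis(pts, "horizontal")
        # rotating the vertical alignment clockwise by 90 gives the horizontal
        np.testing.assert_allclose(h, v @ np.array([[0, 1], [-1, 0]]).T, atol=1e-9)

    def test_round_trip_identity(self, rng):
        pts = rng.normal((100, 200), (3, 9), (1000, 2))
        rot, tr = rotate_to_axis(pts)
        back = apply_inverse(rot, tr)
        np.testing.assert_allclose(back, pts, atol=1e-9)

    def test_alignment_idempotent(self, rng):
        pts = rng.normal(0, 1, (10_000, 2)) * [1, 5]
        rot, _ = rotate_to_axis(pts)
        _, tr2 = rotate_to_axis(rot)
        assert abs(tr2.rotation_deg) % 180 < 0.5 or abs(tr2.rotation_deg % 180 - 180) < 0.5


class TestRemoveOutliers:
    def test_single_far_point_removed(self, rng):
        pts = np.vstack([rng.normal(0, 1, (5000, 2)), [[6.5, 0.0]]])
        kept = remove_outliers(pts, 5.0, 5.0)
        assert len(kept) == 5000
        assert not np.any(np.all(kept == [6.5, 0.0], axis=1))

    def test_gaussian_tail_mass(self, rng):
        pts = rng.normal(0, 1, (100_000, 2))
        kept = remove_outliers(pts, 3.5, 3.5)
        removed_frac = 1 - len(kept) / len(pts)
        expected = 2 * 2 * (1 - stats.norm.cdf(3.5))  # both tails, both dims
        assert removed_frac < expected * 1.5
        assert removed_frac > expected / 1.5

    def test_infinite_thresholds_identity(self, rng):
        pts = rng.normal(0, 1, (500, 2))
        np.testing.assert_array_equal(remove_outliers(pts, np.inf, np.inf), pts)

    def test_never_increases_sd(self, rng):
        pts = rng.standard_t(3, (20_000, 2))
        kept = remove_outliers(pts, 3.0, 3.0)
        assert np.all(kept.std(axis=0) <= pts.std(axis=0))

    def test_window_matches_removal(self, rng):
        pts = rng.normal(0, 2, (2000, 2))
        (xlo, xhi), (ylo, yhi) = outlier_window(pts, 2.0, 3.0)
        kept = remove_outliers(pts, 2.0, 3.0)
        assert kept[:, 0].min() >= xlo and kept[:, 0].max() <= xhi
        assert kept[:, 1].min() >= ylo and kept[:, 1].max() <= yhi


class TestTransforms:
    def test_origin_maps_to_centroid(self):
        tr = ClusterTransform((10.0, -4.0), 37.0)
        np.testing.assert_allclose(apply_inverse(np.zeros((1, 2)), tr), [[10.0, -4.0]])

    def test_centroid_separation_preserved(self, rng):
        a = rng.normal((0, 0), (1, 3), (2000, 2))
        b = rng.normal((30, 10), (2, 5), (2000, 2))
        ra, ta = rotate_to_axis(a)
        rb, tb = rotate_to_axis(b)
        back_a = apply_inverse(ra, ta)
        back_b = apply_inverse(rb, tb)
        orig_sep = a.mean(0) - b.mean(0)
        new_sep = back_a.mean(0) - back_b.mean(0)
        np.testing.assert_allclose(new_sep, orig_sep, atol=1e-9)


class TestConfigValidation:
    def test_bad_ranges_rejected(self):
        with pytest.raises(ValueError):
            RosettaConfig(min_clusters=5, max_clusters=2)
        with pytest.raises(ValueError):
            RosettaConfig(min_clusters=1, use_cluster_id=False)
        with pytest.raises(ValueError):
            RosettaConfig(min_components_per_cluster=(2, 1),
                          max_components_per_cluster=(1, 1))
        with pytest.raises(ValueError):
            RosettaConfig(angle_method="diagonal")
        with pytest.raises(ValueError):
            RosettaConfig(threshold_x=-1.0)
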