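"""Colocalization counting and nearest-neighbor association statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from woundsight import (
    PunctaSet,
    build_rings,
    coloc_matrix,
    colocalize,
    nn_series,
    reference_events,
    wound_distance_density,
)

CENTER = (16.0, 16.0)


def _punctae(frame, positions, labels_image=None):
    return PunctaSet(frame=frame, table=pd.DataFrame({
        "label": range(1, len(positions) + 1),
        "x_um": [p[0] for p in positions],
        "y_um": [p[1] for p in positions],
        "area_um2": 0.5,
    }), labels_image=labels_image)


def _labeled(positions, shape=(64, 64), px=0.5, radius=1):
    """Binary disks rendered as a label image for mask-overlap tests."""
    img = np.zeros(shape, dtype=np.int32)
    for i, (x, y) in enumerate(positions, start=1):
        cx, cy = int(round(x / px)), int(round(y / px))
        img[max(cy - radius, 0):cy + radius + 1,
            max(cx - radius, 0):cx + radius + 1] = i
    return img


class TestColocalize:
    def test_identical_sets_fully_colocalized(self):
        pos = [(4.0, 4.0), (10.0, 12.0), (20.0, 8.0)]
        img = _labeled(pos)
        a = _punctae(0, pos, img)
        b = _punctae(0, pos, img.copy())
        assert len(colocalize(a, b, rule="mask_overlap")) == len(pos)
        assert len(colocalize(a, b, rule="centroid_distance", tol=0.5)) == len(pos)

    def test_disjoint_sets_share_nothing(self):
        a = _punctae(0, [(2.0, 2.0)], _labeled([(2.0, 2.0)]))
        b = _punctae(0, [(30.0, 30.0)], _labeled([(30.0, 30.0)]))
        assert len(colocalize(a, b, rule="mask_overlap")) == 0
        assert len(colocalize(a, b, rule="centroid_distance", tol=1.0)) == 0

    def test_each_puncta_counted_once(self):
        # two b-punctae overlapping one a-puncta still colocalize it once
        a = _punctae(0, [(10.0, 10.0)], _labeled([(10.0, 10.0)], radius=3))
        b_pos = [(9.5, 10.0), (10.5, 10.0)]
        b = _punctae(0, b_pos, _labeled(b_pos))
        assert len(colocalize(a, b, rule="mask_overlap")) == 1

    def test_centroid_rule_symmetric_for_matched_pairs(self):
        a_pos = [(5.0, 5.0), (15.0, 5.0), (25.0, 5.0)]
        b_pos = [(5.3, 5.0), (15.3, 5.0), (25.3, 5.0)]
        a, b = _punctae(0, a_pos), _punctae(0, b_pos)
        assert len(colocalize(a, b, "centroid_distance", tol=0.5)) == \
            len(colocalize(b, a, "centroid_distance", tol=0.5))

    def test_mismatched_frames_refused(self):
        with pytest.raises(ValueError):
            colocalize(_punctae(0, [(1, 1)]), _punctae(1, [(1, 1)]))

    def test_planted_overlap_fraction_recovered(self):
        """~30 of 100 a-punctae sit on b-punctae; count within binomial error."""
        rng = np.random.default_rng(5)
        counts = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a_pos = [(x, y) for x, y in rng.uniform(4, 60, (100, 2))]
            overlap_idx = rng.choice(100, 30, replace=False)
            b_pos = [a_pos[i] for i in overlap_idx]
            a, b = _punctae(0, a_pos), _punctae(0, b_pos)
            counts.append(len(colocalize(a, b, "centroid_distance", tol=0.3)))
        # chance proximity can only add counts; stay within ~3σ of 30
        assert 30 <= np.mean(counts) <= 30 + 3 * math.sqrt(30)


class TestColocMatrix:
    def test_empty_b_series_zero_matrix(self):
        rings = build_rings(CENTER, n_rings=2, diameter_increment=8.0)
        a = [_punctae(f, [(18.0, 16.0)]) for f in range(4)]
        b = [_punctae(f, []) for f in range(4)]
        cm = coloc_matrix(a, b, rings, wound_frame=2, rule="centroid_distance", tol=0.5)
        assert not cm.values.any()

    def test_same_normalization_contract_as_count_matrix(self):
        rings = build_rings(CENTER, n_rings=1, diameter_increment=8.0)
        pos = [(18.0, 16.0)]
        a = [_punctae(f, pos) for f in range(4)]
        b = [_punctae(f, pos) for f in range(4)]
        cm = coloc_matrix(a, b, rings, wound_frame=2, rule="centroid_distance", tol=0.5)
        assert np.allclose(cm.values[0], 1.0 / rings.ring_areas[0])


class TestReferenceEvents:
    def _series(self, cfg_positions):
        return [_punctae(f, pos) for f, pos in enumerate(cfg_positions)]

    def test_empty_reference_refused(self):
        rings = build_rings(CENTER, n_rings=2, diameter_increment=8.0)
        series = self._series([[], [], [], []])
        with pytest.raises(ValueError, match="empty reference"):
            reference_events(series, rings, wound_frame=2)

    def test_all_rings_full_window_pools_everything(self):
        rings = build_rings(CENTER, n_rings=2, diameter_increment=8.0)
        pos = [(18.0, 16.0), (22.0, 16.0)]
        series = self._series([[], [], pos, pos, pos])
        ref = reference_events(series, rings, wound_frame=2, window=(0.0, 10.0),
                               ring_set=(1, 2))
        # frame 2 sits at t = 0, outside the half-open (0, 10] window;
        # frames 3 and 4 contribute both punctae each
        assert ref.shape == (4, 2)

    def test_window_and_ring_filtering(self):
        rings = build_rings(CENTER, n_rings=2, diameter_increment=8.0)
        inner = (18.0, 16.0)   # 2 µm from the wound → ring 1
        outer = (24.0, 16.0)   # 8 µm → ring 2
        series = self._series([[inner], [inner], [inner, outer], [outer]])
        # frame 2 is t = 0 (excluded by the half-open window); frame 3 holds
        # only the ring-2 point, so a ring-1 reference is empty …
        with pytest.raises(ValueError, match="empty reference"):
            reference_events(series, rings, wound_frame=2, window=(0.0, 10.0),
                             ring_set=(1,))
        # … while pooling both rings picks up exactly that one event
        ref = reference_events(series, rings, wound_frame=2, window=(0.0, 10.0),
                               ring_set=(1, 2))
        assert ref.shape == (1, 2) and tuple(ref[0]) == outer


class TestNNSeries:
    def test_coincident_sets_have_zero_distance(self):
        ref = np.array([[1.0, 1.0], [5.0, 5.0]])
        series = [_punctae(0, [(1.0, 1.0), (5.0, 5.0)]), _punctae(1, [(1.0, 1.0)])]
        with pytest.raises(ValueError):  # normalization by zero distance
            nn_series(ref, series, normalization_frame=0)

    def test_three_four_five_geometry(self):
        ref = np.array([[0.0, 0.0]])
        series = [_punctae(0, [(1.0, 0.0)]), _punctae(1, [(3.0, 4.0)])]
        s = nn_series(ref, series, normalization_frame=0)
        assert s.mean_distance[1] == pytest.approx(5.0)
        assert s.normalized[1] == pytest.approx(5.0)

    def test_missing_frames_propagate_nan(self):
        ref = np.array([[0.0, 0.0]])
        series = [_punctae(0, [(2.0, 0.0)]), _punctae(1, []), _punctae(2, [(4.0, 0.0)])]
        s = nn_series(ref, series, normalization_frame=0)
        assert np.isnan(s.mean_distance[1]) and np.isnan(s.normalized[1])

    def test_permutation_invariance_of_reference(self):
        rng = np.random.default_rng(3)
        ref = rng.uniform(0, 30, (40, 2))
        series = [_punctae(0, rng.uniform(0, 30, (25, 2)))]
        s1 = nn_series(ref, series, normalization_frame=0)
        s2 = nn_series(ref[::-1].copy(), series, normalization_frame=0)
        assert s1.mean_distance[0] == pytest.approx(s2.mean_distance[0], rel=1e-12)

    def test_adding_reference_points_never_increases_distances(self):
        rng = np.random.default_rng(4)
        ref = rng.uniform(0, 30, (10, 2))
        extra = np.vstack([ref, rng.uniform(0, 30, (10, 2))])
        series = [_punctae(0, rng.uniform(0, 30, (25, 2)))]
        d_small = nn_series(ref, series, normalization_frame=0).mean_distance[0]
        d_big = nn_series(extra, series, normalization_frame=0).mean_distance[0]
        assert d_big <= d_small + 1e-12

    def test_agrees_with_independent_kdtree_implementation(self):
        """Cross-check against scikit-learn's KDTree on random point sets."""
        from sklearn.neighbors import KDTree

        rng = np.random.default_rng(21)
        ref = rng.uniform(0, 40, (150, 2))
        q = rng.uniform(0, 40, (80, 2))
        series = [_punctae(0, q)]
        s = nn_series(ref, series, normalization_frame=0)
        d, _ = KDTree(ref, metric="minkowski").query(q, k=1)
        assert s.mean_distance[0] == pytest.approx(d.ravel().mean(), rel=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(1, 60), st.integers(1, 60), st.integers(0, 10_000))
    def test_kdtree_matches_exhaustive_minimum(self, n_ref, n_q, seed):
        """Brute-force oracle on ≤ 200 points: all-pairs minima, exactly."""
        rng = np.random.default_rng(seed)
        ref = rng.uniform(0, 50, (n_ref, 2))
        q = rng.uniform(0, 50, (n_q, 2))
        series = [_punctae(0, q)]
        s = nn_series(ref, series, normalization_frame=0)
        brute = np.min(np.hypot(q[:, 0, None] - ref[None, :, 0],
                                q[:, 1, None] - ref[None, :, 1]), axis=1)
        assert s.mean_distance[0] == pytest.approx(brute.mean(), rel=1e-12)


class TestWoundDistanceDensity:
    def test_point_mass_at_wound(self):
        series = [_punctae(0, [CENTER, CENTER])]
        d = wound_distance_density(series, CENTER, max_extent=10.0)
        assert np.allclose(d, 0.0)

    def test_empty_input_empty_samples(self):
        assert wound_distance_density([_punctae(0, [])], CENTER).size == 0

    def test_uniform_disk_follows_triangle_law(self):
        """Uniform points on a disk: normalized radius has density 2r (CDF r²)."""
        rng = np.random.default_rng(9)
        n = 5000
        r = np.sqrt(rng.random(n))  # uniform disk, unit radius
        th = rng.uniform(0, 2 * math.pi, n)
        pts = np.column_stack([CENTER[0] + 10 * r * np.cos(th),
                               CENTER[1] + 10 * r * np.sin(th)])
        samples = wound_distance_density([_punctae(0, pts)], CENTER, max_extent=10.0)
        from scipy.stats import kstest

        stat, p = kstest(samples, lambda x: np.clip(x, 0, 1) ** 2)
        assert p > 0.01
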