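"""Clustering and aggregation statistics: kNN distances against a
brute-force oracle, densities, per-image and per-case summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endopuncta.morphostats import (
    density,
    export_spatial,
    knn_mean_distance,
    summarize_case,
    summarize_image,
)


def brute_force_knn(points, k):
    """O(n²) all-pairs oracle for the mean k-nearest-neighbour distance."""
    pts = np.asarray(points, dtype=float)
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    np.fill_diagonal(d, np.inf)
    d.sort(axis=1)
    return d[:, :k].mean(axis=1)


TETRAHEDRON = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)]


class TestKnn:
    def test_origin_of_unit_tetrahedron_has_mean_one(self):
        out = knn_mean_distance(TETRAHEDRON, k=3)
        assert out["mean_knn_distance_um"].iloc[0] == pytest.approx(1.0)

    def test_apex_mean_matches_closed_form(self):
        # distances from (1,0,0): 1, √2, √2
        out = knn_mean_distance(TETRAHEDRON, k=3)
        assert out["mean_knn_distance_um"].iloc[1] == pytest.approx((1 + 2 * math.sqrt(2)) / 3)

    def test_insufficient_points_flagged_nan(self):
        out = knn_mean_distance([(0, 0, 0), (1, 1, 1), (2, 0, 0)], k=3)
        assert out["mean_knn_distance_um"].isna().all()

    def test_k_must_be_positive(self):
        with pytest.raises(ValueError):
            knn_mean_distance(TETRAHEDRON, k=0)

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 200))
        pts = rng.uniform(0, 10, size=(n, 3))
        k = int(rng.integers(1, 5))
        out = knn_mean_distance(pts, k=k)
        np.testing.assert_allclose(
            out["mean_knn_distance_um"].to_numpy(), brute_force_knn(pts, k), rtol=1e-12
        )

    def test_invariant_under_permutation(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 5, size=(40, 3))
        perm = rng.permutation(40)
        a = knn_mean_distance(pts, 3)["mean_knn_distance_um"].to_numpy()
        b = knn_mean_distance(pts[perm], 3)["mean_knn_distance_um"].to_numpy()
        np.testing.assert_allclose(a[perm], b, rtol=1e-12)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_rigid_motion_invariance(self, seed):
        """Distances are unchanged by translation and rotation."""
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 5, size=(25, 3))
        R = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
        moved = pts @ R.T + rng.uniform(-100, 100, size=3)
        a = knn_mean_distance(pts, 3)["mean_knn_distance_um"].to_numpy()
        b = knn_mean_distance(moved, 3)["mean_knn_distance_um"].to_numpy()
        np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-9)


class TestDensity:
    def test_basic_ratio(self):
        assert density(50, 250.0) == pytest.approx(0.2)

    def test_zero_count(self):
        assert density(0, 10.0) == 0.0

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            density(5, 0.0)


def _table(volumes, coords=None):
    n = len(volumes)
    if coords is None:
        coords = np.arange(n)[:, None] * [1.0, 0.0, 0.0]
    return pd.DataFrame(
        {
            "volume_um3": volumes,
            "cx_um": np.asarray(coords)[:, 0],
            "cy_um": np.asarray(coords)[:, 1],
            "cz_um": np.asarray(coords)[:, 2],
        }
    )


class TestImageSummary:
    def test_three_volume_example(self):
        out = summarize_image(_table([0.01, 0.02, 0.03]), roi=10.0, k=1)
        row = out.iloc[0]
        assert row["volume_mean_um3"] == pytest.approx(0.02)
        assert row["volume_median_um3"] == pytest.approx(0.02)
        assert row["n_puncta"] == 3
        assert row["density_per_um3"] == pytest.approx(0.3)

    def test_single_punctum_degenerate_stats(self):
        row = summarize_image(_table([0.01]), roi=5.0).iloc[0]
        assert np.isnan(row["volume_sd_um3"])
        assert row["volume_q1_um3"] == row["volume_q3_um3"] == 0.01
        assert np.isnan(row["mean_knn_um"])

    def test_empty_table(self):
        row = summarize_image(_table([]), roi=5.0, roi_role="somatodendritic").iloc[0]
        assert row["n_puncta"] == 0
        assert row["density_per_um3"] == 0.0
        assert np.isnan(row["volume_mean_um3"])

    def test_density_times_volume_reproduces_count(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(0, 50))
            v = float(rng.uniform(1, 500))
            row = summarize_image(_table(rng.uniform(0.004, 0.06, n)), roi=v).iloc[0]
            assert row["density_per_um3"] * row["roi_volume_um3"] == pytest.approx(
                row["n_puncta"], rel=1e-9
            )


class TestCaseSummary:
    def _images(self, means, case="c1", role="somatodendritic"):
        return pd.concat(
            [
                summarize_image(_table([m] * 4), roi=10.0, case_id=case,
                                image_id=f"i{j}", roi_role=role)
                for j, m in enumerate(means)
            ],
            ignore_index=True,
        )

    def test_unweighted_mean_of_image_means(self):
        out = summarize_case(self._images([0.01, 0.03]))
        assert out["volume_mean_um3_mean"].iloc[0] == pytest.approx(0.02)
        assert out["n_images"].iloc[0] == 2

    def test_single_image_case_sd_flagged(self):
        out = summarize_case(self._images([0.02]))
        assert out["volume_mean_um3_mean"].iloc[0] == pytest.approx(0.02)
        assert np.isnan(out["volume_mean_um3_sd"].iloc[0])

    def test_identical_images_have_zero_sd(self):
        out = summarize_case(self._images([0.02, 0.02, 0.02]))
        assert out["volume_mean_um3_sd"].iloc[0] == pytest.approx(0.0, abs=1e-15)

    def test_mixed_case_ids_rejected(self):
        imgs = pd.concat([self._images([0.01], case="a"), self._images([0.02], case="b")])
        with pytest.raises(ValueError, match="mixed"):
            summarize_case(imgs)


class TestExportSpatial:
    def test_row_count_and_bit_exact_metric(self):
        rng = np.random.default_rng(1)
        table = _table(rng.uniform(0.004, 0.06, 20), rng.uniform(0, 5, (20, 3)))
        out = export_spatial(table, color_by="volume_um3")
        assert len(out) == 20
        np.testing.assert_array_equal(out["volume_um3"].to_numpy(), table["volume_um3"].to_numpy())

    def test_undefined_knn_propagates_as_missing(self):
        table = _table([0.01, 0.02, 0.03])
        out = export_spatial(table, color_by="mean_knn", k=3)
        assert out["mean_knn"].isna().all()

    def test_unknown_metric_rejected(self):
        with pytest.raises(KeyError):
            export_spatial(_table([0.01]), color_by="nonexistent")
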