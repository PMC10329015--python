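"""Fold estimators, line scans, 16-84% resolution and channel sums."""

import numpy as np
import pytest
from scipy.special import erf

import gelscope as g
from gelscope.scale import EdgeProfileError, LineProfile


def _pairs(pre, post):
    return g.LandmarkPairs(pre=pre, post=post)


class TestFoldLinear:
    def test_identity_coordinates(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        est = g.fold_linear(_pairs(pts, pts))
        assert est.fold == pytest.approx(1.0)
        assert est.dispersion == pytest.approx(0.0)

    def test_exact_scaling_by_3_7(self):
        rng = np.random.default_rng(0)
        pre = rng.uniform(0, 100, (10, 2))
        est = g.fold_linear(_pairs(pre, 3.7 * pre))
        assert est.fold == pytest.approx(3.7)
        assert est.dispersion == pytest.approx(0.0, abs=1e-9)

    def test_jittered_scaling_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(1)
        pre = rng.uniform(0, 200, (20, 2))
        post = 2.5 * pre + rng.normal(0, 0.5, pre.shape)
        est = g.fold_linear(_pairs(pre, post))
        assert est.fold == pytest.approx(2.5, rel=0.02)
        # O(n^2) brute-force oracle
        ratios = []
        for i in range(20):
            for j in range(i + 1, 20):
                d0 = np.hypot(*(pre[i] - pre[j]))
                d1 = np.hypot(*(post[i] - post[j]))
                ratios.append(d1 / d0)
        assert est.fold == pytest.approx(np.mean(ratios))
        assert est.dispersion == pytest.approx(np.std(ratios, ddof=1))
        assert est.n == len(ratios)

    def test_coincident_pre_landmarks_skipped_with_warning(self):
        pre = np.array([[5.0, 5.0], [5.0, 5.0], [20.0, 20.0]])
        post = np.array([[5.0, 5.0], [6.0, 5.0], [40.0, 40.0]])
        with pytest.warns(UserWarning, match="coincident"):
            est = g.fold_linear(_pairs(pre, post))
        assert est.n == 2

    def test_pixel_sizes_enter_physically(self):
        pre = np.array([[0.0, 0.0], [10.0, 0.0]])
        est = g.fold_linear(
            g.LandmarkPairs(pre=pre, post=pre, pixel_size_pre_um=1.0, pixel_size_post_um=3.7)
        )
        assert est.fold == pytest.approx(3.7)


class TestFoldArea:
    @staticmethod
    def _disc(shape, r):
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        return g.LabelMask(
            (((rr - shape[0] // 2) ** 2 + (cc - shape[1] // 2) ** 2) <= r**2).astype(np.int32)
        )

    def test_identical_masks(self):
        m = self._disc((64, 64), 20)
        assert g.fold_area(m, m).fold == pytest.approx(1.0)

    def test_scaled_disc_within_two_percent(self):
        m = self._disc((64, 64), 20)
        scaled = g.apply_scale(m, 2.0, interpolation="nearest")
        assert g.fold_area(m, scaled).fold == pytest.approx(2.0, rel=0.02)

    def test_area_ratio_13_69_gives_3_7(self):
        a = np.zeros((200, 200), np.int32)
        a[:10, :10] = 1  # 100 px
        b = np.zeros((200, 200), np.int32)
        b[:37, :37] = 1  # 1369 px
        assert g.fold_area(g.LabelMask(a), g.LabelMask(b)).fold == pytest.approx(3.7)

    def test_empty_mask_errors(self):
        with pytest.raises(g.ValidationError, match="empty"):
            g.fold_area(g.LabelMask(np.zeros((8, 8), np.int32)), self._disc((8, 8), 2))


class TestFoldSegmentation:
    def test_same_table_gives_unity(self, small_cell_field):
        image, mask = small_cell_field
        table = g.quantify_cells(image, mask)
        assert g.fold_segmentation(table, table).fold == pytest.approx(1.0)

    def test_end_to_end_rescaled_cell_field(self, small_cell_field):
        image, mask = small_cell_field
        table_pre = g.quantify_cells(image, mask)
        scaled_img = g.apply_scale(image, 3.0)
        scaled_mask = g.apply_scale(mask, 3.0, interpolation="nearest")
        table_post = g.quantify_cells(scaled_img, scaled_mask)
        est = g.fold_segmentation(table_pre, table_post)
        assert est.fold == pytest.approx(3.0, rel=0.05)

    def test_median_and_mean_agree_on_symmetric_distribution(self, small_cell_field):
        image, mask = small_cell_field
        table = g.quantify_cells(image, mask)
        scaled = table.copy()
        scaled["area_px"] = table["area_px"] * 4
        med = g.fold_segmentation(table, scaled, statistic="median").fold
        mean = g.fold_segmentation(table, scaled, statistic="mean").fold
        assert med == pytest.approx(mean, rel=0.01) == pytest.approx(2.0)

    def test_too_few_cells_errors(self):
        import pandas as pd

        t = pd.DataFrame({"area_px": [100.0] * 5})
        with pytest.raises(g.ValidationError, match="at least"):
            g.fold_segmentation(t, t)


class TestLineProfile:
    def test_horizontal_line_returns_row_values(self):
        arr = np.arange(64, dtype=float).reshape(8, 8)
        img = g.MultiplexImage({"m": arr})
        prof = g.line_profile(img, "m", (3, 0), (3, 7))
        np.testing.assert_allclose(prof.intensities, arr[3])
        assert len(prof.positions_um) == 8

    def test_sample_count_is_floor_distance_plus_one(self):
        img = g.MultiplexImage({"m": np.zeros((20, 20))})
        prof = g.line_profile(img, "m", (0, 0), (3, 4))  # distance 5
        assert len(prof.intensities) == 6

    def test_bilinear_midpoint_closed_form(self):
        img = g.MultiplexImage({"m": np.array([[0.0, 0.0], [2.0, 2.0]])})
        prof = g.line_profile(img, "m", (0.5, 0), (0.5, 1))
        np.testing.assert_allclose(prof.intensities, [1.0, 1.0])

    def test_positions_use_pre_expansion_convention(self):
        arr = np.zeros((16, 16))
        a = g.MultiplexImage({"m": arr}, pixel_size_um=0.5, expansion_fold=1.0)
        b = g.MultiplexImage({"m": arr}, pixel_size_um=0.5, expansion_fold=2.0)
        pa = g.line_profile(a, "m", (0, 0), (0, 10))
        pb = g.line_profile(b, "m", (0, 0), (0, 10))
        np.testing.assert_allclose(pa.positions_um, 2.0 * pb.positions_um)

    def test_endpoint_outside_errors(self):
        img = g.MultiplexImage({"m": np.zeros((8, 8))})
        with pytest.raises(g.ValidationError, match="outside"):
            g.line_profile(img, "m", (0, 0), (10, 0))


def _edge_profile(n=100, kind="ramp", ramp_len=20, sigma=2.0, lo=5.0, hi=55.0):
    x = np.arange(n, dtype=float)
    mid = n / 2
    if kind == "step":
        y = np.where(x < mid, lo, hi)
    elif kind == "ramp":
        y = lo + (hi - lo) * np.clip((x - (mid - ramp_len / 2)) / ramp_len, 0, 1)
    else:  # gaussian-blurred edge: analytic error-function profile
        y = lo + (hi - lo) * 0.5 * (1 + erf((x - mid) / (sigma * np.sqrt(2))))
    return LineProfile((0, 0), (0, n - 1), x, y, "m")


class TestResolution1684:
    def test_ideal_step_edge_at_most_one_pixel(self):
        assert g.resolution_16_84(_edge_profile(kind="step")) <= 1.0

    def test_linear_ramp_gives_068_L(self):
        d = g.resolution_16_84(_edge_profile(kind="ramp", ramp_len=20))
        assert d == pytest.approx(0.68 * 20, rel=1e-6)

    def test_gaussian_sigma2_edge_gives_about_4px(self):
        d = g.resolution_16_84(_edge_profile(kind="gauss", sigma=2.0))
        # 16th/84th normal quantiles sit at -/+ one sigma
        assert d == pytest.approx(4.0, rel=0.05)

    def test_invariant_to_affine_intensity_transform(self):
        p = _edge_profile(kind="gauss", sigma=3.0)
        q = LineProfile(p.p0, p.p1, p.positions_um, 2.5 * p.intensities + 40.0, "m")
        assert g.resolution_16_84(q) == pytest.approx(g.resolution_16_84(p), rel=1e-9)

    def test_decreasing_edge_handled(self):
        p = _edge_profile(kind="gauss", sigma=2.0)
        q = LineProfile(p.p0, p.p1, p.positions_um, p.intensities[::-1].copy(), "m")
        assert g.resolution_16_84(q) == pytest.approx(g.resolution_16_84(p), rel=1e-6)

    def test_plateau_free_profile_errors(self):
        x = np.arange(50, dtype=float)
        p = LineProfile((0, 0), (0, 49), x, np.sin(x / 3) + 2, "m")
        with pytest.raises(EdgeProfileError):
            g.resolution_16_84(p)

    def test_summary_mean_sd(self):
        est = g.summarize_resolution([4.0, 4.4, 3.6])
        assert est.mean_um == pytest.approx(4.0)
        assert est.sd_um == pytest.approx(np.std([4.0, 4.4, 3.6], ddof=1))
        assert est.n_scans == 3


class TestSumChannels:
    def test_zero_and_constant_fovs(self):
        z = g.MultiplexImage({"H3": np.zeros((10, 10))}, fov_id="z")
        c = g.MultiplexImage({"H3": np.full((10, 10), 3.0)}, fov_id="c")
        table = g.sum_channels([z, c], ["H3"])
        assert table["H3"].tolist() == [0.0, 300.0]

    def test_matches_loop_oracle(self, rng):
        fovs = [
            g.MultiplexImage({"a": rng.random((6, 6)), "b": rng.random((6, 6))}, fov_id=f"f{i}")
            for i in range(3)
        ]
        table = g.sum_channels(fovs, ["a", "b"])
        for i, fov in enumerate(fovs):
            for ch in ("a", "b"):
                total = 0.0
                for r in range(6):
                    for c in range(6):
                        total += fov[ch][r, c]
                assert table.loc[i, ch] == pytest.approx(total)

    def test_missing_channel_errors(self):
        fov = g.MultiplexImage({"a": np.zeros((4, 4))})
        with pytest.raises(g.ValidationError, match="lacks"):
            g.sum_channels([fov], ["b"])


class TestFoldConcordance:
    """All three estimators agree on one synthetic tissue at a known fold."""

    @pytest.mark.parametrize("fold", [2.0, 3.7])
    def test_estimators_concordant(self, fold):
        image, mask = g.make_cell_field(
            n_cells=120, shape=(220, 220), mean_area_px=90.0, area_cv=0.25, seed=21
        )
        noisy_pre = g.add_poisson_noise(image, seed=31)
        scaled_img = g.apply_scale(image, fold)
        scaled_mask = g.apply_scale(mask, fold, interpolation="nearest")
        noisy_post = g.add_poisson_noise(scaled_img, seed=32)

        centroids_pre = g.quantify_cells(noisy_pre, mask)
        centroids_post = g.quantify_cells(noisy_post, scaled_mask)
        est_lin = g.fold_linear(
            g.LandmarkPairs(
                pre=centroids_pre[["centroid_row", "centroid_col"]].to_numpy(),
                post=centroids_post[["centroid_row", "centroid_col"]].to_numpy(),
            )
        )
        tissue_pre = g.LabelMask((mask.data > 0).astype(np.int32))
        tissue_post = g.LabelMask((scaled_mask.data > 0).astype(np.int32))
        est_area = g.fold_area(tissue_pre, tissue_post)
        est_seg = g.fold_segmentation(centroids_pre, centroids_post)

        for est in (est_lin, est_area, est_seg):
            assert est.fold == pytest.approx(fold, rel=0.05), est.method
        folds = [est_lin.fold, est_area.fold, est_seg.fold]
        assert max(folds) / min(folds) <= 1.05


def test_screen_success_percent_worked_example():
    # 58 of 73 clones validated -> 79.45%, reported as ~80%
    assert g.screen_success_percent(58, 73) == pytest.approx(100 * 58 / 73)
    with pytest.raises(g.ValidationError):
        g.screen_success_percent(5, 0)
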