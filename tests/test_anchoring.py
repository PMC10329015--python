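"""Step-ring algebra, profiling, aggregation and peak localisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import ndimage

import gelscope as g
from conftest import random_blob
from gelscope.anchoring import heatmap_and_peaks, step_rings
from oracles import chessboard_rings_oracle
from gelscope.phantoms import signed_boundary_distance


def _mask_from(obj):
    return g.LabelMask(obj.astype(np.int32))


class TestStepRings:
    def test_single_pixel_first_ring_has_eight_pixels(self):
        obj = np.zeros((9, 9), bool)
        obj[4, 4] = True
        rings = step_rings(_mask_from(obj), 1, k_min=-3, k_max=2)
        assert rings.steps[1].size == 8
        assert rings.steps[2].size == 16
        assert rings.steps[-1].size == 1  # the pixel itself erodes away first
        assert rings.steps[-2].size == 0
        assert rings.steps[-3].size == 0

    def test_square_object_matches_distance_transform_oracle(self):
        obj = np.zeros((31, 31), bool)
        obj[10:21, 10:21] = True  # 11x11 square
        rings = step_rings(_mask_from(obj), 1, k_min=-5, k_max=3)
        oracle = chessboard_rings_oracle(obj, -5, 3)
        for k, expected in oracle.items():
            assert np.array_equal(rings.ring_mask(k), expected), f"step {k}"

    def test_unknown_object_errors(self):
        obj = np.zeros((8, 8), bool)
        obj[4, 4] = True
        with pytest.raises(g.ValidationError, match="17"):
            step_rings(_mask_from(obj), 17, k_min=-1, k_max=1)

    def test_rings_clipped_at_border(self):
        obj = np.zeros((10, 10), bool)
        obj[0:3, 0:3] = True
        rings = step_rings(_mask_from(obj), 1, k_min=-2, k_max=3)
        total = sum(v.size for k, v in rings.steps.items() if k > 0)
        full = chessboard_rings_oracle(obj, -2, 3)
        assert total == sum(full[k].sum() for k in (1, 2, 3))

    @given(st.integers(0, 1000))
    def test_ring_algebra_on_random_blobs(self, seed):
        rng = np.random.default_rng(seed)
        obj = random_blob(rng)
        k_min, k_max = -4, 4
        rings = step_rings(_mask_from(obj), 1, k_min=k_min, k_max=k_max)
        # pairwise disjoint
        all_idx = np.concatenate([v for v in rings.steps.values()])
        assert all_idx.size == np.unique(all_idx).size
        # positive rings outside, negative rings inside
        flat = obj.ravel()
        for k, idx in rings.steps.items():
            if k > 0:
                assert not flat[idx].any()
            else:
                assert flat[idx].all()
        # unions reconstruct k-fold dilation/erosion exactly
        dil = ndimage.binary_dilation(obj, np.ones((3, 3)), iterations=k_max)
        outer = np.zeros_like(obj)
        for k in range(1, k_max + 1):
            outer |= rings.ring_mask(k)
        assert np.array_equal(outer, dil & ~obj)
        ero = ndimage.binary_erosion(obj, np.ones((3, 3)), iterations=-k_min, border_value=0)
        inner = np.zeros_like(obj)
        for k in range(k_min, 0):
            inner |= rings.ring_mask(k)
        assert np.array_equal(inner, obj & ~ero)
        # level sets of the chessboard distance transform
        oracle = chessboard_rings_oracle(obj, k_min, k_max)
        for k in oracle:
            assert np.array_equal(rings.ring_mask(k), oracle[k])

    def test_convex_object_outer_ring_counts_nondecreasing(self):
        rr, cc = np.ogrid[:64, :64]
        obj = (rr - 32) ** 2 + (cc - 32) ** 2 <= 100
        rings = step_rings(_mask_from(obj), 1, k_min=-1, k_max=15)
        counts = [rings.steps[k].size for k in range(1, 16)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestExcludeOverlaps:
    def _two_objects(self):
        data = np.zeros((20, 30), np.int32)
        data[8:12, 4:8] = 1
        data[8:12, 12:16] = 2  # 4 px gap
        return g.LabelMask(data)

    def test_isolated_object_unchanged(self):
        data = np.zeros((16, 16), np.int32)
        data[6:10, 6:10] = 1
        rings = step_rings(g.LabelMask(data), 1, k_min=-1, k_max=3)
        out = g.exclude_overlaps(rings, g.LabelMask(data))
        for k in rings.steps:
            assert np.array_equal(out.steps[k], rings.steps[k])

    def test_overlap_removed_matches_set_difference_oracle(self):
        mask = self._two_objects()
        rings = step_rings(mask, 1, k_min=-1, k_max=5)
        out = g.exclude_overlaps(rings, mask)
        other = mask.data == 2
        for k in rings.steps:
            expected = rings.ring_mask(k) & ~other
            assert np.array_equal(out.ring_mask(k), expected), f"step {k}"
        # ring(+5) of object 1 does reach into object 2
        assert rings.ring_mask(5).sum() > out.ring_mask(5).sum()

    def test_no_output_ring_intersects_other_objects(self):
        mask = self._two_objects()
        out = g.exclude_overlaps(step_rings(mask, 1, k_min=-1, k_max=6), mask)
        other = mask.data == 2
        for k in out.steps:
            assert not (out.ring_mask(k) & other).any()


class TestProfileObject:
    def test_constant_channel_every_step_mean_is_v(self):
        data = np.zeros((24, 24), np.int32)
        data[10:14, 10:14] = 1
        img = g.MultiplexImage({"m": np.full((24, 24), 7.0)})
        rings = step_rings(g.LabelMask(data), 1, k_min=-2, k_max=3)
        rec = g.profile_object(img, rings)
        nonempty = [k for k, v in rings.steps.items() if v.size]
        assert (rec.loc[nonempty, "m"] == 7.0).all()

    def test_empty_ring_yields_missing_not_zero(self):
        data = np.zeros((12, 12), np.int32)
        data[6, 6] = 1
        img = g.MultiplexImage({"m": np.ones((12, 12))})
        rings = step_rings(g.LabelMask(data), 1, k_min=-3, k_max=1)
        rec = g.profile_object(img, rings)
        assert np.isnan(rec.loc[-2, "m"])
        assert rec.loc[1, "m"] == 1.0

    def test_class_fraction_one_when_ring_covered(self):
        data = np.zeros((20, 20), np.int32)
        data[8:12, 8:12] = 1
        cmap = g.ClassMap(np.ones((20, 20), np.int32), {1: "astrocyte"})
        img = g.MultiplexImage({"m": np.zeros((20, 20))})
        rings = step_rings(g.LabelMask(data), 1, k_min=-1, k_max=2)
        rec = g.profile_object(img, rings, [cmap])
        assert (rec["frac_astrocyte"].dropna() == 1.0).all()

    def test_annulus_peak_matches_radial_histogram_oracle(self):
        spec = g.PhantomSpec(
            width_px=96,
            height_px=96,
            vessels=[g.Vessel((48, 48), 10, 3)],
            layers=[g.Layer("M", 8.0, 1.0, 100.0)],
            seed=1,
        )
        image, mask, _ = g.make_vessel_phantom(spec, metric="chessboard")
        rings = step_rings(mask, 1, k_min=-5, k_max=15)
        rec = g.profile_object(image, rings)
        # oracle: per-step mean from the signed chessboard distance map
        sd = signed_boundary_distance(mask.data == 1, metric="chessboard")
        oracle = {
            k: image["M"][sd == k].mean()
            for k in range(-5, 16)
            if k != 0 and (sd == k).any()
        }
        peak_oracle = max(oracle, key=oracle.get)
        assert rec["M"].idxmax() == peak_oracle == 8


class TestAggregateProfiles:
    def _rec(self, values):
        return pd.DataFrame({"m": values}, index=pd.Index([-1, 1, 2], name="step"))

    def test_single_object_mean_is_record_ci_missing(self):
        prof = g.aggregate_profiles([self._rec([4.0, 9.0, 16.0])], transform="none")
        m = prof.matrix("mean")["m"]
        assert m.tolist() == [4.0, 9.0, 16.0]
        assert prof.matrix("ci_low")["m"].isna().all()

    def test_sqrt_applied_before_averaging(self):
        prof = g.aggregate_profiles(
            [self._rec([4.0, 4.0, 4.0]), self._rec([16.0, 16.0, 16.0])], transform="sqrt"
        )
        assert (prof.matrix("mean")["m"] == 3.0).all()  # (2 + 4) / 2

    def test_ci_formula_against_direct_computation(self):
        vals = [self._rec([1.0, 2.0, 3.0]), self._rec([2.0, 4.0, 6.0]), self._rec([3.0, 6.0, 9.0])]
        prof = g.aggregate_profiles(vals, transform="none")
        row = prof.stats[(prof.stats["step"] == 1) & (prof.stats["quantity"] == "m")].iloc[0]
        x = np.array([2.0, 4.0, 6.0])
        assert row["mean"] == pytest.approx(4.0)
        assert row["ci_low"] == pytest.approx(4.0 - 1.96 * x.std(ddof=1) / np.sqrt(3))

    def test_missing_values_reduce_n_not_mean(self):
        a = self._rec([1.0, np.nan, 3.0])
        b = self._rec([3.0, 5.0, 5.0])
        prof = g.aggregate_profiles([a, b], transform="none")
        s = prof.stats.set_index(["step", "quantity"])
        assert s.loc[(1, "m"), "n"] == 1
        assert s.loc[(1, "m"), "mean"] == 5.0
        assert s.loc[(-1, "m"), "n"] == 2

    def test_zero_objects_errors(self):
        with pytest.raises(g.ValidationError):
            g.aggregate_profiles([], transform="none")


class TestHeatmapAndPeaks:
    def test_linear_rise_peaks_at_k_max(self):
        rec = pd.DataFrame({"m": [1.0, 2.0, 3.0, 4.0]}, index=pd.Index([-2, -1, 1, 2], name="step"))
        prof = g.aggregate_profiles([rec], transform="none")
        peaks = heatmap_and_peaks(prof)
        assert peaks.peaks["m"] == 2

    def test_z_vectors_standardized(self, rng):
        recs = [
            pd.DataFrame(
                {"a": rng.random(6), "b": rng.random(6)},
                index=pd.Index([-3, -2, -1, 1, 2, 3], name="step"),
            )
            for _ in range(5)
        ]
        peaks = heatmap_and_peaks(g.aggregate_profiles(recs, transform="none"))
        for q in ("a", "b"):
            assert abs(peaks.z[q].mean()) < 1e-9
            assert abs(peaks.z[q].std(ddof=0) - 1) < 1e-9

    def test_tie_breaks_toward_lumen(self):
        rec = pd.DataFrame({"m": [5.0, 1.0, 5.0]}, index=pd.Index([-1, 1, 2], name="step"))
        prof = g.aggregate_profiles([rec], transform="none")
        assert heatmap_and_peaks(prof).peaks["m"] == -1

    def test_constant_channel_flagged_and_excluded(self):
        rec = pd.DataFrame(
            {"flat": [2.0, 2.0, 2.0], "rise": [1.0, 2.0, 3.0]},
            index=pd.Index([-1, 1, 2], name="step"),
        )
        peaks = heatmap_and_peaks(g.aggregate_profiles([rec], transform="none"))
        assert peaks.excluded == ["flat"]
        assert list(peaks.z.columns) == ["rise"]


class TestEndToEnd:
    def test_noise_free_peak_ordering_recovered_euclidean_metric(self):
        offsets = {"A": -6.0, "B": 0.0, "C": 3.0, "D": 8.0}
        spec = g.PhantomSpec(
            width_px=200,
            height_px=200,
            vessels=[g.Vessel((50 + 66 * i, 50 + 66 * j), 8, 4) for i in range(2) for j in range(2)],
            layers=[g.Layer(m, o, 2.0, 100.0) for m, o in offsets.items()],
            background_rate=0.1,
            seed=2,
        )
        image, mask, truth = g.make_vessel_phantom(spec)
        res = g.anchor_vessels(image, mask, k_min=-10, k_max=12, transform="sqrt")
        recovered = res.peaks.ordering(["A", "B", "C", "D"])
        assert recovered == ["A", "B", "C", "D"]

    def test_border_objects_excluded_by_default(self):
        spec = g.PhantomSpec(
            width_px=100,
            height_px=100,
            vessels=[g.Vessel((20, 20), 6, 3), g.Vessel((70, 70), 6, 3)],
            layers=[g.Layer("M", 0.0, 2.0, 50.0)],
            seed=3,
        )
        image, mask, _ = g.make_vessel_phantom(spec)
        res = g.anchor_vessels(image, mask, k_min=-5, k_max=15)
        assert res.excluded_objects == [1]
        assert res.profile.n_objects == 1

    def test_dsdna_normalization_makes_profiles_scale_invariant(self):
        spec = g.PhantomSpec(
            width_px=120,
            height_px=120,
            vessels=[g.Vessel((60, 60), 8, 4)],
            layers=[g.Layer("M", 2.0, 2.0, 60.0), g.Layer("dsDNA", -8.0, 4.0, 90.0)],
            background_rate=1.0,
            seed=4,
        )
        image, mask, _ = g.make_vessel_phantom(spec, noise=True)
        scaled = image.map_channels(lambda a: 7.3 * a)
        p1 = g.anchor_vessels(
            g.normalize_tile_by_dsdna(image, "dsDNA"), mask, k_min=-6, k_max=8
        ).profile
        p2 = g.anchor_vessels(
            g.normalize_tile_by_dsdna(scaled, "dsDNA"), mask, k_min=-6, k_max=8
        ).profile
        a = p1.matrix("mean").to_numpy()
        b = p2.matrix("mean").to_numpy()
        np.testing.assert_allclose(a, b, rtol=1e-9)
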