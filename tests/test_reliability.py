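"""ICC(3,1) statistics: oracle agreement, invariances, maps and summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from taskrel import (
    activation_masked_medians,
    anova_mean_squares,
    classify_icc,
    icc31,
    icc31_confint,
    icc_map,
    icc_standardize,
    median_icc,
    overlap_percentage,
    pairing_permutation_null,
    threshold_icc_map,
)
from taskrel.reliability import EmptyMaskError, IccUndefinedError


def oracle_icc31(d):
    """Brute-force two-way ANOVA mean squares, written independently."""
    d = np.asarray(d, float)
    n, k = d.shape
    gm = d.mean()
    bms = k * sum((d[i].mean() - gm) ** 2 for i in range(n)) / (n - 1)
    sse = sum(
        (d[i, j] - d[i].mean() - d[:, j].mean() + gm) ** 2
        for i in range(n)
        for j in range(k)
    )
    ems = sse / ((n - 1) * (k - 1))
    return (bms - ems) / (bms + (k - 1) * ems)


class TestICC31:
    def test_worked_example_against_frozen_oracle(self):
        m = np.array([[1, 2], [3, 3], [5, 6], [7, 6], [9, 10.0]])
        assert icc31(m) == pytest.approx(0.9595959595959598, abs=1e-12)
        assert icc31(m) == pytest.approx(oracle_icc31(m), abs=1e-12)

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(14)
        m = rng.normal(size=(12, 2))
        long = pd.DataFrame(
            {
                "s": np.repeat(np.arange(12), 2),
                "r": np.tile([0, 1], 12),
                "y": m.ravel(),
            }
        )
        table = pg.intraclass_corr(long, "s", "r", "y")
        sel = table["Type"].isin(["ICC3", "ICC(C,1)"])
        ref = float(table.loc[sel, "ICC"].iloc[0])
        assert icc31(m) == pytest.approx(ref, abs=1e-10)

    def test_identical_sessions_give_one(self):
        x = np.arange(6, dtype=float)
        assert icc31(np.stack([x, x], axis=1)) == pytest.approx(1.0)

    def test_additive_session_offset_ignored(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        assert icc31(np.stack([x, x + 7.3], axis=1)) == pytest.approx(1.0)

    @given(
        st.integers(min_value=0, max_value=10_000),
        st.floats(min_value=-5, max_value=5),
        st.floats(min_value=0.1, max_value=10),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariant_to_session_shift_and_affine_rescale(self, seed, shift, scale):
        rng = np.random.default_rng(seed)
        m = rng.normal(size=(8, 2))
        base = icc31(m)
        shifted = m.copy()
        shifted[:, 1] += shift
        assert icc31(shifted) == pytest.approx(base, abs=1e-9)
        assert icc31(m * scale + shift) == pytest.approx(base, abs=1e-9)

    def test_zero_variance_signalled(self):
        with pytest.raises(IccUndefinedError):
            icc31(np.full((5, 2), 3.0))

    def test_exposes_anova_mean_squares(self):
        m = np.array([[1, 2], [3, 3], [5, 6], [7, 6], [9, 10.0]])
        ms = anova_mean_squares(m)
        assert ms.n == 5 and ms.k == 2
        assert ms.bms > ms.ems >= 0
        assert icc31(m) == pytest.approx((ms.bms - ms.ems) / (ms.bms + ms.ems))

    def test_confint_brackets_point_estimate(self):
        rng = np.random.default_rng(3)
        m = rng.normal(size=(15, 2)) + rng.normal(size=(15, 1))
        lo, hi = icc31_confint(m)
        assert lo < icc31(m) < hi


class TestICCMap:
    def test_duplicate_sessions_give_one_everywhere(self):
        rng = np.random.default_rng(0)
        ses = rng.normal(size=(10, 4, 4, 4))
        stack = np.stack([ses, ses], axis=1)
        out = icc_map(stack)
        assert np.allclose(out, 1.0)

    def test_matches_scalar_voxelwise(self):
        rng = np.random.default_rng(1)
        stack = rng.normal(size=(9, 2, 3, 3, 1))
        out = icc_map(stack)
        for idx in np.ndindex(3, 3, 1):
            assert out[idx] == pytest.approx(icc31(stack[(...,) + idx][:, :]), abs=1e-12)

    def test_independent_sessions_near_zero_mean(self):
        rng = np.random.default_rng(2)
        stack = rng.normal(size=(200, 2, 6, 6, 6))
        assert abs(np.nanmean(icc_map(stack))) < 0.05

    def test_mask_applied(self):
        rng = np.random.default_rng(3)
        stack = rng.normal(size=(6, 2, 4, 4, 4))
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, 0] = True
        out = icc_map(stack, mask)
        assert np.isfinite(out[0, 0, 0])
        assert np.isnan(out[1:]).all()

    def test_only_two_sessions_supported(self):
        with pytest.raises(ValueError):
            icc_map(np.zeros((5, 3, 2, 2, 2)))


class TestStandardize:
    def test_zero_maps_to_zero(self):
        assert icc_standardize(np.array(0.0), 15) == 0.0

    def test_frozen_closed_form_value(self):
        # atanh(0.77) * sqrt(12), high-precision reference
        assert icc_standardize(np.array(0.77), 15) == pytest.approx(3.5345190355743017, abs=1e-12)

    def test_strictly_increasing_and_clipped(self):
        grid = np.linspace(-1, 1, 201)
        z = icc_standardize(grid, 15)
        assert np.all(np.diff(z) > 0)
        assert np.isfinite(z).all()

    def test_needs_four_subjects(self):
        with pytest.raises(ValueError):
            icc_standardize(np.array(0.5), 3)


class TestThresholdedMap:
    def test_subthreshold_map_is_empty(self):
        icc = np.full((5, 5, 5), 0.3)
        z = np.full((5, 5, 5), 1.0)
        out = threshold_icc_map(icc, z, 15, method="fixed_extent", cluster_k=1)
        assert not out.sig_mask.any()
        assert np.isnan(out.masked_icc).all()

    def test_surviving_cluster_keeps_original_icc_values(self):
        rng = np.random.default_rng(5)
        icc = rng.uniform(0.0, 0.2, size=(8, 8, 8))
        icc[2:5, 2:5, 2:5] = rng.uniform(0.8, 0.95, size=(3, 3, 3))
        z = icc_standardize(icc, 15)
        out = threshold_icc_map(icc, z, 15, z_thresh=3.1, method="fixed_extent", cluster_k=5)
        assert out.sig_mask.sum() == 27
        assert np.array_equal(out.masked_icc[out.sig_mask], icc[out.sig_mask])

    def test_pairing_null_controls_false_positives(self):
        """Under true ICC 0, the chance of any surviving voxel is ~alpha."""
        rng = np.random.default_rng(6)
        hits = 0
        reps = 100
        for rep in range(reps):
            stack = rng.normal(size=(12, 2, 7, 7, 7))
            icc = icc_map(stack)
            z = icc_standardize(icc, 12)
            nulls = pairing_permutation_null(stack, 200, rng=np.random.default_rng(rep))
            out = threshold_icc_map(
                icc, z, 12, z_thresh=2.3, alpha=0.05, method="permutation", null_zmaps=nulls
            )
            hits += out.sig_mask.any()
        assert hits / reps < 0.12


class TestSummaries:
    def test_median_basic(self):
        assert median_icc(np.array([0.7])) == 0.7
        assert median_icc(np.array([0.1, 0.7, 0.9])) == 0.7

    def test_median_empty_signalled(self):
        with pytest.raises(EmptyMaskError):
            median_icc(np.full((3, 3), np.nan))

    def test_median_of_uniform_block(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(0.5, 0.9, size=20_000)
        assert median_icc(vals) == pytest.approx(0.7, abs=0.01)

    def test_sweep_constant_images(self):
        icc = np.full((6, 6, 6), 0.4)
        z = np.full((6, 6, 6), 5.0)
        table = activation_masked_medians(icc, z)
        assert list(table["z_threshold"]) == [2.3, 3.1, 3.7, 4.3]
        assert np.allclose(table["median_icc"], 0.4)

    def test_sweep_masks_nested(self):
        rng = np.random.default_rng(8)
        icc = rng.uniform(-0.2, 0.9, size=(8, 8, 8))
        z = rng.normal(2.5, 1.5, size=(8, 8, 8))
        table = activation_masked_medians(icc, z)
        assert np.all(np.diff(table["n_voxels"]) <= 0)

    def test_sweep_empty_rows_flagged_not_dropped(self):
        icc = np.full((4, 4, 4), 0.5)
        z = np.full((4, 4, 4), 3.5)
        table = activation_masked_medians(icc, z)
        assert len(table) == 4
        assert bool(table["empty"].iloc[-1]) is True
        assert np.isnan(table["median_icc"].iloc[-1])

    def test_sweep_dissociation_scenario(self):
        """High-activation region disjoint from high-ICC region: sweep medians
        fall below the thresholded-map median, the flat/low profile the sweep
        is designed to reveal."""
        icc = np.full((10, 10, 10), 0.05)
        icc[0:4, 0:4, 0:4] = 0.9  # reliable but weakly activated
        act = np.zeros((10, 10, 10))
        act[6:10, 6:10, 6:10] = 6.0  # strongly activated but unreliable
        z = icc_standardize(icc, 15)
        thresholded = threshold_icc_map(icc, z, 15, method="fixed_extent", cluster_k=5)
        sweep = activation_masked_medians(icc, act)
        assert median_icc(thresholded.masked_icc) > 0.8
        assert np.all(sweep["median_icc"] < 0.2)

    @pytest.mark.parametrize(
        "build,expected",
        [
            (lambda m: (m, m.copy()), 100.0),
            (lambda m: (m, ~m), 0.0),
        ],
    )
    def test_overlap_extremes(self, build, expected):
        m = np.zeros((5, 5, 5), bool)
        m[1:3, 1:3, 1:3] = True
        a, b = build(m)
        assert overlap_percentage(a, b) == expected

    def test_overlap_partial(self):
        icc = np.zeros((10, 1, 1), bool)
        icc[:10] = True
        act = np.zeros((10, 1, 1), bool)
        act[:4] = True
        assert overlap_percentage(icc, act) == 40.0

    def test_overlap_empty_icc_mask_signalled(self):
        with pytest.raises(EmptyMaskError):
            overlap_percentage(np.zeros((3, 3, 3), bool), np.ones((3, 3, 3), bool))


class TestClassification:
    @pytest.mark.parametrize(
        "value,label",
        [(0.76, "excellent"), (0.75, "good"), (0.6, "good"), (0.59, "fair"),
         (0.4, "fair"), (0.39, "poor"), (0.17, "poor"), (-0.5, "poor")],
    )
    def test_band_edges(self, value, label):
        assert classify_icc(value) == label

    @given(st.floats(min_value=-1.0, max_value=1.0, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_partition_no_gaps(self, v):
        assert classify_icc(v) in {"poor", "fair", "good", "excellent"}

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_icc(1.5)
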