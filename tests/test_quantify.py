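"""Marker quantification: intensity extraction, k-means threshold, ratios."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from nephroquant import (
    NoiseModel,
    SphereImageParams,
    classify_cells,
    fit_threshold,
    generate_sphere_image,
    measure_nuclei,
    positive_ratio,
    proliferation_ratio,
)
from tests.conftest import make_stack


def exhaustive_kmeans_sse(values, k):
    """Exact 1-D k-means oracle: minimum SSE over contiguous partitions.

    For squared-error clustering of sorted 1-D data the optimal partition is
    contiguous, so enumerating split points is an exhaustive search.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    best = np.inf
    best_parts = None
    for splits in combinations(range(1, n), k - 1):
        bounds = (0, *splits, n)
        sse = sum(
            ((x[a:b] - x[a:b].mean()) ** 2).sum()
            for a, b in zip(bounds, bounds[1:])
        )
        if sse < best:
            best = sse
            best_parts = [x[a:b] for a, b in zip(bounds, bounds[1:])]
    return best, best_parts


def model_sse(values, model):
    """Within-cluster SSE of a fitted 1-D threshold model."""
    x = np.asarray(values, dtype=float)
    sse = 0.0
    for c in range(1, model.k + 1):
        sel = x[model.assignments == c]
        if sel.size:
            sse += ((sel - sel.mean()) ** 2).sum()
    return sse


def table_from_means(means, sds=None):
    means = np.asarray(means, dtype=float)
    sds = np.zeros_like(means) if sds is None else np.asarray(sds, dtype=float)
    return pd.DataFrame(
        {
            "label": np.arange(1, len(means) + 1),
            "size": np.full(len(means), 50),
            "SIX2_mean": means,
            "SIX2_sd": sds,
        }
    )


class TestMeasureNuclei:
    def test_uniform_marker_channel(self):
        mask = np.zeros((20, 20), dtype=int)
        mask[2:6, 2:6] = 1
        mask[10:15, 10:15] = 2
        stack = make_stack(np.zeros((20, 20)), SIX2=np.full((20, 20), 7.0))
        table = measure_nuclei(stack, mask)
        np.testing.assert_allclose(table["SIX2_mean"], 7.0)
        np.testing.assert_allclose(table["SIX2_sd"], 0.0)

    def test_hand_computed_mean_and_population_sd(self):
        mask = np.zeros((4, 4), dtype=int)
        marker = np.zeros((4, 4))
        mask[0, 0:4] = 1
        marker[0, 0:4] = [1, 2, 3, 6]
        table = measure_nuclei(make_stack(np.zeros((4, 4)), SIX2=marker), mask)
        assert table.loc[0, "SIX2_mean"] == pytest.approx(3.0)
        # population (divisor n) convention
        assert table.loc[0, "SIX2_sd"] == pytest.approx(1.8708, abs=1e-4)

    def test_shape_mismatch_raises(self):
        stack = make_stack(np.zeros((8, 8)), SIX2=np.zeros((8, 8)))
        with pytest.raises(ValueError, match="shape"):
            measure_nuclei(stack, np.zeros((9, 9), dtype=int))

    def test_empty_mask_gives_empty_table(self):
        stack = make_stack(np.zeros((8, 8)), SIX2=np.zeros((8, 8)))
        table = measure_nuclei(stack, np.zeros((8, 8), dtype=int))
        assert len(table) == 0
        assert "SIX2_mean" in table.columns

    def test_noiseless_image_recovers_drawn_brightness(self):
        # psf and noise off, true label mask: per-nucleus mean equals the
        # generator's drawn brightness exactly (generator oracle)
        params = SphereImageParams(
            psf_sigma=0.0, noise=NoiseModel(gain=0.0, read_sd=0.0), seed=21
        )
        img, gt = generate_sphere_image(params)
        yy, xx = np.mgrid[tuple(slice(s) for s in img.shape)]
        labels = np.zeros(img.shape, dtype=np.int32)
        for _, row in gt.nuclei.iterrows():
            disk = np.hypot(yy - row["y"], xx - row["x"]) <= row["radius"]
            labels[disk] = int(row["nucleus_id"])
        table = measure_nuclei(img, labels).set_index("label")
        for _, row in gt.nuclei.iterrows():
            assert table.loc[int(row["nucleus_id"]), "SIX2_mean"] == (
                pytest.approx(row["SIX2_brightness"], rel=1e-5)
            )


class TestFitThreshold:
    def test_worked_example_two_clusters(self):
        table = table_from_means([1, 2, 3, 10, 11, 12])
        model = fit_threshold(table, "SIX2", k=2, feature_mode="mean")
        np.testing.assert_allclose(sorted(model.centers[:, 0]), [2.0, 11.0])
        assert model.threshold == pytest.approx(6.5)
        sse, parts = exhaustive_kmeans_sse([1, 2, 3, 10, 11, 12], 2)
        assert model_sse(table["SIX2_mean"], model) == pytest.approx(sse)

    def test_kmeans_sse_matches_exhaustive_partition_minimum(self):
        # exact-optimality oracle on small 1-D inputs
        rng = np.random.default_rng(99)
        for trial in range(100):
            n = int(rng.integers(6, 13))
            k = int(rng.integers(2, 4))
            vals = np.round(rng.uniform(0, 100, n), 3)
            if np.unique(vals).size < k:
                continue
            table = table_from_means(vals)
            model = fit_threshold(table, "SIX2", k=k, feature_mode="mean", seed=0)
            sse_opt, _ = exhaustive_kmeans_sse(vals, k)
            assert model_sse(vals, model) == pytest.approx(
                sse_opt, rel=1e-9, abs=1e-9
            ), f"trial {trial}"

    def test_all_identical_intensities_degenerate(self):
        table = table_from_means([5.0] * 10)
        with pytest.warns(UserWarning, match="identical"):
            model = fit_threshold(table, "SIX2", k=3)
        assert model.degenerate
        classified = classify_cells(table, model)
        assert not classified["SIX2_positive"].any()

    def test_too_few_distinct_points_raises(self):
        table = table_from_means([1.0, 1.0, 2.0, 2.0])
        with pytest.raises(ValueError, match="degenerate"):
            fit_threshold(table, "SIX2", k=3, feature_mode="mean")

    def test_well_separated_components_classified_accurately(self):
        # two-component synthetic table: accuracy vs truth >= 0.99
        rng = np.random.default_rng(17)
        truth = rng.random(200) < 0.4
        means = np.where(
            truth, rng.normal(500, 60, 200), rng.normal(50, 15, 200)
        )
        sds = np.abs(rng.normal(20, 5, 200))
        table = pd.DataFrame(
            {
                "label": np.arange(1, 201),
                "size": 50,
                "SIX2_mean": np.clip(means, 0, None),
                "SIX2_sd": sds,
            }
        )
        model = fit_threshold(table, "SIX2", k=3, seed=1)
        classified = classify_cells(table, model)
        accuracy = (classified["SIX2_positive"] == truth).mean()
        assert accuracy >= 0.99

    def test_imbalanced_positive_minority_still_separated(self):
        # a 5% positive fraction must not drag the threshold into the
        # negative mode (the widest-gap boundary rule)
        rng = np.random.default_rng(3)
        truth = rng.random(200) < 0.05
        means = np.where(
            truth, rng.normal(500, 60, 200), rng.normal(50, 15, 200)
        )
        table = table_from_means(np.clip(means, 0, None))
        model = fit_threshold(table, "SIX2", k=3, feature_mode="mean", seed=1)
        classified = classify_cells(table, model)
        assert (classified["SIX2_positive"] == truth).mean() >= 0.99

    def test_determinism_fixed_seed(self):
        rng = np.random.default_rng(0)
        table = table_from_means(rng.uniform(0, 300, 100))
        m1 = fit_threshold(table, "SIX2", k=3, seed=7, feature_mode="mean")
        m2 = fit_threshold(table, "SIX2", k=3, seed=7, feature_mode="mean")
        assert m1.threshold == m2.threshold
        np.testing.assert_array_equal(m1.assignments, m2.assignments)


class TestClassifyCells:
    def test_counting(self):
        means = np.concatenate([np.full(13, 10.0), np.full(7, 100.0)])
        table = table_from_means(means)
        model = fit_threshold(table, "SIX2", k=2, feature_mode="mean")
        classified = classify_cells(table, model)
        assert int(classified["SIX2_positive"].sum()) == 7

    def test_cell_exactly_at_threshold_is_negative(self):
        table = table_from_means([10, 20, 100, 110])
        model = fit_threshold(table, "SIX2", k=2, feature_mode="mean")
        probe = table_from_means([model.threshold])
        classified = classify_cells(probe, model)
        assert not classified["SIX2_positive"].iloc[0]

    def test_scale_equivariance(self):
        # multiplying the channel by c rescales tau by c and leaves every
        # classification unchanged
        rng = np.random.default_rng(12)
        means = np.concatenate(
            [rng.normal(40, 10, 120), rng.normal(400, 60, 80)]
        )
        sds = np.abs(rng.normal(15, 4, 200))
        c = 3.7
        t1 = pd.DataFrame(
            {"label": np.arange(200), "size": 50, "SIX2_mean": means, "SIX2_sd": sds}
        )
        t2 = t1.assign(SIX2_mean=means * c, SIX2_sd=sds * c)
        m1 = fit_threshold(t1, "SIX2", k=3, seed=4)
        m2 = fit_threshold(t2, "SIX2", k=3, seed=4)
        assert m2.threshold == pytest.approx(c * m1.threshold, rel=1e-9)
        c1 = classify_cells(t1, m1)["SIX2_positive"]
        c2 = classify_cells(t2, m2)["SIX2_positive"]
        np.testing.assert_array_equal(c1.to_numpy(), c2.to_numpy())

    def test_class_counts_conserve_total(self):
        rng = np.random.default_rng(8)
        table = table_from_means(rng.uniform(0, 300, 150))
        model = fit_threshold(table, "SIX2", k=3, feature_mode="mean")
        classified = classify_cells(table, model)
        counts = classified["SIX2_class"].value_counts()
        assert counts.sum() == 150


class TestRatios:
    def test_all_positive_saturates_at_one(self):
        table = table_from_means([100.0] * 5)
        table["SIX2_positive"] = True
        rr = positive_ratio(table, "SIX2")
        assert rr.ratio == 1.0

    def test_counting_ratio(self):
        table = table_from_means(np.arange(200, dtype=float))
        table["SIX2_positive"] = np.arange(200) >= 103  # 97 positive
        rr = positive_ratio(table, "SIX2")
        assert rr.ratio == pytest.approx(0.485)
        assert rr.percentage == pytest.approx(48.5)

    def test_zero_nuclei_is_an_error(self):
        table = table_from_means([])
        table["SIX2_positive"] = pd.Series(dtype=bool)
        with pytest.raises(ValueError, match="zero nuclei"):
            positive_ratio(table, "SIX2")

    def test_pooled_vs_per_image_scope(self):
        t1 = table_from_means(np.zeros(10))
        t1["SIX2_positive"] = [True] * 5 + [False] * 5
        t2 = table_from_means(np.zeros(30))
        t2["SIX2_positive"] = [True] * 6 + [False] * 24
        pooled = positive_ratio([t1, t2], "SIX2", scope="pooled")
        assert pooled.ratio == pytest.approx(11 / 40)
        per = positive_ratio([t1, t2], "SIX2", scope="per_image")
        assert [r.ratio for r in per] == [pytest.approx(0.5), pytest.approx(0.2)]

    def test_proliferation_ratio_zero_when_no_signal_above_threshold(self):
        from nephroquant.quantify import ThresholdModel

        table = table_from_means([5.0, 6.0, 7.0]).rename(
            columns={"SIX2_mean": "EdU_mean", "SIX2_sd": "EdU_sd"}
        )
        model = ThresholdModel(
            channel="EdU",
            k=2,
            feature_mode="mean",
            centers=np.array([[6.0], [500.0]]),
            assignments=np.array([1, 1, 1]),
            threshold=250.0,
            class_names=("negative", "positive"),
            feature_mean=np.zeros(1),
            feature_sd=np.ones(1),
        )
        rr = proliferation_ratio(table, "EdU", model=model)
        assert rr.ratio == 0.0

    def test_proliferation_ratio_missing_channel(self):
        with pytest.raises(KeyError):
            proliferation_ratio(table_from_means([1.0, 2.0]), "EdU")
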