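import numpy as np
import pandas as pd
import pytest

from rseikit import data
from rseikit.engine import (
    GRADE_NAMES,
    NormalizedIndexStack,
    change_detect,
    class_ratios,
    combined_rate,
    compose_rsei,
    correlation_report,
    cumulative_rates,
    grade,
    percentile_normalize,
    run_spca,
    summary,
)
from rseikit.raster import RasterGrid


def grid(values, **kw):
    return RasterGrid(np.asarray(values, dtype=float), **kw)


def random_stack(rng, n=4, shape=(32, 32)):
    names = ["greenness", "wetness", "dryness", "heat"][:n]
    return NormalizedIndexStack(
        {name: grid(rng.random(shape)) for name in names}
    )


class TestPercentileNormalize:
    def test_linear_ramp_maps_to_unit_interval(self):
        g = grid(np.linspace(0, 100, 1000).reshape(10, 100))
        out = percentile_normalize(g)
        assert out.values.min() == 0.0
        assert out.values.max() == 1.0

    def test_constant_raster_maps_to_half(self):
        out = percentile_normalize(grid(np.full((5, 5), 42.0)))
        np.testing.assert_allclose(out.values, 0.5)

    def test_outlier_clipped_to_one(self):
        vals = np.linspace(0, 1, 999).tolist() + [10.0]
        out = percentile_normalize(grid(np.array(vals).reshape(40, 25)))
        assert out.values.ravel()[-1] == 1.0

    def test_empty_raster_raises(self):
        with pytest.raises(ValueError):
            percentile_normalize(grid(np.full((3, 3), np.nan)))

    def test_nodata_preserved(self):
        vals = np.linspace(0, 1, 16).reshape(4, 4)
        vals[0, 0] = np.nan
        out = percentile_normalize(grid(vals))
        assert np.isnan(out.values[0, 0])


class TestSPCA:
    def test_cumulative_of_published_rates(self):
        cum = cumulative_rates(data.PC_CONTRIBUTION_RATES_2019[:3])
        assert cum[-1] == pytest.approx(89.60, abs=1e-9)

    def test_two_perfectly_correlated_layers(self):
        base = np.linspace(0, 1, 64).reshape(8, 8)
        stack = NormalizedIndexStack({"a": grid(base), "b": grid(base)})
        pca = run_spca(stack)
        assert pca.contribution_rate[0] == pytest.approx(100.0)

    def test_orthonormal_loadings_and_rate_sum(self, rng):
        pca = run_spca(random_stack(rng))
        L = pca.loadings
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-9)
        assert pca.contribution_rate.sum() == pytest.approx(100.0, abs=1e-9)
        assert np.all(np.diff(pca.cumulative_rate) >= -1e-12)

    def test_reconstruction_exact_from_all_components(self, rng):
        stack = random_stack(rng)
        pca = run_spca(stack)
        X = stack.matrix()
        scores = (X - pca.means) @ pca.loadings
        back = scores @ pca.loadings.T + pca.means
        np.testing.assert_allclose(back, X, atol=1e-9)

    def test_matches_sklearn_pca(self, rng):
        # independent cross-check of eigenvalues and loading directions
        from sklearn.decomposition import PCA

        stack = random_stack(rng)
        ours = run_spca(stack)
        X = stack.matrix()
        ref = PCA(n_components=X.shape[1]).fit(X)
        # sklearn uses ddof=1; rescale
        ref_evals = ref.explained_variance_ * (len(X) - 1) / len(X)
        np.testing.assert_allclose(ours.eigenvalues, ref_evals, rtol=1e-8)
        for j in range(X.shape[1]):
            dot = abs(ref.components_[j] @ ours.loadings[:, j])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_eigenvalues_descending(self, rng):
        pca = run_spca(random_stack(rng, n=4))
        assert np.all(np.diff(pca.eigenvalues) <= 1e-12)


class TestComposeRSEI:
    def test_range_and_greenness_orientation(self, rng):
        stack = random_stack(rng)
        pca = run_spca(stack)
        rsei = compose_rsei(stack, pca)
        assert np.nanmin(rsei.values) == pytest.approx(0.0)
        assert np.nanmax(rsei.values) == pytest.approx(1.0)
        g = stack.layers["greenness"].values.ravel()
        r = np.corrcoef(g, rsei.values.ravel())[0, 1]
        assert r > 0

    def test_rank_invariance_of_rescaling(self, rng):
        stack = random_stack(rng)
        pca = run_spca(stack)
        rsei = compose_rsei(stack, pca)
        pc1 = pca.loadings[:, 0]
        if pca.loading("greenness", 0) < 0:
            pc1 = -pc1
        scores = (stack.matrix() - pca.means) @ pc1
        order_scores = np.argsort(scores)
        order_rsei = np.argsort(rsei.values[stack.valid_mask])
        np.testing.assert_array_equal(order_scores, order_rsei)


class TestGrade:
    def test_mean_061_is_good(self):
        table, classes = grade(grid([[0.61]]), pixel_area_km2=1.0)
        assert GRADE_NAMES[int(classes.values[0, 0])] == "Good"

    def test_all_medium(self):
        table, _ = grade(grid(np.full((10, 10), 0.5)), pixel_area_km2=0.01)
        assert combined_rate(table, ["Medium"]) == pytest.approx(100.0)

    def test_bin_edges(self):
        vals = np.array([[0.0, 0.19999, 0.2, 0.4], [0.6, 0.8, 1.0, 0.79999]])
        _, classes = grade(grid(vals), pixel_area_km2=1.0)
        want = np.array([[0, 0, 1, 2], [3, 4, 4, 3]], dtype=float)
        np.testing.assert_array_equal(classes.values, want)

    def test_area_conservation(self, rng):
        g = grid(rng.random((20, 20)), pixel_size=(10.0, 10.0))
        table, _ = grade(g)
        assert table["area_km2"].sum() == pytest.approx(400 * 1e-4)
        assert table["ratio_pct"].sum() == pytest.approx(100.0)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            grade(grid([[1.2]]), pixel_area_km2=1.0)


class TestCombinedRate:
    def test_published_2000_rate(self):
        t = data.grade_table_frame(2000)
        assert combined_rate(t, ["Good", "Excellent"]) == pytest.approx(4.05)

    def test_published_2014_rate(self):
        t = data.grade_table_frame(2014)
        assert combined_rate(t, ["Good", "Excellent"]) == pytest.approx(49.42)

    def test_empty_subset_is_zero(self):
        assert combined_rate(data.grade_table_frame(2019), []) == 0.0

    def test_unknown_grade_raises(self):
        with pytest.raises(KeyError):
            combined_rate(data.grade_table_frame(2019), ["Superb"])


class TestChangeDetect:
    def test_identical_inputs_all_unchanged(self, rng):
        g = grid(rng.random((10, 10)))
        table, _ = change_detect(g, g)
        assert table.set_index("class")["ratio_pct"]["Unchanged"] == 100.0

    def test_uniform_shifts(self):
        a = grid(np.full((5, 5), 0.4))
        table, _ = change_detect(a, grid(np.full((5, 5), 0.55)))
        assert table.set_index("class")["ratio_pct"]["Better"] == 100.0
        table, _ = change_detect(a, grid(np.full((5, 5), 0.25)))
        assert table.set_index("class")["ratio_pct"]["Worse"] == 100.0

    def test_threshold_boundary_is_unchanged(self):
        a = grid(np.full((3, 3), 0.5))
        b = grid(np.full((3, 3), 0.6))  # delta exactly +0.1
        table, _ = change_detect(a, b, threshold=0.1)
        assert table.set_index("class")["ratio_pct"]["Unchanged"] == 100.0

    def test_published_area_ratio(self):
        ratios = class_ratios(data.CHANGE_AREAS["2000-2007"],
                              data.STUDY_AREA_KM2)
        assert ratios["Worse"] == pytest.approx(47.93, abs=0.005)

    def test_shape_mismatch_raises(self):
        from rseikit.raster import CoregistrationError

        with pytest.raises(CoregistrationError):
            change_detect(grid(np.zeros((3, 3))), grid(np.zeros((4, 3))))


class TestReports:
    def test_self_correlation_one_and_oracle_mean(self, rng):
        stack = random_stack(rng)
        matrix, means = correlation_report(stack)
        for n in stack.names:
            assert matrix.loc[n, n] == pytest.approx(1.0)
        # independent loop oracle for the mean |r|
        corr = matrix.to_numpy()
        for i, n in enumerate(stack.names):
            vals = [abs(corr[i, j]) for j in range(len(stack.names)) if j != i]
            assert means[n] == pytest.approx(np.mean(vals), abs=1e-12)

    def test_independent_layers_nearly_uncorrelated(self, rng):
        stack = NormalizedIndexStack(
            {f"n{i}": grid(rng.random((100, 100))) for i in range(3)}
        )
        matrix, _ = correlation_report(stack)
        off = matrix.to_numpy()[np.triu_indices(3, 1)]
        assert np.all(np.abs(off) < 0.05)

    def test_summary_constant_layer_and_oracle(self, rng):
        vals = rng.random((8, 8))
        stack = NormalizedIndexStack(
            {"a": grid(np.full((8, 8), 0.3)), "b": grid(vals)}
        )
        t = summary(stack).set_index("index")
        assert t.loc["a", "mean"] == pytest.approx(0.3)
        assert t.loc["a", "sd"] == 0.0
        # two-pass oracle
        m = vals.sum() / vals.size
        sd = np.sqrt(((vals - m) ** 2).sum() / vals.size)
        assert t.loc["b", "mean"] == pytest.approx(m, abs=1e-12)
        assert t.loc["b", "sd"] == pytest.approx(sd, abs=1e-12)

    def test_summary_excludes_nodata(self, rng):
        vals = rng.random((6, 6))
        with_nan = vals.copy()
        with_nan[0, :] = np.nan
        a = NormalizedIndexStack({"x": grid(vals[1:]), "y": grid(vals[1:])})
        b = NormalizedIndexStack({"x": grid(with_nan), "y": grid(with_nan)})
        ta = summary(a).set_index("index")
        tb = summary(b).set_index("index")
        assert ta.loc["x", "mean"] == pytest.approx(tb.loc["x", "mean"])


class TestStackValidation:
    def test_rejects_unnormalized_layer(self, rng):
        with pytest.raises(ValueError):
            NormalizedIndexStack(
                {"a": grid(rng.random((4, 4))), "b": grid(rng.random((4, 4)) * 5)}
            )

    def test_union_nodata_mask(self, rng):
        a = rng.random((4, 4))
        b = rng.random((4, 4))
        a[0, 0] = np.nan
        b[3, 3] = np.nan
        stack = NormalizedIndexStack({"a": grid(a), "b": grid(b)})
        assert not stack.valid_mask[0, 0]
        assert not stack.valid_mask[3, 3]
        assert stack.valid_mask.sum() == 14
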