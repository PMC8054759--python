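import numpy as np
import pandas as pd
import pytest

from conftest import make_grid
from corridorscape.errors import EmptyDesignError, MissingLayerError
from corridorscape.evaluation import auc
from corridorscape.sdm import (
    TrainingDesign,
    extract_design,
    fit_bioclim,
    fit_model,
    fit_presence_background,
    load_model,
    predict_raster,
    save_model,
)


def design_from(X, y, names=None):
    X = np.asarray(X, dtype=float)
    names = names or tuple(f"p{i}" for i in range(X.shape[1]))
    return TrainingDesign(X, np.asarray(y), tuple(names))


def points_df(coords):
    return pd.DataFrame({"lon": [c[0] for c in coords], "lat": [c[1] for c in coords]})


class TestExtractDesign:
    def make_stack(self):
        a = make_grid(np.arange(9, dtype=float).reshape(3, 3), name="a")
        b = make_grid(10 + np.arange(9, dtype=float).reshape(3, 3), name="b")
        b.mask[0, 0] = True
        return {"a": a, "b": b}

    def test_nearest_cell_extraction(self):
        stack = self.make_stack()
        pres = points_df([(1.5, 1.5)])  # centre of cell (1, 1)
        absn = points_df([(2.5, 0.5)])  # centre of cell (2, 2)
        d = extract_design(pres, absn, stack)
        np.testing.assert_array_equal(d.X, [[4.0, 14.0], [8.0, 18.0]])
        np.testing.assert_array_equal(d.y, [1, 0])

    def test_masked_rows_dropped(self):
        stack = self.make_stack()
        pres = points_df([(0.5, 2.5), (1.5, 1.5)])  # first sits on b's masked cell
        d = extract_design(pres, points_df([(2.5, 0.5)]), stack)
        assert d.n_presence == 1

    def test_row_count_is_n_plus_m(self):
        stack = self.make_stack()
        pres = points_df([(1.5, 1.5), (2.5, 1.5)])
        absn = points_df([(0.5, 0.5), (1.5, 0.5), (2.5, 0.5)])
        d = extract_design(pres, absn, stack)
        assert len(d.y) == 5

    def test_no_usable_presences_is_error(self):
        stack = self.make_stack()
        with pytest.raises(EmptyDesignError):
            extract_design(points_df([(99.0, 99.0)]), points_df([(1.5, 1.5)]), stack)


class TestBioclim:
    def test_median_scores_one_and_outside_envelope_zero(self):
        # x at the empirical median (p = 0.5) scores 1; below the minimum, 0
        X = np.column_stack([np.arange(1, 5, dtype=float)])
        m = fit_bioclim(design_from(X, np.ones(4)))
        assert m.score(np.array([[2.5]]))[0] == pytest.approx(1.0)
        assert m.score(np.array([[0.5]]))[0] == 0.0

    def test_tail_score_fraction(self):
        # training values {1..5}, x=2: p = 2/5, score = 0.8
        X = np.column_stack([np.arange(1, 6, dtype=float)])
        m = fit_bioclim(design_from(X, np.ones(5)))
        assert m.score(np.array([[2.0]]))[0] == pytest.approx(0.8)

    def test_min_over_predictors_binds(self):
        X = np.column_stack([np.arange(1, 6, dtype=float), np.arange(1, 6, dtype=float)])
        m = fit_bioclim(design_from(X, np.ones(5)))
        assert m.score(np.array([[2.0, 3.0]]))[0] == pytest.approx(0.8)

    def test_constant_predictor_point_envelope(self):
        X = np.column_stack([np.full(4, 7.0), np.arange(4, dtype=float)])
        m = fit_bioclim(design_from(X, np.ones(4)))
        assert m.score(np.array([[7.0, 1.5]]))[0] > 0
        assert m.score(np.array([[7.1, 1.5]]))[0] == 0.0

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 2))
        Xq = rng.normal(size=(15, 2))
        m = fit_bioclim(design_from(X, np.ones(40)))
        Xt, Xqt = X.copy(), Xq.copy()
        Xt[:, 0] = np.exp(Xt[:, 0])
        Xqt[:, 0] = np.exp(Xqt[:, 0])
        mt = fit_bioclim(design_from(Xt, np.ones(40)))
        np.testing.assert_allclose(m.score(Xq), mt.score(Xqt))


class TestPresenceBackground:
    def separable_design(self):
        rng = np.random.default_rng(1)
        x_pres = rng.uniform(2.0, 3.0, size=100)
        x_abs = rng.uniform(0.0, 1.0, size=100)
        X = np.r_[x_pres, x_abs][:, None]
        y = np.r_[np.ones(100), np.zeros(100)]
        return design_from(X, y)

    @pytest.mark.parametrize("alg", ["GLM", "MAXENT", "RF"])
    def test_perfect_separation_gives_training_auc_one(self, alg):
        d = self.separable_design()
        m = fit_presence_background(d, alg, seed=0)
        s = m.score(d.X)
        assert auc(s[d.y == 1], s[d.y == 0]) == pytest.approx(1.0)

    def test_null_design_gives_chance_level_glm_auc(self):
        # label independent of the predictor: training AUC stays near 0.5
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(2000, 1))
            y = rng.integers(0, 2, size=2000)
            d = design_from(X, y)
            m = fit_presence_background(d, "GLM", seed=seed)
            s = m.score(d.X)
            assert 0.4 <= auc(s[y == 1], s[y == 0]) <= 0.6

    @pytest.mark.parametrize("alg", ["GLM", "MAXENT", "RF"])
    def test_same_seed_identical_scores(self, alg):
        d = self.separable_design()
        s1 = fit_presence_background(d, alg, seed=7).score(d.X)
        s2 = fit_presence_background(d, alg, seed=7).score(d.X)
        np.testing.assert_array_equal(s1, s2)

    @pytest.mark.parametrize("alg", ["BC", "GLM", "MAXENT", "RF"])
    def test_scores_in_unit_interval(self, alg):
        d = self.separable_design()
        s = fit_model(d, alg, seed=0).score(d.X)
        assert np.all((s >= 0) & (s <= 1))


class TestPredictRaster:
    def uniform_stack(self, value, mask=None):
        g = make_grid(np.full((4, 4), float(value)), mask=mask, name="a")
        return {"a": g}

    def test_bioclim_on_training_median_scores_one_everywhere(self):
        X = np.column_stack([np.arange(1, 5, dtype=float)])
        m = fit_bioclim(design_from(X, np.ones(4), names=("a",)))
        out = predict_raster(m, self.uniform_stack(2.5))
        np.testing.assert_allclose(out.values, 1.0)

    def test_mask_pattern_preserved(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 2] = True
        X = np.column_stack([np.arange(1, 6, dtype=float)])
        m = fit_bioclim(design_from(X, np.ones(5), names=("a",)))
        out = predict_raster(m, self.uniform_stack(3.0, mask=mask))
        np.testing.assert_array_equal(out.mask, mask)
        assert np.isnan(out.values[1, 2])

    def test_raster_scores_match_pointwise_scores(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 5, size=(10, 10))
        stack = {"a": make_grid(vals, name="a")}
        labels = (rng.random(200) < 0.5).astype(int)
        labels[0], labels[1] = 1, 0
        d = design_from(rng.uniform(0, 5, size=(200, 1)), labels, names=("a",))
        m = fit_presence_background(d, "GLM", seed=0)
        out = predict_raster(m, stack)
        idx = rng.integers(0, 10, size=(100, 2))
        direct = m.score(vals[idx[:, 0], idx[:, 1]][:, None])
        np.testing.assert_allclose(out.values[idx[:, 0], idx[:, 1]], direct, atol=1e-12)

    def test_missing_layer_raises(self):
        X = np.column_stack([np.arange(1, 6, dtype=float)])
        m = fit_bioclim(design_from(X, np.ones(5), names=("elevation",)))
        with pytest.raises(MissingLayerError):
            predict_raster(m, self.uniform_stack(3.0))


@pytest.mark.parametrize("alg", ["BC", "GLM", "MAXENT", "RF"])
def test_model_archive_round_trip(tmp_path, alg):
    rng = np.random.default_rng(3)
    X = rng.normal(size=(80, 3))
    y = (X[:, 0] + rng.normal(scale=0.5, size=80) > 0).astype(int)
    y[:5] = 1  # both classes guaranteed
    d = design_from(X, y)
    m = fit_model(d, alg, seed=1)
    save_model(tmp_path / "m.json", m)
    back = load_model(tmp_path / "m.json")
    np.testing.assert_allclose(back.score(X), m.score(X))
    assert back.algorithm == alg
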