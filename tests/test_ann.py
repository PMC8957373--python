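"""Shallow network: initialization, forward pass, Levenberg-Marquardt
training, weighted loss, pixelwise prediction."""

import numpy as np
import pytest
from scipy import linalg

from oxymosaic.ann import ShallowANNRegressor, predict_map
from oxymosaic.mosaic import DataCube


def make_data(rng, n=2000, noise=0.0):
    X = rng.uniform(0.6, 1.4, (n, 16))
    y = 40 + 25 * (X[:, 2] - 1) - 15 * (X[:, 9] - 1) + rng.normal(0, noise, n)
    return X, y


class TestInitialization:
    def test_same_seed_identical(self):
        a = ShallowANNRegressor(n_hidden=3, random_state=5).initialize()
        b = ShallowANNRegressor(n_hidden=3, random_state=5).initialize()
        np.testing.assert_array_equal(a.W1_, b.W1_)
        np.testing.assert_array_equal(a.W2_, b.W2_)

    def test_neighboring_seeds_differ(self):
        a = ShallowANNRegressor(n_hidden=3, random_state=5).initialize()
        b = ShallowANNRegressor(n_hidden=3, random_state=6).initialize()
        assert not np.allclose(a.W1_, b.W1_)

    def test_parameter_count(self):
        m = ShallowANNRegressor(n_hidden=3)
        assert m.n_parameters_ == 3 * 16 + 3 + 3 + 1 == 55

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            ShallowANNRegressor(n_hidden=0).initialize()


class TestForward:
    def test_hand_computed_single_hidden_unit(self):
        w1 = np.linspace(-0.5, 0.5, 16)
        model = ShallowANNRegressor.from_weights(W1=w1[None, :], b1=[0.2],
                                                 W2=[3.0], b2=1.5)
        x = np.linspace(0.8, 1.2, 16)
        expected = 3.0 * np.tanh(float(w1 @ x) + 0.2) + 1.5
        assert model.predict(x[None, :])[0] == pytest.approx(expected, abs=1e-12)

    def test_constant_network(self):
        model = ShallowANNRegressor.from_weights(
            W1=np.zeros((3, 16)), b1=np.zeros(3), W2=np.zeros(3), b2=50.0)
        out = model.predict(np.random.default_rng(0).uniform(0, 2, (10, 16)))
        np.testing.assert_allclose(out, 50.0)

    def test_batch_equals_per_row(self, rng):
        model = ShallowANNRegressor(n_hidden=4, random_state=0).initialize()
        X = rng.uniform(0.5, 1.5, (20, 16))
        batch = model.predict(X)
        loop = np.array([model.predict(row[None, :])[0] for row in X])
        np.testing.assert_allclose(batch, loop, atol=1e-12)

    def test_wrong_width_rejected(self, rng):
        model = ShallowANNRegressor(n_hidden=2, random_state=0).initialize()
        with pytest.raises(ValueError, match="channels"):
            model.predict(rng.uniform(0, 1, (5, 8)))


class TestJacobianAndLMStep:
    def test_jacobian_matches_finite_differences(self, rng):
        model = ShallowANNRegressor(n_hidden=3, random_state=1).initialize()
        xs = rng.uniform(-1, 1, (7, 16))
        theta = model._pack()
        _, u = model._forward_scaled(xs)
        jac = model._jacobian(xs, u)
        eps = 1e-6
        for p in range(theta.size):
            th = theta.copy()
            th[p] += eps
            model._unpack(th)
            up, _ = model._forward_scaled(xs)
            th[p] -= 2 * eps
            model._unpack(th)
            dn, _ = model._forward_scaled(xs)
            model._unpack(theta)
            np.testing.assert_allclose(jac[:, p], (up - dn) / (2 * eps),
                                       atol=1e-6)

    def test_step_limits_gradient_descent_and_gauss_newton(self, rng):
        # mu -> inf: step direction approaches the negative gradient;
        # mu -> 0: step approaches the Gauss-Newton solution
        model = ShallowANNRegressor(n_hidden=2, random_state=3).initialize()
        xs = rng.uniform(-1, 1, (50, 16))
        ts = rng.uniform(-1, 1, 50)
        ys, u = model._forward_scaled(xs)
        r = ys - ts
        jac = model._jacobian(xs, u)
        grad = jac.T @ r
        jtj = jac.T @ jac
        p = jtj.shape[0]

        big = linalg.solve(jtj + 1e12 * np.eye(p), -grad)
        cos = big @ (-grad) / (np.linalg.norm(big) * np.linalg.norm(grad))
        assert cos > 0.999999

        small = linalg.solve(jtj + 1e-12 * np.eye(p), -grad)
        gn = linalg.lstsq(jac, -r)[0]
        np.testing.assert_allclose(small, gn, rtol=1e-4, atol=1e-8)


class TestTraining:
    def test_recovers_frozen_teacher_network(self, rng):
        teacher = ShallowANNRegressor.from_weights(
            W1=rng.normal(0, 1.5, (3, 16)), b1=rng.normal(0, 0.5, 3),
            W2=rng.normal(0, 40, 3), b2=50.0)
        X = rng.uniform(0.7, 1.3, (4000, 16))
        y = teacher.predict(X)
        student = ShallowANNRegressor(n_hidden=3, random_state=0).fit(X, y)
        tr = student.split_indices_["train"]
        assert np.mean((student.predict(X[tr]) - y[tr]) ** 2) < 1e-6

    def test_linear_target_fit_with_one_node(self, rng):
        X, y = make_data(rng, noise=0.0)
        model = ShallowANNRegressor(n_hidden=1, random_state=2).fit(X, y)
        va = model.split_indices_["val"]
        rmse = np.sqrt(np.mean((model.predict(X[va]) - y[va]) ** 2))
        assert rmse < 0.1

    def test_train_loss_not_above_initial(self, rng):
        X, y = make_data(rng, n=800, noise=5.0)
        model = ShallowANNRegressor(n_hidden=3, random_state=4,
                                    split_random_state=11, max_epochs=30)
        model.fit(X, y)
        init = ShallowANNRegressor(n_hidden=3, random_state=4).initialize()
        # replay initial loss in the fitted model's scaled space
        tr = model.split_indices_["train"]
        xs = model.input_scaler_.transform(X[tr])
        ts = model.target_scaler_.transform(y[tr, None]).ravel()
        init_loss = np.mean((init._forward_scaled(xs)[0] - ts) ** 2)
        final_loss = np.mean((model._forward_scaled(xs)[0] - ts) ** 2)
        assert final_loss <= init_loss

    def test_uniform_weights_match_unweighted(self, rng):
        X, y = make_data(rng, n=600, noise=2.0)
        kw = dict(n_hidden=2, random_state=7, max_epochs=25)
        a = ShallowANNRegressor(**kw).fit(X, y)
        b = ShallowANNRegressor(**kw).fit(X, y, sample_weight=np.ones_like(y))
        np.testing.assert_allclose(a.predict(X[:20]), b.predict(X[:20]),
                                   atol=1e-10)

    def test_zero_weighted_samples_are_ignored(self, rng):
        # corrupt a slice of targets but zero their weights: the fit
        # should match training without those rows entirely
        X, y = make_data(rng, n=900, noise=0.0)
        y_bad = y.copy()
        bad = slice(0, 100)
        y_bad[bad] = 999.0
        w = np.ones_like(y)
        w[bad] = 0.0
        model = ShallowANNRegressor(n_hidden=2, random_state=9, max_epochs=40)
        model.fit(X, y_bad, sample_weight=w)
        good = np.arange(100, 900)
        rmse = np.sqrt(np.mean((model.predict(X[good]) - y[good]) ** 2))
        assert rmse < 0.5

    def test_split_fractions_and_exclusivity(self, rng):
        X, y = make_data(rng, n=1000)
        model = ShallowANNRegressor(n_hidden=1, random_state=0, max_epochs=3)
        model.fit(X, y)
        idx = model.split_indices_
        assert len(idx["val"]) == 150 and len(idx["test"]) == 150
        assert len(idx["train"]) == 700
        all_idx = np.concatenate([idx["train"], idx["val"], idx["test"]])
        assert np.array_equal(np.sort(all_idx), np.arange(1000))

    def test_split_seed_fixes_split_across_reinits(self, rng):
        X, y = make_data(rng, n=500)
        a = ShallowANNRegressor(n_hidden=1, random_state=1,
                                split_random_state=99, max_epochs=2).fit(X, y)
        b = ShallowANNRegressor(n_hidden=1, random_state=2,
                                split_random_state=99, max_epochs=2).fit(X, y)
        np.testing.assert_array_equal(a.split_indices_["train"],
                                      b.split_indices_["train"])
        assert not np.allclose(a.W1_, b.W1_)

    def test_serialization_roundtrip(self, rng):
        X, y = make_data(rng, n=400)
        model = ShallowANNRegressor(n_hidden=2, random_state=0, max_epochs=5)
        model.fit(X, y)
        back = ShallowANNRegressor.from_dict(model.to_dict())
        np.testing.assert_allclose(back.predict(X[:10]), model.predict(X[:10]),
                                   atol=1e-12)


class TestSklearnCompat:
    def test_get_set_params_clone(self):
        from sklearn.base import clone
        model = ShallowANNRegressor(n_hidden=5, random_state=3)
        params = model.get_params()
        assert params["n_hidden"] == 5
        cloned = clone(model)
        assert cloned.get_params() == params

    def test_works_in_grid_search(self, rng):
        from sklearn.model_selection import GridSearchCV
        X, y = make_data(rng, n=400, noise=1.0)
        gs = GridSearchCV(ShallowANNRegressor(random_state=0, max_epochs=10),
                          {"n_hidden": [1, 2]}, cv=2)
        gs.fit(X, y)
        assert gs.best_params_["n_hidden"] in (1, 2)


class TestPredictMap:
    def test_homogeneous_cube_constant_map(self, rng):
        model = ShallowANNRegressor(n_hidden=2, random_state=0).initialize()
        spec = rng.uniform(0.2, 1.0, 16)
        cube = DataCube(values=np.broadcast_to(spec, (6, 6, 16)).copy(),
                        stage="reflectance")
        out = predict_map(model, cube)
        single = model.predict((spec / spec.mean())[None, :])[0]
        np.testing.assert_allclose(out, single, atol=1e-12)

    def test_masked_pixels_are_nan(self, rng):
        model = ShallowANNRegressor(n_hidden=2, random_state=0).initialize()
        cube = DataCube(values=rng.uniform(0.2, 1.0, (6, 6, 16)),
                        stage="reflectance")
        mask = np.zeros((6, 6), dtype=bool)
        mask[2:4, 2:4] = True
        out = predict_map(model, cube, mask)
        assert np.isnan(out[~mask]).all() and np.isfinite(out[mask]).all()

    def test_empty_mask_gives_empty_map(self, rng):
        model = ShallowANNRegressor(n_hidden=2, random_state=0).initialize()
        cube = DataCube(values=rng.uniform(0.2, 1.0, (6, 6, 16)),
                        stage="reflectance")
        assert np.isnan(predict_map(model, cube, np.zeros((6, 6), bool))).all()


class TestPredictMapOnSimulation:
    def test_two_region_scene_medians_near_truth(self, desk_cohort, desk_loso):
        """A LOSO-trained network applied pixelwise to a synthetic
        two-region scene (SO2 20% / 80%) recovers both region medians
        to within 5%."""
        from oxymosaic.synthetic import (forward_reflectance, sensor_response,
                                         white_response)
        model = desk_loso.models["S00"]
        p = desk_cohort.subjects["S01"]  # in-distribution optics
        bank = desk_cohort.bank
        so2 = np.where(np.arange(16)[:, None] < 8, 20.0, 80.0) * np.ones((1, 16))
        refl = forward_reflectance(so2 / 100.0, np.full((16, 16), p.f_rbc),
                                   np.full((16, 16), p.melanin),
                                   p.path_length_mm, p.scatter_scale)
        channels = sensor_response(refl, bank) / white_response(bank)
        cube = DataCube(values=channels, stage="reflectance")
        out = predict_map(model, cube)
        assert abs(np.median(out[:8]) - 20.0) < 5.0
        assert abs(np.median(out[8:]) - 80.0) < 5.0

    def test_full_frame_map_is_fast(self, rng):
        # pixelwise inference over a full 512x272 cube is a couple of
        # matrix products; it should take far less than a second
        import time
        model = ShallowANNRegressor(n_hidden=3, random_state=0).initialize()
        cube = DataCube(values=rng.uniform(0.2, 1.0, (272, 512, 16)),
                        stage="reflectance")
        t0 = time.perf_counter()
        predict_map(model, cube)
        assert time.perf_counter() - t0 < 5.0
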