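"""Multiblock PLS fit/predict contracts and algebraic identities."""

import numpy as np
import pytest

from blockpls import BlockPartition, Dataset, FitOptions, autoscale, fit_mbpls
from blockpls.mbpls import fitted_coefficients, predict, predict_components

from _oracles import (
    mbpls_straightline,
    nipals_pls1,
    nipals_pls1_predict,
    ols_coefficients,
)
from conftest import make_dataset, random_fit


def _scaled(rng, n=12, p=8):
    ds = make_dataset(rng, n=n, p=p)
    scaled, params = autoscale(ds)
    return ds, scaled, params


class TestFit:
    def test_two_block_toy_matches_straightline_transcription(self, rng):
        ds, scaled, params = _scaled(rng, n=4, p=4)
        blocks = [np.array([0, 1]), np.array([2, 3])]
        part = BlockPartition(labels=np.array([1, 1, 2, 2]))
        model = fit_mbpls(scaled, part, FitOptions(n_components=1))
        ref = mbpls_straightline(scaled.X, scaled.y, blocks, 1)
        for c in range(2):
            np.testing.assert_allclose(model.U[c][:, 0], ref["u"][0][c], atol=1e-10)
        np.testing.assert_allclose(model.W[:, 0], ref["w"][0], atol=1e-10)
        np.testing.assert_allclose(model.T[:, 0], ref["t"][0], atol=1e-10)
        np.testing.assert_allclose(model.P[:, 0], ref["p"][0], atol=1e-10)
        assert model.q[0] == pytest.approx(ref["q"][0], abs=1e-10)

    def test_multi_component_matches_straightline(self, rng):
        ds, scaled, params = _scaled(rng, n=15, p=9)
        part = BlockPartition(labels=np.array([1, 1, 1, 2, 2, 3, 3, 3, 3]))
        model = fit_mbpls(scaled, part, FitOptions(n_components=3))
        ref = mbpls_straightline(scaled.X, scaled.y, part.blocks(), 3)
        for r in range(3):
            np.testing.assert_allclose(model.W[:, r], ref["w"][r], atol=1e-10)
            np.testing.assert_allclose(model.T[:, r], ref["t"][r], atol=1e-10)
            assert model.q[r] == pytest.approx(ref["q"][r], abs=1e-10)

    def test_orthogonal_response_gives_zero_components_and_mean_prediction(self):
        # y constructed in the null space of [X | 1]' so every covariance is 0
        rng = np.random.default_rng(5)
        X = rng.standard_normal((8, 3))
        Xc = X - X.mean(axis=0)
        basis = np.linalg.svd(np.column_stack([Xc, np.ones(8)]).T)[2][4:]
        y = basis[0] * 3.0 + 42.0  # orthogonal direction, shifted
        ds = Dataset(
            X=X,
            sample_ids=[f"s{i}" for i in range(8)],
            variable_ids=list("abc"),
            y=y,
        )
        scaled, params = autoscale(ds)
        part = BlockPartition(labels=np.array([1, 1, 2]))
        model = fit_mbpls(scaled, part, FitOptions(n_components=2), scaling=params)
        assert model.n_components == 0
        np.testing.assert_allclose(predict(model, ds), np.full(8, y.mean()), atol=1e-8)
        np.testing.assert_array_equal(fitted_coefficients(model), np.zeros(3))

    def test_partition_mismatch_errors(self, rng):
        _, scaled, _ = _scaled(rng)
        with pytest.raises(ValueError, match="partition"):
            fit_mbpls(scaled, BlockPartition(labels=np.ones(3, dtype=int)))


class TestSingleBlockEquivalence:
    @pytest.mark.parametrize("n_components", [1, 2, 3])
    def test_matches_nipals_pls1(self, rng, n_components):
        for _ in range(10):
            ds, scaled, params = _scaled(rng, n=10, p=8)
            part = BlockPartition.single_block(8)
            model = fit_mbpls(
                scaled, part, FitOptions(n_components=n_components), scaling=params
            )
            W, P, q = nipals_pls1(scaled.X, scaled.y, n_components)
            # fitted values
            ref_fit = nipals_pls1_predict(scaled.X, W, P, q)
            got_fit = predict(model, ds)
            np.testing.assert_allclose(
                got_fit, ref_fit * params.y_sd + params.y_mean, atol=1e-8
            )
            # held-out predictions
            Xn = rng.standard_normal((6, 8))
            new = Dataset(
                X=Xn,
                sample_ids=[f"h{i}" for i in range(6)],
                variable_ids=ds.variable_ids,
            )
            ref = nipals_pls1_predict((Xn - params.x_mean) / params.x_sd, W, P, q)
            np.testing.assert_allclose(
                predict(model, new), ref * params.y_sd + params.y_mean, atol=1e-8
            )


class TestPredict:
    def test_training_predictions_equal_fitted_values(self, rng):
        for _ in range(5):
            model, scaled, part = random_fit(rng)
            fitted_scaled = model.T @ model.q
            expect = fitted_scaled * model.scaling.y_sd + model.scaling.y_mean
            raw = Dataset(
                X=scaled.X * model.scaling.x_sd + model.scaling.x_mean,
                sample_ids=scaled.sample_ids,
                variable_ids=scaled.variable_ids,
            )
            np.testing.assert_allclose(predict(model, raw), expect, atol=1e-10)

    def test_variable_mismatch_errors_with_ids(self, rng):
        model, scaled, _ = random_fit(rng, n=10, p=6)
        wrong = Dataset(
            X=np.zeros((3, 6)),
            sample_ids=list("abc"),
            variable_ids=[f"other{j}" for j in range(6)],
        )
        with pytest.raises(ValueError, match="variable mismatch"):
            predict(model, wrong)

    def test_block_relabeling_invariance(self, rng):
        ds, scaled, params = _scaled(rng, n=14, p=10)
        labels = np.array([1, 1, 1, 2, 2, 3, 3, 3, 3, 3])
        perm = {1: 3, 2: 1, 3: 2}
        relabeled = np.array([perm[v] for v in labels])
        new = Dataset(
            X=rng.standard_normal((5, 10)),
            sample_ids=[f"n{i}" for i in range(5)],
            variable_ids=ds.variable_ids,
        )
        preds = []
        for lab in (labels, relabeled):
            model = fit_mbpls(
                scaled,
                BlockPartition(labels=lab),
                FitOptions(n_components=2),
                scaling=params,
            )
            preds.append(predict(model, new))
        np.testing.assert_allclose(preds[0], preds[1], atol=1e-10)

    def test_variable_reordering_invariance(self, rng):
        ds, scaled, params = _scaled(rng, n=14, p=10)
        labels = np.array([1, 1, 1, 1, 1, 2, 2, 2, 2, 2])
        order = rng.permutation(10)
        new = Dataset(
            X=rng.standard_normal((5, 10)),
            sample_ids=[f"n{i}" for i in range(5)],
            variable_ids=ds.variable_ids,
        )
        m1 = fit_mbpls(
            scaled, BlockPartition(labels=labels), FitOptions(n_components=2),
            scaling=params,
        )
        scaled_perm = Dataset(
            X=scaled.X[:, order],
            sample_ids=scaled.sample_ids,
            variable_ids=[scaled.variable_ids[j] for j in order],
            y=scaled.y,
        )
        params_perm = type(params)(
            x_mean=params.x_mean[order],
            x_sd=params.x_sd[order],
            y_mean=params.y_mean,
            y_sd=params.y_sd,
        )
        m2 = fit_mbpls(
            scaled_perm,
            BlockPartition(labels=labels[order]),
            FitOptions(n_components=2),
            scaling=params_perm,
        )
        new_perm = new.select_variables(order)
        np.testing.assert_allclose(predict(m1, new), predict(m2, new_perm), atol=1e-10)


class TestProperties:
    def test_super_score_orthogonality_and_deflation_exactness(self, rng):
        for _ in range(20):
            model, scaled, _ = random_fit(rng)
            T = model.T
            for r in range(model.n_components):
                for s in range(r + 1, model.n_components):
                    bound = 1e-8 * np.linalg.norm(T[:, r]) * np.linalg.norm(T[:, s])
                    assert abs(T[:, r] @ T[:, s]) <= bound
            # replay the component loop from the stored weights: the recovered
            # scores must match the stored ones and the final residual plus the
            # rank-one contributions must reconstruct the scaled X
            E = scaled.X.copy()
            blocks = model.partition.blocks()
            sizes = model.block_sizes.astype(float)
            T_replay = np.zeros_like(T)
            for r in range(model.n_components):
                S = np.column_stack(
                    [E[:, idx] @ model.U[c][:, r] / sizes[c] for c, idx in enumerate(blocks)]
                )
                t = S @ model.W[:, r]
                T_replay[:, r] = t
                E = E - np.outer(t, model.P[:, r])
            np.testing.assert_allclose(T_replay, T, atol=1e-10)
            np.testing.assert_allclose(E + T_replay @ model.P.T, scaled.X, atol=1e-10)

    def test_residual_norm_nonincreasing(self, rng):
        model, scaled, _ = random_fit(rng, n=20, p=15, n_components=4)
        f = scaled.y.copy()
        norms = [np.linalg.norm(f)]
        for r in range(model.n_components):
            f = f - model.T[:, r] * model.q[r]
            norms.append(np.linalg.norm(f))
        assert np.all(np.diff(norms) <= 1e-10)


class TestFittedCoefficients:
    def test_reproduces_predictions_on_new_rows(self, rng):
        for _ in range(5):
            model, scaled, _ = random_fit(rng)
            b = fitted_coefficients(model)
            Xn = rng.standard_normal((20, model.p))
            new = Dataset(
                X=Xn * model.scaling.x_sd + model.scaling.x_mean,
                sample_ids=[f"n{i}" for i in range(20)],
                variable_ids=model.variable_ids,
            )
            via_predict = predict(model, new)
            via_coef = (Xn @ b) * model.scaling.y_sd + model.scaling.y_mean
            assert np.abs(via_predict - via_coef).max() <= 1e-8

    def test_full_rank_full_components_recovers_ols(self, rng):
        ds, scaled, params = _scaled(rng, n=30, p=5)
        part = BlockPartition.single_block(5)
        model = fit_mbpls(scaled, part, FitOptions(n_components=5), scaling=params)
        b = fitted_coefficients(model)
        ref = ols_coefficients(scaled.X, scaled.y)
        np.testing.assert_allclose(b, ref, atol=1e-6)


class TestSerialization:
    def test_model_dict_round_trip_preserves_predictions(self, rng):
        from blockpls.mbpls import MbplsModel

        model, scaled, _ = random_fit(rng, n=15, p=10, n_blocks=3)
        back = MbplsModel.from_dict(model.to_dict())
        new = Dataset(
            X=rng.standard_normal((4, 10)),
            sample_ids=list("wxyz"),
            variable_ids=model.variable_ids,
        )
        np.testing.assert_allclose(predict(model, new), predict(back, new), atol=1e-12)
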