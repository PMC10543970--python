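import math

import numpy as np
import pandas as pd
import pytest

from fermsense import (
    AnnModel,
    AnnSpec,
    FitGrid,
    MinMaxNormalizer,
    evaluate,
    grid_search,
    logsig,
    predict_growth_rate_chain,
    reference_grid,
    select_best,
    split_dataset,
    tansig,
    train_ann,
)
from fermsense.ann import forward_normalized, pack


def tiny_model(w1, b1, w2, b2, n_in, mins=None, maxs=None):
    theta = pack(np.asarray(w1, float), np.asarray(b1, float),
                 np.asarray(w2, float), b2)
    return AnnModel(
        theta=theta,
        n_inputs=n_in,
        n_hidden=np.asarray(w1).shape[0],
        engine="lm",
        x_norm=MinMaxNormalizer(mins or [0.0] * n_in, maxs or [1.0] * n_in),
        y_norm=MinMaxNormalizer([0.0], [1.0]),
    )


class TestNormalization:
    def test_unit_range_unchanged(self):
        x = np.array([[0.0, 0.2], [0.5, 1.0], [1.0, 0.0]])
        norm = MinMaxNormalizer.fit(x)
        np.testing.assert_allclose(norm.transform(x), x)

    def test_round_trip_exact(self, rng):
        x = rng.normal(3, 10, size=(40, 5))
        norm = MinMaxNormalizer.fit(x)
        np.testing.assert_allclose(norm.inverse(norm.transform(x)), x, atol=1e-12)

    def test_out_of_range_passes_through_unclipped(self):
        train = np.array([[0.0], [10.0]])
        norm = MinMaxNormalizer.fit(train)
        out = norm.transform(np.array([[-5.0], [15.0]]))
        # reference: (x - min)/(max - min), no clipping
        np.testing.assert_allclose(out.ravel(), [-0.5, 1.5])

    def test_constant_feature_named(self):
        x = np.column_stack([np.arange(10.0), np.full(10, 2.0)])
        with pytest.raises(ValueError, match="tcd_au"):
            MinMaxNormalizer.fit(x, names=["our", "tcd_au"])


class TestSplit:
    def test_eighty_rows_give_60_10_10(self):
        tr, va, te = split_dataset(80, seed=0)
        assert (len(tr), len(va), len(te)) == (60, 10, 10)

    def test_partition_is_disjoint_and_complete(self):
        tr, va, te = split_dataset(53, seed=3)
        allidx = np.concatenate([tr, va, te])
        assert len(set(allidx)) == 53
        assert sorted(allidx) == list(range(53))

    def test_determinism_and_entropy(self):
        a = split_dataset(40, seed=5)
        b = split_dataset(40, seed=5)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)
        differing = sum(
            not np.array_equal(split_dataset(40, seed=s)[0], a[0])
            for s in range(6, 106)
        )
        assert differing > 90

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            split_dataset(20, fractions=(0.5, 0.2, 0.2))


class TestForward:
    def test_zero_weights_give_mid_output(self):
        m = tiny_model(np.zeros((3, 2)), np.zeros(3), np.zeros(3), 0.0, 2)
        out = m.forward(np.array([[0.4, 0.9]]))
        assert out[0] == pytest.approx(0.5)  # logsig(0) in unit output range

    def test_activation_limits(self):
        assert tansig(0.0) == 0.0
        assert tansig(50.0) == pytest.approx(1.0, abs=1e-12)
        assert tansig(-50.0) == pytest.approx(-1.0, abs=1e-12)
        assert logsig(0.0) == 0.5

    def test_hand_computed_scalar_oracle(self):
        """2 inputs, 1 hidden unit, weights (1, -1), output weight 2, at
        normalized x = (0.3, 0.1): scalar chain computed with math.*"""
        z1 = 1.0 * 0.3 + (-1.0) * 0.1
        a1 = math.tanh(z1)
        expect = 1.0 / (1.0 + math.exp(-2.0 * a1))
        m = tiny_model([[1.0, -1.0]], [0.0], [2.0], 0.0, 2)
        out = m.forward(np.array([[0.3, 0.1]]))
        assert out[0] == pytest.approx(expect, abs=1e-14)

    def test_dimension_mismatch_rejected(self):
        m = tiny_model([[1.0, -1.0]], [0.0], [2.0], 0.0, 2)
        with pytest.raises(ValueError, match="inputs"):
            m.forward(np.ones((3, 5)))

    def test_normalized_output_within_unit_interval(self, rng):
        theta = rng.normal(size=4 * 3 + 3 + 3 + 1)
        out, _, _ = forward_normalized(theta, rng.uniform(0, 1, (20, 4)), 3)
        assert np.all((out > 0) & (out < 1))

    def test_json_round_trip(self, rng, tmp_path):
        x = rng.uniform(0, 1, (60, 3))
        y = x @ [1.0, -0.5, 0.2] + 2.0
        spec = AnnSpec(n_inputs=3, n_hidden=2, engine="lm", restarts=2, seed=0)
        model = train_ann(spec, x, y, feature_names=["a", "b", "c"], output_name="y")
        model.to_json(tmp_path / "m.json")
        back = AnnModel.from_json(tmp_path / "m.json")
        np.testing.assert_allclose(back.forward(x), model.forward(x), atol=1e-12)
        assert back.feature_names == ("a", "b", "c")


class TestEvaluate:
    def test_perfect_and_mean_predictions(self, rng):
        y = rng.normal(size=30)
        assert evaluate(y, y) == (0.0, 1.0)
        rmse, r2 = evaluate(y, np.full_like(y, y.mean()))
        assert r2 == pytest.approx(0.0, abs=1e-12)
        assert rmse == pytest.approx(y.std(), rel=1e-12)

    def test_matches_brute_force(self, rng):
        y, p = rng.normal(size=50), rng.normal(size=50)
        rmse, r2 = evaluate(y, p)
        assert rmse == pytest.approx(np.sqrt(np.mean((y - p) ** 2)), rel=1e-12)
        assert r2 == pytest.approx(
            1 - np.sum((y - p) ** 2) / np.sum((y - y.mean()) ** 2), rel=1e-12
        )

    def test_zero_variance_flagged(self):
        rmse, r2 = evaluate(np.ones(5), np.zeros(5))
        assert rmse == 1.0 and np.isnan(r2)


class TestSelection:
    def test_reference_grid_selections(self):
        """The packaged grids select LM/8 (RMSE 0.74), LM/6 (0.40) and
        SCG/10 (0.081)."""
        sel = select_best(reference_grid("batch_biomass"))
        assert (sel.engine, sel.n_hidden) == ("lm", 8)
        assert (sel.rmse, sel.r2) == (0.74, 0.98)
        sel = select_best(reference_grid("fedbatch_biomass"))
        assert (sel.engine, sel.n_hidden) == ("lm", 6)
        assert (sel.rmse, sel.r2) == (0.40, 0.99)
        sel = select_best(reference_grid("growth_rate"))
        assert (sel.engine, sel.n_hidden) == ("scg", 10)
        assert (sel.rmse, sel.r2) == (0.081, 0.90)

    def test_tie_breaks_fewer_nodes_then_engine_order(self):
        grid = FitGrid(
            pd.DataFrame(
                {
                    "engine": ["br", "lm", "scg", "lm"],
                    "n_hidden": [4, 4, 6, 2],
                    "rmse": [0.5, 0.5, 0.5, 0.5],
                    "r2": [0.9, 0.9, 0.9, 0.9],
                }
            )
        )
        sel = select_best(grid)
        assert (sel.engine, sel.n_hidden) == ("lm", 2)

    def test_single_cell_and_empty(self):
        one = FitGrid(
            pd.DataFrame(
                {"engine": ["scg"], "n_hidden": [3], "rmse": [1.0], "r2": [0.5]}
            )
        )
        assert select_best(one).engine == "scg"
        empty = FitGrid(
            pd.DataFrame(
                {"engine": [], "n_hidden": [], "rmse": [], "r2": []}
            )
        )
        with pytest.raises(ValueError, match="populated"):
            select_best(empty)


class TestGridSearch:
    def test_sweep_counts_and_determinism(self, rng):
        x = rng.uniform(0, 1, (60, 2))
        y = np.sin(3 * x[:, 0]) + x[:, 1]
        g1 = grid_search(x, y, engines=("scg", "lm"), nodes=(2, 3), seed=7,
                         restarts=2, max_epochs=60)
        assert len(g1.frame) == 4
        assert g1.frame.rmse.notna().all()
        g2 = grid_search(x, y, engines=("scg", "lm"), nodes=(2, 3), seed=7,
                         restarts=2, max_epochs=60)
        pd.testing.assert_frame_equal(g1.frame, g2.frame)

    def test_noiseless_data_reaches_noise_floor(self, rng):
        x = rng.uniform(0, 1, (80, 2))
        y = 2.0 + x[:, 0] + 0.5 * x[:, 1]
        g = grid_search(x, y, engines=("lm",), nodes=(3,), seed=1, restarts=3)
        assert g.frame.rmse.min() < 1e-2


class TestGrowthRateChain:
    def _models(self, rng):
        x = rng.uniform(0, 1, (80, 2))
        y_b = 1 + x[:, 0]
        fed = train_ann(
            AnnSpec(n_inputs=2, n_hidden=2, engine="lm", restarts=2, seed=0),
            x, y_b, feature_names=["do_pct", "tcd_au"],
        )
        xg = np.column_stack([x, fed.forward(x)])
        y_g = 0.2 * xg[:, 2]
        growth = train_ann(
            AnnSpec(n_inputs=3, n_hidden=2, engine="lm", restarts=2, seed=1),
            xg, y_g,
            feature_names=["do_pct", "tcd_au", "ann_predicted_biomass"],
        )
        return fed, growth

    def test_chain_equals_manual_two_step(self, rng):
        fed, growth = self._models(rng)
        frame = pd.DataFrame(
            {"do_pct": rng.uniform(0, 1, 25), "tcd_au": rng.uniform(0, 1, 25)}
        )
        chained = predict_growth_rate_chain(fed, growth, frame)
        manual = frame.copy()
        manual["ann_predicted_biomass"] = fed.forward_frame(frame)
        np.testing.assert_allclose(chained, growth.forward_frame(manual), atol=1e-12)

    def test_zero_weight_on_biomass_input_makes_chain_invariant(self, rng):
        fed, growth = self._models(rng)
        # zero every connection from the chained biomass input
        w1, b1, w2, b2 = growth.weights
        w1 = w1.copy()
        w1[:, list(growth.feature_names).index("ann_predicted_biomass")] = 0.0
        growth.theta = pack(w1, b1, w2, b2)
        frame = pd.DataFrame(
            {"do_pct": rng.uniform(0, 1, 10), "tcd_au": rng.uniform(0, 1, 10)}
        )
        out1 = predict_growth_rate_chain(fed, growth, frame)
        # swap in a totally different upstream model
        fed2, _ = self._models(np.random.default_rng(99))
        out2 = predict_growth_rate_chain(fed2, growth, frame)
        np.testing.assert_allclose(out1, out2, atol=1e-9)

    def test_feature_mismatch_rejected(self, rng):
        fed, _ = self._models(rng)
        with pytest.raises(ValueError, match="predicted-biomass"):
            predict_growth_rate_chain(fed, fed, pd.DataFrame())
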