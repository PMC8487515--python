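import numpy as np
import pytest

import lacfnforest as lf
from lacfnforest.laminar import LaminarModel


class TestLayerWeights:
    def test_four_layers_triangular(self):
        np.testing.assert_allclose(lf.layer_weights(4), [0.1, 0.2, 0.3, 0.4])

    def test_single_layer(self):
        np.testing.assert_allclose(lf.layer_weights(1), [1.0])

    @pytest.mark.parametrize("N", [2, 3, 5, 10, 50])
    def test_sum_one_strictly_increasing(self, N):
        w = lf.layer_weights(N)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(w) > 0)

    def test_invalid_layer_count_raises(self):
        with pytest.raises(ValueError):
            lf.layer_weights(0)


class TestConfidenceGating:
    def test_worked_single_bit_example(self):
        outputs, rule = lf.worked_example_fixture()
        Y, X = lf.gate_samples(outputs.reshape(-1, 1), rule, is_final=False)
        np.testing.assert_array_equal(outputs[Y], [0.07, 0.95])
        np.testing.assert_array_equal(outputs[X], [0.35, 0.52, 0.83])

    def test_final_layer_classifies_everyone(self):
        outputs, rule = lf.worked_example_fixture()
        Y, X = lf.gate_samples(outputs.reshape(-1, 1), rule, is_final=True)
        assert len(Y) == 5 and len(X) == 0

    def test_multibit_requires_every_bit_confident(self):
        rule = lf.ConfidenceRule()
        o = np.array([[0.05, 0.95],   # both confident
                      [0.05, 0.50],   # one uncertain bit
                      [0.40, 0.60]])  # both uncertain
        Y, X = lf.gate_samples(o, rule, is_final=False)
        np.testing.assert_array_equal(Y, [0])
        np.testing.assert_array_equal(X, [1, 2])

    def test_max_bit_mode_gates_on_largest_output(self):
        rule = lf.ConfidenceRule()
        o = np.array([[0.50, 0.95],   # max bit confident, other bit not
                      [0.50, 0.50]])  # max bit uncertain
        Y_all, _ = lf.gate_samples(o, rule, is_final=False, mode="all_bits")
        Y_max, _ = lf.gate_samples(o, rule, is_final=False, mode="max_bit")
        assert len(Y_all) == 0
        np.testing.assert_array_equal(Y_max, [0])

    def test_empty_interval_list_gates_nothing(self):
        rule = lf.ConfidenceRule(intervals=(), final_threshold=0.5)
        Y, X = lf.gate_samples(np.array([[0.01], [0.99]]), rule, is_final=False)
        assert len(Y) == 0 and len(X) == 2

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            lf.ConfidenceRule(((0.0, 0.5), (0.4, 1.0)))

    def test_out_of_range_interval_rejected(self):
        with pytest.raises(ValueError, match="within"):
            lf.ConfidenceRule(((0.0, 1.5),))


class TestDenseAugment:
    def test_no_history_is_identity(self, rng):
        X0 = rng.normal(size=(6, 10))
        assert lf.dense_augment(X0, []) is X0

    def test_width_after_three_layers(self, rng):
        X0 = rng.normal(size=(4, 100))
        hist = [rng.random((4, 2)) for _ in range(3)]
        aug = lf.dense_augment(X0, hist)
        assert aug.shape == (4, 106)
        # column order: base first, then layers in order
        np.testing.assert_array_equal(aug[:, :100], X0)
        np.testing.assert_array_equal(aug[:, 100:102], hist[0])
        np.testing.assert_array_equal(aug[:, 104:106], hist[2])

    def test_misaligned_history_raises(self, rng):
        with pytest.raises(ValueError, match="misaligned"):
            lf.dense_augment(rng.normal(size=(5, 3)), [rng.random((4, 2))])


class TestLaminarConfig:
    def test_arithmetic_widening_widths(self):
        cfg = lf.LaminarConfig(num_layers=4, k_base=3)
        assert [cfg.layer_width(l) for l in (1, 2, 3, 4)] == [3, 4, 5, 6]

    def test_constant_widening(self):
        cfg = lf.LaminarConfig(k_base=3, widening="constant")
        assert [cfg.layer_width(l) for l in (1, 2, 3, 4)] == [3, 3, 3, 3]


class TestTrainedLaminar:
    def test_first_layer_structure(self, trained_small_model):
        model, _, _, _ = trained_small_model
        layer1 = model.layers[0]
        assert layer1.layer_index == 1
        assert len(layer1.forests) == 3  # K = 3
        for forest in layer1.forests:
            for level in forest.levels:
                assert len(level.trees) == 2  # log2(4) FNTs

    def test_layer_widths_follow_widening_rule(self, trained_small_model):
        model, _, _, _ = trained_small_model
        for layer in model.layers:
            assert len(layer.forests) == model.config.layer_width(layer.layer_index)

    def test_function_sets_round_robin(self, trained_small_model):
        model, _, _, _ = trained_small_model
        sets = model.config.function_sets
        for layer in model.layers:
            for i, forest in enumerate(layer.forests):
                assert forest.function_set == sets[i % len(sets)]

    def test_routing_every_sample_exits_once(self, trained_small_model):
        model, routing, X, y = trained_small_model
        assert routing.exit_layer.shape == (X.shape[0],)
        assert np.all(routing.exit_layer >= 1)
        assert np.all(routing.exit_layer <= len(model.layers))

    def test_uncertain_counts_non_increasing(self, trained_small_model):
        _, routing, _, _ = trained_small_model
        counts = routing.uncertain_counts()
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_layer_input_widths_grow_densely(self, trained_small_model):
        model, _, X, _ = trained_small_model
        B = model.codebook.num_bits
        d0 = X.shape[1]
        for layer in model.layers:
            expected = d0 + (layer.layer_index - 1) * B
            for forest in layer.forests:
                assert forest.base_input_dim == expected

    def test_predictions_in_unit_box_and_decoded(self, trained_small_model):
        model, _, X, _ = trained_small_model
        classes, y_f = model.predict(X)
        assert np.all((y_f >= 0.0) & (y_f <= 1.0))
        np.testing.assert_array_equal(model.codebook.decode(y_f), classes)

    def test_prediction_deterministic(self, trained_small_model):
        model, _, X, _ = trained_small_model
        c1, s1 = model.predict(X)
        c2, s2 = model.predict(X)
        np.testing.assert_array_equal(c1, c2)
        np.testing.assert_array_equal(s1, s2)

    def test_width_mismatch_raises(self, trained_small_model):
        model, _, X, _ = trained_small_model
        with pytest.raises(ValueError, match="width"):
            model.predict(X[:, :-1])

    def test_serialization_round_trip(self, trained_small_model):
        model, _, X, _ = trained_small_model
        clone = LaminarModel.from_json(model.to_json())
        c1, s1 = model.predict(X)
        c2, s2 = clone.predict(X)
        np.testing.assert_array_equal(c1, c2)
        np.testing.assert_array_equal(s1, s2)
        np.testing.assert_allclose(clone.layer_weights_, model.layer_weights_)

    def test_per_forest_augmentation_widens_inputs(self, easy_dataset,
                                                   tiny_budgets):
        # with per-forest columns, layer 2 sees d0 + B * width(1) inputs
        X, y, _ = easy_dataset
        evo, pso = tiny_budgets
        rule = lf.ConfidenceRule(intervals=(), final_threshold=0.5)
        cfg = lf.LaminarConfig(num_layers=2, k_base=2, confidence=rule,
                               augment_per_forest=True, seed=6,
                               max_cascade_levels=1)
        model, _ = lf.train_laminar(X, y, cfg, evo, pso)
        assert len(model.layers) == 2
        B = model.codebook.num_bits
        expected = X.shape[1] + B * len(model.layers[0].forests)
        for forest in model.layers[1].forests:
            assert forest.base_input_dim == expected
        # prediction runs the same augmentation path
        classes, y_f = model.predict(X)
        assert classes.shape == (X.shape[0],)
        clone = LaminarModel.from_json(model.to_json())
        np.testing.assert_array_equal(clone.predict(X)[0], classes)

    def test_training_deterministic_under_seed(self, easy_dataset, tiny_budgets):
        X, y, _ = easy_dataset
        evo, pso = tiny_budgets
        cfg = lf.LaminarConfig(seed=9, num_layers=2, max_cascade_levels=1)
        m1, r1 = lf.train_laminar(X, y, cfg, evo, pso)
        m2, r2 = lf.train_laminar(X, y, cfg, evo, pso)
        assert m1.to_json() == m2.to_json()
        np.testing.assert_array_equal(r1.exit_layer, r2.exit_layer)


class TestEarlyExitCombination:
    def test_layer_predict_is_mean_of_forests(self, trained_small_model):
        model, _, X, _ = trained_small_model
        layer1 = model.layers[0]
        out = lf.layer_predict(layer1, X)
        manual = np.mean([f.forward(X) for f in layer1.forests], axis=0)
        np.testing.assert_allclose(out, manual, atol=1e-15)
        assert np.all((out >= 0.0) & (out <= 1.0))

    def test_early_exit_uses_renormalised_prefix_weights(self, trained_small_model):
        # a sample exiting at layer 1 must carry exactly layer 1's output
        model, _, X, _ = trained_small_model
        out1 = model.layers[0].predict(X)
        conf, _ = lf.gate_samples(out1, model.config.confidence, is_final=False)
        if conf.size:
            _, y_f = model.predict(X)
            np.testing.assert_allclose(y_f[conf], out1[conf], atol=1e-12)

    def test_full_traversal_uses_triangular_weights(self, easy_dataset,
                                                    tiny_budgets):
        # disable early exit: empty confidence region forces every sample
        # through all layers, so y_f must equal the w=(1/3, 2/3) combination
        X, y, _ = easy_dataset
        evo, pso = tiny_budgets
        rule = lf.ConfidenceRule(intervals=(), final_threshold=0.5)
        cfg = lf.LaminarConfig(num_layers=2, confidence=rule, seed=4,
                               max_cascade_levels=1)
        model, _ = lf.train_laminar(X, y, cfg, evo, pso)
        assert len(model.layers) == 2
        out1 = model.layers[0].predict(X)
        out2 = model.layers[1].predict(lf.dense_augment(X, [out1]))
        w = lf.layer_weights(2)
        expected = w[0] * out1 + w[1] * out2
        _, y_f = model.predict(X)
        np.testing.assert_allclose(y_f, expected, atol=1e-12)
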