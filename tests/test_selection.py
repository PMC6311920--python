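import numpy as np
import pytest

from isomirpanel import (
    ExpressionMatrix,
    GeneratorConfig,
    LabelVector,
    evaluate_topn,
    filter_low_expression,
    generate,
    run_pipeline,
    select_plateau,
    smote_balance,
    weight_all,
)


def _labels(seq):
    return LabelVector(np.array(list(seq), dtype=object))


class TestSmoteBalance:
    def test_balanced_input_returned_unchanged(self):
        x = np.arange(8.0).reshape(4, 2)
        y = _labels("ABAB")
        bx, by = smote_balance(x, y, seed=0)
        np.testing.assert_array_equal(bx, x)
        assert list(by.labels) == list(y.labels)

    def test_synthetic_points_lie_on_segment(self):
        # minority class B has only (0,0) and (1,1): with k=1 every
        # synthetic point must fall on the diagonal segment between them
        x = np.array([[5.0, 0.0], [6.0, 1.0], [7.0, 2.0], [8.0, 3.0],
                      [0.0, 0.0], [1.0, 1.0]])
        y = _labels("AAAABB")
        bx, by = smote_balance(x, y, k=1, seed=3)
        synth = bx[6:]
        assert synth.shape == (2, 2)
        np.testing.assert_allclose(synth[:, 0], synth[:, 1], atol=1e-12)
        assert ((synth >= 0.0) & (synth <= 1.0)).all()

    def test_all_classes_balanced_to_majority(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(18, 3))
        y = LabelVector(np.array(["A"] * 10 + ["B"] * 3 + ["C"] * 5, dtype=object))
        _, by = smote_balance(x, y, seed=5)
        assert by.class_counts() == {"A": 10, "B": 10, "C": 10}

    def test_originals_retained(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(7, 2))
        y = LabelVector(np.array(["A"] * 5 + ["B"] * 2, dtype=object))
        bx, _ = smote_balance(x, y, seed=0)
        np.testing.assert_array_equal(bx[:7], x)

    def test_singleton_class_rejected(self):
        x = np.zeros((3, 2))
        y = LabelVector(np.array(["A", "A", "B"], dtype=object))
        with pytest.raises(ValueError, match="single sample"):
            smote_balance(x, y, seed=0)


class TestSelectPlateau:
    def test_worked_example_picks_first_plateau_point(self):
        grid = [1, 2, 3, 4, 5, 6]
        auc = [0.70, 0.80, 0.85, 0.86, 0.861, 0.862]
        n, found = select_plateau(grid, auc, epsilon=0.005)
        assert (n, found) == (4, True)

    def test_flat_curve_picks_first_point(self):
        n, found = select_plateau([1, 2, 3], [0.9, 0.9, 0.9], epsilon=0.005)
        assert (n, found) == (1, True)

    def test_strictly_rising_curve_falls_back_to_argmax(self):
        grid = [1, 2, 3, 4]
        auc = [0.5, 0.6, 0.7, 0.8]
        n, found = select_plateau(grid, auc, epsilon=0.005)
        assert (n, found) == (4, False)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            select_plateau([1, 2], [0.5])

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError):
            select_plateau([2, 1], [0.5, 0.6])


class TestEvaluateTopn:
    def test_deterministic_given_seed(self, small_dataset):
        matrix, labels, _ = small_dataset
        _, filtered = filter_low_expression(matrix)
        w = weight_all(filtered, labels)
        grid = [1, 3, 5]
        a1, s1 = evaluate_topn(filtered, labels, w, grid, seed=11)
        a2, s2 = evaluate_topn(filtered, labels, w, grid, seed=11)
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(s1, s2)

    def test_auc_bounded(self, small_dataset):
        matrix, labels, _ = small_dataset
        _, filtered = filter_low_expression(matrix)
        w = weight_all(filtered, labels)
        auc, sd = evaluate_topn(filtered, labels, w, [2, 4], seed=0)
        assert ((auc >= 0) & (auc <= 1)).all()
        assert (sd >= 0).all()

    def test_separated_classes_reach_high_auc(self):
        cfg = GeneratorConfig(n_samples=120, n_noise=40, n_informative=6,
                              effect_size=2.0, dispersion=0.5, seed=13)
        matrix, labels, truth = generate(cfg)
        _, filtered = filter_low_expression(matrix)
        w = weight_all(filtered, labels)
        n = min(len(truth), filtered.n_features)
        auc, _ = evaluate_topn(filtered, labels, w, [n], seed=13)
        assert auc[0] > 0.95

    def test_permuted_labels_give_chance_auc(self, small_dataset):
        matrix, labels, _ = small_dataset
        _, filtered = filter_low_expression(matrix)
        rng = np.random.default_rng(21)
        permuted = LabelVector(rng.permutation(labels.labels), labels.sample_ids)
        w = weight_all(filtered, permuted)
        grid = list(range(1, min(7, filtered.n_features + 1)))
        auc, _ = evaluate_topn(filtered, permuted, w, grid, seed=21)
        assert abs(auc.mean() - 0.5) < 0.1

    def test_oversized_panel_rejected(self, small_dataset):
        matrix, labels, _ = small_dataset
        _, filtered = filter_low_expression(matrix)
        w = weight_all(filtered, labels)
        with pytest.raises(ValueError, match="exceeds"):
            evaluate_topn(filtered, labels, w, [filtered.n_features + 1], seed=0)

    def test_class_too_small_for_stratification(self):
        rng = np.random.default_rng(0)
        m = ExpressionMatrix(rng.exponential(1, (3, 12)),
                             ["a", "b", "c"], [f"s{i}" for i in range(12)])
        y = LabelVector(np.array(["A"] * 9 + ["B"] * 3, dtype=object))
        w = weight_all(m, y)
        with pytest.raises(ValueError, match="stratified"):
            evaluate_topn(m, y, w, [2], seed=0)


class TestRunPipeline:
    def test_end_to_end_on_small_benchmark(self, small_dataset):
        matrix, labels, truth = small_dataset
        res = run_pipeline(matrix, labels, grid=list(range(1, 7)), seed=7)
        sel = res.selection
        assert sel.chosen_n in sel.grid
        assert len(sel.panel) == sel.chosen_n
        assert set(res.filter_result.kept_ids) >= set(sel.panel)
        # ranking order of the panel matches the weight vector
        assert sel.panel == res.weights.top(sel.chosen_n)

    def test_method_dispatch_produces_valid_results(self, small_dataset):
        matrix, labels, _ = small_dataset
        for method in ("fisher", "hellinger"):
            res = run_pipeline(matrix, labels, method=method,
                               grid=[1, 2, 3, 4], seed=3)
            assert res.selection.method == method
            assert 0.0 <= res.selection.auc.max() <= 1.0

    def test_stage_errors_carry_context(self):
        rng = np.random.default_rng(4)
        m = ExpressionMatrix(rng.exponential(1, (8, 10)),
                             [f"f{i}" for i in range(8)],
                             [f"s{i}" for i in range(10)])
        # one singleton class: stratified CV must fail inside selection
        y = LabelVector(np.array(["A"] * 9 + ["B"], dtype=object), m.sample_ids)
        with pytest.raises(RuntimeError, match="evaluation stage"):
            run_pipeline(m, y, grid=[1, 2], seed=0)

    def test_determinism_end_to_end(self, small_dataset):
        matrix, labels, _ = small_dataset
        r1 = run_pipeline(matrix, labels, grid=[1, 2, 3], seed=5)
        r2 = run_pipeline(matrix, labels, grid=[1, 2, 3], seed=5)
        np.testing.assert_array_equal(r1.selection.auc, r2.selection.auc)
        assert r1.selection.panel == r2.selection.panel
        assert r1.selection.chosen_n == r2.selection.chosen_n
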