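import logging

import numpy as np
import pytest

from cpetsrc import (
    CodingBudget,
    ConfigurationError,
    Dictionary,
    InputError,
    LabeledDataset,
    LearningSchedule,
    SRCALModel,
    load_srcal_model,
    make_dct_dictionary,
    save_srcal_model,
    src_fit,
    src_predict,
    srcal_fit,
    srcal_predict,
)


def _toy_dataset():
    """Two orthogonal-ish classes in R^4: class a spans e1/e2, class b spans e3/e4."""
    samples = np.array(
        [
            [1.0, 0.2, 0.0, 0.0],
            [0.3, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.1],
            [0.0, 0.0, 0.4, 1.0],
        ]
    )
    return LabeledDataset(samples, ["a", "a", "b", "b"], ["a", "b"])


class TestSrc:
    def test_fit_groups_unit_norm_columns_by_class(self):
        model = src_fit(_toy_dataset())
        assert model.dictionary.atoms.shape == (4, 4)
        np.testing.assert_allclose(np.linalg.norm(model.dictionary.atoms, axis=0), 1.0)
        assert list(model.class_blocks["a"]) == [0, 1]
        assert list(model.class_blocks["b"]) == [2, 3]

    def test_single_sample_per_class_is_usable(self):
        data = LabeledDataset(np.eye(3)[:2], ["a", "b"], ["a", "b"])
        model = src_fit(data)
        assert src_predict(model, np.array([1.0, 0.0, 0.0]), CodingBudget(1)) == "a"

    def test_warns_when_not_overcomplete(self, caplog):
        rng = np.random.default_rng(0)
        data = LabeledDataset(rng.normal(size=(24, 270)), ["a", "b"] * 12, ["a", "b"])
        with caplog.at_level(logging.WARNING, logger="cpetsrc.classifiers"):
            model = src_fit(data)
        assert model.dictionary.atoms.shape == (270, 24)
        assert any("overcomplete" in rec.message for rec in caplog.records)

    def test_training_sample_classified_exactly(self):
        data = _toy_dataset()
        model = src_fit(data)
        label, residuals = src_predict(
            model, data.samples[0], CodingBudget(1), return_residuals=True
        )
        assert label == "a"
        assert residuals[0] == pytest.approx(0.0, abs=1e-10)

    def test_class_residuals_match_dense_linear_algebra(self):
        """Oracle: per-class residuals computed independently with lstsq projections."""
        data = _toy_dataset()
        model = src_fit(data)
        y = np.array([0.9, 0.5, 0.05, 0.0])
        label, residuals = src_predict(
            model, y, CodingBudget(4), return_residuals=True
        )
        yn = y / np.linalg.norm(y)
        # independent route: full least squares on all 4 atoms, then class split
        coef, *_ = np.linalg.lstsq(model.dictionary.atoms, yn, rcond=None)
        for j, cls in enumerate(model.class_order):
            cols = model.class_blocks[cls]
            expected = np.linalg.norm(yn - model.dictionary.atoms[:, cols] @ coef[cols])
            assert residuals[j] == pytest.approx(expected, abs=1e-8)
        assert label == "a"

    def test_tie_goes_to_earlier_class(self):
        # perfectly symmetric classes: both residuals identical for y on the bisector
        samples = np.array([[1.0, 0.0], [0.0, 1.0]])
        data = LabeledDataset(samples, ["a", "b"], ["a", "b"])
        model = src_fit(data)
        assert src_predict(model, np.array([1.0, 1.0]), CodingBudget(1)) == "a"

    def test_zero_sample_rejected(self):
        model = src_fit(_toy_dataset())
        with pytest.raises(InputError):
            src_predict(model, np.zeros(4), CodingBudget(1))

    def test_class_reconstructions_partition_full_reconstruction(self):
        """Summing per-class reconstructions D_j alpha_j recovers D alpha exactly."""
        from cpetsrc import omp_solve, reconstruct
        from cpetsrc.preprocessing import l2_normalize

        model = src_fit(_toy_dataset())
        y = l2_normalize(np.array([0.9, 0.5, 0.3, 0.2]))
        code = omp_solve(y, model.dictionary, CodingBudget(3))
        alpha = code.to_dense()
        total = sum(
            model.dictionary.atoms[:, model.class_blocks[cls]] @ alpha[model.class_blocks[cls]]
            for cls in model.class_order
        )
        np.testing.assert_allclose(total, reconstruct(model.dictionary, code), atol=1e-12)

    def test_scale_invariance(self):
        data = _toy_dataset()
        model = src_fit(data)
        y = np.array([0.9, 0.5, 0.05, 0.0])
        for scale in (0.01, 1.0, 250.0):
            assert src_predict(model, scale * y, CodingBudget(2)) == src_predict(
                model, y, CodingBudget(2)
            )


class TestSrcalFit:
    def test_no_learning_returns_raw_dct(self):
        data = LabeledDataset(np.eye(4), ["a", "a", "b", "b"], ["a", "b"])
        model = srcal_fit(data, schedule=LearningSchedule(n_iterations=0, sparse_factor=1))
        expected = make_dct_dictionary(6, 12)
        np.testing.assert_array_equal(model.learned.atoms, expected.atoms)
        assert model.learned.split_row == 4
        assert model.m == 4 and model.n_classes == 2

    def test_learning_decreases_objective_on_separable_data(self, small_dataset):
        from cpetsrc import reconstruction_objective
        from cpetsrc.preprocessing import l2_normalize, one_hot

        schedule = LearningSchedule(n_iterations=10, sparse_factor=5)
        model = srcal_fit(small_dataset, schedule=schedule)
        m = small_dataset.length
        augmented = np.array(
            [
                np.concatenate(
                    [l2_normalize(s), one_hot(l, small_dataset.class_order)]
                )
                for s, l in zip(small_dataset.samples, small_dataset.labels)
            ]
        )
        initial = make_dct_dictionary(m + 2, 2 * (m + 2), split_row=m)
        obj0 = reconstruction_objective(augmented, initial, CodingBudget(5))
        obj1 = reconstruction_objective(augmented, model.learned, CodingBudget(5))
        assert obj1 < obj0

    def test_single_class_rejected(self):
        with pytest.raises((ConfigurationError, InputError)):
            srcal_fit(LabeledDataset(np.eye(3)[:2], ["a", "a"], ["a", "a"]))


def _one_hot_lower_model():
    """Hand-built model: 3 signal rows + 2 label rows, one-hot lower block."""
    upper = np.array(
        [
            [1.0, 0.0, 0.5],
            [0.0, 1.0, 0.5],
            [0.0, 0.0, 0.1],
        ]
    )
    lower = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 1.0]])
    atoms = np.vstack([upper, lower])
    atoms = atoms / np.linalg.norm(atoms, axis=0)
    return SRCALModel(Dictionary(atoms, split_row=3), ["c1", "c2"], sparse_factor=1)


class TestSrcalPredict:
    def test_exact_atom_reads_its_one_hot_label(self):
        model = _one_hot_lower_model()
        y = np.array([1.0, 0.0, 0.0])  # upper block of atom 0 (class c1)
        label, ly = srcal_predict(model, y, CodingBudget(1), return_label_vector=True)
        assert label == "c1"
        assert abs(ly[0]) > abs(ly[1])
        assert ly[1] == pytest.approx(0.0, abs=1e-10)

    def test_largest_absolute_value_wins_regardless_of_sign(self):
        # lower block engineered so L_y = (-0.8, 0.3) up to positive scale
        atoms = np.vstack([np.eye(2), [-0.8, 0.0], [0.3, 0.0]])
        atoms = atoms / np.linalg.norm(atoms, axis=0)
        model = SRCALModel(Dictionary(atoms, split_row=2), ["c1", "c2"], sparse_factor=1)
        label, ly = srcal_predict(model, np.array([1.0, 0.0]), CodingBudget(1),
                                  return_label_vector=True)
        assert ly[0] < 0 < ly[1]
        assert abs(ly[0]) > abs(ly[1])
        assert label == "c1"

    def test_scale_invariance(self, small_dataset):
        model = srcal_fit(
            small_dataset, schedule=LearningSchedule(n_iterations=3, sparse_factor=3)
        )
        y = small_dataset.samples[0] + 0.01
        for scale in (0.05, 1.0, 30.0):
            assert srcal_predict(model, scale * y) == srcal_predict(model, y)

    def test_permuting_class_order_permutes_label_vector(self):
        """Swapping class order (and the label rows with it) swaps L_y, not the winner."""
        base = _one_hot_lower_model()
        atoms = base.learned.atoms.copy()
        atoms[[3, 4]] = atoms[[4, 3]]  # permute the label-block rows
        swapped = SRCALModel(Dictionary(atoms, split_row=3), ["c2", "c1"], sparse_factor=1)
        y = np.array([0.7, 0.6, 0.2])
        lf, vf = srcal_predict(base, y, CodingBudget(2), return_label_vector=True)
        lr, vr = srcal_predict(swapped, y, CodingBudget(2), return_label_vector=True)
        np.testing.assert_allclose(vf, vr[::-1], atol=1e-12)
        assert lf == lr

    def test_wrong_length_rejected(self):
        model = _one_hot_lower_model()
        with pytest.raises(InputError):
            srcal_predict(model, np.ones(5), CodingBudget(1))


class TestModelSerialization:
    def test_round_trip(self, small_dataset, tmp_path):
        model = srcal_fit(
            small_dataset, schedule=LearningSchedule(n_iterations=2, sparse_factor=3)
        )
        path = tmp_path / "model.txt"
        save_srcal_model(model, path)
        loaded = load_srcal_model(path)
        assert loaded.class_order == [str(c) for c in model.class_order]
        assert loaded.sparse_factor == model.sparse_factor
        np.testing.assert_allclose(loaded.learned.atoms, model.learned.atoms, atol=1e-15)
        y = small_dataset.samples[3]
        assert srcal_predict(loaded, y) == srcal_predict(model, y)
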