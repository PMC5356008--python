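"""SVR training, prediction, serialization, and the dual-QP cross-check."""

import numpy as np
import pytest

import locusrt as lr
from locusrt import encoding
from locusrt.errors import (
    ModelCompatibilityError,
    ModelFormatError,
    TrainingError,
)
from sklearn.metrics.pairwise import rbf_kernel as _sk_rbf

from conftest import svr_dual_qp


class TestRBFKernel:
    def test_identical_vectors(self):
        u = lr.encode_peptide("FEGIIYR")
        assert lr.rbf_kernel(u, u, gamma=3.7) == 1.0

    def test_hamming_distance_for_binary(self):
        """For binary vectors the squared distance is the differing-entry
        count, so K = exp(-gamma * k)."""
        u = np.zeros(10)
        v = np.zeros(10)
        v[[1, 4, 7]] = 1.0  # k = 3
        gamma = 0.25
        assert lr.rbf_kernel(u, v, gamma) == pytest.approx(np.exp(-gamma * 3))

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(0)
        u, v = (rng.random(20) < 0.5).astype(float), (rng.random(20) < 0.5).astype(float)
        k = lr.rbf_kernel(u, v, 0.1)
        assert k == lr.rbf_kernel(v, u, 0.1)
        assert 0 < k <= 1

    def test_small_gamma_limit(self):
        u = lr.encode_peptide("ACDK")
        v = lr.encode_peptide("FEGIIYR")
        assert lr.rbf_kernel(u, v, 1e-12) == pytest.approx(1.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            lr.rbf_kernel(np.zeros(3), np.zeros(4), 1.0)

    def test_nonpositive_gamma(self):
        with pytest.raises(ValueError):
            lr.rbf_kernel(np.zeros(3), np.zeros(3), 0.0)


class TestHyperparamGrid:
    def test_default_ranges(self):
        g = lr.HyperparamGrid.default()
        assert g.C_values == tuple(2.0**i for i in range(-8, 9))
        assert g.gamma_values == tuple(2.0**i for i in range(-8, 9))
        assert g.epsilon_values == (1e-3, 1e-2, 1e-1)
        assert g.folds == 3
        assert g.size() == 17 * 17 * 3 == 867

    def test_points_sorted_smallest_first(self):
        g = lr.HyperparamGrid(
            C_values=(4.0, 1.0), gamma_values=(0.5, 0.1), epsilon_values=(0.1,)
        )
        pts = list(g.points())
        assert (pts[0].C, pts[0].gamma) == (1.0, 0.1)
        assert len(pts) == 4

    def test_invalid_hyperparams(self):
        with pytest.raises(ValueError):
            lr.SVRHyperparams(C=0.0, gamma=1.0, epsilon=0.1)


class TestGridSearchTrain:
    def test_one_point_grid_uses_those_hyperparams(self, tiny_dataset, one_point_grid):
        m = lr.grid_search_train(tiny_dataset, one_point_grid)
        assert m.hyperparams == lr.SVRHyperparams(64.0, 2.0**-6, 0.1)
        assert m.training_size == len(tiny_dataset)

    def test_fewer_peptides_than_folds(self):
        ds = lr.generate_dataset(2, seed=0)
        with pytest.raises(TrainingError):
            lr.grid_search_train(ds, lr.HyperparamGrid.coarse())

    def test_argmin_invariant_to_value_order(self, tiny_dataset):
        base = dict(epsilon_values=(0.1,), folds=3, cv_seed=1)
        g1 = lr.HyperparamGrid(
            C_values=(1.0, 64.0), gamma_values=(2.0**-6, 0.5), **base
        )
        g2 = lr.HyperparamGrid(
            C_values=(64.0, 1.0), gamma_values=(0.5, 2.0**-6), **base
        )
        m1 = lr.grid_search_train(tiny_dataset, g1)
        m2 = lr.grid_search_train(tiny_dataset, g2)
        assert m1.hyperparams == m2.hyperparams
        assert m1.cv_score == m2.cv_score

    def test_deterministic_given_seed(self, tiny_dataset):
        g = lr.HyperparamGrid.coarse(cv_seed=5)
        m1 = lr.grid_search_train(tiny_dataset, g)
        m2 = lr.grid_search_train(tiny_dataset, g)
        assert m1.hyperparams == m2.hyperparams
        probe = lr.generate_peptides(10, seed=77)
        assert np.array_equal(lr.predict(m1, probe), lr.predict(m2, probe))

    def test_noiseless_linear_target_is_recovered(self, noiseless_model):
        """SVR on enough noiseless data fits the (linear-in-features) ground
        truth nearly perfectly out of sample."""
        train = lr.generate_dataset(1000, noiseless_model, seed=21)
        test = lr.generate_dataset(300, noiseless_model, seed=22, exclude=train.sequences)
        grid = lr.HyperparamGrid(
            C_values=(2.0**6, 2.0**8),
            gamma_values=(2.0**-8, 2.0**-6),
            epsilon_values=(0.01,),
        )
        m = lr.grid_search_train(train, grid)
        r = lr.pearson_r(lr.predict(m, test.peptides), test.rts)
        assert r > 0.99


class TestPredict:
    def test_training_points_inside_tube_when_noiseless(self, noiseless_model):
        """With ample C and a flexible kernel, every noiseless training RT is
        approximated within the epsilon tube (plus solver slack)."""
        ds = lr.generate_dataset(15, noiseless_model, seed=5)
        eps = 0.1
        grid = lr.HyperparamGrid(
            C_values=(2.0**8,), gamma_values=(0.05,), epsilon_values=(eps,)
        )
        m = lr.grid_search_train(ds, grid)
        resid = np.abs(lr.predict(m, ds.peptides) - ds.rts)
        assert resid.max() <= eps + 10 * m.solver_tol

    def test_batch_order_and_size_independent(self, tiny_model):
        peps = lr.generate_peptides(12, seed=9)
        full = lr.predict(tiny_model, peps)
        # the same peptide submitted twice in one batch: identical rows
        twice = lr.predict(tiny_model, [peps[0], peps[0]])
        assert twice[0] == twice[1]
        # reordering or resizing the batch changes nothing beyond float
        # round-off in the kernel matrix product
        rev = lr.predict(tiny_model, peps[::-1])
        assert np.allclose(full[::-1], rev, rtol=0, atol=1e-8)
        singles = np.array([lr.predict(tiny_model, [p])[0] for p in peps])
        assert np.allclose(full, singles, rtol=0, atol=1e-8)

    def test_empty_input(self, tiny_model):
        assert lr.predict(tiny_model, []).shape == (0,)

    def test_huge_epsilon_gives_constant_function(self, tiny_dataset):
        grid = lr.HyperparamGrid(
            C_values=(4.0,), gamma_values=(0.05,), epsilon_values=(1000.0,)
        )
        m = lr.grid_search_train(tiny_dataset, grid)
        preds = lr.predict(m, lr.generate_peptides(20, seed=13))
        assert np.ptp(preds) <= 10 * m.solver_tol


class TestDualQPOracle:
    def test_predictions_match_brute_force_dual_solution(self):
        """libsvm's solution on <= 30 points agrees with an independent
        SLSQP solve of the epsilon-SVR dual QP to within 1e-4 min."""
        gt = lr.GroundTruthRTModel.default()
        peps = lr.generate_peptides(20, seed=3)
        rng = np.random.default_rng(3)
        ds = lr.RTDataset(
            tuple(
                lr.Peptide(p.sequence, observed_rt=lr.ground_truth_rt(p, gt, rng))
                for p in peps
            ),
            gradient_minutes=gt.gradient_minutes,
        )
        C, gamma, eps = 4.0, 0.05, 0.1
        grid = lr.HyperparamGrid(
            C_values=(C,), gamma_values=(gamma,), epsilon_values=(eps,)
        )
        m = lr.grid_search_train(ds, grid, solver_tol=1e-6)
        X = encoding.encode_batch(ds.peptides)
        beta, b = svr_dual_qp(_sk_rbf(X, X, gamma=gamma), ds.rts, C, eps)
        probes = lr.generate_peptides(50, seed=99)
        Xq = encoding.encode_batch(probes)
        oracle = _sk_rbf(Xq, X, gamma=gamma) @ beta + b
        ours = lr.predict(m, probes)
        assert np.abs(oracle - ours).max() < 1e-4


class TestSerialization:
    def test_round_trip_identical_predictions(self, tiny_model, tmp_path):
        path = tmp_path / "model.json"
        lr.save_model(tiny_model, path)
        loaded = lr.load_model(path)
        probes = lr.generate_peptides(100, seed=31)
        assert np.array_equal(lr.predict(tiny_model, probes), lr.predict(loaded, probes))
        assert loaded.hyperparams == tiny_model.hyperparams
        assert loaded.solver_tol == tiny_model.solver_tol

    def test_truncated_file_raises(self, tiny_model, tmp_path):
        path = tmp_path / "model.json"
        lr.save_model(tiny_model, path)
        path.write_text(path.read_text()[: 40])
        with pytest.raises(ModelFormatError):
            lr.load_model(path)

    def test_wrong_format_raises(self, tmp_path):
        path = tmp_path / "other.json"
        path.write_text('{"format": "something-else"}')
        with pytest.raises(ModelFormatError):
            lr.load_model(path)

    def test_foreign_alphabet_fails_on_predict(self, tiny_model, tmp_path):
        import json

        path = tmp_path / "model.json"
        lr.save_model(tiny_model, path)
        doc = json.loads(path.read_text())
        doc["alphabet"] = doc["alphabet"][::-1]
        path.write_text(json.dumps(doc))
        loaded = lr.load_model(path)
        with pytest.raises(ModelCompatibilityError):
            lr.predict(loaded, ["ACDK"])
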