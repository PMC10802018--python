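"""Mean-teacher GCN: normalisation, forward, losses, EMA, training."""

import numpy as np
import pytest

from mosegcn._autodiff import Tensor
from mosegcn.omics_data import UNLABELED
from mosegcn.segcn import (
    GCNParams,
    SEGCNConfig,
    TeacherStudentState,
    consistency_loss,
    consistency_ramp,
    ema_update,
    fit,
    gcn_forward,
    normalize_adjacency,
    predict,
    supervised_ce_loss,
    total_loss,
)


def _params(theta1, theta2):
    return GCNParams(
        theta1=Tensor(np.asarray(theta1, dtype=float), requires_grad=True),
        theta2=Tensor(np.asarray(theta2, dtype=float), requires_grad=True),
    )


def _oracle_normalize(A):
    n = A.shape[0]
    At = A.copy()
    for i in range(n):
        At[i, i] = 0.0
    At = At + np.eye(n)
    out = np.zeros_like(At)
    for i in range(n):
        for j in range(n):
            di = sum(At[i, k] for k in range(n))
            dj = sum(At[j, k] for k in range(n))
            out[i, j] = At[i, j] / np.sqrt(di * dj)
    return out


def _oracle_forward(A_hat, X, t1, t2):
    h = A_hat @ X @ t1
    h = np.maximum(h, 0.0)
    z = A_hat @ h @ t2
    out = np.zeros_like(z)
    for i in range(z.shape[0]):
        e = np.exp(z[i] - z[i].max())
        out[i] = e / e.sum()
    return out


class TestNormalizeAdjacency:
    def test_empty_graph_gives_identity(self):
        np.testing.assert_allclose(normalize_adjacency(np.zeros((4, 4))).matrix, np.eye(4))

    def test_two_node_complete_graph(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_allclose(normalize_adjacency(A).matrix, [[0.5, 0.5], [0.5, 0.5]])

    def test_matches_loop_oracle(self, rng):
        A = np.abs(rng.normal(size=(6, 6)))
        A = (A + A.T) / 2
        np.testing.assert_allclose(
            normalize_adjacency(A).matrix, _oracle_normalize(A), atol=1e-10
        )

    def test_entries_in_unit_interval_and_positive_diagonal(self, rng):
        A = np.abs(rng.normal(size=(7, 7)))
        A = (A + A.T) / 2
        M = normalize_adjacency(A).matrix
        assert (M >= 0).all() and (M <= 1).all()
        assert (np.diag(M) > 0).all()

    def test_asymmetric_rejected(self):
        A = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            normalize_adjacency(A)


class TestGCNForward:
    def test_identity_collapse_to_row_softmax(self, rng):
        X = rng.normal(size=(3, 3))
        p = _params(np.eye(3), np.eye(3))
        out = gcn_forward(np.eye(3), X, p, activation="linear")
        e = np.exp(X - X.max(axis=1, keepdims=True))
        np.testing.assert_allclose(out, e / e.sum(axis=1, keepdims=True), atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        M = np.abs(rng.normal(size=(5, 5)))
        A = normalize_adjacency((M + M.T) / 2)
        p = _params(rng.normal(size=(4, 6)), rng.normal(size=(6, 3)))
        out = gcn_forward(A, rng.normal(size=(5, 4)), p)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-8)

    def test_matches_loop_oracle(self, rng):
        A = np.abs(rng.normal(size=(6, 6)))
        A_hat = normalize_adjacency((A + A.T) / 2).matrix
        X = rng.normal(size=(6, 4))
        t1 = rng.normal(size=(4, 5))
        t2 = rng.normal(size=(5, 3))
        out = gcn_forward(A_hat, X, _params(t1, t2), perturb=False)
        np.testing.assert_allclose(out, _oracle_forward(A_hat, X, t1, t2), atol=1e-6)


class TestLosses:
    def test_perfect_prediction_zero_ce(self):
        assert supervised_ce_loss([[1.0, 0.0]], [[1, 0]]) == 0.0

    def test_uniform_prediction_ce_is_log_c(self):
        probs = np.full((3, 4), 0.25)
        y = np.eye(4)[[0, 1, 2]]
        assert supervised_ce_loss(probs, y) == pytest.approx(np.log(4))

    def test_single_term_ce(self):
        assert supervised_ce_loss([[0.7, 0.3]], [[1, 0]]) == pytest.approx(-np.log(0.7))

    def test_zero_probability_clamped(self):
        assert np.isfinite(supervised_ce_loss([[0.0, 1.0]], [[1, 0]]))

    def test_identical_outputs_zero_consistency(self, rng):
        p = rng.random((4, 3))
        p /= p.sum(axis=1, keepdims=True)
        assert consistency_loss(p, p) == 0.0

    def test_opposite_onehots_unit_mse(self):
        assert consistency_loss([[1.0, 0.0]], [[0.0, 1.0]]) == pytest.approx(1.0)

    def test_consistency_matches_explicit_sum(self, rng):
        a = rng.random((5, 3))
        b = rng.random((5, 3))
        expected = sum(
            (a[i, j] - b[i, j]) ** 2 for i in range(5) for j in range(3)
        ) / 15
        assert consistency_loss(a, b) == pytest.approx(expected, abs=1e-12)

    def test_total_loss_degeneracies(self, rng):
        A = normalize_adjacency(np.zeros((4, 4)))
        X = rng.normal(size=(4, 3))
        p = _params(rng.normal(size=(3, 5)), rng.normal(size=(5, 2)))
        y = np.array([0, 1, UNLABELED, UNLABELED])
        lam0 = TeacherStudentState(p, p.detached_copy(), 0.99, 0.0, dropout=0.0)
        probs = gcn_forward(A, X, p)
        ce = supervised_ce_loss(probs[:2], np.eye(2)[y[:2]])
        assert total_loss(lam0, A, X, y) == pytest.approx(ce)
        # teacher identical to unperturbed student: consistency contributes 0
        same = TeacherStudentState(p, p.detached_copy(), 0.99, 0.7, dropout=0.0)
        assert total_loss(same, A, X, y) == pytest.approx(ce)


class TestEMA:
    def _state(self, alpha):
        s = _params([[1.0]], [[0.0]])
        t = _params([[0.5]], [[2.0]])
        return TeacherStudentState(s, t, alpha, 1.0)

    def test_alpha_zero_copies_student(self):
        st = ema_update(self._state(0.0))
        assert st.teacher.theta1.value[0, 0] == 1.0
        assert st.teacher.theta2.value[0, 0] == 0.0

    def test_alpha_one_freezes_teacher(self):
        st = ema_update(self._state(1.0))
        assert st.teacher.theta1.value[0, 0] == 0.5
        assert st.teacher.theta2.value[0, 0] == 2.0

    def test_direct_arithmetic(self):
        s = _params([[0.0]], [[0.0]])
        t = _params([[1.0]], [[1.0]])
        st = ema_update(TeacherStudentState(s, t, 0.99, 1.0))
        assert st.teacher.theta1.value[0, 0] == pytest.approx(0.99)
        assert st.step == 1

    def test_student_untouched(self):
        st = self._state(0.5)
        ema_update(st)
        assert st.student.theta1.value[0, 0] == 1.0


class TestRamp:
    def test_reaches_maximum_after_ramp(self):
        assert consistency_ramp(300, 1000, 0.3, 1.0) == 1.0
        assert consistency_ramp(999, 1000, 0.3, 2.5) == 2.5

    def test_starts_near_zero_and_increases(self):
        vals = [consistency_ramp(e, 1000, 0.3, 1.0) for e in range(0, 300, 50)]
        assert vals[0] < 0.01
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestFit:
    def _problem(self, rng, n=30, c=3):
        # three well-separated blobs on a ring graph of within-blob edges
        centers = np.array([[0, 0], [6, 0], [0, 6]], dtype=float)
        y_true = np.repeat(np.arange(c), n // c)
        X = centers[y_true] + rng.normal(scale=0.4, size=(n, 2))
        from mosegcn.snf import affinity_kernel, pairwise_distance

        W = affinity_kernel(pairwise_distance(X), k_neighbors=5).W
        A = normalize_adjacency(W)
        y = np.full(n, UNLABELED)
        labeled = np.concatenate([np.flatnonzero(y_true == k)[:3] for k in range(c)])
        y[labeled] = y_true[labeled]
        return X, A, y, y_true

    def test_supervised_loss_decreases(self, rng):
        X, A, y, _ = self._problem(rng)
        _, log = fit(X, A, y, 3, SEGCNConfig(epochs=80, hidden_dim=16, seed=0))
        assert log.ce_loss.iloc[-1] < log.ce_loss.iloc[0]

    def test_unlabeled_nodes_classified(self, rng):
        X, A, y, y_true = self._problem(rng)
        state, _ = fit(X, A, y, 3, SEGCNConfig(epochs=300, hidden_dim=16, seed=0))
        pred, probs = predict(state, A, X)
        test_mask = y == UNLABELED
        assert (pred[test_mask] == y_true[test_mask]).mean() > 0.9
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-8)

    def test_lambda_zero_consistency_is_inert(self, rng):
        # with lambda = 0 the consistency branch must not affect the student:
        # swapping its functional form changes nothing
        X, A, y, _ = self._problem(rng)
        cfg_mse = SEGCNConfig(epochs=40, hidden_dim=8, seed=3, lambda_max=0.0, consistency="mse")
        cfg_kl = SEGCNConfig(epochs=40, hidden_dim=8, seed=3, lambda_max=0.0, consistency="kl")
        s1, log1 = fit(X, A, y, 3, cfg_mse)
        s2, log2 = fit(X, A, y, 3, cfg_kl)
        np.testing.assert_array_equal(s1.student.theta1.value, s2.student.theta1.value)
        np.testing.assert_array_equal(log1.ce_loss.values, log2.ce_loss.values)

    def test_same_seed_identical_logs(self, rng):
        X, A, y, _ = self._problem(rng)
        cfg = SEGCNConfig(epochs=30, hidden_dim=8, seed=11)
        _, log1 = fit(X, A, y, 3, cfg)
        _, log2 = fit(X, A, y, 3, cfg)
        assert log1.to_csv() == log2.to_csv()

    def test_missing_labeled_class_rejected(self, rng):
        X, A, y, _ = self._problem(rng)
        y[y == 2] = UNLABELED
        with pytest.raises(ValueError, match="no labeled node"):
            fit(X, A, y, 3, SEGCNConfig(epochs=5))

    def test_checkpoint_hook_fires_on_schedule(self, rng):
        X, A, y, _ = self._problem(rng)
        seen = []
        fit(X, A, y, 3, SEGCNConfig(epochs=50, hidden_dim=8, seed=0),
            checkpoint_every=20, on_checkpoint=lambda e, s: seen.append(e))
        assert seen == [20, 40, 50]


class TestPredict:
    def test_tie_broken_to_lowest_class(self):
        # two identical logits produce an exact tie; argmax picks class 0
        p = _params(np.zeros((2, 2)), np.zeros((2, 2)))
        state = TeacherStudentState(p, p.detached_copy(), 0.99, 1.0)
        A = normalize_adjacency(np.zeros((3, 3)))
        pred, probs = predict(state, A, np.ones((3, 2)))
        np.testing.assert_array_equal(pred, 0)
        np.testing.assert_allclose(probs, 0.5)

    def test_alpha_zero_teacher_equals_student(self, rng):
        X = rng.normal(size=(6, 3))
        A = normalize_adjacency(np.zeros((6, 6)))
        y = np.array([0, 1, UNLABELED, UNLABELED, 0, 1])
        state, _ = fit(X, A, y, 2, SEGCNConfig(epochs=25, hidden_dim=4, seed=2,
                                               alpha_ema=0.0, lambda_max=0.0))
        pt, _ = predict(state, A, X, model="teacher")
        ps, _ = predict(state, A, X, model="student")
        np.testing.assert_array_equal(pt, ps)
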