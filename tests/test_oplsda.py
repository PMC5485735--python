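"""OPLS-DA: oracle equivalences, CV, S-line, VIP, prediction."""

import numpy as np
import pytest

from nmrprofiler import (
    ClassVector,
    apply_scaling,
    cross_validate,
    fit_oplsda,
    fit_scaling,
    generate_profiles,
    predict,
    sline,
    vip,
    vip_with_cvse,
)


def two_class_y(n_per=4):
    return ClassVector(np.array([1.0] * n_per + [-1.0] * n_per))


def random_xy(rng, n=8, k=5):
    x = rng.normal(size=(n, k))
    y = two_class_y(n // 2)
    return x - x.mean(0), y


def pls1_oracle(x, y_c):
    """One-component PLS1 by the closed-form weight direction w = X'y/||X'y||."""
    w = x.T @ y_c
    w /= np.linalg.norm(w)
    t = x @ w
    q = y_c @ t / (t @ t)
    return w, t, q


class TestFit:
    def test_equals_pls1_oracle_without_ortho(self, rng):
        for _ in range(5):
            x, y = random_xy(rng)
            m = fit_oplsda(x, y, n_ortho=0)
            w, t, q = pls1_oracle(x, y.centered)
            np.testing.assert_allclose(m.w, w, atol=1e-10)
            np.testing.assert_allclose(m.t_pred, t, atol=1e-10)
            assert m.q == pytest.approx(q, abs=1e-10)

    def test_self_predictive_limit(self, rng):
        y = two_class_y(7)
        x = np.column_stack([y.y, rng.normal(scale=0.1, size=(14, 6))])
        m = fit_oplsda(x - x.mean(0), y, n_ortho=0)
        assert m.r2y_cum > 0.99

    def test_orthogonal_scores_uncorrelated_with_predictive(self, dataset):
        x = dataset.profile.to_array()
        xs = apply_scaling(x, fit_scaling(x))
        m = fit_oplsda(xs, ClassVector(dataset.y), n_ortho=2)
        for a in range(2):
            r = np.corrcoef(m.t_pred, m.t_ortho[:, a])[0, 1]
            assert abs(r) < 1e-8
        assert np.linalg.norm(m.w) == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= m.r2y_cum <= 1.0

    def test_label_flip_symmetry(self, dataset):
        x = dataset.profile.to_array()
        xs = apply_scaling(x, fit_scaling(x))
        y = ClassVector(dataset.y)
        m1 = fit_oplsda(xs, y, n_ortho=1)
        m2 = fit_oplsda(xs, ClassVector(-y.y), n_ortho=1)
        np.testing.assert_allclose(m2.t_pred, -m1.t_pred, atol=1e-8)
        assert m2.q == pytest.approx(m1.q, rel=1e-10)  # y_c·t both flip
        assert m2.r2y_cum == pytest.approx(m1.r2y_cum, rel=1e-10)
        s1, s2 = sline(m1, xs), sline(m2, xs)
        np.testing.assert_allclose(s2["p_ctr"], -s1["p_ctr"], atol=1e-10)
        np.testing.assert_allclose(s2["p_corr"], -s1["p_corr"], atol=1e-10)
        np.testing.assert_allclose(vip(m2), vip(m1), atol=1e-12)

    def test_one_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_oplsda(rng.normal(size=(6, 4)), ClassVector(np.ones(6) * 0))

    def test_no_predictive_direction(self):
        x = np.zeros((8, 3))
        x[:, 0] = [1, -1] * 4  # orthogonal to y after centering
        y = two_class_y(4)
        x[:, 0] = [1, 1, -1, -1, 1, 1, -1, -1]
        x = x - x.mean(0)
        x[:, 1:] = 0.0
        if abs(x[:, 0] @ y.centered) < 1e-12:
            with pytest.raises(ValueError, match="no predictive direction"):
                fit_oplsda(x, y, n_ortho=0)


class TestCrossValidate:
    def test_perfectly_predictable(self, rng):
        y = two_class_y(7)
        x = np.column_stack([y.y, rng.normal(scale=0.05, size=(14, 4))]) + 5.0
        cv = cross_validate(x, y, n_ortho=0, n_folds=7, seed=0)
        assert cv.q2_cum > 0.95

    def test_loo_equals_explicit_loop(self, dataset):
        x = dataset.profile.to_array()
        y = ClassVector(dataset.y)
        cv = cross_validate(x, y, n_ortho=1, n_folds=len(y.y), seed=3)
        press = 0.0
        for i in range(len(y.y)):
            mask = np.arange(len(y.y)) != i
            params = fit_scaling(x[mask])
            m = fit_oplsda(apply_scaling(x[mask], params), ClassVector(y.y[mask]), 1)
            yhat = predict(m, x[[i]], scaling=params)["y_hat"][0]
            press += (y.y[i] - yhat) ** 2
        q2_oracle = 1.0 - press / (y.centered @ y.centered)
        assert cv.q2_cum == pytest.approx(q2_oracle, abs=1e-10)

    def test_fold_structure(self, dataset):
        y = ClassVector(dataset.y)
        cv = cross_validate(dataset.profile.to_array(), y, 1, 7, seed=5)
        counts = np.bincount(cv.fold_assignment)
        assert counts.max() - counts.min() <= 1
        assert cv.n_folds == 7
        # every sample held out exactly once
        assert cv.fold_assignment.size == 14

    def test_too_many_folds_rejected(self, dataset):
        with pytest.raises(ValueError, match="n_folds"):
            cross_validate(dataset.profile.to_array(), ClassVector(dataset.y), 1, 20, seed=0)

    def test_overfitting_gap_r2y_above_q2(self, dataset, rng):
        x = dataset.profile.to_array()
        r2s, q2s = [], []
        for seed in range(20):
            r = np.random.default_rng(seed)
            y = ClassVector(r.permutation(dataset.y))
            params = fit_scaling(x)
            m = fit_oplsda(apply_scaling(x, params), y, 1)
            cv = cross_validate(x, y, 1, 7, seed=seed)
            r2s.append(m.r2y_cum)
            q2s.append(cv.q2_cum)
            assert cv.q2_cum <= 1.0
        assert np.median(r2s) > np.median(q2s)


class TestSline:
    def test_exact_and_anti_correlated_columns(self, dataset, rng):
        x = dataset.profile.to_array()
        xs = apply_scaling(x, fit_scaling(x))
        m = fit_oplsda(xs, ClassVector(dataset.y), 1)
        t = m.t_pred
        probe = np.column_stack([t, -2.0 * t, rng.normal(size=t.size)])
        sl = sline(m, probe)
        assert sl["p_corr"][0] == pytest.approx(1.0, abs=1e-12)
        assert sl["p_corr"][1] == pytest.approx(-1.0, abs=1e-12)
        assert sl["p_ctr"][1] == pytest.approx(-2.0 * np.var(t, ddof=1), rel=1e-10)

    def test_matches_textbook_correlation(self, dataset):
        x = dataset.profile.to_array()
        xs = apply_scaling(x, fit_scaling(x))
        m = fit_oplsda(xs, ClassVector(dataset.y), 1)
        sl = sline(m, xs, var_ids=dataset.profile.var_ids)
        for j in (0, 17, 53, 109):
            r = np.corrcoef(m.t_pred, xs[:, j])[0, 1]
            assert sl["p_corr"][j] == pytest.approx(r, abs=1e-12)
        assert (sl["p_corr"].abs() <= 1 + 1e-12).all()

    def test_zero_variance_column_rejected(self, dataset):
        x = dataset.profile.to_array()
        xs = apply_scaling(x, fit_scaling(x))
        m = fit_oplsda(xs, ClassVector(dataset.y), 1)
        bad = xs.copy()
        bad[:, 2] = 0.0
        with pytest.raises(ValueError, match="var_id 3"):
            sline(m, bad, var_ids=dataset.profile.var_ids)


class TestVIP:
    def test_mean_square_is_one(self, dataset):
        x = dataset.profile.to_array()
        xs = apply_scaling(x, fit_scaling(x))
        m = fit_oplsda(xs, ClassVector(dataset.y), 1)
        for mode in ("predictive", "total"):
            v = vip(m, mode)
            assert np.mean(v**2) == pytest.approx(1.0, abs=1e-8)
            assert (v >= 0).all()

    def test_informative_variable_ranks_first(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            n, k = 100, 15
            y = ClassVector(np.array([1.0, -1.0] * (n // 2)))
            x = r.normal(size=(n, k))
            x[:, 7] += 3.0 * y.y  # single strongly informative variable
            params = fit_scaling(x)
            m = fit_oplsda(apply_scaling(x, params), y, 0)
            hits += int(np.argmax(vip(m)) == 7)
        assert hits == 20

    def test_cvse_zero_for_degenerate_cv(self):
        # all case rows identical and all control rows identical -> every
        # training fold produces the same submodel, so the jack-knife SE -> 0
        case = np.array([1.0, 3.0, 2.0, 5.0])
        ctrl = np.array([2.0, 1.0, 4.0, 4.0])
        x = np.vstack([np.tile(case, (7, 1)), np.tile(ctrl, (7, 1))])
        x += 1e-9 * np.arange(14)[:, None]  # avoid exactly-constant columns
        y = ClassVector(np.array([-1.0] * 7 + [1.0] * 7))
        cv = cross_validate(x, y, 0, 7, seed=1)
        params = fit_scaling(x)
        m = fit_oplsda(apply_scaling(x, params), y, 0)
        _, cvse = vip_with_cvse(m, cv)
        np.testing.assert_allclose(cvse, 0, atol=1e-4)

    def test_cvse_requires_cv(self, dataset):
        from nmrprofiler.oplsda import CVMetrics

        x = dataset.profile.to_array()
        m = fit_oplsda(apply_scaling(x, fit_scaling(x)), ClassVector(dataset.y), 1)
        empty = CVMetrics(0.0, 0.0, 1.0, np.zeros(14, dtype=int), [])
        with pytest.raises(ValueError, match="cross-validation"):
            vip_with_cvse(m, empty)


class TestPredict:
    def test_in_sample_reproduction(self, dataset):
        x = dataset.profile.to_array()
        params = fit_scaling(x)
        m = fit_oplsda(apply_scaling(x, params), ClassVector(dataset.y), 1)
        out = predict(m, x, scaling=params)
        np.testing.assert_allclose(out["t_pred"], m.t_pred, atol=1e-10)
        np.testing.assert_allclose(out["y_hat"], m.t_pred * m.q + m.y_mean, atol=1e-10)

    def test_tiny_perturbation_keeps_label(self, dataset, rng):
        x = dataset.profile.to_array()
        params = fit_scaling(x)
        m = fit_oplsda(apply_scaling(x, params), ClassVector(dataset.y), 1)
        base = predict(m, x[[0]], scaling=params)["labels"][0]
        noisy = x[[0]] * (1 + 1e-9 * rng.normal(size=(1, x.shape[1])))
        assert predict(m, noisy, scaling=params)["labels"][0] == base

    def test_held_out_balanced_accuracy(self, tpl):
        accs = []
        for seed in range(10):
            train = generate_profiles(tpl, 7, 7, seed=seed)
            test = generate_profiles(tpl, 7, 7, seed=1000 + seed)
            x = train.profile.to_array()
            params = fit_scaling(x)
            m = fit_oplsda(apply_scaling(x, params), ClassVector(train.y), 1)
            pred = predict(m, test.profile.to_array(), scaling=params)["labels"]
            yt = test.y
            tpr = np.mean(pred[yt == 1] == 1)
            tnr = np.mean(pred[yt == -1] == -1)
            accs.append((tpr + tnr) / 2)
        assert np.mean(accs) > 0.8
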