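"""GMM / LR / MLP classifiers, disease profiles and ROC."""

import dataclasses

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import multivariate_normal

from mnprof.classify import (
    fit_censored,
    fit_gmm,
    fit_logistic,
    fit_mlp,
    fit_predict_loao,
    orient_sick_component,
    predict_profile,
    roc_auc,
)
from mnprof.spectra import standardize

from conftest import make_table


def brute_force_auc(scores, labels):
    """Pairwise concordance probability with ties counted 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def mixture_1d(rng, n=1000, mu=(-3.0, 3.0), w=0.5):
    z = rng.random(n) < w
    x = np.where(z, rng.normal(mu[1], 1.0, n), rng.normal(mu[0], 1.0, n))
    return x[:, None], z


class TestGmm:
    def test_recovers_two_well_separated_components(self, rng):
        x, _ = mixture_1d(rng)
        m = fit_gmm(x, seed=0)
        means = np.sort(m.means.ravel())
        assert np.allclose(means, [-3.0, 3.0], atol=0.15)
        assert np.allclose(np.sort(m.weights), [0.5, 0.5], atol=0.03)

    def test_loglik_trace_non_decreasing(self, rng):
        x = rng.normal(size=(80, 2))
        m = fit_gmm(x, seed=1)
        assert (np.diff(m.loglik_trace) >= -1e-8).all()

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            fit_gmm(np.ones((20, 1)))

    def test_matches_sklearn_mixture(self, rng):
        from sklearn.mixture import GaussianMixture

        x, _ = mixture_1d(rng, n=600)
        m = fit_gmm(x, seed=0)
        ref = GaussianMixture(2, n_init=5, random_state=0).fit(x)
        assert np.allclose(
            np.sort(m.means.ravel()), np.sort(ref.means_.ravel()), atol=0.05
        )

    def test_same_seed_reproduces_fit(self, rng):
        x = rng.normal(size=(60, 2))
        a, b = fit_gmm(x, seed=5), fit_gmm(x, seed=5)
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.weights, b.weights)


class TestOrientation:
    def test_majority_disease_component_is_sick(self, rng):
        x, z = mixture_1d(rng, n=400, w=0.4)
        m = fit_gmm(x, seed=0)
        cond = np.where(z, "vcp", "control")
        oriented = orient_sick_component(m, cond)
        sick_members = m.train_assignments == oriented.sick_component
        assert (cond[sick_members] == "vcp").mean() > 0.9

    def test_relabeling_flips_orientation(self, rng):
        x, z = mixture_1d(rng, n=400, w=0.4)
        m = fit_gmm(x, seed=0)
        a = orient_sick_component(m, np.where(z, "vcp", "control"))
        b = orient_sick_component(m, np.where(~z, "vcp", "control"))
        assert a.sick_component == 1 - b.sick_component

    def test_tied_occupancy_takes_smaller_weight(self, rng):
        x = np.r_[rng.normal(-3, 0.5, (30, 1)), rng.normal(3, 0.5, (10, 1))]
        m = fit_gmm(x, seed=0)
        # balanced disease fraction in both components -> tie
        cond = np.array(
            ["vcp" if i % 2 else "control" for i in range(40)]
        )
        with pytest.warns(UserWarning, match="tied"):
            oriented = orient_sick_component(m, cond)
        assert oriented.sick_component == int(np.argmin(m.weights))


class TestLogistic:
    def test_separable_data_with_penalty_is_finite_and_monotone(self):
        x = np.r_[np.linspace(-2, -1, 10), np.linspace(1, 2, 10)][:, None]
        y = np.r_[np.zeros(10), np.ones(10)]
        m = fit_logistic(x, y, lam=1.0)
        assert np.isfinite(m.coef).all()
        P, _ = predict_profile(m, np.linspace(-3, 3, 50)[:, None])
        assert (np.diff(P) > 0).all()

    def test_symmetric_data_has_zero_intercept(self, rng):
        x = rng.normal(size=(200, 1))
        x = np.r_[x, -x]
        y = np.r_[np.ones(200), np.zeros(200)]
        m = fit_logistic(x, y, lam=1.0)
        assert abs(m.intercept) < 1e-6

    def test_matches_sklearn_ridge_logistic(self, rng):
        from sklearn.linear_model import LogisticRegression

        x = rng.normal(size=(300, 4))
        y = (rng.random(300) < expit(x @ [1.0, -0.5, 0.3, 0.0])).astype(float)
        lam = 2.0
        m = fit_logistic(x, y, lam=lam)
        ref = LogisticRegression(C=1.0 / lam, tol=1e-10, max_iter=5000).fit(x, y)
        assert np.allclose(m.coef, ref.coef_.ravel(), atol=1e-4)
        assert m.intercept == pytest.approx(float(ref.intercept_[0]), abs=1e-4)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic(rng.normal(size=(10, 1)), np.zeros(10))


class TestMlp:
    def test_captures_xor_where_lr_cannot(self, rng):
        n = 400
        x = rng.normal(size=(n, 2))
        y = ((x[:, 0] > 0) ^ (x[:, 1] > 0)).astype(float)
        mlp = fit_mlp(x, y, seed=0)
        _, s_mlp = predict_profile(mlp, x)
        lr = fit_logistic(x, y, lam=1.0)
        _, s_lr = predict_profile(lr, x)
        assert roc_auc(s_mlp, y).auc > 0.95
        assert abs(roc_auc(s_lr, y).auc - 0.5) < 0.1

    def test_linearly_separable_at_least_matches_lr(self, rng):
        x = rng.normal(size=(300, 2))
        y = (x[:, 0] + 0.5 * x[:, 1] > 0).astype(float)
        auc_mlp = roc_auc(predict_profile(fit_mlp(x, y, seed=0), x)[1], y).auc
        auc_lr = roc_auc(
            predict_profile(fit_logistic(x, y, lam=1.0), x)[1], y
        ).auc
        assert auc_mlp >= auc_lr - 0.02

    def test_same_seed_bit_identical(self, rng):
        x = rng.normal(size=(100, 3))
        y = (x[:, 0] > 0).astype(float)
        a = fit_mlp(x, y, seed=7)
        b = fit_mlp(x, y, seed=7)
        Pa, Sa = predict_profile(a, x)
        Pb, Sb = predict_profile(b, x)
        assert np.array_equal(Sa, Sb) and np.array_equal(Pa, Pb)

    def test_invalid_hidden_size(self, rng):
        with pytest.raises(ValueError):
            fit_mlp(rng.normal(size=(20, 2)), np.r_[np.zeros(10), np.ones(10)], hidden=0)


def mixed_condition_table(rng, n_per=15, n_feat=4):
    conds = ["control"] * n_per + ["sod1"] * n_per + ["vcp"] * n_per
    x = rng.normal(size=(3 * n_per, n_feat))
    x[n_per:] += 1.0  # disease shift
    samples = [f"{c}_{i % 2}" for i, c in enumerate(conds)]
    t = make_table(
        x, [f"AreaShape_F{j}" for j in range(n_feat)], samples, conds
    )
    return standardize(t)


class TestCensored:
    def test_model_sees_no_censored_rows(self, rng):
        t = mixed_condition_table(rng)
        m = fit_censored("lr", t, {"control", "vcp"}, lam=1.0)
        mask = t.conditions.isin({"control", "vcp"}).to_numpy()
        y = (t.conditions[mask] != "control").to_numpy(dtype=float)
        direct = fit_logistic(t.values.to_numpy()[mask], y, lam=1.0)
        assert np.allclose(m.coef, direct.coef, atol=1e-9)
        assert m.trained_conditions == ("control", "vcp")

    def test_keeping_one_class_errors(self, rng):
        t = mixed_condition_table(rng)
        with pytest.raises(ValueError, match="class"):
            fit_censored("lr", t, {"control"})

    def test_scores_censored_out_condition_at_predict_time(self, rng):
        t = mixed_condition_table(rng)
        m = fit_censored("mlp", t, {"control", "vcp"}, seed=0)
        sod1 = t.conditions.to_numpy() == "sod1"
        P, S = predict_profile(m, t.values.to_numpy()[sod1])
        assert np.isfinite(P).all() and np.isfinite(S).all()


class TestLeaveOneAnimalOut:
    def test_covers_every_cell_without_memorizing_animals(self, rng):
        t = mixed_condition_table(rng, n_per=16)
        P, S = fit_predict_loao("lr", t, lam=1.0)
        assert np.isfinite(P).all() and len(P) == t.n_cells
        # held-out predictions differ from in-sample scores
        y = (t.conditions != "control").to_numpy(dtype=float)
        m = fit_logistic(t.values.to_numpy(), y, lam=1.0)
        _, s_in = predict_profile(m, t.values.to_numpy())
        assert not np.allclose(S, s_in)

    def test_holding_out_the_only_control_animal_errors(self, rng):
        x = rng.normal(size=(20, 3))
        conds = ["control"] * 10 + ["vcp"] * 10
        t = make_table(
            x, [f"AreaShape_F{j}" for j in range(3)],
            ["c_only"] * 10 + ["v1"] * 5 + ["v2"] * 5, conds,
        )
        with pytest.raises(ValueError, match="single class"):
            fit_predict_loao("lr", t, lam=1.0)


class TestPredictProfile:
    def test_zero_score_is_half_probability(self):
        from mnprof.classify import LrModel

        m = LrModel(coef=np.array([1.0]), intercept=0.0, l2_strength=1.0)
        P, S = predict_profile(m, np.array([[0.0]]))
        assert S[0] == 0.0 and P[0] == 0.5

    def test_saturated_probabilities_keep_distinct_severity(self):
        from mnprof.classify import LrModel

        m = LrModel(coef=np.array([10.0]), intercept=0.0, l2_strength=1.0)
        P, S = predict_profile(m, np.array([[4.0], [5.0]]))
        assert (1.0 - P < 1e-12).all()  # both effectively probability 1
        assert S[1] - S[0] > 5.0  # severity still distinguishes them

    def test_probability_strictly_increasing_in_score(self, rng):
        from mnprof.classify import LrModel

        m = LrModel(coef=np.array([2.0]), intercept=-1.0, l2_strength=1.0)
        x = np.sort(rng.normal(size=30))[:, None]
        P, S = predict_profile(m, x)
        assert (np.diff(S) >= 0).all() and (np.diff(P) >= 0).all()

    def test_gmm_posterior_equals_density_ratio(self, rng):
        x, z = mixture_1d(rng, n=300)
        m = fit_gmm(x, seed=0)
        m = orient_sick_component(m, np.where(z, "vcp", "control"))
        pts = rng.normal(0.0, 2.5, size=(20, 1))
        P, S = predict_profile(m, pts)
        s = m.sick_component
        f1 = m.weights[s] * multivariate_normal(
            m.means[s], m.covariances[s]
        ).pdf(pts)
        f0 = m.weights[1 - s] * multivariate_normal(
            m.means[1 - s], m.covariances[1 - s]
        ).pdf(pts)
        assert np.allclose(P, f1 / (f0 + f1), atol=1e-9)
        assert np.allclose(S, np.log(f1) - np.log(f0), atol=1e-9)

    def test_unoriented_gmm_refuses_profiles(self, rng):
        x, _ = mixture_1d(rng, n=200)
        m = fit_gmm(x, seed=0)
        with pytest.raises(ValueError, match="orient"):
            predict_profile(m, x)

    def test_dimension_mismatch_rejected(self, rng):
        from mnprof.classify import LrModel

        m = LrModel(coef=np.array([1.0, 2.0]), intercept=0.0, l2_strength=1.0)
        with pytest.raises(ValueError, match="columns"):
            predict_profile(m, rng.normal(size=(5, 3)))


class TestRocAuc:
    def test_hand_example(self):
        res = roc_auc(
            np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1])
        )
        assert res.auc == pytest.approx(0.75)

    def test_perfect_and_tied_scores(self):
        assert roc_auc(np.array([1, 2, 3, 4]), np.array([0, 0, 1, 1])).auc == 1.0
        assert roc_auc(np.ones(6), np.array([0, 1] * 3)).auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_monotone_transform_invariance(self, rng):
        s = rng.normal(size=50)
        y = (rng.random(50) < 0.4).astype(int)
        a = roc_auc(s, y).auc
        assert roc_auc(np.exp(s), y).auc == pytest.approx(a)
        assert roc_auc(3 * s - 7, y).auc == pytest.approx(a)

    def test_matches_brute_force_concordance(self, rng):
        for _ in range(30):
            n = rng.integers(6, 25)
            s = rng.integers(0, 6, size=n).astype(float)  # ties likely
            y = np.r_[np.zeros(n // 2), np.ones(n - n // 2)]
            rng.shuffle(y)
            if len(np.unique(y)) < 2:
                continue
            assert roc_auc(s, y).auc == pytest.approx(brute_force_auc(s, y))
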