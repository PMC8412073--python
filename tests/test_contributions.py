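"""Per-measurement contribution decomposition and category tests."""

import numpy as np
import pytest

from mnprof.classify import LrModel, fit_gmm, fit_logistic, fit_mlp
from mnprof.contributions import (
    ContributionProfile,
    category_lmm,
    category_permutation_z,
    contributions_gmm,
    contributions_lr,
    contributions_mlp,
    nc_ratio_contribution,
    top_contributors,
)
from mnprof.spectra import Decomposition


def lr_model(coef, names=None):
    coef = np.asarray(coef, dtype=float)
    names = names or [f"AreaShape_F{j}" for j in range(len(coef))]
    return LrModel(coef=coef, intercept=0.3, l2_strength=1.0, feature_names=names)


def profile(c, names=None, group=None, cid="p"):
    c = np.asarray(c, dtype=float)
    names = names or [f"AreaShape_F{j}" for j in range(len(c))]
    return ContributionProfile(cid, c, names, group)


class TestLrContributions:
    def test_single_active_coefficient(self):
        assert contributions_lr(lr_model([2.0, 0.0, 0.0])).contributions.tolist() == [
            1.0,
            0.0,
            0.0,
        ]

    def test_sign_blind(self):
        c = contributions_lr(lr_model([1.0, -1.0])).contributions
        assert c.tolist() == [0.5, 0.5]

    def test_scale_invariance(self):
        a = contributions_lr(lr_model([0.2, 0.5, -0.1])).contributions
        b = contributions_lr(lr_model([2.0, 5.0, -1.0])).contributions
        assert np.allclose(a, b)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            contributions_lr(lr_model([0.0, 0.0]))

    def test_duplicated_feature_splits_contribution(self, rng):
        x = rng.normal(size=(400, 3))
        y = (rng.random(400) < 1 / (1 + np.exp(-x @ [1.5, -1.0, 0.0]))).astype(float)
        base = contributions_lr(
            fit_logistic(x, y, lam=1.0, feature_names=["a", "b", "c"])
        )
        xd = np.column_stack([x, x[:, 0]])  # duplicate first column
        dup = contributions_lr(
            fit_logistic(xd, y, lam=1.0, feature_names=["a", "b", "c", "a2"])
        )
        merged = np.array(
            [dup.contributions[0] + dup.contributions[3], *dup.contributions[1:3]]
        )
        assert merged.sum() == pytest.approx(1.0)
        # ridge splits the duplicated weight; pooled mass matches original
        assert np.allclose(merged, base.contributions, atol=0.03)


def decomposition(loadings, names=None):
    loadings = np.asarray(loadings, dtype=float)
    m, r = loadings.shape
    return Decomposition(
        loadings=loadings,
        scores=np.zeros((5, r)),
        variance_fraction=np.full(r, 1.0 / r),
        entropy=1.0,
        n_components=r,
        measurement_names=names or [f"AreaShape_F{j}" for j in range(m)],
    )


def gmm_model(means, covs, weights=(0.5, 0.5), pcs=(0,)):
    from mnprof.classify import GmmModel

    return GmmModel(
        weights=np.asarray(weights, dtype=float),
        means=np.asarray(means, dtype=float),
        covariances=np.asarray(covs, dtype=float),
        loglik_trace=[0.0],
        pc_indices=list(pcs),
        sick_component=1,
    )


class TestGmmContributions:
    def test_identity_loading_single_pc(self):
        d = decomposition(np.array([[1.0], [0.0], [0.0]]))
        m = gmm_model([[0.0], [2.0]], [np.eye(1) * 0.5, np.eye(1) * 0.5])
        c = contributions_gmm(m, d).contributions
        assert np.allclose(c, [1.0, 0.0, 0.0])

    def test_zero_weight_pc_is_ignored(self, rng):
        L = rng.normal(size=(6, 2))
        d = decomposition(L)
        cov = np.eye(2)
        # discriminant w = Sigma^-1 delta = (1, 0): PC2 carries no weight
        m2 = gmm_model([[0.0, 0.0], [1.0, 0.0]], [cov, cov], pcs=(0, 1))
        m1 = gmm_model([[0.0], [1.0]], [np.eye(1), np.eye(1)], pcs=(0,))
        c2 = contributions_gmm(m2, d).contributions
        c1 = contributions_gmm(m1, decomposition(L[:, :1])).contributions
        assert np.allclose(c2, c1)

    def test_matches_brute_force_linear_algebra(self, rng):
        L = rng.normal(size=(8, 2))
        d = decomposition(L)
        cov0 = np.array([[1.0, 0.3], [0.3, 0.8]])
        cov1 = np.array([[0.6, -0.1], [-0.1, 1.2]])
        w = (0.4, 0.6)
        mu = np.array([[0.2, -0.5], [1.0, 0.7]])
        m = gmm_model(mu, [cov0, cov1], weights=w, pcs=(0, 1))
        pooled = w[0] * cov0 + w[1] * cov1
        v = np.abs(L @ np.linalg.solve(pooled, mu[1] - mu[0]))
        assert np.allclose(
            contributions_gmm(m, d).contributions, v / v.sum(), atol=1e-9
        )


class TestMlpContributions:
    def fabricate(self, W1, W2, names):
        rng = np.random.default_rng(0)
        p = W1.shape[0]
        x = rng.normal(size=(30, p))
        y = (rng.random(30) < 0.5).astype(float)
        y[:2] = [0, 1]
        m = fit_mlp(x, y, hidden=W1.shape[1], seed=0, max_iter=5, feature_names=names)
        m.estimator.coefs_ = [np.asarray(W1, float), np.asarray(W2, float).reshape(-1, 1)]
        return m

    def test_hand_built_path_products(self):
        W1 = np.array([[1.0, -2.0], [0.5, 0.0]])
        W2 = np.array([3.0, -1.0])
        m = self.fabricate(W1, W2, ["a", "b"])
        c = contributions_mlp(m).contributions
        raw = np.array(
            [abs(1.0 * 3.0) + abs(-2.0 * -1.0), abs(0.5 * 3.0) + 0.0]
        )
        assert np.allclose(c, raw / raw.sum())

    def test_single_active_input(self):
        W1 = np.array([[0.0, 0.0], [2.0, -1.0]])
        W2 = np.array([1.0, 1.0])
        m = self.fabricate(W1, W2, ["a", "b"])
        assert np.allclose(contributions_mlp(m).contributions, [0.0, 1.0])

    def test_input_permutation_equivariance(self, rng):
        W1 = rng.normal(size=(4, 3))
        W2 = rng.normal(size=3)
        names = ["a", "b", "c", "d"]
        c = contributions_mlp(self.fabricate(W1, W2, names)).contributions
        perm = [2, 0, 3, 1]
        cp = contributions_mlp(
            self.fabricate(W1[perm], W2, [names[i] for i in perm])
        ).contributions
        assert np.allclose(cp, c[perm])


class TestTopContributors:
    def test_basic_ranking(self):
        top = top_contributors(profile([0.7, 0.2, 0.1]), 1)
        assert top == [("AreaShape_F0", 0.7)]

    def test_full_ranking_and_tie_break(self):
        p = profile([0.25, 0.25, 0.5], names=["b", "a", "c"])
        assert [n for n, _ in top_contributors(p, 3)] == ["c", "a", "b"]

    @pytest.mark.parametrize("k", [0, 4])
    def test_invalid_k(self, k):
        with pytest.raises(ValueError):
            top_contributors(profile([0.5, 0.3, 0.2]), k)


def category_labels():
    return np.array(["area_shape"] * 10 + ["texture"] * 10 + ["intensity"] * 10)


class TestCategoryLmm:
    def make_profiles(self, rng, boost=2.0):
        out = []
        for i in range(3):
            c = np.abs(rng.normal(1.0, 0.05, size=30))
            c[:10] *= boost  # comALS classifiers load extra on area-shape
            out.append(profile(c / c.sum(), group="comALS", cid=f"com{i}"))
        for i in range(3):
            c = np.abs(rng.normal(1.0, 0.05, size=30))
            out.append(profile(c / c.sum(), group="vcpALS", cid=f"vcp{i}"))
        return out

    def test_planted_enrichment_recovered(self, rng):
        tests = {
            t.category: t for t in category_lmm(self.make_profiles(rng), category_labels())
        }
        t = tests["area_shape"]
        assert t.effect > 0  # comALS-enriched
        assert t.p_value < 0.05

    def test_identical_groups_not_significant(self, rng):
        profs = self.make_profiles(rng, boost=1.0)
        tests = category_lmm(profs, category_labels())
        assert all(t.p_value > 0.05 for t in tests)

    def test_single_classifier_group_rejected(self, rng):
        profs = self.make_profiles(rng)[:4]  # only one vcpALS profile
        with pytest.raises(ValueError, match=">= 2"):
            category_lmm(profs, category_labels())


class TestPermutationZ:
    def test_planted_enrichment_gives_large_z(self):
        c = np.zeros(100)
        c[:10] = 0.1  # all mass on a 10-measurement category
        cats = np.array(["hot"] * 10 + ["cold"] * 90)
        z = {t.category: t.z for t in category_permutation_z(profile(c, names=[f"m{i}" for i in range(100)]), cats, seed=0)}
        assert z["hot"] > 5

    def test_seeded_determinism(self, rng):
        c = np.abs(rng.normal(size=60))
        c /= c.sum()
        p = profile(c, names=[f"m{i}" for i in range(60)])
        cats = np.array(["a", "b", "c"] * 20)
        za = [t.z for t in category_permutation_z(p, cats, n_perm=500, seed=9)]
        zb = [t.z for t in category_permutation_z(p, cats, n_perm=500, seed=9)]
        assert za == zb

    def test_uniform_profile_has_degenerate_null(self):
        p = profile(np.full(40, 0.025), names=[f"m{i}" for i in range(40)])
        cats = np.array(["a", "b"] * 20)
        assert all(t.z == 0.0 for t in category_permutation_z(p, cats, seed=1))

    def test_too_few_permutations_rejected(self):
        p = profile([0.5, 0.5], names=["m0", "m1"])
        with pytest.raises(ValueError):
            category_permutation_z(p, np.array(["a", "b"]), n_perm=50)


class TestNcRatioContribution:
    def test_reads_the_single_matching_column(self):
        p = profile(
            [0.6, 0.4],
            names=["Intensity_NCRatio_SFPQ", "AreaShape_F1"],
        )
        assert nc_ratio_contribution(p, "SFPQ") == pytest.approx(0.6)
        assert nc_ratio_contribution(p, "SFPQ") + 0.4 == pytest.approx(1.0)

    def test_absent_channel_rejected(self):
        p = profile([1.0], names=["AreaShape_F0"])
        with pytest.raises(ValueError):
            nc_ratio_contribution(p, "FUS")
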