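"""EM estimation: ascent, recovery, posteriors, covariance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dcmkit
from dcmkit.estimation import GDINAEstimator, class_posteriors, em_fit
from dcmkit.irf import ItemParams, class_probability_table
from dcmkit.latent import QMatrix


@pytest.fixture(scope="module")
def small_fit():
    q = dcmkit.generate_qmatrix(8, 2, {1: 0.5, 2: 0.5}, seed=5)
    params = dcmkit.generate_item_params(q, seed=6)
    prof = dcmkit.generate_profiles(
        800, {"kind": "independent", "prevalence": 0.4, "n_criteria": 2},
        seed=7)
    X = dcmkit.generate_responses(prof, q, params, seed=8)
    est = em_fit(X, q, assignment="GDINA", random_state=0)
    return X, q, params, est


class TestEmFit:
    def test_loglik_nondecreasing(self, small_fit):
        _, _, _, est = small_fit
        assert np.all(np.diff(est.loglik_path_) >= -1e-8)

    def test_class_props_simplex(self, small_fit):
        _, _, _, est = small_fit
        pi = est.class_props_
        assert pi.min() >= 0
        assert abs(pi.sum() - 1) < 1e-10
        assert np.isfinite(est.loglik_)

    def test_point_mass_structure_recovers_sample_means(self):
        # with the latent class fixed, the item MLE is the sample mean
        q = QMatrix(np.array([[1], [1], [1]]))
        rng = np.random.default_rng(3)
        X = (rng.random((500, 3)) < [0.3, 0.5, 0.7]).astype(float)
        pi = np.array([0.0, 1.0])  # everyone in the criterion-present class
        est = GDINAEstimator(q, structure="fixed", fixed_class_props=pi,
                             random_state=0).fit(X)
        for j in range(3):
            assert est.prob_tables_[j][1] == pytest.approx(
                X[:, j].mean(), abs=1e-9)

    def test_conjunctive_recovery_guess_slip(self):
        # DINA data, guess = slip = 0.1, J = 10, K = 2, n = 2000
        q = dcmkit.generate_qmatrix(10, 2, {1: 0.6, 2: 0.4}, seed=40)
        params = []
        for j in range(q.n_items):
            k = q.kstar(j)
            coeffs = np.array([0.1, 0.8])
            params.append(ItemParams("DINA" if k > 1 else "GDINA",
                                     q.entries[j], coeffs))
        prof = dcmkit.generate_profiles(
            2000, {"kind": "independent", "prevalence": 0.5, "n_criteria": 2},
            seed=41)
        X = dcmkit.generate_responses(prof, q, params, seed=42)
        est = em_fit(X, q, assignment=[p.model for p in params],
                     random_state=0)
        for j, p in enumerate(params):
            true = class_probability_table(p)
            assert np.abs(est.prob_tables_[j] - true).max() < 0.05

    def test_constant_item_warns_and_stays_bounded(self):
        q = QMatrix(np.array([[1], [1]]))
        X = np.column_stack([np.ones(60), np.random.default_rng(0)
                             .integers(0, 2, 60)]).astype(float)
        with pytest.warns(UserWarning, match="constant"):
            est = GDINAEstimator(q, random_state=0).fit(X)
        assert est.prob_tables_[0].max() <= 1 - est.prob_bound

    def test_input_validation(self):
        q = QMatrix(np.array([[1], [1]]))
        with pytest.raises(ValueError, match="empty"):
            GDINAEstimator(q).fit(np.empty((0, 2)))
        with pytest.raises(ValueError, match="non-binary"):
            GDINAEstimator(q).fit(np.array([[0.0, 2.0], [1.0, 0.0]]))

    def test_reduced_fit_matches_expanded_constraint_loglik(self):
        # a reduced fit and its saturated-expansion evaluation agree
        q = dcmkit.generate_qmatrix(6, 2, {1: 0.5, 2: 0.5}, seed=50)
        params = dcmkit.generate_item_params(
            q, seed=51, models=["GDINA" if q.kstar(j) == 1 else "ACDM"
                                for j in range(6)])
        prof = dcmkit.generate_profiles(
            1000, {"kind": "independent", "prevalence": 0.4,
                   "n_criteria": 2}, seed=52)
        X = dcmkit.generate_responses(prof, q, params, seed=53)
        fit = em_fit(X, q, assignment=[p.model for p in params],
                     random_state=0)
        # evaluating the same tables through the saturated expansion gives
        # the identical marginal log-likelihood
        from dcmkit.irf import expand_to_gdina

        expanded = [expand_to_gdina(p) for p in fit.item_params_]
        tables = [class_probability_table(p) for p in expanded]
        for t_fit, t_exp in zip(fit.prob_tables_, tables):
            assert np.allclose(t_fit, t_exp, atol=1e-9)
        assert fit.loglik_ == pytest.approx(fit.loglik_of(X), abs=1e-6)


class TestPosteriors:
    def test_uninformative_items_return_class_props(self):
        q = QMatrix(np.array([[1], [1]]))
        pi = np.array([0.3, 0.7])
        from conftest import assemble_fitted

        est = assemble_fitted(q, [np.array([0.6, 0.6]),
                                  np.array([0.4, 0.4])], pi)
        post = est.predict_proba(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert np.allclose(post, pi, atol=1e-12)

    def test_two_item_toy_matches_hand_bayes(self):
        # K=1, two items; posterior by explicit Bayes table
        q = QMatrix(np.array([[1], [1]]))
        p1 = np.array([0.2, 0.8])   # item 1: P(X=1 | alpha=0/1)
        p2 = np.array([0.3, 0.9])
        pi = np.array([0.6, 0.4])
        from conftest import assemble_fitted

        est = assemble_fitted(q, [p1, p2], pi)
        X = np.array([[1.0, 0.0]])
        lik = np.array([pi[0] * p1[0] * (1 - p2[0]),
                        pi[1] * p1[1] * (1 - p2[1])])
        expected = lik / lik.sum()
        assert np.allclose(est.predict_proba(X)[0], expected, atol=1e-12)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_rows_sum_to_one(self, small_fit, seed):
        X, q, _, est = small_fit
        rng = np.random.default_rng(seed)
        Xr = rng.integers(0, 2, size=(5, q.n_items)).astype(float)
        post = est.predict_proba(Xr)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-10)
        assert post.min() >= 0

    def test_all_missing_respondent_gets_prior(self, small_fit):
        X, q, _, est = small_fit
        row = np.full((1, q.n_items), np.nan)
        with pytest.warns(UserWarning, match="no observed"):
            post = est.predict_proba(row)
        assert np.allclose(post[0], est.class_props_, atol=1e-12)

    def test_functional_wrapper_equivalence(self, small_fit):
        X, _, _, est = small_fit
        assert np.array_equal(class_posteriors(X, est),
                              est.predict_proba(X))


class TestCovariance:
    def test_information_additivity_on_duplication(self, small_fit):
        X, q, _, est = small_fit
        c1, _ = est.item_covariance(X, 0)
        c2, _ = est.item_covariance(np.vstack([X, X]), 0)
        assert np.allclose(c2, c1 / 2, atol=1e-8)

    def test_single_class_bernoulli_closed_form(self):
        q = QMatrix(np.array([[1]]))
        rng = np.random.default_rng(9)
        X = (rng.random((400, 1)) < 0.35).astype(float)
        pi = np.array([0.0, 1.0])
        est = GDINAEstimator(q, structure="fixed", fixed_class_props=pi,
                             random_state=0).fit(X)
        cov, _ = est.item_covariance(X, 0)
        p = X[:, 0].mean()
        assert cov[1, 1] == pytest.approx(p * (1 - p) / X.shape[0],
                                          rel=1e-6)

    def test_covariance_tracks_sampling_variance(self):
        # Monte-Carlo: the OPG diagonal should match the empirical
        # refit-to-refit variance within a factor of two
        q = QMatrix(np.array([[1, 0], [1, 0], [0, 1], [0, 1], [1, 1]]))
        params = dcmkit.generate_item_params(
            q, seed=60, models=["GDINA"] * 4 + ["ACDM"])
        spec = {"kind": "independent", "prevalence": 0.5, "n_criteria": 2}
        reps = 120
        ests = []
        root = np.random.default_rng(61)
        for _ in range(reps):
            s = root.integers(2**31, size=2)
            prof = dcmkit.generate_profiles(600, spec, seed=int(s[0]))
            X = dcmkit.generate_responses(prof, q, params, seed=int(s[1]))
            fit = em_fit(X, q, assignment="GDINA", random_state=0)
            ests.append(fit.prob_tables_[0][1])  # item 1, criterion present
        prof = dcmkit.generate_profiles(600, spec, seed=1)
        X = dcmkit.generate_responses(prof, q, params, seed=2)
        fit = em_fit(X, q, assignment="GDINA", random_state=0)
        # the joint covariance accounts for co-estimation of the other
        # items and the structural proportions
        full, slices = fit.joint_covariance(X)
        var = full[slices[0], slices[0]][1, 1]
        ratio = np.var(ests, ddof=1) / var
        assert 0.5 < ratio < 2.0


def test_serialization_round_trips_fitted_values(small_fit, tmp_path):
    X, _, _, est = small_fit
    import json

    path = tmp_path / "fit.json"
    est.to_json(path)
    payload = json.loads(path.read_text())
    assert payload["loglik"] == pytest.approx(est.loglik_)
    assert np.allclose(payload["class_props"], est.class_props_)
    params = [ItemParams.from_dict(d) for d in payload["item_params"]]
    for p, orig in zip(params, est.item_params_):
        assert p == orig
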