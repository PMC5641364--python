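"""Item screening: S-X² fit, DIF Wald, decisions, and the exclusion loop."""

import itertools

import numpy as np
import pytest

import dcmkit
from dcmkit.estimation import em_fit
from dcmkit.latent import QMatrix
from dcmkit.screening import (
    dif_wald,
    screen_items,
    screening_loop,
    screening_reasons,
    sx2_item_fit,
)
from conftest import assemble_fitted


class TestSX2:
    def test_expected_proportions_match_enumeration(self):
        """Recursion-based rest-score expectations equal direct enumeration
        over all classes and response patterns (3 items, K = 1)."""
        q = QMatrix(np.array([[1], [1], [1]]))
        tables = [np.array([0.2, 0.8]), np.array([0.3, 0.7]),
                  np.array([0.25, 0.9])]
        pi = np.array([0.55, 0.45])
        est = assemble_fitted(q, tables, pi)

        # enumeration oracle for item 0: P(X0=1, rest=s) / P(rest=s)
        probs = {0: {}, 1: {}}
        joint = np.zeros(3)   # P(X0 = 1, rest score = s)
        marg = np.zeros(3)    # P(rest score = s)
        for c in (0, 1):
            for x in itertools.product((0, 1), repeat=3):
                p = pi[c]
                for j in range(3):
                    pj = tables[j][c]
                    p *= pj if x[j] == 1 else 1 - pj
                s = x[1] + x[2]
                marg[s] += p
                if x[0] == 1:
                    joint[s] += p
        expected = joint / marg

        from dcmkit.screening import _rest_score_dist

        dist = _rest_score_dist(est.prob_tables_, est.group_index_, 0)
        p_item = est.prob_tables_[0][est.group_index_[0]]
        got = ((pi * p_item) @ dist) / (pi @ dist)
        assert np.allclose(got[:3], expected, atol=1e-12)

    def test_statistic_nonnegative_and_df_bookkeeping(self):
        q = dcmkit.generate_qmatrix(12, 2, {1: 0.6, 2: 0.4}, seed=80)
        params = dcmkit.generate_item_params(q, seed=81)
        prof = dcmkit.generate_profiles(
            600, {"kind": "independent", "prevalence": 0.4,
                  "n_criteria": 2}, seed=82)
        X = dcmkit.generate_responses(prof, q, params, seed=83)
        est = em_fit(X, q, assignment="GDINA", random_state=0)
        for j in range(q.n_items):
            res = sx2_item_fit(X, est, j)
            if res.computable:
                assert res.statistic >= 0
                assert res.df >= 1
                assert 0 <= res.pvalue <= 1

    def test_too_few_score_groups_not_computable(self):
        q = QMatrix(np.array([[1], [1]]))
        X = np.ones((50, 2))
        X[:, 1] = 0
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = em_fit(X, q, random_state=0)
        res = sx2_item_fit(X, est, 0)
        assert not res.computable


class TestDifWald:
    @pytest.fixture(scope="class")
    def dif_setup(self):
        rows = [[1, 0]] * 4 + [[0, 1]] * 4 + [[1, 1], [1, 1]]
        q = QMatrix(np.array(rows))
        params = dcmkit.generate_item_params(
            q, seed=90, models=["GDINA"] * 8 + ["ACDM", "ACDM"],
            baseline_range=(0.10, 0.15), disc_range=(0.45, 0.60))
        prof = dcmkit.generate_profiles(
            1200, {"kind": "independent", "prevalence": 0.45,
                   "n_criteria": 2}, seed=91)
        X = dcmkit.generate_responses(prof, q, params, seed=92).astype(float)
        return q, params, prof, X

    def test_duplicated_groups_show_no_dif(self, dif_setup):
        q, _, _, X = dif_setup
        Xdup = np.vstack([X, X])
        groups = np.repeat([0, 1], X.shape[0])
        res = dif_wald(Xdup, groups, q, 8,
                       estimator_kwargs={"random_state": 0})
        assert res.statistic == pytest.approx(0.0, abs=1e-4)
        assert res.pvalue > 0.99

    def test_df_is_saturated_parameter_count(self, dif_setup):
        q, _, _, X = dif_setup
        groups = np.repeat([0, 1], X.shape[0] // 2)
        assert dif_wald(X, groups, q, 9,
                        estimator_kwargs={"random_state": 0}).df == 4
        assert dif_wald(X, groups, q, 0,
                        estimator_kwargs={"random_state": 0}).df == 2

    def test_injected_shift_detected(self, dif_setup):
        q, params, prof, X = dif_setup
        X = X.copy()
        focal = dcmkit.inject_dif(params[8], 0.2)
        from dcmkit.simulate import response_probabilities

        half = X.shape[0] // 2
        pfoc = response_probabilities(
            prof[half:], q, params[:8] + [focal] + params[9:])[:, 8]
        X[half:, 8] = (np.random.default_rng(93).random(half) < pfoc)
        groups = np.repeat([0, 1], half)
        res = dif_wald(X, groups, q, 8,
                       estimator_kwargs={"random_state": 0})
        assert res.pvalue < 0.05

    def test_small_group_floor(self, dif_setup):
        q, _, _, X = dif_setup
        groups = np.zeros(X.shape[0])
        groups[:10] = 1
        with pytest.warns(UserWarning, match="floor"):
            res = dif_wald(X, groups, q, 8, min_group=50)
        assert not res.computable


class TestDecisions:
    def test_discrimination_cut_is_strict(self):
        assert screening_reasons(0.452, 0.5) == ()
        assert screening_reasons(0.45, 0.5) == ()
        assert screening_reasons(0.449, 0.5) == ("low_discrimination",)

    def test_reason_codes_determine_decision(self):
        reasons = screening_reasons(0.3, 0.01, {"sex": 0.02})
        assert set(reasons) == {"low_discrimination", "poor_fit", "dif_sex"}
        assert screening_reasons(0.6, np.nan, {"sex": np.nan}) == ()


class TestScreeningLoop:
    @pytest.fixture(scope="class")
    def clean_study(self):
        q = dcmkit.generate_qmatrix(10, 2, {1: 0.6, 2: 0.4}, seed=202)
        params = dcmkit.generate_item_params(q, seed=203)
        prof = dcmkit.generate_profiles(
            900, {"kind": "independent", "prevalence": 0.45,
                  "n_criteria": 2}, seed=204)
        X = dcmkit.generate_responses(prof, q, params, seed=205)
        return q, params, X

    def test_clean_items_fixed_point(self, clean_study):
        q, _, X = clean_study
        final_q, rounds = screening_loop(
            X, q, estimator_kwargs={"random_state": 0})
        assert len(rounds) == 1
        assert final_q.n_items == q.n_items
        assert all(r.decision == "keep" for r in rounds[0])

    def test_planted_flat_item_dropped(self, clean_study):
        q, params, X = clean_study
        # append a flat (uninformative) item measuring criterion 1
        qext = QMatrix(np.vstack([q.entries, [1, 0]]),
                       item_ids=q.item_ids + ("flat",),
                       criterion_ids=q.criterion_ids)
        rng = np.random.default_rng(104)
        Xext = np.column_stack([X, (rng.random(X.shape[0]) < 0.5)])
        final_q, rounds = screening_loop(
            Xext, qext, estimator_kwargs={"random_state": 0})
        assert "flat" not in final_q.item_ids
        flat_rec = [r for r in rounds[0] if r.item_id == "flat"][0]
        assert "low_discrimination" in flat_rec.reasons
        # loop refits after the drop and then terminates
        assert all(r.decision == "keep" for r in rounds[-1])

    def test_forced_keep_guards_criterion_coverage(self):
        # both items measuring criterion 2 are flat: one must be retained
        rows = [[1, 0]] * 4 + [[0, 1]]
        q = QMatrix(np.array(rows))
        params = dcmkit.generate_item_params(q, seed=105)
        prof = dcmkit.generate_profiles(
            700, {"kind": "independent", "prevalence": 0.45,
                  "n_criteria": 2}, seed=106)
        X = dcmkit.generate_responses(prof, q, params, seed=107).astype(float)
        rng = np.random.default_rng(108)
        X[:, 4] = rng.random(700) < 0.5  # flatten the only S2 item
        with pytest.warns(UserWarning, match="retained despite flags"):
            final_q, rounds = screening_loop(
                X, q, estimator_kwargs={"random_state": 0})
        assert "item5" in final_q.item_ids
        rec = [r for r in rounds[0] if r.item_id == "item5"][0]
        assert rec.forced_keep

    def test_terminates_within_item_budget(self, clean_study):
        q, _, X = clean_study
        _, rounds = screening_loop(X, q,
                                   estimator_kwargs={"random_state": 0})
        assert len(rounds) <= q.n_items


def test_screen_items_report_round_trip(tmp_path):
    q = dcmkit.generate_qmatrix(8, 2, {1: 0.6, 2: 0.4}, seed=110)
    params = dcmkit.generate_item_params(q, seed=111)
    prof = dcmkit.generate_profiles(
        500, {"kind": "independent", "prevalence": 0.45, "n_criteria": 2},
        seed=112)
    X = dcmkit.generate_responses(prof, q, params, seed=113)
    recs = screen_items(X, q, estimator_kwargs={"random_state": 0})
    from dcmkit.screening import screening_report

    df = screening_report(recs)
    assert len(df) == 8
    assert {"item_id", "selected", "discrimination", "sx2_stat", "sx2_df",
            "sx2_p", "decision"} <= set(df.columns)
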