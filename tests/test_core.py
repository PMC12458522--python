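import logging
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from cpmkit import (
    EdgeMask,
    SyntheticSpec,
    edge_behavior_association,
    fit_cpm,
    loocv_cpm,
    network_strength,
    predict_cpm,
    select_edges,
    simulate_cohort,
)
from cpmkit.core import EdgeAssociation

from conftest import make_cohort


def naive_loocv(dataset, threshold, rule="sum_of_predictions"):
    """Straight-line per-fold re-implementation used as the dual oracle."""
    n = dataset.n_subjects
    pred = np.empty(n)
    masks = []
    for f in range(n):
        rows = [i for i in range(n) if i != f]
        X, y = dataset.edge_matrix[rows], dataset.score[rows]
        r = np.empty(dataset.n_edges)
        p = np.empty(dataset.n_edges)
        for k in range(dataset.n_edges):
            r[k], p[k] = stats.pearsonr(X[:, k], y)
        pos = np.flatnonzero((p < threshold) & (r > 0))
        neg = np.flatnonzero((p < threshold) & (r < 0))

        def ols(s):
            if np.ptp(s) == 0:
                return y.mean(), 0.0
            slope = np.cov(s, y, ddof=1)[0, 1] / np.var(s, ddof=1)
            return y.mean() - slope * s.mean(), slope

        sp, sn = X[:, pos].sum(axis=1), X[:, neg].sum(axis=1)
        (ap, bp), (an, bn) = ols(sp), ols(sn)
        tp = dataset.edge_matrix[f, pos].sum()
        tn = dataset.edge_matrix[f, neg].sum()
        if rule == "two_predictor":
            design = np.column_stack([np.ones(n - 1), sp, sn])
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            pred[f] = coef[0] + coef[1] * tp + coef[2] * tn
        else:
            pred[f] = (ap + bp * tp) + (an + bn * tn)
        masks.append((set(pos.tolist()), set(neg.tolist())))
    return pred, masks


class TestEdgeBehaviorAssociation:
    def test_printed_toy_matches_definitional_sums(self):
        edge = np.array([1.0, 2, 3, 4, 5, 6])
        score = np.array([2.0, 1, 4, 3, 6, 5])
        X = np.column_stack([edge, np.ones(6) * 0.5 + np.arange(6) % 2, -edge])
        X[:, 1] += np.array([0.1, -0.3, 0.2, 0.0, -0.1, 0.4])
        ds = make_cohort(X, score, node_count=3)
        r, p = edge_behavior_association(ds)
        n = 6
        sx, sy = math.fsum(edge), math.fsum(score)
        sxx = math.fsum(v * v for v in edge)
        syy = math.fsum(v * v for v in score)
        sxy = math.fsum(a * b for a, b in zip(edge, score))
        r_oracle = (n * sxy - sx * sy) / math.sqrt((n * sxx - sx**2) * (n * syy - sy**2))
        assert r[0] == pytest.approx(r_oracle, abs=1e-12)
        assert r[2] == pytest.approx(-r_oracle, abs=1e-12)
        for k in range(3):
            rk, pk = stats.pearsonr(X[:, k], score)
            assert r[k] == pytest.approx(rk, abs=1e-12)
            assert p[k] == pytest.approx(pk, rel=1e-10)

    def test_edge_equal_to_score_is_perfect(self, rng):
        score = rng.normal(size=10)
        X = np.column_stack([score, rng.normal(size=10), rng.normal(size=10)])
        r, p = edge_behavior_association(make_cohort(X, score, node_count=3))
        assert r[0] == pytest.approx(1.0, abs=1e-12)
        assert p[0] < 1e-12

    def test_orthogonalized_edge_has_zero_r(self, rng):
        score = rng.normal(size=10)
        raw = rng.normal(size=10)
        sc = score - score.mean()
        ortho = raw - (raw - raw.mean()) @ sc / (sc @ sc) * sc
        ortho -= ortho.mean() - raw.mean()  # keep nonconstant
        X = np.column_stack([ortho, rng.normal(size=10), rng.normal(size=10)])
        r, _ = edge_behavior_association(make_cohort(X, score, node_count=3))
        assert abs(r[0]) < 1e-12

    def test_partial_pearson_matches_residual_oracle(self, rng):
        n = 12
        X = rng.normal(size=(n, 3))
        score = rng.normal(size=n)
        age = rng.uniform(5, 14, n)
        motion = rng.uniform(0.05, 0.3, n)
        ds = make_cohort(X, score, age=age, motion=motion, node_count=3)
        r, p = edge_behavior_association(ds, method="partial_pearson")
        design = np.column_stack([np.ones(n), age, motion])
        proj = design @ np.linalg.solve(design.T @ design, design.T)
        y_res = score - proj @ score
        df = n - 2 - 2
        for k in range(3):
            x_res = X[:, k] - proj @ X[:, k]
            rk = stats.pearsonr(x_res, y_res)[0]
            assert r[k] == pytest.approx(rk, abs=1e-12)
            t = abs(rk) * math.sqrt(df / (1 - rk**2))
            assert p[k] == pytest.approx(2 * stats.t.sf(t, df), rel=1e-10)

    def test_constant_edge_logged_not_crashed(self, rng, caplog):
        X = np.column_stack([np.full(8, 2.0), rng.normal(size=8), rng.normal(size=8)])
        ds = make_cohort(X, rng.normal(size=8), node_count=3)
        with caplog.at_level(logging.WARNING, logger="cpmkit.core"):
            r, p = edge_behavior_association(ds)
        assert r[0] == 0.0 and p[0] == 1.0
        assert "constant edge" in caplog.text


class TestSelectEdges:
    def test_all_insignificant_gives_empty_masks(self):
        assoc = EdgeAssociation(r=np.array([0.2, -0.3]), p=np.array([0.5, 0.5]))
        pos, neg = select_edges(assoc, 0.05)
        assert len(pos) == 0 and len(neg) == 0

    @pytest.mark.parametrize(
        "threshold,expected_pos,expected_neg",
        [(0.05, {0}, {1}), (0.01, {0}, set())],
    )
    def test_threshold_splits_by_sign(self, threshold, expected_pos, expected_neg):
        assoc = EdgeAssociation(
            r=np.array([0.5, -0.4, 0.9]), p=np.array([0.001, 0.04, 0.2])
        )
        pos, neg = select_edges(assoc, threshold)
        assert pos.as_set() == expected_pos
        assert neg.as_set() == expected_neg

    def test_zero_r_never_selected(self):
        assoc = EdgeAssociation(r=np.array([0.0, 0.5]), p=np.array([0.0001, 0.0001]))
        pos, neg = select_edges(assoc, 0.05)
        assert pos.as_set() == {1} and len(neg) == 0

    @given(st.integers(0, 2**32 - 1))
    def test_disjoint_and_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        assoc = EdgeAssociation(r=rng.normal(size=30), p=rng.uniform(size=30))
        masks = {t: select_edges(assoc, t) for t in (0.01, 0.05, 0.2)}
        for pos, neg in masks.values():
            assert not (pos.as_set() & neg.as_set())
        assert masks[0.01][0].as_set() <= masks[0.05][0].as_set() <= masks[0.2][0].as_set()
        assert masks[0.01][1].as_set() <= masks[0.05][1].as_set() <= masks[0.2][1].as_set()


class TestNetworkStrength:
    def test_sums_masked_entries(self):
        mask = EdgeMask(np.array([0, 2]), "positive", 3)
        assert network_strength(np.array([1.0, 5.0, 2.0]), mask) == 3.0

    def test_empty_mask_is_zero(self):
        mask = EdgeMask(np.array([], dtype=int), "positive", 3)
        assert network_strength(np.array([1.0, 5.0, 2.0]), mask) == 0.0

    def test_full_mask_on_ones_counts_edges(self):
        E = 45
        mask = EdgeMask(np.arange(E), "negative", E)
        assert network_strength(np.ones(E), mask) == E


class TestFitPredict:
    def test_noiseless_line_recovered(self, rng):
        X = rng.normal(size=(12, 6))
        pos = EdgeMask(np.array([0, 3]), "positive", 6)
        neg = EdgeMask(np.array([1]), "negative", 6)
        strength = X[:, [0, 3]].sum(axis=1)
        y = 2.5 * strength - 7.0
        ds = make_cohort(X, y, node_count=4)
        model = fit_cpm(ds, pos, neg)
        assert model.pos_coefficients[1] == pytest.approx(2.5, abs=1e-10)
        assert model.pos_coefficients[0] == pytest.approx(-7.0, abs=1e-10)
        _, _, combined = predict_cpm(model, X)
        pred_pos = model.pos_coefficients[0] + model.pos_coefficients[1] * strength
        assert np.allclose(pred_pos, y, atol=1e-9)
        assert isinstance(combined, np.ndarray)

    def test_empty_mask_predicts_training_mean(self):
        X = np.random.default_rng(0).normal(size=(3, 3))
        ds = make_cohort(X, [10.0, 20.0, 30.0], node_count=3)
        empty = EdgeMask(np.array([], dtype=int), "positive", 3)
        neg = EdgeMask(np.array([0]), "negative", 3)
        model = fit_cpm(ds, empty, neg)
        pred_pos, _, _ = predict_cpm(model, np.array([99.0, 1.0, -5.0]))
        assert pred_pos == pytest.approx(20.0)

    def test_coefficients_match_closed_form_ols(self, rng):
        X = rng.normal(size=(5, 6))
        y = rng.normal(size=5)
        pos = EdgeMask(np.array([0, 2, 4]), "positive", 6)
        neg = EdgeMask(np.array([1, 5]), "negative", 6)
        model = fit_cpm(make_cohort(X, y, node_count=4), pos, neg)
        s = X[:, [0, 2, 4]].sum(axis=1)
        slope = ((s - s.mean()) @ (y - y.mean())) / ((s - s.mean()) @ (s - s.mean()))
        assert model.pos_coefficients[1] == pytest.approx(slope, abs=1e-12)
        assert model.pos_coefficients[0] == pytest.approx(y.mean() - slope * s.mean(), abs=1e-12)

    def test_too_few_subjects_rejected(self, rng):
        X = rng.normal(size=(2, 3))
        with pytest.raises(ValueError, match="at least 3"):
            fit_cpm(
                make_cohort(X, [1.0, 2.0], node_count=3),
                EdgeMask(np.array([0]), "positive", 3),
                EdgeMask(np.array([1]), "negative", 3),
            )

    def test_zero_slope_models_sum_intercepts(self):
        pos = EdgeMask(np.array([0]), "positive", 3)
        neg = EdgeMask(np.array([1]), "negative", 3)
        from cpmkit.core import CPMModel

        model = CPMModel(pos, neg, (5.0, 0.0), (7.0, 0.0))
        _, _, combined = predict_cpm(model, np.array([1.0, 2.0, 3.0]))
        assert combined == 12.0

    def test_combined_sum_rule_is_exact_sum(self, planted_cohort):
        ds, _ = planted_cohort
        res = loocv_cpm(ds, 0.05)
        assert np.allclose(res.predicted, res.predicted_pos + res.predicted_neg, atol=0)


class TestLoocv:
    def test_minimal_five_subjects_completes(self, rng):
        X = rng.normal(size=(5, 10))
        res = loocv_cpm(make_cohort(X, rng.normal(size=5), node_count=5), 0.2)
        assert len(res.folds) == 5

    def test_perfect_edge_selected_in_every_fold(self, rng):
        n = 30
        score = rng.normal(size=n)
        X = rng.normal(size=(n, 15))
        X[:, 7] = score
        res = loocv_cpm(make_cohort(X, score, node_count=6), 0.01)
        for fold in res.folds:
            assert 7 in fold.pos_mask.as_set()

    @pytest.mark.parametrize("rule", ["sum_of_predictions", "two_predictor"])
    def test_matches_naive_reimplementation(self, planted_cohort, rule):
        ds, _ = planted_cohort
        res = loocv_cpm(ds, 0.05, combined_rule=rule)
        pred_oracle, masks_oracle = naive_loocv(ds, 0.05, rule)
        for fold, (pos, neg) in zip(res.folds, masks_oracle):
            assert fold.pos_mask.as_set() == pos
            assert fold.neg_mask.as_set() == neg
        assert np.allclose(res.predicted, pred_oracle, atol=1e-10)

    def test_fold_masks_equal_external_reselection(self):
        # n = 12 subjects, 10 nodes -> E = 45
        ds, _ = simulate_cohort(
            SyntheticSpec(n_subjects=12, n_nodes=10, n_signal_pos=3, n_signal_neg=3, seed=21)
        )
        res = loocv_cpm(ds, 0.1)
        for f in range(ds.n_subjects):
            rows = np.array([i for i in range(ds.n_subjects) if i != f])
            assoc = edge_behavior_association(ds.subset(rows))
            pos, neg = select_edges(assoc, 0.1)
            assert res.folds[f].pos_mask.as_set() == pos.as_set()
            assert res.folds[f].neg_mask.as_set() == neg.as_set()

    def test_subject_permutation_equivariance(self, planted_cohort):
        ds, _ = planted_cohort
        res = loocv_cpm(ds, 0.05)
        perm = np.random.default_rng(77).permutation(ds.n_subjects)
        res_p = loocv_cpm(ds.subset(perm), 0.05)
        by_id = {f.held_out_subject: f for f in res.folds}
        for fold in res_p.folds:
            ref = by_id[fold.held_out_subject]
            assert fold.pos_mask.as_set() == ref.pos_mask.as_set()
            assert fold.predicted_combined == pytest.approx(ref.predicted_combined, abs=1e-9)

    def test_partial_method_agrees_with_manual_fold(self, planted_cohort):
        ds, _ = planted_cohort
        res = loocv_cpm(ds, 0.1, method="partial_pearson")
        rows = np.arange(1, ds.n_subjects)
        assoc = edge_behavior_association(ds.subset(rows), "partial_pearson")
        pos, neg = select_edges(assoc, 0.1)
        assert res.folds[0].pos_mask.as_set() == pos.as_set()
        assert res.folds[0].neg_mask.as_set() == neg.as_set()

    def test_degenerate_fold_error_names_subject(self, rng):
        X = rng.normal(size=(6, 10))
        y = np.array([1.0, 1, 1, 1, 1, 2])
        with pytest.raises(ValueError, match="constant"):
            loocv_cpm(make_cohort(X, y, node_count=5), 0.05)
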