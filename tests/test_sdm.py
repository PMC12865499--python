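import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refugia.sdm import (build_presence_background, ensemble_predict, evaluate_auc,
                         evaluate_tss, fit_ensemble, fit_parametric, fit_sre,
                         sample_pseudo_absences, split_cv, summarize_evals,
                         thin_occurrences)
from refugia.synthetic import OccurrenceSet

from conftest import make_occurrences, make_raster
from oracles import auc_pair_counting, irls_logistic, tss_exhaustive


class TestThinning:
    def test_collapses_cell_duplicates(self):
        grid = make_raster(np.zeros((10, 10)))
        occ = make_occurrences([(2, 2), (2, 2), (2, 2), (5, 5)], grid)
        assert len(thin_occurrences(occ, grid)) == 2

    def test_idempotent(self):
        grid = make_raster(np.zeros((10, 10)))
        occ = make_occurrences([(1, 1), (2, 3), (4, 4)], grid)
        once = thin_occurrences(occ, grid)
        assert thin_occurrences(once, grid).table.equals(once.table)

    def test_first_record_wins(self):
        grid = make_raster(np.zeros((5, 5)))
        occ = make_occurrences([(1, 1), (1, 1)], grid, elevation=[100.0, 200.0])
        thinned = thin_occurrences(occ, grid)
        assert thinned.table["elevation"].iloc[0] == 100.0

    def test_count_equals_distinct_cells_bruteforce(self):
        rng = np.random.default_rng(3)
        grid = make_raster(np.zeros((10, 10)))
        rc = rng.integers(0, 10, size=(100, 2))
        occ = make_occurrences(rc, grid)
        assert len(thin_occurrences(occ, grid)) == len({tuple(p) for p in rc})

    def test_empty_input_warns(self):
        grid = make_raster(np.zeros((5, 5)))
        occ = make_occurrences(np.empty((0, 2), dtype=int), grid)
        with pytest.warns(UserWarning, match="empty"):
            assert len(thin_occurrences(occ, grid)) == 0


class TestPseudoAbsences:
    def test_exhaustion_selects_every_candidate(self):
        domain = make_raster(np.zeros((3, 4)))
        pres = make_occurrences([(0, 0), (1, 1)], domain)
        with pytest.warns(UserWarning, match="reduced"):
            sets = sample_pseudo_absences(domain, pres, n_sets=2, n_each=20, seed=0)
        for s in sets:
            assert len(s) == 10
            assert not {(0, 0), (1, 1)} & set(map(tuple, s))

    def test_deterministic_and_seed_sensitive(self):
        domain = make_raster(np.zeros((20, 20)))
        pres = make_occurrences([(0, 0)], domain)
        a = sample_pseudo_absences(domain, pres, n_sets=2, n_each=50, seed=1)
        b = sample_pseudo_absences(domain, pres, n_sets=2, n_each=50, seed=1)
        c = sample_pseudo_absences(domain, pres, n_sets=2, n_each=50, seed=2)
        np.testing.assert_array_equal(a[0], b[0])
        assert not np.array_equal(a[0], c[0])
        assert not np.array_equal(a[0], a[1])  # sets differ within one seed

    def test_cell_inclusion_frequency_is_uniform(self):
        from scipy import stats
        domain = make_raster(np.zeros((4, 4)))
        pres = make_occurrences([(0, 0)], domain)  # 15 candidates
        target = (2, 2)
        hits = 0
        n_rep = 2000
        for seed in range(n_rep):
            s = sample_pseudo_absences(domain, pres, n_sets=1, n_each=5, seed=seed)[0]
            hits += target in set(map(tuple, s))
        lo, hi = stats.binom.ppf([0.0005, 0.9995], n_rep, 5 / 15)
        assert lo <= hits <= hi

    def test_no_candidates_is_an_error(self):
        domain = make_raster(np.zeros((2, 2)))
        pres = make_occurrences([(0, 0), (0, 1), (1, 0), (1, 1)], domain)
        with pytest.raises(ValueError, match="no candidate"):
            sample_pseudo_absences(domain, pres, n_sets=1, n_each=1, seed=0)


class TestSplitCv:
    def test_seventy_thirty_arithmetic(self):
        splits = split_cv(10, 10, repeats=1, seed=0)
        train, test = splits[0]
        assert (train < 10).sum() == 7 and (test < 10).sum() == 3
        assert (train >= 10).sum() == 7 and (test >= 10).sum() == 3

    def test_every_repeat_partitions_all_indices(self):
        splits = split_cv(13, 37, repeats=10, seed=1)
        assert len(splits) == 10
        for train, test in splits:
            combined = np.sort(np.concatenate([train, test]))
            np.testing.assert_array_equal(combined, np.arange(50))

    def test_repeats_are_distinct(self):
        splits = split_cv(20, 20, repeats=10, seed=2)
        trains = {tuple(tr) for tr, _ in splits}
        assert len(trains) == 10

    def test_too_few_presences_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            split_cv(5, 100)


class TestSre:
    def test_envelope_contains_its_support_at_q0(self):
        X = np.array([[0.0, 0.0], [1.0, 2.0], [2.0, 1.0]])
        model = fit_sre(X, q=0.0)
        np.testing.assert_array_equal(model.predict(X), 1.0)

    def test_point_outside_range_scores_zero(self):
        model = fit_sre(np.array([[0.0, 0.0], [1.0, 1.0]]), q=0.0)
        assert model.predict(np.array([[5.0, 0.5]]))[0] == 0.0

    def test_matches_interval_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 2))
        q = 0.025
        model = fit_sre(X, q=q)
        lo = np.quantile(X, q, axis=0)
        hi = np.quantile(X, 1 - q, axis=0)
        probe = rng.normal(size=(50, 2), scale=2)
        expected = np.all((probe >= lo) & (probe <= hi), axis=1).astype(float)
        np.testing.assert_array_equal(model.predict(probe), expected)

    def test_large_quantile_rejected(self):
        with pytest.raises(ValueError, match="q"):
            fit_sre(np.zeros((5, 2)), q=0.5)


class TestLogisticPoly2:
    def test_separable_data_reaches_training_auc_one(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-3, 0.5, (30, 2)), rng.normal(3, 0.5, (30, 2))])
        y = np.repeat([0.0, 1.0], 30)
        model = fit_parametric(X, y, "logistic_poly2")
        assert evaluate_auc(model.predict(X), y) == 1.0

    def test_null_labels_give_chance_auc(self):
        # training AUC carries a small overfit inflation from the 5 expanded
        # terms; the mean over simulations must still sit near chance
        aucs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(2000, 2))
            y = rng.integers(0, 2, 2000).astype(float)
            model = fit_parametric(X, y, "logistic_poly2")
            aucs.append(evaluate_auc(model.predict(X), y))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_coefficients_match_irls_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 2))
        eta = 0.5 + X[:, 0] - 0.8 * X[:, 1] + 0.3 * X[:, 0] * X[:, 1]
        y = (rng.random(50) < 1 / (1 + np.exp(-eta))).astype(float)
        model = fit_parametric(X, y, "logistic_poly2")
        assert not model.penalized
        D = model._design(X)
        expected = irls_logistic(D, y)
        np.testing.assert_allclose(model.coef, expected, atol=1e-6)

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_parametric(np.zeros((10, 2)), np.ones(10), "logistic_poly2")

    def test_boosted_trees_contract(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(-1, 1, (100, 2)), rng.normal(1, 1, (100, 2))])
        y = np.repeat([0.0, 1.0], 100)
        model = fit_parametric(X, y, "boosted_trees", seed=0)
        p = model.predict(X)
        assert p.min() >= 0 and p.max() <= 1
        assert evaluate_auc(p, y) > 0.8


class TestMetrics:
    def test_perfect_ranking(self):
        assert evaluate_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert evaluate_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_perfectly_separated_tss_is_one(self):
        tss, _ = evaluate_tss([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert tss == 1.0

    def test_null_tss_near_zero(self):
        rng = np.random.default_rng(4)
        scores = rng.random(5000)
        labels = rng.integers(0, 2, 5000)
        tss, _ = evaluate_tss(scores, labels)
        assert tss == pytest.approx(0.0, abs=0.06)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            evaluate_auc([0.1, 0.2], [1, 1])
        with pytest.raises(ValueError, match="both"):
            evaluate_tss([0.1, 0.2], [0, 0])

    @pytest.mark.parametrize("seed", range(20))
    def test_metrics_match_bruteforce_oracles(self, seed):
        rng = np.random.default_rng(seed)
        # coarse score grid forces ties; both classes guaranteed
        scores = rng.choice(np.linspace(0, 1, 11), size=30)
        labels = np.concatenate([[0, 1], rng.integers(0, 2, 28)])
        assert evaluate_auc(scores, labels) == auc_pair_counting(scores, labels)
        assert evaluate_tss(scores, labels) == tss_exhaustive(scores, labels)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6), st.floats(0.1, 5.0))
    def test_auc_invariant_under_monotone_transform(self, seed, scale):
        rng = np.random.default_rng(seed)
        scores = rng.random(40)
        labels = np.concatenate([[0, 1], rng.integers(0, 2, 38)])
        a = evaluate_auc(scores, labels)
        b = evaluate_auc(np.exp(scale * scores), labels)
        assert a == pytest.approx(b, abs=1e-12)


class TestEnsemble:
    def _members(self, preds_tss):
        """Stub members with fixed per-cell predictions and TSS values."""
        from refugia.sdm import EvalResult, FittedMember

        class Stub:
            def __init__(self, vals):
                self.vals = np.asarray(vals, dtype=float)

            def predict(self, X):
                return self.vals[: len(X)]

        out = []
        for k, (vals, tss) in enumerate(preds_tss):
            ev = EvalResult("stub", 0, k, auc=0.9, tss=tss, tss_threshold=0.5)
            out.append(FittedMember("stub", 0, k, model=Stub(vals), eval=ev))
        return out

    def _predictors(self, n=4):
        data = np.random.default_rng(0).normal(size=(2, 2, 2))
        pc = make_raster(data)
        from refugia.synthetic import SLICE_LABELS
        return {s: pc for s in SLICE_LABELS}

    def test_single_member_identity(self):
        members = self._members([([0.2, 0.4, 0.6, 0.8], 0.9)])
        stack = ensemble_predict(members, self._predictors(), tss_min=0.4)
        np.testing.assert_allclose(stack.current.data.ravel(), [0.2, 0.4, 0.6, 0.8])

    def test_opposite_binary_members_average_to_half(self):
        members = self._members([([0.0] * 4, 0.9), ([1.0] * 4, 0.9)])
        stack = ensemble_predict(members, self._predictors(), tss_min=0.4)
        np.testing.assert_allclose(stack.current.data, 0.5)

    def test_committee_mean_over_passing_members_only(self):
        preds = [([0.1] * 4, 0.9), ([0.5] * 4, 0.9), ([0.9] * 4, 0.2)]
        members = self._members(preds)
        stack = ensemble_predict(members, self._predictors(), tss_min=0.4)
        np.testing.assert_allclose(stack.current.data, 0.3)  # third member excluded

    def test_five_member_mean_matches_hand_average(self):
        rng = np.random.default_rng(9)
        preds = [(rng.random(4), 0.5 + 0.1 * k) for k in range(5)]
        members = self._members(preds)
        stack = ensemble_predict(members, self._predictors(), tss_min=0.0)
        expected = np.mean([p for p, _ in preds], axis=0).reshape(2, 2)
        np.testing.assert_allclose(stack.current.data, expected)

    def test_removing_below_average_member_raises_mean(self):
        preds = [([0.8] * 4, 0.9), ([0.6] * 4, 0.9), ([0.1] * 4, 0.9)]
        all_m = self._members(preds)
        trimmed = self._members(preds[:2])
        full = ensemble_predict(all_m, self._predictors(), tss_min=0.4)
        part = ensemble_predict(trimmed, self._predictors(), tss_min=0.4)
        assert np.all(part.current.data > full.current.data)

    def test_no_passing_member_raises_listing_tss(self):
        members = self._members([([0.5] * 4, 0.1), ([0.5] * 4, 0.2)])
        with pytest.raises(ValueError, match="TSS.*0.100"):
            ensemble_predict(members, self._predictors(), tss_min=0.4)


class TestFitEnsemble:
    def test_member_grid_and_summary_shape(self):
        rng = np.random.default_rng(10)
        domain = make_raster(rng.normal(size=(2, 12, 12)))
        pres_rc = np.column_stack([rng.integers(0, 12, 15), rng.integers(0, 12, 15)])
        pres_rc = np.unique(pres_rc, axis=0)
        occ = make_occurrences(pres_rc, domain)
        # separate presences from background in predictor space
        domain.data[:, pres_rc[:, 0], pres_rc[:, 1]] += 4.0
        pa = sample_pseudo_absences(domain, occ, n_sets=2, n_each=40, seed=0)
        pb = build_presence_background(occ, domain, pa)
        members = fit_ensemble(pb, algorithms=("sre", "logistic_poly2"),
                               repeats=3, seed=0)
        assert len(members) == 2 * 3 * 2
        summary = summarize_evals(members)
        assert set(summary["algorithm"]) == {"sre", "logistic_poly2"}
        assert (summary["auc_mean"] > 0.8).all()
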