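import itertools
import math

import numpy as np
import pytest

from pathpair import (
    ClassifierSpec,
    ResultsStore,
    SimConfig,
    SplitPlan,
    aggregate_importance,
    build_pair_dataset,
    compute_metrics,
    importance_correlation,
    run_cv,
    simulate,
    tune,
)
from pathpair.errors import (
    AggregationError,
    InsufficientPairsError,
    ShapeError,
    TuningError,
)
from pathpair.evaluate import ImportanceTable, TrialRecord


def _contingency_oracle(tp, fp, tn, fn):
    """Closed-form confusion-matrix metrics, zero-denominator -> 0."""
    n = tp + fp + tn + fn
    acc = (tp + tn) / n
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    d = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(d) if d else 0.0
    return acc, prec, rec, f1, mcc


def _sequences(tp, fp, tn, fn):
    pred = [1] * tp + [1] * fp + [0] * tn + [0] * fn
    truth = [1] * tp + [0] * fp + [0] * tn + [1] * fn
    return pred, truth


class TestComputeMetrics:
    def test_perfect_prediction(self):
        m = compute_metrics([1, 0, 1, 0], [1, 0, 1, 0])
        assert m.mcc == 1.0 and m.f1 == 1.0 and m.accuracy == 1.0

    def test_all_negative_predictions_give_zero_mcc(self):
        m = compute_metrics([0, 0, 0, 0], [1, 0, 1, 0])
        assert m.mcc == 0.0 and m.precision == 0.0 and m.recall == 0.0

    def test_known_contingency_value(self):
        # TP=4, TN=90, FP=3, FN=3 -> MCC = 351/651
        pred, truth = _sequences(tp=4, fp=3, tn=90, fn=3)
        m = compute_metrics(pred, truth)
        assert m.mcc == pytest.approx(351 / 651)
        assert m.mcc == pytest.approx(0.5392, abs=5e-5)

    def test_exhaustive_small_count_agreement_with_oracle(self):
        for tp, fp, tn, fn in itertools.product(range(6), repeat=4):
            if tp + fp + tn + fn == 0:
                continue
            pred, truth = _sequences(tp, fp, tn, fn)
            m = compute_metrics(pred, truth)
            acc, prec, rec, f1, mcc = _contingency_oracle(tp, fp, tn, fn)
            assert m.accuracy == pytest.approx(acc)
            assert m.precision == pytest.approx(prec)
            assert m.recall == pytest.approx(rec)
            assert m.f1 == pytest.approx(f1)
            assert m.mcc == pytest.approx(mcc)
            assert -1 <= m.mcc <= 1

    def test_agrees_with_sklearn_on_mixed_predictions(self):
        from sklearn.metrics import f1_score, matthews_corrcoef

        rng = np.random.default_rng(0)
        for _ in range(20):
            truth = rng.integers(0, 2, 30)
            pred = rng.integers(0, 2, 30)
            m = compute_metrics(pred, truth)
            assert m.mcc == pytest.approx(matthews_corrcoef(truth, pred), abs=1e-12)
            assert m.f1 == pytest.approx(f1_score(truth, pred, zero_division=0))

    def test_length_mismatch_raises(self):
        with pytest.raises(ShapeError):
            compute_metrics([1, 0], [1])


@pytest.fixture(scope="module")
def small_ds():
    m, mem, _ = simulate(SimConfig(n_metabolites=300, n_pathways=4, seed=42))
    return build_pair_dataset(m, mem)


class TestRunCv:
    def test_cardinality_and_store_rows(self, small_ds):
        with ResultsStore() as store:
            records = run_cv(
                ClassifierSpec("gbt", {"n_estimators": 50}, seed=0),
                small_ds,
                3,
                SplitPlan(seed=0),
                store=store,
            )
            assert len(records) == 3
            got = store.query(
                "SELECT COUNT(*) AS n FROM cv_results "
                "WHERE pathway = 'overall' AND metric_name = 'mcc'"
            )
            assert got.n[0] == 3
            per_path = store.query(
                "SELECT COUNT(DISTINCT pathway) AS n FROM cv_results "
                "WHERE pathway != 'overall'"
            )
            assert per_path.n[0] == 4

    def test_per_pathway_mccs_reported_for_every_pathway(self, small_ds):
        records = run_cv(
            ClassifierSpec("gbt", {"n_estimators": 50}, seed=0),
            small_ds,
            1,
            SplitPlan(seed=5),
        )
        assert set(records[0].per_pathway_mcc) == set(small_ds.pathways.entry_ids)

    def test_planted_signal_recovered(self, small_ds):
        records = run_cv(
            ClassifierSpec("gbt", seed=0), small_ds, 5, SplitPlan(seed=0)
        )
        mccs = [r.metrics.mcc for r in records]
        assert np.mean(mccs) >= 0.6  # planted signal at reduced sample size

    def test_iteration_seeds_are_independent_of_execution_order(self, small_ds):
        spec = ClassifierSpec("gbt", {"n_estimators": 50}, seed=0)
        plan = SplitPlan(seed=10)
        full = run_cv(spec, small_ds, 3, plan)
        # re-running only the final iteration reproduces its metrics
        last = run_cv(spec, small_ds, 3, plan)[2]
        assert full[2].metrics == last.metrics


class TestTune:
    def test_singleton_space_returns_that_point(self, small_ds):
        space = {"n_estimators": {"type": "categorical", "choices": [60]}}
        best = tune(space, small_ds, kind="gbt", n_trials=2, cv_per_trial=2, seed=0)
        assert best == {"n_estimators": 60}

    def test_dominant_configuration_selected(self, small_ds):
        # 2 estimators of depth 1 cannot learn 4 pathway signatures;
        # 150 deeper trees can: the dominant point must win.
        space = {
            "n_estimators": {"type": "categorical", "choices": [2, 150]},
            "max_depth": {"type": "categorical", "choices": [6]},
        }
        with ResultsStore() as store:
            best = tune(
                space,
                small_ds,
                kind="gbt",
                n_trials=6,
                cv_per_trial=3,
                store=store,
                seed=1,
            )
            assert best["n_estimators"] == 150
            trials = store.query("SELECT * FROM trials")
            assert len(trials) == 6

    def test_median_of_trial_mccs(self):
        t = TrialRecord(0, {}, mccs=[0.2, 0.4, 0.6])
        assert t.median_mcc == pytest.approx(0.4)
        t_even = TrialRecord(0, {}, mccs=[0.2, 0.4])
        assert t_even.median_mcc == pytest.approx(0.3)

    def test_empty_space_raises(self, small_ds):
        with pytest.raises(TuningError):
            tune({}, small_ds, kind="gbt", n_trials=1, cv_per_trial=1)

    def test_deterministic_given_seed(self, small_ds):
        space = {
            "n_estimators": {"type": "int", "low": 10, "high": 60},
            "learning_rate": {"type": "float", "low": 0.05, "high": 0.3, "log": True},
        }
        kw = dict(kind="gbt", n_trials=3, cv_per_trial=2, seed=9)
        assert tune(space, small_ds, **kw) == tune(space, small_ds, **kw)


class TestAggregateImportance:
    def test_equal_scores_give_uniform_relative_importance(self):
        table = aggregate_importance([{"metabolite::a": 2.0, "metabolite::b": 2.0}])
        np.testing.assert_allclose(
            table.table.mean_relative_importance, [0.5, 0.5]
        )

    def test_mean_of_identical_iterations_is_idempotent(self):
        scores = {"metabolite::a": 1.0, "metabolite::b": 3.0}
        one = aggregate_importance([scores])
        two = aggregate_importance([scores, scores])
        np.testing.assert_allclose(
            one.table.mean_relative_importance, two.table.mean_relative_importance
        )

    def test_matches_brute_force_softmax_mean_oracle(self):
        rng = np.random.default_rng(2)
        names = [f"metabolite::f{j}" for j in range(5)]
        iters = [dict(zip(names, rng.uniform(0, 3, 5))) for _ in range(3)]
        table = aggregate_importance(iters)
        raw = np.array([[it[n] for n in names] for it in iters])
        soft = np.exp(raw) / np.exp(raw).sum(axis=1, keepdims=True)
        expected = dict(zip(names, soft.mean(axis=0)))
        got = dict(
            zip(table.table.feature_name, table.table.mean_relative_importance)
        )
        for name in names:
            assert got[name] == pytest.approx(expected[name])

    def test_per_iteration_relative_importances_sum_to_one(self):
        rng = np.random.default_rng(3)
        iters = [
            {f"metabolite::f{j}": float(rng.uniform(0, 2)) for j in range(4)}
            for _ in range(5)
        ]
        table = aggregate_importance(iters)
        np.testing.assert_allclose(
            table.per_iteration_relative.sum(axis=1), np.ones(5)
        )

    def test_always_zero_features_are_excluded(self):
        iters = [
            {"metabolite::a": 1.0, "metabolite::dead": 0.0},
            {"metabolite::a": 2.0, "metabolite::dead": 0.0},
        ]
        table = aggregate_importance(iters)
        assert list(table.table.feature_name) == ["metabolite::a"]

    def test_ranks_descend_with_name_tiebreak(self):
        iters = [{"metabolite::b": 1.0, "metabolite::a": 1.0, "pathway::c": 9.0}]
        t = aggregate_importance(iters).table
        assert list(t.feature_name) == [
            "pathway::c", "metabolite::a", "metabolite::b"
        ]
        assert list(t["rank"]) == [1, 2, 3]

    def test_counterpart_rank_links_shared_atom_colors(self):
        iters = [{"metabolite::x": 3.0, "pathway::x": 1.0, "pathway::y": 2.0}]
        t = aggregate_importance(iters).table.set_index("feature_name")
        assert t.loc["metabolite::x", "counterpart_rank"] == t.loc["pathway::x", "rank"]
        assert np.isnan(t.loc["pathway::y", "counterpart_rank"])

    def test_empty_input_raises(self):
        with pytest.raises(AggregationError):
            aggregate_importance([])


def _table_from_importances(met, path):
    iters = [
        {**{f"metabolite::{k}": v for k, v in met.items()},
         **{f"pathway::{k}": v for k, v in path.items()}}
    ]
    return aggregate_importance(iters)


class TestImportanceCorrelation:
    def test_identical_importances_correlate_perfectly(self):
        met = {"a": 1.0, "b": 2.0, "c": 3.0}
        table = _table_from_importances(met, dict(met))
        pearson, spearman, n = importance_correlation(table)
        assert pearson == pytest.approx(1.0)
        assert spearman == pytest.approx(1.0)
        assert n == 3

    def test_constant_side_reports_nan_pearson(self):
        table = _table_from_importances(
            {"a": 1.0, "b": 2.0, "c": 3.0}, {"a": 2.0, "b": 2.0, "c": 2.0}
        )
        pearson, spearman, n = importance_correlation(table)
        assert math.isnan(pearson)

    def test_too_few_pairs_raises(self):
        table = _table_from_importances({"a": 1.0, "b": 2.0}, {"a": 1.0, "c": 2.0})
        with pytest.raises(InsufficientPairsError):
            importance_correlation(table)

    def test_independent_importances_are_weakly_correlated(self):
        """Null simulation: random independent sides rarely exceed |r| = 0.3."""
        rng = np.random.default_rng(0)
        hits = 0
        n_seeds = 40
        for _ in range(n_seeds):
            met = {f"f{j}": float(rng.uniform(0.5, 3)) for j in range(100)}
            path = {f"f{j}": float(rng.uniform(0.5, 3)) for j in range(100)}
            pearson, _, n = importance_correlation(_table_from_importances(met, path))
            assert n == 100
            if abs(pearson) < 0.3:
                hits += 1
        assert hits / n_seeds >= 0.95
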