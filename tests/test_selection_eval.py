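import numpy as np
import pytest

from ctxsel.fs_metrics import ScoredTerm
from ctxsel.selection_eval import (
    DEFAULT_FRACTION_GRID,
    EvalResult,
    NearestCentroidClassifier,
    NotFittedError,
    ReductionScoreInput,
    evaluate,
    overlap_comparison,
    project,
    reduction_score,
    select_top,
    sweep,
    train_and_evaluate,
)
from ctxsel.synthetic_corpus import GeneratorConfig, generate
from conftest import make_corpus


def scores(metric="M", **kv):
    return [ScoredTerm(t, metric, v) for t, v in kv.items()]


class TestSelectTop:
    def test_orders_by_score_descending(self):
        sel = select_top(scores(a=3, b=1, c=2), n=2)
        assert sel.selected == ("a", "c")

    def test_lexicographic_tie_break(self):
        sel = select_top(scores(b=1, a=1), n=1)
        assert sel.selected == ("a",)

    def test_fraction_one_selects_everything(self):
        sel = select_top(scores(a=1, b=2, c=3), fraction=1.0)
        assert sel.selected == ("c", "b", "a")
        assert sel.N == 3

    def test_oversized_n_selects_all_with_warning(self):
        with pytest.warns(UserWarning, match="selecting all"):
            sel = select_top(scores(a=1, b=2), n=5)
        assert sel.N == 2

    def test_stability_under_low_score_additions(self):
        base = select_top(scores(a=5, b=4, c=3), n=2)
        extended = select_top(scores(a=5, b=4, c=3, z=1), n=2)
        assert base.selected == extended.selected

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            select_top(scores(a=1), n=1, fraction=0.5)
        with pytest.raises(ValueError):
            select_top(scores(a=1), fraction=1.5)
        with pytest.raises(ValueError):
            select_top(scores(a=1, b=1) + [ScoredTerm("c", "OTHER", 1)], n=1)


class TestProject:
    corpus = make_corpus([("d1", ["x", "x", "y"], "c1"), ("d2", ["y"], "c2")])

    def test_counts(self):
        X = project(self.corpus, ["x"])
        assert X.tolist() == [[2.0], [0.0]]

    def test_empty_selection(self):
        assert project(self.corpus, []).shape == (2, 0)

    def test_full_vocabulary_is_bow(self):
        X = project(self.corpus, list(self.corpus.vocabulary))
        assert X.tolist() == [[2.0, 1.0], [0.0, 1.0]]

    def test_unknown_term_rejected(self):
        with pytest.raises(ValueError):
            project(self.corpus, ["zz"])


class TestEvaluate:
    def test_hand_confusion(self):
        gold = ["p"] * 3 + ["n"] * 7
        pred = ["p", "p", "n", "p", "n", "n", "n", "n", "n", "n"]
        r = evaluate(pred, gold, "p")
        assert (r.tp, r.fp, r.tn, r.fn) == (2, 1, 6, 1)
        assert r.precision == pytest.approx(2 / 3)
        assert r.recall == pytest.approx(2 / 3)
        assert r.f1 == pytest.approx(2 / 3)

    def test_perfect_predictions(self):
        r = evaluate(["p", "n"], ["p", "n"], "p")
        assert r.precision == r.recall == r.f1 == 1.0

    def test_degenerate_counts_define_zero(self):
        r = evaluate(["n", "n"], ["n", "n"], "p")
        assert r.precision == r.recall == r.f1 == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate(["p"], ["p", "n"], "p")

    @pytest.mark.parametrize("tp,fp,fn,tn", [(5, 2, 3, 10), (1, 0, 4, 5),
                                             (7, 7, 0, 6), (3, 3, 3, 1)])
    def test_f1_between_precision_and_recall(self, tp, fp, fn, tn):
        gold = ["p"] * (tp + fn) + ["n"] * (fp + tn)
        pred = (["p"] * tp + ["n"] * fn) + (["p"] * fp + ["n"] * tn)
        r = evaluate(pred, gold, "p")
        if r.precision > 0 and r.recall > 0:
            assert min(r.precision, r.recall) <= r.f1 <= max(r.precision, r.recall)
        if r.precision == r.recall:
            assert r.f1 == pytest.approx(r.precision)


class TestReductionScore:
    def test_hand_value(self):
        inp = ReductionScoreInput(dims=(100, 300), f1s=(50.0, 60.0), dim_N=300)
        assert reduction_score(inp) == pytest.approx(105.0)

    def test_collapses_to_mean_when_dims_equal_max(self):
        inp = ReductionScoreInput(dims=(500, 500), f1s=(40.0, 80.0), dim_N=500)
        assert reduction_score(inp) == pytest.approx(60.0)

    def test_zero_f1s(self):
        inp = ReductionScoreInput(dims=(10, 20), f1s=(0.0, 0.0), dim_N=20)
        assert reduction_score(inp) == 0.0

    def test_linearity_and_monotonicity(self):
        dims, dim_n = (100, 300, 900), 900
        a = ReductionScoreInput(dims=dims, f1s=(10.0, 20.0, 30.0), dim_N=dim_n)
        b = ReductionScoreInput(dims=dims, f1s=(5.0, 2.0, 1.0), dim_N=dim_n)
        ab = ReductionScoreInput(dims=dims, f1s=(15.0, 22.0, 31.0), dim_N=dim_n)
        assert reduction_score(ab) == pytest.approx(
            reduction_score(a) + reduction_score(b)
        )
        bumped = ReductionScoreInput(dims=dims, f1s=(10.0, 25.0, 30.0), dim_N=dim_n)
        assert reduction_score(bumped) >= reduction_score(a)

    def test_invalid_dims_rejected(self):
        with pytest.raises(ValueError):
            ReductionScoreInput(dims=(0, 10), f1s=(1.0, 2.0), dim_N=10)
        with pytest.raises(ValueError):
            ReductionScoreInput(dims=(5, 20), f1s=(1.0, 2.0), dim_N=10)


class TestNearestCentroid:
    def test_predict_before_fit_raises(self):
        with pytest.raises(NotFittedError):
            NearestCentroidClassifier("p").predict(np.zeros((1, 2)))

    def test_single_class_training_predicts_it_everywhere(self):
        clf = NearestCentroidClassifier("p").fit(np.eye(3), ["n", "n", "n"])
        assert clf.predict(np.random.default_rng(0).normal(size=(4, 3))) == ["n"] * 4

    def test_deterministic_given_same_data(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 6))
        y = ["p" if i % 2 else "n" for i in range(20)]
        T = rng.normal(size=(10, 6))
        p1 = NearestCentroidClassifier("p").fit(X, y).predict(T)
        p2 = NearestCentroidClassifier("p").fit(X, y).predict(T)
        assert p1 == p2

    def test_zero_vector_goes_to_low_signal_class(self):
        # class "p" exhibits the features, "n" does not: absence -> "n"
        X = np.array([[1.0, 1.0], [1.0, 0.0], [0.0, 0.0], [0.0, 0.0]])
        clf = NearestCentroidClassifier("p").fit(X, ["p", "p", "n", "n"])
        assert clf.predict(np.zeros((1, 2))) == ["n"]

    def test_well_separated_synthetic_classes(self):
        corpus, _ = generate(GeneratorConfig(seed=0))
        train, test = corpus.subset("train"), corpus.subset("test")
        res = train_and_evaluate(
            train, test, list(train.vocabulary), "relevant"
        )
        assert res.f1 > 0.9


class TestOverlapComparison:
    corpus, _ = generate(GeneratorConfig(seed=2))
    train, test = corpus.subset("train"), corpus.subset("test")

    def test_identical_rankings_have_zero_increments(self):
        sc = scores(a=3, b=2, c=1)
        sc = [ScoredTerm(t, "M", v) for t, v in
              zip(self.train.vocabulary[:3], (3, 2, 1))]
        res = overlap_comparison(sc, sc, 2, self.train, self.test, "relevant")
        assert len(res["common_terms"]) == 2
        assert res["increment_a"] == res["increment_b"] == 0.0

    def test_disjoint_rankings_have_empty_intersection(self):
        v = list(self.train.vocabulary)
        sa = [ScoredTerm(t, "A", 2) for t in v[:4]]
        sb = [ScoredTerm(t, "B", 2) for t in v[4:8]]
        sa += [ScoredTerm(t, "A", 1) for t in v[4:8]]
        sb += [ScoredTerm(t, "B", 1) for t in v[:4]]
        res = overlap_comparison(sa, sb, 4, self.train, self.test, "relevant")
        assert res["common_terms"] == ()
        assert 0.0 <= res["f1_common"] <= 1.0

    def test_common_never_exceeds_n(self):
        v = list(self.train.vocabulary)
        rng = np.random.default_rng(0)
        sa = [ScoredTerm(t, "A", float(x)) for t, x in zip(v, rng.normal(size=len(v)))]
        sb = [ScoredTerm(t, "B", float(x)) for t, x in zip(v, rng.normal(size=len(v)))]
        res = overlap_comparison(sa, sb, 10, self.train, self.test, "relevant")
        assert len(res["common_terms"]) <= 10


class TestSweep:
    def test_full_vocabulary_row_matches_direct_evaluation(self):
        corpus, _ = generate(GeneratorConfig(seed=4))
        train, test = corpus.subset("train"), corpus.subset("test")
        sc = [ScoredTerm(t, "M", 1.0) for t in train.vocabulary]
        rows = sweep(sc, train, test, "relevant", fractions=[1.0])
        direct = train_and_evaluate(train, test, list(train.vocabulary), "relevant")
        assert len(rows) == 1
        assert rows[0]["f1"] == pytest.approx(direct.f1)
        assert rows[0]["n_features"] == len(train.vocabulary)

    def test_default_grid_has_twenty_sizes(self):
        assert len(DEFAULT_FRACTION_GRID) == 20

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sweep([ScoredTerm("a", "M", 1.0)], None, None, "p", fractions=[])
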