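"""Top-N selection, document projection, evaluation and sweeps.

Selection keeps the N highest-scoring terms (ties broken lexicographically,
so selections are deterministic).  Projected documents are plain
term-count vectors over the selected features (tf-idf weighting optional).
Evaluation reports TP/FP/TN/FN with

    precision = TP/(TP+FP),  recall = TP/(TP+FN),
    F1 = 2 * precision * recall / (precision + recall),

degenerate denominators yielding 0.  The dimension-reduction score of a
sweep rewards accuracy at small feature counts:

    Score = (1/k) * sum_i (dim_N / dim_i) * F1_i,

with F1 on the 0-100 scale.  A small deterministic nearest-centroid
classifier (cosine rule, unresolvable ties -> positive class) serves as the
built-in baseline; heavier models (e.g. a polynomial-kernel SVM) plug in
through the same fit/predict contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from ctxsel.corpus_io import Corpus
from ctxsel.fs_metrics import ScoredTerm


@dataclass(frozen=True)
class SelectionResult:
    """Top-N terms of one metric, ordered by non-increasing score."""

    metric_id: str
    selected: Tuple[str, ...]
    N: int
    fraction: float


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    f1: float


def select_top(
    scores: Sequence[ScoredTerm],
    n: Optional[int] = None,
    fraction: Optional[float] = None,
) -> SelectionResult:
    """Keep the N (or round(fraction * |vocabulary|)) highest-scoring terms.

    Exactly one of ``n``/``fraction`` must be given.  N larger than the
    vocabulary selects everything.  Ordering: score descending, then term
    lexicographic — stable in the sense that adding a term scoring below
    the N-th selected score never changes the selection.
    """
    if (n is None) == (fraction is None):
        raise ValueError("specify exactly one of n or fraction")
    if not scores:
        raise ValueError("empty score list")
    metric_ids = {s.metric_id for s in scores}
    if len(metric_ids) != 1:
        raise ValueError(f"scores mix metrics: {sorted(metric_ids)}")
    vocab_size = len(scores)
    if fraction is not None:
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        n = max(1, round(fraction * vocab_size))
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > vocab_size:
        warnings.warn(
            f"requested N={n} exceeds the vocabulary ({vocab_size}); "
            "selecting all terms",
            stacklevel=2,
        )
        n = vocab_size
    ordered = sorted(scores, key=lambda s: (-s.score, s.term))
    return SelectionResult(
        metric_id=metric_ids.pop(),
        selected=tuple(s.term for s in ordered[:n]),
        N=n,
        fraction=n / vocab_size,
    )


def project(
    corpus: Corpus,
    selected: Sequence[str],
    weighting: str = "count",
) -> np.ndarray:
    """Document-by-feature matrix restricted to the selected terms.

    Raw term counts by default; ``weighting="tfidf"`` multiplies counts by
    ``log(n_docs / doc_freq)`` computed on this corpus.  Rows follow corpus
    document order, columns the order of ``selected``.
    """
    if weighting not in ("count", "tfidf"):
        raise ValueError(f"unknown weighting: {weighting!r}")
    unknown = set(selected) - set(corpus.vocabulary)
    if unknown:
        raise ValueError(f"selected terms outside vocabulary: {sorted(unknown)[:5]}")
    col = {t: j for j, t in enumerate(selected)}
    X = np.zeros((len(corpus.documents), len(selected)))
    for i, doc in enumerate(corpus.documents):
        for tok in doc.tokens:
            j = col.get(tok)
            if j is not None:
                X[i, j] += 1.0
    if weighting == "tfidf" and len(selected):
        df = (X > 0).sum(axis=0)
        idf = np.log(len(corpus.documents) / np.maximum(df, 1))
        X = X * idf
    return X


def evaluate(
    predicted: Sequence[str],
    gold: Sequence[str],
    positive_category: str,
) -> EvalResult:
    """Confusion counts and precision/recall/F1 for one positive category."""
    if len(predicted) != len(gold):
        raise ValueError(
            f"label sequences differ in length: {len(predicted)} vs {len(gold)}"
        )
    tp = fp = tn = fn = 0
    for p, g in zip(predicted, gold):
        if g == positive_category:
            if p == positive_category:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_category:
                fp += 1
            else:
                tn += 1
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return EvalResult(tp, fp, tn, fn, precision, recall, f1)


@dataclass(frozen=True)
class ReductionScoreInput:
    dims: Tuple[int, ...]
    f1s: Tuple[float, ...]  # 0-100 scale
    dim_N: int

    def __post_init__(self):
        if len(self.dims) != len(self.f1s):
            raise ValueError("dims and f1s must have equal length")
        if any(d <= 0 for d in self.dims):
            raise ValueError("all dims must be > 0")
        if any(d > self.dim_N for d in self.dims):
            raise ValueError("dims must not exceed dim_N")


def reduction_score(inp: ReductionScoreInput) -> float:
    """Dimension-reduction rate score of a feature-size sweep.

    ``(1/k) * sum_i (dim_N / dim_i) * F1_i`` — each trial's F1 (0-100
    scale) weighted by how aggressively it reduced the feature space.
    """
    k = len(inp.dims)
    if k == 0:
        raise ValueError("empty sweep")
    return sum(
        (inp.dim_N / d) * f1 for d, f1 in zip(inp.dims, inp.f1s)
    ) / k


class NotFittedError(RuntimeError):
    pass


class NearestCentroidClassifier:
    """Deterministic nearest-centroid baseline over projected vectors.

    Fit stores per-class mean vectors; predict assigns the class whose
    centroid has the highest cosine similarity to the document vector.
    A document showing *none* of the selected features (all-zero vector)
    is assigned to the class whose centroid carries the least mass on
    those features — absence of the selected signal is itself evidence.
    Remaining ties (equal cosine, equal centroid norms, empty feature set)
    resolve to the majority training class and finally to the positive
    class; a zero centroid scores -inf under the cosine rule.  Training on
    a single class predicts that class everywhere; everything is
    deterministic given the inputs.
    """

    def __init__(self, positive_category: str):
        self.positive_category = positive_category
        self._centroids: Optional[Dict[str, np.ndarray]] = None
        self._majority: Optional[str] = None

    def fit(self, X: np.ndarray, labels: Sequence[str]) -> "NearestCentroidClassifier":
        X = np.asarray(X, dtype=float)
        if X.shape[0] != len(labels):
            raise ValueError("X rows and labels must match")
        labels = list(labels)
        self._centroids = {}
        for cat in sorted(set(labels)):
            rows = [i for i, l in enumerate(labels) if l == cat]
            self._centroids[cat] = X[rows].mean(axis=0)
        counts = {c: labels.count(c) for c in self._centroids}
        top = max(counts.values())
        majority = [c for c, k in counts.items() if k == top]
        if len(majority) > 1 and self.positive_category in majority:
            self._majority = self.positive_category
        else:
            self._majority = sorted(majority)[0]
        return self

    def _break_tie(self, winners: List[str]) -> str:
        if self._majority in winners:
            return self._majority
        if self.positive_category in winners:
            return self.positive_category
        return winners[0]

    def predict(self, X: np.ndarray) -> List[str]:
        if self._centroids is None:
            raise NotFittedError("predict called before fit")
        X = np.asarray(X, dtype=float)
        cats = sorted(self._centroids)
        if len(cats) == 1:
            return [cats[0]] * X.shape[0]
        C = np.stack([self._centroids[c] for c in cats])
        c_norm = np.linalg.norm(C, axis=1)
        out = []
        for x in X:
            x_norm = np.linalg.norm(x)
            if x_norm == 0.0:
                least = np.min(c_norm)
                winners = [c for c, nrm in zip(cats, c_norm) if nrm == least]
                out.append(self._break_tie(winners))
                continue
            with np.errstate(invalid="ignore", divide="ignore"):
                sims = np.where(
                    c_norm > 0, (C @ x) / (c_norm * x_norm), -np.inf
                )
            best = np.max(sims)
            winners = [c for c, s in zip(cats, sims) if s == best]
            out.append(winners[0] if len(winners) == 1 else self._break_tie(winners))
        return out


def train_and_evaluate(
    train: Corpus,
    test: Corpus,
    selected: Sequence[str],
    positive_category: str,
    classifier=None,
    weighting: str = "count",
) -> EvalResult:
    """Project both splits onto ``selected``, fit, predict, evaluate.

    An empty feature set degenerates to all-zero vectors; the baseline then
    predicts its tie-break class everywhere.
    """
    if classifier is None:
        classifier = NearestCentroidClassifier(positive_category)
    X_train = project(train, selected, weighting)
    X_test = project(test, selected, weighting)
    classifier.fit(X_train, [d.label for d in train.documents])
    predicted = classifier.predict(X_test)
    return evaluate(
        predicted, [d.label for d in test.documents], positive_category
    )


def overlap_comparison(
    scores_a: Sequence[ScoredTerm],
    scores_b: Sequence[ScoredTerm],
    n: int,
    train: Corpus,
    test: Corpus,
    positive_category: str,
    classifier_factory=None,
    weighting: str = "count",
) -> Dict[str, object]:
    """Common-vs-special feature comparison of two metrics' top-N lists.

    Trains/evaluates three times — on the intersection of the two top-N
    selections, on A's top-N and on B's top-N — and reports the F1
    increments of the full selections over the common core.  An empty
    intersection is legal: the classifier sees all-zero vectors and falls
    back to its tie-break class.
    """
    if classifier_factory is None:
        classifier_factory = lambda: NearestCentroidClassifier(positive_category)
    sel_a = select_top(scores_a, n=n)
    sel_b = select_top(scores_b, n=n)
    common = tuple(sorted(set(sel_a.selected) & set(sel_b.selected)))
    results = {}
    for key, feats in (
        ("common", common),
        ("a", sel_a.selected),
        ("b", sel_b.selected),
    ):
        results[key] = train_and_evaluate(
            train, test, feats, positive_category, classifier_factory(), weighting
        )
    return {
        "common_terms": common,
        "f1_common": results["common"].f1,
        "f1_a": results["a"].f1,
        "f1_b": results["b"].f1,
        "increment_a": results["a"].f1 - results["common"].f1,
        "increment_b": results["b"].f1 - results["common"].f1,
    }


DEFAULT_FRACTION_GRID = (
    0.005, 0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08, 0.09,
    0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90, 1.00,
)


def sweep(
    scores: Sequence[ScoredTerm],
    train: Corpus,
    test: Corpus,
    positive_category: str,
    fractions: Sequence[float] = DEFAULT_FRACTION_GRID,
    classifier_factory=None,
    weighting: str = "count",
) -> List[Dict[str, float]]:
    """Per-feature-size F1 rows for one metric's ranking.

    Each row carries metric_id, n_features, fraction, precision, recall and
    f1; feed the rows' (n_features, f1) pairs to :func:`reduction_score`.
    """
    if not fractions:
        raise ValueError("empty sweep grid")
    if classifier_factory is None:
        classifier_factory = lambda: NearestCentroidClassifier(positive_category)
    rows = []
    for frac in fractions:
        sel = select_top(scores, fraction=frac)
        res = train_and_evaluate(
            train,
            test,
            sel.selected,
            positive_category,
            classifier_factory(),
            weighting,
        )
        rows.append(
            {
                "metric_id": sel.metric_id,
                "n_features": sel.N,
                "fraction": frac,
                "precision": res.precision,
                "recall": res.recall,
                "f1": res.f1,
            }
        )
    return rows
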