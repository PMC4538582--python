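"""Univariate filter feature-selection metrics.

Six frequency-based scores and their four context-similarity counterparts.
With P(t|c) = doc(t,c)/doc(c), P(t|c-bar) = doc(t,c-bar)/doc(c-bar) and
P(c|t) = doc(t,c)/doc(t), summing over categories c_i:

* ``DF``       = sum P(t|c_i)
* ``GI``       = sum P(t|c_i)^2 * P(c_i|t)^2
* ``CDM``      = sum |log((P(t|c_i)+eps) / (P(t|c-bar_i)+eps))|
* ``Acc2``     = sum |P(t|c_i) - P(t|c-bar_i)|
* ``TFIDF``    = sum tf(t,c_i) * log(1 / P(t|c_i))   (0 * log(inf) := 0)
* ``GINI_NTF`` = sum (tf_norm(t,c_i)/doc(c_i))^2
  * (tf_norm(t,c_i) / (tf_norm(t,c_i)+tf_norm(t,c-bar_i)))^2

The ``_cs`` variants substitute the context similarity sim_context(t, c)
(see :mod:`ctxsel.context_similarity`) for the document frequency doc(t, c):

* ``DF_cs``   = sum sim(t,c_i)/doc(c_i)
* ``GI_cs``   = sum (sim(t,c_i)/doc(c_i))^2 * (sim(t,c_i)/doc(t))^2
* ``CDM_cs``  = sum |log( ((sim(t,c_i)+eps)/doc(c_i))
  * (doc(c-bar_i)/(sim(t,c-bar_i)+eps)) )|
* ``Acc2_cs`` = sum |sim(t,c_i)/doc(c_i) - sim(t,c-bar_i)/doc(c-bar_i)|

Logs are natural; the base only rescales CDM/TFIDF and leaves rankings
untouched.  An additive epsilon keeps log ratios finite at zero counts, and
CDM/Acc2 summands are taken in absolute value (the signed two-category sum
would be identically zero for Acc2 and sign-ambiguous for CDM); signed CDM
is available via ``cdm_signed=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from ctxsel.context_similarity import ContextConfig, context_similarity_table
from ctxsel.corpus_io import Corpus, CountTable, build_counts

FREQUENCY_METRICS = ("DF", "GI", "CDM", "Acc2", "TFIDF", "GINI_NTF")
CONTEXT_METRICS = ("DF_cs", "GI_cs", "CDM_cs", "Acc2_cs")
ALL_METRICS = FREQUENCY_METRICS + CONTEXT_METRICS


@dataclass(frozen=True)
class ScoredTerm:
    term: str
    metric_id: str
    score: float


@dataclass(frozen=True)
class SmoothingPolicy:
    """Additive smoothing for the log-ratio metrics.

    ``epsilon`` is added to both numerator and denominator of every ratio
    that can reach 0, preserving the ordering of nonzero ratios while
    keeping all scores finite.
    """

    epsilon: float = 1e-6

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


class UnknownMetricError(ValueError):
    pass


def _check_metric(metric_id: str, allowed: Sequence[str]) -> None:
    if metric_id not in allowed:
        raise UnknownMetricError(
            f"unknown metric {metric_id!r}; expected one of {list(allowed)}"
        )


def frequency_metric(
    counts: CountTable,
    metric_id: str,
    smoothing: SmoothingPolicy = SmoothingPolicy(),
    cdm_signed: bool = False,
) -> List[ScoredTerm]:
    """Score every vocabulary term with one frequency-based metric."""
    _check_metric(metric_id, FREQUENCY_METRICS)
    if len(counts.categories) < 2:
        raise ValueError("counts must cover at least 2 categories")
    eps = smoothing.epsilon
    out = []
    for term in counts.vocabulary:
        score = 0.0
        for cat in counts.categories:
            p = counts.p_t_given_c(term, cat)
            p_not = counts.p_t_given_not_c(term, cat)
            if metric_id == "DF":
                score += p
            elif metric_id == "GI":
                score += p * p * counts.p_c_given_t(term, cat) ** 2
            elif metric_id == "CDM":
                ratio = math.log((p + eps) / (p_not + eps))
                score += ratio if cdm_signed else abs(ratio)
            elif metric_id == "Acc2":
                score += abs(p - p_not)
            elif metric_id == "TFIDF":
                tf = counts.tf(term, cat)
                if tf > 0 and p > 0:
                    score += tf * -math.log(p)
            elif metric_id == "GINI_NTF":
                tfn = counts.tf_norm(term, cat)
                tfn_not = counts.tf_norm_not(term, cat)
                if tfn > 0:
                    share = tfn / (tfn + tfn_not)
                    score += (tfn / counts.doc_total_cat(cat)) ** 2 * share**2
        out.append(ScoredTerm(term=term, metric_id=metric_id, score=score))
    return out


def context_metric(
    corpus: Corpus,
    counts: CountTable,
    metric_id: str,
    ctx_config: ContextConfig = ContextConfig(),
    smoothing: SmoothingPolicy = SmoothingPolicy(),
    cdm_signed: bool = False,
    sim_tables: Optional[
        Tuple[Dict[Tuple[str, str], float], Dict[Tuple[str, str], float]]
    ] = None,
) -> List[ScoredTerm]:
    """Score every vocabulary term with one context-similarity metric.

    ``sim_tables`` (as returned by
    :func:`ctxsel.context_similarity.context_similarity_table`) lets callers
    compute the quadratic window-pair sums once and share them across the
    four ``_cs`` metrics; when omitted it is computed here.
    """
    _check_metric(metric_id, CONTEXT_METRICS)
    if sim_tables is None:
        sim_tables = context_similarity_table(corpus, ctx_config)
    sims, sims_not = sim_tables
    eps = smoothing.epsilon
    out = []
    for term in counts.vocabulary:
        score = 0.0
        for cat in counts.categories:
            s = sims[(term, cat)]
            s_not = sims_not[(term, cat)]
            doc_c = counts.doc_total_cat(cat)
            doc_not_c = counts.doc_total_not(cat)
            if metric_id == "DF_cs":
                score += s / doc_c
            elif metric_id == "GI_cs":
                doc_t = counts.doc_total(term)
                if doc_t > 0:
                    score += (s / doc_c) ** 2 * (s / doc_t) ** 2
            elif metric_id == "CDM_cs":
                ratio = math.log(
                    ((s + eps) / doc_c) * (doc_not_c / (s_not + eps))
                )
                score += ratio if cdm_signed else abs(ratio)
            elif metric_id == "Acc2_cs":
                score += abs(s / doc_c - s_not / doc_not_c)
        out.append(ScoredTerm(term=term, metric_id=metric_id, score=score))
    return out


def scores_to_frame(scores: Iterable[ScoredTerm]) -> pd.DataFrame:
    """ScoredTerm rows -> DataFrame with a deterministic dense rank.

    Rank is 1-based, descending by score with lexicographic term
    tie-breaking — the same order used by top-N selection.
    """
    df = pd.DataFrame(
        [(s.term, s.metric_id, s.score) for s in scores],
        columns=["term", "metric_id", "score"],
    )
    frames = []
    for _, group in df.groupby("metric_id", sort=True):
        group = group.sort_values(
            ["score", "term"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        group["rank"] = group.index + 1
        frames.append(group)
    return pd.concat(frames, ignore_index=True)


def score_all(
    corpus: Corpus,
    metric_ids: Sequence[str] = ALL_METRICS,
    ctx_config: ContextConfig = ContextConfig(),
    smoothing: SmoothingPolicy = SmoothingPolicy(),
    counts: Optional[CountTable] = None,
    cdm_signed: bool = False,
) -> pd.DataFrame:
    """Score the corpus with several metrics; context windows computed once.

    Returns a tidy frame (term, metric_id, score, rank); identical inputs
    and configs give identical tables.
    """
    for m in metric_ids:
        _check_metric(m, ALL_METRICS)
    if not metric_ids:
        return pd.DataFrame(columns=["term", "metric_id", "score", "rank"])
    if counts is None:
        counts = build_counts(corpus)
    sim_tables = None
    if any(m in CONTEXT_METRICS for m in metric_ids):
        sim_tables = context_similarity_table(corpus, ctx_config)
    rows: List[ScoredTerm] = []
    for m in metric_ids:
        if m in FREQUENCY_METRICS:
            rows.extend(frequency_metric(counts, m, smoothing, cdm_signed))
        else:
            rows.extend(
                context_metric(
                    corpus,
                    counts,
                    m,
                    ctx_config,
                    smoothing,
                    cdm_signed,
                    sim_tables,
                )
            )
    return scores_to_frame(rows)


def write_scores(df: pd.DataFrame, path: str) -> None:
    """Write a score table as TSV with full float precision."""
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_scores(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
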