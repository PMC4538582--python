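"""Context windows and windowed Jaro-Winkler context similarity.

The central quantity is ``sim_context(t, c)``: for every pair of context
windows of a term *t* inside category *c*, compare the two windows' context
strings at every width v = 0..W with Jaro-Winkler similarity, weight width v
by 1/(v+1), and sum over all unordered pairs.  Width 0 compares the bare
term with itself and therefore contributes exactly 1 per pair; it is
included by default because that is how the summation is defined, and can
be switched off (``include_v0=False``).

A term whose occurrences sit in recurring phrase templates within a category
accumulates near-maximal pair similarities (Σ 1/(v+1) = 25/12 at W = 3),
whereas a ubiquitous term in random contexts stays near the v=0 floor — this
contrast is what the ``_cs`` feature-selection metrics exploit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ctxsel._jaro import (
    _pairwise_context_sum,
    encode_chars,
    jaro_arrays,
    jaro_winkler_arrays,
)
from ctxsel.corpus_io import Corpus, TokenizedDocument


@dataclass(frozen=True)
class ContextWindow:
    """One occurrence of a term with up to W tokens of context on each side.

    ``left`` and ``right`` are verbatim slices of the source document around
    ``position`` (nearest token last in ``left``), truncated — never padded —
    at document boundaries.
    """

    term: str
    doc_id: str
    position: int
    left: Tuple[str, ...]
    right: Tuple[str, ...]
    W: int

    def __post_init__(self):
        if len(self.left) > self.W or len(self.right) > self.W:
            raise ValueError("context longer than the declared window bound")


@dataclass(frozen=True)
class ContextConfig:
    """Parameters of the context-similarity measure.

    ``window_size`` (W) is the maximum number of tokens taken on each side
    of an occurrence; 3 is the default working value.  The Jaro-Winkler
    prefix parameters are Winkler's standard ones.  ``occurrence_mode``
    selects one window per document ("first") or one per occurrence ("all").
    ``string_mode`` compares context strings character-wise ("char", the
    default) or as token-symbol sequences ("token").
    ``max_windows_per_term`` optionally caps the number of windows entering
    the quadratic pair sum via deterministic seeded subsampling (off by
    default).
    """

    window_size: int = 3
    jw_prefix_scale: float = 0.1
    jw_max_prefix: int = 4
    jw_boost_threshold: float = 0.7
    occurrence_mode: str = "first"
    include_v0: bool = True
    string_mode: str = "char"
    max_windows_per_term: Optional[int] = None
    seed: int = 0

    def __post_init__(self):
        if self.window_size < 0:
            raise ValueError("window_size must be >= 0")
        if not 0.0 <= self.jw_prefix_scale:
            raise ValueError("jw_prefix_scale must be >= 0")
        if self.jw_prefix_scale * self.jw_max_prefix > 1.0:
            raise ValueError(
                "jw_prefix_scale * jw_max_prefix must be <= 1 "
                "(similarity could exceed 1)"
            )
        if self.occurrence_mode not in ("first", "all"):
            raise ValueError("occurrence_mode must be 'first' or 'all'")
        if self.string_mode not in ("char", "token"):
            raise ValueError("string_mode must be 'char' or 'token'")


def extract_contexts(
    doc: TokenizedDocument,
    term: str,
    W: int,
    occurrence_mode: str = "first",
) -> List[ContextWindow]:
    """Context windows of ``term`` in one document.

    Returns one window per selected occurrence (all of them, or only the
    first), an empty list if the term is absent.
    """
    if W < 0:
        raise ValueError("W must be >= 0")
    windows = []
    for pos, tok in enumerate(doc.tokens):
        if tok != term:
            continue
        windows.append(
            ContextWindow(
                term=term,
                doc_id=doc.doc_id,
                position=pos,
                left=tuple(doc.tokens[max(0, pos - W) : pos]),
                right=tuple(doc.tokens[pos + 1 : pos + 1 + W]),
                W=W,
            )
        )
        if occurrence_mode == "first":
            break
    return windows


def context_string(window: ContextWindow, v: int) -> str:
    """The width-``v`` context string: up to v left tokens, the term, up to
    v right tokens, joined by single spaces.  ``v = 0`` is the bare term."""
    if not 0 <= v <= window.W:
        raise ValueError(f"width v={v} outside [0, W={window.W}]")
    if v == 0:
        return window.term
    parts = list(window.left[len(window.left) - min(v, len(window.left)) :])
    parts.append(window.term)
    parts.extend(window.right[:v])
    return " ".join(parts)


def _context_tokens(window: ContextWindow, v: int) -> Tuple[str, ...]:
    if v == 0:
        return (window.term,)
    left = window.left[len(window.left) - min(v, len(window.left)) :]
    return left + (window.term,) + tuple(window.right[:v])


def jaro(s1: str, s2: str) -> float:
    """Jaro similarity of two strings, in [0, 1]."""
    return jaro_arrays(encode_chars(s1), encode_chars(s2))


def jaro_winkler(
    s1: str,
    s2: str,
    p: float = 0.1,
    lmax: int = 4,
    bt: float = 0.7,
) -> float:
    """Jaro-Winkler similarity: Jaro plus a common-prefix bonus.

    ``jaro + l * p * (1 - jaro)`` with ``l`` the length of the common prefix
    capped at ``lmax``, applied only when the Jaro score reaches the boost
    threshold ``bt``.  0 means no similarity, 1 an exact match.
    """
    if p * lmax > 1.0:
        raise ValueError("p * lmax must be <= 1")
    if p < 0.0:
        raise ValueError("p must be >= 0")
    return jaro_winkler_arrays(encode_chars(s1), encode_chars(s2), p, lmax, bt)


def _token_ids(
    windows: Sequence[ContextWindow], W: int
) -> Dict[str, int]:
    vocab = set()
    for w in windows:
        vocab.add(w.term)
        vocab.update(w.left)
        vocab.update(w.right)
    return {tok: i for i, tok in enumerate(sorted(vocab))}


def _encode_window(
    window: ContextWindow,
    W: int,
    string_mode: str,
    token_ids: Optional[Dict[str, int]],
) -> List[np.ndarray]:
    """Symbol arrays for widths v = 1..W."""
    rows = []
    for v in range(1, W + 1):
        if string_mode == "char":
            rows.append(encode_chars(context_string(window, v)))
        else:
            toks = _context_tokens(window, v)
            rows.append(
                np.array([token_ids[t] for t in toks], dtype=np.int32)
            )
    return rows


def pair_similarity(
    win_a: ContextWindow,
    win_b: ContextWindow,
    config: ContextConfig = ContextConfig(),
) -> float:
    """Similarity of one pair of context windows of the same term.

    ``sum over v = 0..W of dis(context_string(a, v), context_string(b, v))
    / (v + 1)`` with ``dis`` = Jaro-Winkler.  Symmetric in its two windows;
    the value lies in [1, sum over v of 1/(v+1)] when the v=0 term is
    included.
    """
    if win_a.term != win_b.term:
        raise ValueError(
            f"window terms differ: {win_a.term!r} vs {win_b.term!r}"
        )
    W = config.window_size
    if win_a.W < W or win_b.W < W:
        raise ValueError("windows were extracted with a bound smaller than W")
    token_ids = None
    if config.string_mode == "token":
        token_ids = _token_ids([win_a, win_b], W)
    total = 0.0
    start = 0 if config.include_v0 else 1
    for v in range(start, W + 1):
        if config.string_mode == "char":
            a = encode_chars(context_string(win_a, v))
            b = encode_chars(context_string(win_b, v))
        else:
            a = np.array(
                [token_ids[t] for t in _context_tokens(win_a, v)],
                dtype=np.int32,
            )
            b = np.array(
                [token_ids[t] for t in _context_tokens(win_b, v)],
                dtype=np.int32,
            )
        sim = jaro_winkler_arrays(
            a,
            b,
            config.jw_prefix_scale,
            config.jw_max_prefix,
            config.jw_boost_threshold,
        )
        total += sim / (v + 1)
    return total


def _collect_windows(
    corpus: Corpus, config: ContextConfig
) -> Dict[str, Dict[str, List[ContextWindow]]]:
    """All context windows, grouped term -> category -> window list."""
    windows: Dict[str, Dict[str, List[ContextWindow]]] = {}
    W = config.window_size
    for doc in corpus.documents:
        seen_in_doc = set()
        for pos, tok in enumerate(doc.tokens):
            if config.occurrence_mode == "first" and tok in seen_in_doc:
                continue
            seen_in_doc.add(tok)
            win = ContextWindow(
                term=tok,
                doc_id=doc.doc_id,
                position=pos,
                left=tuple(doc.tokens[max(0, pos - W) : pos]),
                right=tuple(doc.tokens[pos + 1 : pos + 1 + W]),
                W=W,
            )
            windows.setdefault(tok, {}).setdefault(doc.label, []).append(win)
    return windows


def _subsample(
    wins: List[ContextWindow], term: str, config: ContextConfig
) -> List[ContextWindow]:
    cap = config.max_windows_per_term
    if cap is None or len(wins) <= cap:
        return wins
    rng = np.random.default_rng([config.seed, zlib.crc32(term.encode())])
    idx = np.sort(rng.choice(len(wins), size=cap, replace=False))
    return [wins[i] for i in idx]


def _sum_pairs_naive(
    wins: Sequence[ContextWindow], config: ContextConfig
) -> float:
    total = 0.0
    for i in range(len(wins)):
        for j in range(i + 1, len(wins)):
            total += pair_similarity(wins[i], wins[j], config)
    return total


def _sum_pairs_fast(
    wins: Sequence[ContextWindow], config: ContextConfig
) -> float:
    n = len(wins)
    if n < 2:
        return 0.0
    W = config.window_size
    token_ids = (
        _token_ids(wins, W) if config.string_mode == "token" else None
    )
    encoded = [
        _encode_window(w, W, config.string_mode, token_ids) for w in wins
    ]
    if W == 0:
        base = 1.0 if config.include_v0 else 0.0
        return base * (n * (n - 1) // 2)
    maxlen = max(1, max(len(row) for rows in encoded for row in rows))
    codes = np.zeros((n, W, maxlen), dtype=np.int32)
    lengths = np.zeros((n, W), dtype=np.int64)
    for i, rows in enumerate(encoded):
        for v, row in enumerate(rows):
            codes[i, v, : len(row)] = row
            lengths[i, v] = len(row)
    weights = np.array([1.0 / (v + 1) for v in range(1, W + 1)])
    base = 1.0 if config.include_v0 else 0.0
    return _pairwise_context_sum(
        codes,
        lengths,
        weights,
        base,
        config.jw_prefix_scale,
        config.jw_max_prefix,
        config.jw_boost_threshold,
    )


def category_context_similarity(
    corpus: Corpus,
    term: str,
    category: str,
    config: ContextConfig = ContextConfig(),
    complement: bool = False,
    method: str = "fast",
) -> float:
    """sim_context(t, c): summed pair similarity of t's windows within c.

    With ``complement=True`` the windows are taken from every document *not*
    in ``category`` (the c-bar similarity of the ``_cs`` metrics).  Fewer
    than two windows — including an absent term — give 0.  ``method`` picks
    the batched numba path ("fast") or the literal double loop ("naive");
    the two agree to floating-point identity and the naive path exists as a
    readable reference and test oracle.
    """
    if category not in corpus.categories:
        raise ValueError(f"unknown category: {category!r}")
    wins: List[ContextWindow] = []
    for doc in corpus.documents:
        in_cat = doc.label == category
        if in_cat == complement:
            continue
        wins.extend(
            extract_contexts(
                doc, term, config.window_size, config.occurrence_mode
            )
        )
    wins = _subsample(wins, term, config)
    if len(wins) < 2:
        return 0.0
    if method == "naive":
        return _sum_pairs_naive(wins, config)
    if method == "fast":
        return _sum_pairs_fast(wins, config)
    raise ValueError(f"unknown method: {method!r}")


def context_similarity_table(
    corpus: Corpus,
    config: ContextConfig = ContextConfig(),
    terms: Optional[Sequence[str]] = None,
) -> Tuple[Dict[Tuple[str, str], float], Dict[Tuple[str, str], float]]:
    """sim_context(t, c) and sim_context(t, c-bar) for many terms at once.

    Windows are collected in a single corpus pass and shared by all four
    ``_cs`` metrics.  Returns two ``(term, category) -> value`` maps: the
    within-category similarity and the complement similarity.  For a
    two-category corpus the complement of one category is exactly the other
    category's window set, so no extra pair sums are needed; with more
    categories the complement pools windows across the remaining categories
    (pairs may then span complement categories).
    """
    wanted = set(corpus.vocabulary if terms is None else terms)
    windows = _collect_windows(corpus, config)
    sims: Dict[Tuple[str, str], float] = {}
    sims_not: Dict[Tuple[str, str], float] = {}
    two_cat = len(corpus.categories) == 2
    for term in sorted(wanted):
        per_cat = windows.get(term, {})
        for cat in corpus.categories:
            wins = _subsample(per_cat.get(cat, []), term, config)
            sims[(term, cat)] = (
                _sum_pairs_fast(wins, config) if len(wins) >= 2 else 0.0
            )
        for cat in corpus.categories:
            if two_cat:
                other = (
                    corpus.categories[1]
                    if cat == corpus.categories[0]
                    else corpus.categories[0]
                )
                sims_not[(term, cat)] = sims[(term, other)]
            else:
                pooled: List[ContextWindow] = []
                for other in corpus.categories:
                    if other != cat:
                        pooled.extend(per_cat.get(other, []))
                pooled = _subsample(pooled, term, config)
                sims_not[(term, cat)] = (
                    _sum_pairs_fast(pooled, config)
                    if len(pooled) >= 2
                    else 0.0
                )
    return sims, sims_not
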