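"""Reading, normalizing and counting labeled document collections.

Documents are plain-text records with a binary (or k-ary) category label,
e.g. abstracts tagged as describing protein-protein interactions or not.
Preprocessing follows the usual bag-of-words recipe for interaction-article
classification: lower-case everything, strip punctuation, drop stop words,
no stemming.  Tokens are maximal runs of ASCII alphanumerics, so gene and
protein symbols like ``b7`` survive intact.

Two on-disk layouts are supported:

* ``delimited`` — UTF-8, tab-separated, one document per line with columns
  ``doc_id``, ``label``, ``text`` and an optional fourth ``split`` column
  (``train``/``test``; defaults to ``train``).
* ``directory`` — ``<root>/<label>/<doc_id>.txt``, read in lexicographic
  file order so re-loading is deterministic.

:func:`build_counts` produces the :class:`CountTable` of per-term,
per-category document frequencies and (length-normalized) term frequencies
that every filter metric consumes.
"""

from __future__ import annotations

import os
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from ctxsel.stopwords import DEFAULT_STOPWORDS

_TOKEN_RE = re.compile(r"[0-9a-z]+")


@dataclass(frozen=True)
class RawDocument:
    """A document as read from disk, before normalization."""

    doc_id: str
    text: str
    label: str
    split: str = "train"


@dataclass(frozen=True)
class TokenizedDocument:
    """A normalized document: ordered lowercase tokens plus its label."""

    doc_id: str
    tokens: Tuple[str, ...]
    label: str
    split: str = "train"


@dataclass(frozen=True)
class Corpus:
    """A tokenized collection with its ordered category and term inventories.

    ``categories`` is the sorted set of labels, ``vocabulary`` the sorted
    union of all document tokens.  Document order is the (deterministic)
    input order.
    """

    documents: Tuple[TokenizedDocument, ...]
    categories: Tuple[str, ...]
    vocabulary: Tuple[str, ...]

    @staticmethod
    def from_documents(documents: Sequence[TokenizedDocument]) -> "Corpus":
        docs = tuple(documents)
        categories = tuple(sorted({d.label for d in docs}))
        vocab = tuple(sorted({t for d in docs for t in d.tokens}))
        return Corpus(documents=docs, categories=categories, vocabulary=vocab)

    def subset(self, split: Optional[str] = None) -> "Corpus":
        """Corpus restricted to one split tag; categories/vocab recomputed."""
        if split is None:
            return self
        return Corpus.from_documents(
            [d for d in self.documents if d.split == split]
        )

    def __len__(self) -> int:
        return len(self.documents)


def tokenize(
    text: str,
    stopwords: Iterable[str] = DEFAULT_STOPWORDS,
    min_token_len: int = 1,
    keep_numeric: bool = True,
) -> List[str]:
    """Normalize raw text to a token sequence.

    Lower-cases, splits on any maximal run of non-alphanumeric characters,
    removes ``stopwords`` (which must be lowercase) and applies no stemming.
    ``min_token_len`` and ``keep_numeric`` control whether single characters
    and purely numeric tokens survive; both are permissive by default.
    """
    stopset = stopwords if isinstance(stopwords, (set, frozenset)) else set(stopwords)
    tokens = []
    for tok in _TOKEN_RE.findall(text.lower()):
        if len(tok) < min_token_len:
            continue
        if not keep_numeric and tok.isdigit():
            continue
        if tok in stopset:
            continue
        tokens.append(tok)
    return tokens


class CorpusFormatError(ValueError):
    """Raised for malformed corpus files (bad labels, duplicate ids, ...)."""


def _read_delimited(path: str) -> List[Tuple[str, str, str, str]]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected doc_id<TAB>label<TAB>text"
                )
            doc_id, label, text = parts[0], parts[1], parts[2]
            split = parts[3] if len(parts) > 3 and parts[3] else "train"
            records.append((doc_id, label, text, split))
    return records


def _read_directory(path: str) -> List[Tuple[str, str, str, str]]:
    records = []
    for label in sorted(os.listdir(path)):
        subdir = os.path.join(path, label)
        if not os.path.isdir(subdir):
            continue
        for fname in sorted(os.listdir(subdir)):
            if not fname.endswith(".txt"):
                continue
            doc_id = fname[: -len(".txt")]
            with open(os.path.join(subdir, fname), encoding="utf-8") as fh:
                text = fh.read()
            records.append((doc_id, label, text, "train"))
    return records


def load_corpus(
    path: str,
    layout: str = "delimited",
    label_map: Optional[Dict[str, str]] = None,
    stopwords: Iterable[str] = DEFAULT_STOPWORDS,
    min_token_len: int = 1,
    keep_numeric: bool = True,
) -> Corpus:
    """Load and normalize a labeled collection from disk.

    ``label_map``, when given, both renames raw labels and restricts the
    admissible label set; a record whose label is missing from the map is an
    error naming the offending ``doc_id``.  Duplicate ids and empty corpora
    are errors too.  Loading the same input twice yields an identical
    :class:`Corpus` (document order, tokens and inventories).
    """
    if layout == "delimited":
        records = _read_delimited(path)
    elif layout == "directory":
        records = _read_directory(path)
    else:
        raise ValueError(f"unknown layout: {layout!r}")

    if not records:
        raise CorpusFormatError(f"empty corpus: {path}")

    seen = set()
    docs = []
    for doc_id, label, text, split in records:
        if doc_id in seen:
            raise CorpusFormatError(f"duplicate doc_id: {doc_id!r}")
        seen.add(doc_id)
        if label_map is not None:
            if label not in label_map:
                raise CorpusFormatError(
                    f"document {doc_id!r} has unknown label {label!r}"
                )
            label = label_map[label]
        docs.append(
            TokenizedDocument(
                doc_id=doc_id,
                tokens=tuple(
                    tokenize(
                        text,
                        stopwords,
                        min_token_len=min_token_len,
                        keep_numeric=keep_numeric,
                    )
                ),
                label=label,
                split=split,
            )
        )
    return Corpus.from_documents(docs)


@dataclass
class CountTable:
    """Per-term document/term-frequency statistics over a corpus.

    Stores doc(t, c), tf(t, c), tf_norm(t, c), doc(c) and doc(t); complements
    (doc(t, c-bar), doc(c-bar)) are derived on demand.  ``tf_norm`` defaults
    to the per-document-length normalization
    ``sum over category-c docs d of tf(t, d) / len(d)``; ``mode="maxtf"``
    divides by the document's maximum term count instead.
    """

    categories: Tuple[str, ...]
    vocabulary: Tuple[str, ...]
    n_documents: int
    doc_totals: Dict[str, int] = field(default_factory=dict)
    _doc: Dict[Tuple[str, str], int] = field(default_factory=dict)
    _tf: Dict[Tuple[str, str], int] = field(default_factory=dict)
    _tf_norm: Dict[Tuple[str, str], float] = field(default_factory=dict)
    _doc_t: Dict[str, int] = field(default_factory=dict)

    def doc_count(self, term: str, category: str) -> int:
        return self._doc.get((term, category), 0)

    def doc_count_not(self, term: str, category: str) -> int:
        return self.doc_total(term) - self.doc_count(term, category)

    def doc_total_cat(self, category: str) -> int:
        return self.doc_totals[category]

    def doc_total_not(self, category: str) -> int:
        return self.n_documents - self.doc_totals[category]

    def doc_total(self, term: str) -> int:
        return self._doc_t.get(term, 0)

    def tf(self, term: str, category: str) -> int:
        return self._tf.get((term, category), 0)

    def tf_norm(self, term: str, category: str) -> float:
        return self._tf_norm.get((term, category), 0.0)

    def tf_norm_not(self, term: str, category: str) -> float:
        return sum(
            self.tf_norm(term, c) for c in self.categories if c != category
        )

    # conditional probabilities used by the frequency metrics
    def p_t_given_c(self, term: str, category: str) -> float:
        return self.doc_count(term, category) / self.doc_total_cat(category)

    def p_t_given_not_c(self, term: str, category: str) -> float:
        n = self.doc_total_not(category)
        return self.doc_count_not(term, category) / n if n else 0.0

    def p_c_given_t(self, term: str, category: str) -> float:
        n = self.doc_total(term)
        return self.doc_count(term, category) / n if n else 0.0


def build_counts(corpus: Corpus, tf_norm_mode: str = "doclen") -> CountTable:
    """Accumulate the :class:`CountTable` for a (nonempty) corpus."""
    if not corpus.documents:
        raise ValueError("cannot build counts for an empty corpus")
    if tf_norm_mode not in ("doclen", "maxtf"):
        raise ValueError(f"unknown tf_norm_mode: {tf_norm_mode!r}")

    table = CountTable(
        categories=corpus.categories,
        vocabulary=corpus.vocabulary,
        n_documents=len(corpus.documents),
        doc_totals={c: 0 for c in corpus.categories},
    )
    for doc in corpus.documents:
        table.doc_totals[doc.label] += 1
        counts = Counter(doc.tokens)
        if not counts:
            continue
        denom = (
            len(doc.tokens) if tf_norm_mode == "doclen" else max(counts.values())
        )
        for term, n in counts.items():
            key = (term, doc.label)
            table._doc[key] = table._doc.get(key, 0) + 1
            table._tf[key] = table._tf.get(key, 0) + n
            table._tf_norm[key] = table._tf_norm.get(key, 0.0) + n / denom
            table._doc_t[term] = table._doc_t.get(term, 0) + 1
    return table
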