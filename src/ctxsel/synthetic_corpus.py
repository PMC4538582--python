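"""Synthetic two-class labeled corpora with planted ground truth.

The generator emulates the statistical structure that separates
context-similarity scoring from frequency scoring in interaction-article
triage:

* **Discriminative terms** occur (almost) only in documents of their own
  class, embedded in a fixed phrase template of W tokens on each side —
  recurring multiword chunks, so their within-class context windows are
  near-identical and sim_context is close to its maximum
  C(n, 2) * sum 1/(v+1).  A small cross-class rate plants stray occurrences
  (with random neighbors) in the other class, mimicking words like
  "activate" that occasionally show up in nonrelevant abstracts.
* **Ubiquitous terms** occur in both classes at a high per-document rate
  but at random positions with random neighbors — the "protein"/"cell"
  phenomenon: excellent document frequency, no recurring context.
* **Noise vocabulary** fills the remaining positions uniformly; the
  template filler tokens come from a dedicated vocabulary disjoint from all
  other roles.

Occurrence rates are realized as exact host counts drawn uniformly without
replacement, stratified by the train/test split (``round(rate * n_split)``
documents within each split), and the verbatim-template fraction is an
exact count over each term's host set — a balanced design that removes
binomial nuisance variance so the planted frequency/context contrasts are
reproducible even at small corpus sizes; which documents host a term, and
the window contexts themselves, remain random.

Every random draw flows from one ``numpy`` Generator seeded by
``config.seed``.  The draw order — vocabulary construction, then host-set
assignment class by class (own-class discriminative terms, cross-class
strays, ubiquitous terms), then documents in order with a fixed
per-document item order — is part of the reproducibility contract, so
equal configs give token-identical corpora.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from ctxsel.corpus_io import Corpus, TokenizedDocument
from ctxsel.context_similarity import ContextConfig
from ctxsel.fs_metrics import (
    CONTEXT_METRICS,
    SmoothingPolicy,
    context_metric,
    frequency_metric,
)
from ctxsel import corpus_io

ROLE_DISCRIMINATIVE = "discriminative"  # prefix; full role carries the label
ROLE_UBIQUITOUS = "ubiquitous"
ROLE_TEMPLATE = "template"
ROLE_NOISE = "noise"

LABELS = ("irrelevant", "relevant")
POSITIVE = "relevant"


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic two-class corpus.

    Defaults are a desk-scale analogue of a triage collection: 60 abstracts
    per class of 48 content tokens each (after stop-word removal), four
    discriminative terms per class sitting in width-3 phrase templates in
    90% of their class's documents (95% of occurrences verbatim, the rest
    with shuffled neighbors, and strays in 15% of other-class documents),
    six ubiquitous both-class terms hosted by 60% of all documents, and a
    40-term noise vocabulary.  The rate asymmetry is deliberate: ubiquitous
    terms must beat everything on document frequency while discriminative
    terms must beat them on within-class context similarity (see the
    methods note for the margin analysis behind these numbers).
    """

    n_docs_per_class: int = 60
    doc_length: int = 48
    n_discriminative: int = 8  # total, split evenly between the classes
    n_ubiquitous: int = 6
    n_noise_vocab: int = 40
    window_size: int = 3
    template_fidelity: float = 0.95  # P(occurrence uses its template verbatim)
    disc_doc_rate: float = 0.9  # fraction of class docs hosting a class term
    cross_class_rate: float = 0.15  # fraction of other-class docs with a stray
    ubiquitous_rate: float = 0.6  # fraction of docs hosting a ubiquitous term
    test_fraction: float = 0.25
    phrase_templates: Optional[Dict[str, Tuple[str, ...]]] = None
    seed: int = 0

    def __post_init__(self):
        for name in (
            "n_docs_per_class",
            "doc_length",
            "n_discriminative",
            "n_ubiquitous",
            "n_noise_vocab",
            "window_size",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "template_fidelity",
            "disc_doc_rate",
            "cross_class_rate",
            "ubiquitous_rate",
            "test_fraction",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_discriminative % len(LABELS):
            raise ValueError(
                "n_discriminative must split evenly between the classes"
            )
        # worst case: every segment, stray and ubiquitous term present
        segment = 2 * self.window_size + 1
        per_class = self.n_discriminative // len(LABELS)
        needed = (
            per_class * segment
            + (self.n_discriminative - per_class)
            + self.n_ubiquitous
        )
        if self.n_docs_per_class > 0 and self.doc_length < needed:
            raise ValueError(
                f"doc_length={self.doc_length} too small to host "
                f"{per_class} templates of width {self.window_size} plus "
                f"planted terms (needs >= {needed})"
            )


GroundTruth = Dict[str, str]


def benchmark_config(seed: int = 0) -> GeneratorConfig:
    """Study conditions for end-to-end classification benchmarks.

    The default :class:`GeneratorConfig` is built for metric-ranking
    contrasts and keeps the informative (discriminative + template)
    vocabulary dense, which makes *any* feature subset classify well.  For
    experiments that compare classifier F1 across feature-selection
    strategies, feature selection only has room to matter when informative
    terms are sparse in the vocabulary and no single term covers its class:
    400 documents (200 per class), six discriminative terms per class
    hosted by only 60% of their class's documents, 24 ubiquitous terms and
    a 300-term noise vocabulary, so informative terms are ~20% of the
    ~400-term vocabulary and a top-5% selection holds about 20 features.
    """
    return GeneratorConfig(
        n_docs_per_class=200,
        doc_length=80,
        n_discriminative=12,
        n_ubiquitous=24,
        n_noise_vocab=300,
        disc_doc_rate=0.6,
        seed=seed,
    )


def _noise_vocabulary(rng: np.random.Generator, size: int) -> List[str]:
    """Unique random lowercase words, 4-8 letters, no digits (planted
    vocabulary always carries digits, so the roles cannot collide)."""
    letters = np.array(list(string.ascii_lowercase))
    words: List[str] = []
    seen = set()
    while len(words) < size:
        length = int(rng.integers(4, 9))
        word = "".join(rng.choice(letters, size=length))
        if word not in seen:
            seen.add(word)
            words.append(word)
    return words


def _build_vocab(config: GeneratorConfig, rng: np.random.Generator):
    per_class = config.n_discriminative // len(LABELS)
    disc: Dict[str, List[str]] = {}
    templates: Dict[str, Tuple[str, ...]] = {}
    for label in LABELS:
        short = label[:3]
        disc[label] = [f"sig{short}{i}" for i in range(per_class)]
    w = config.window_size
    for label in LABELS:
        for i, term in enumerate(disc[label]):
            if config.phrase_templates and term in config.phrase_templates:
                tpl = tuple(config.phrase_templates[term])
                if len(tpl) != 2 * w:
                    raise ValueError(
                        f"template for {term!r} must have {2 * w} tokens"
                    )
            else:
                tpl = tuple(
                    f"tpl{label[:3]}{i}x{j}" for j in range(2 * w)
                )
            templates[term] = tpl
    ubiq = [f"ubi{i}" for i in range(config.n_ubiquitous)]
    noise = _noise_vocabulary(rng, config.n_noise_vocab)
    return disc, templates, ubiq, noise


def generate(config: GeneratorConfig = GeneratorConfig()) -> Tuple[Corpus, GroundTruth]:
    """Generate a labeled corpus and its term-role ground truth.

    Each class-``c`` discriminative term is embedded inside its 2W-token
    phrase template in a ``disc_doc_rate`` fraction of class-c documents
    (an exact count within each split, uniformly chosen); a
    ``template_fidelity`` fraction of those embeddings (again an exact
    count) is verbatim and the rest get their template tokens shuffled.
    The term also appears bare (random neighbors) in a ``cross_class_rate``
    fraction of other-class documents, and each ubiquitous term appears
    bare in a ``ubiquitous_rate`` fraction of the documents of every class.
    Remaining positions are filled uniformly from the noise vocabulary and
    the per-document items (template segments are atomic) are shuffled, so
    every document has exactly ``doc_length`` tokens.  The first
    ``1 - test_fraction`` of each class's documents are tagged ``train``,
    the rest ``test``.
    """
    rng = np.random.default_rng(config.seed)
    disc, templates, ubiq, noise = _build_vocab(config, rng)
    w = config.window_size
    n_c = config.n_docs_per_class

    truth: GroundTruth = {}
    for label in LABELS:
        for term in disc[label]:
            truth[term] = f"{ROLE_DISCRIMINATIVE}_{label}"
        for term in disc[label]:
            for tok in templates[term]:
                truth[tok] = ROLE_TEMPLATE
    for term in ubiq:
        truth[term] = ROLE_UBIQUITOUS
    for term in noise:
        truth[term] = ROLE_NOISE

    n_train = int(np.ceil((1.0 - config.test_fraction) * n_c))

    def _hosts(rate: float) -> set:
        chosen: set = set()
        for lo, hi in ((0, n_train), (n_train, n_c)):
            k = int(round(rate * (hi - lo)))
            if k:
                chosen.update(
                    int(i) for i in rng.choice(hi - lo, size=k, replace=False) + lo
                )
        return chosen

    # host-set and verbatim-set assignment, class by class, in fixed order
    hosts: Dict[Tuple[str, str], set] = {}
    verbatim: Dict[str, set] = {}
    for label in LABELS:
        others = [t for lab in LABELS if lab != label for t in disc[lab]]
        for term in disc[label]:
            hosts[(term, label)] = _hosts(config.disc_doc_rate)
            host_list = sorted(hosts[(term, label)])
            k = int(round(config.template_fidelity * len(host_list)))
            verbatim[term] = (
                {host_list[int(i)] for i in rng.choice(len(host_list), size=k, replace=False)}
                if host_list
                else set()
            )
        for term in others:
            hosts[(term, label)] = _hosts(config.cross_class_rate)
        for term in ubiq:
            hosts[(term, label)] = _hosts(config.ubiquitous_rate)

    noise_arr = np.array(noise) if noise else np.array(["filler"])
    docs: List[TokenizedDocument] = []
    for label in LABELS:
        others = [t for lab in LABELS if lab != label for t in disc[lab]]
        for i in range(n_c):
            items: List[Tuple[str, ...]] = []
            for term in disc[label]:
                if i in hosts[(term, label)]:
                    tpl = list(templates[term])
                    if i not in verbatim[term]:
                        tpl = list(rng.permutation(tpl))
                    items.append(tuple(tpl[:w]) + (term,) + tuple(tpl[w:]))
            for term in others:
                if i in hosts[(term, label)]:
                    items.append((term,))
            for term in ubiq:
                if i in hosts[(term, label)]:
                    items.append((term,))
            filler = config.doc_length - sum(len(seg) for seg in items)
            if filler < 0:  # pragma: no cover - excluded by config validation
                raise ValueError("doc_length too small to host a template")
            for tok in rng.choice(noise_arr, size=filler):
                items.append((str(tok),))
            order = rng.permutation(len(items))
            tokens = tuple(tok for k in order for tok in items[k])
            docs.append(
                TokenizedDocument(
                    doc_id=f"{label}_{i:04d}",
                    tokens=tokens,
                    label=label,
                    split="train" if i < n_train else "test",
                )
            )
    return Corpus.from_documents(docs), truth


@dataclass(frozen=True)
class SeparationReport:
    """Outcome of the discriminative-vs-ubiquitous separation predicate."""

    passed: bool
    cs_separated: Dict[str, bool]
    df_ubiquitous_top_decile: bool
    vacuous: bool = False


def expected_separation(
    corpus: Corpus,
    truth: GroundTruth,
    ctx_config: Optional[ContextConfig] = None,
    smoothing: SmoothingPolicy = SmoothingPolicy(),
) -> SeparationReport:
    """Check the contrast the generator is supposed to plant.

    Passes when (a) under every ``_cs`` metric the lowest-scoring planted
    discriminative term still outranks the highest-scoring ubiquitous term,
    and (b) plain DF puts at least one ubiquitous term in its top decile.
    A corpus with no discriminative or no ubiquitous terms passes vacuously.
    """
    disc_terms = [
        t
        for t, role in truth.items()
        if role.startswith(ROLE_DISCRIMINATIVE) and t in corpus.vocabulary
    ]
    ubiq_terms = [
        t
        for t, role in truth.items()
        if role == ROLE_UBIQUITOUS and t in corpus.vocabulary
    ]
    if not disc_terms or not ubiq_terms or not corpus.documents:
        return SeparationReport(
            passed=True, cs_separated={}, df_ubiquitous_top_decile=True,
            vacuous=True,
        )
    if ctx_config is None:
        ctx_config = ContextConfig()
    counts = corpus_io.build_counts(corpus)
    from ctxsel.context_similarity import context_similarity_table

    sim_tables = context_similarity_table(corpus, ctx_config)
    cs_ok: Dict[str, bool] = {}
    for metric in CONTEXT_METRICS:
        scored = {
            s.term: s.score
            for s in context_metric(
                corpus, counts, metric, ctx_config, smoothing,
                sim_tables=sim_tables,
            )
        }
        cs_ok[metric] = min(scored[t] for t in disc_terms) > max(
            scored[t] for t in ubiq_terms
        )
    df_scores = frequency_metric(counts, "DF", smoothing)
    ordered = sorted(df_scores, key=lambda s: (-s.score, s.term))
    decile = max(1, int(np.ceil(len(ordered) / 10)))
    top = {s.term for s in ordered[:decile]}
    df_ok = any(t in top for t in ubiq_terms)
    return SeparationReport(
        passed=all(cs_ok.values()) and df_ok,
        cs_separated=cs_ok,
        df_ubiquitous_top_decile=df_ok,
    )


def write_corpus(corpus: Corpus, path: str) -> None:
    """Write the delimited corpus format (doc_id, label, text, split)."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in corpus.documents:
            fh.write(
                f"{doc.doc_id}\t{doc.label}\t{' '.join(doc.tokens)}\t{doc.split}\n"
            )


def write_ground_truth(truth: GroundTruth, path: str) -> None:
    """Write the (term, role) sidecar as TSV, terms sorted."""
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(truth):
            fh.write(f"{term}\t{truth[term]}\n")


def read_ground_truth(path: str) -> GroundTruth:
    truth: GroundTruth = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            term, role = line.split("\t")
            truth[term] = role
    return truth
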