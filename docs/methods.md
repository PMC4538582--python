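# Methods

## Model

`ctxsel` scores bag-of-words features for labeled document collections with
univariate filter metrics and selects the top-N. All symbols are computed
from a `CountTable`: doc(t, c) (documents of category c containing term t),
doc(c), doc(t), tf(t, c), and a length-normalized term frequency
tf_norm(t, c) = Σ_d tf(t, d)/len(d) over category-c documents (an
alternative max-tf normalization is available; normalization exists so term
frequencies are comparable across documents of different lengths).
Probabilities are ratios of these counts: P(t|c) = doc(t,c)/doc(c),
P(t|c̄) = doc(t,c̄)/doc(c̄), P(c|t) = doc(t,c)/doc(t).

Frequency-based metrics (summed over categories): DF = Σ P(t|c_i);
GI = Σ P(t|c_i)² P(c_i|t)²; CDM = Σ |log((P(t|c_i)+ε)/(P(t|c̄_i)+ε))|;
Acc2 = Σ |P(t|c_i) − P(t|c̄_i)|; TFIDF = Σ tf(t,c_i)·log(1/P(t|c_i)) with
0·log∞ := 0; GINI_NTF = Σ (tf_norm(t,c_i)/doc(c_i))² ·
(tf_norm(t,c_i)/(tf_norm(t,c_i)+tf_norm(t,c̄_i)))².

The context-similarity metrics substitute sim_context(t, c) for doc(t, c).
A context window is the up-to-W tokens on each side of an occurrence,
truncated (never padded) at document boundaries. For a window pair the
similarity is Σ_{v=0..W} JW(s(v), s'(v))/(v+1), where s(v) joins the inner
v left tokens, the term, and the inner v right tokens with single spaces
and JW is Jaro-Winkler similarity computed character-wise.
sim_context(t, c) sums this over all unordered pairs of t's windows within
category c; the complement quantity sim_context(t, c̄) pools the windows of
every other category (for two categories it is exactly the other
category's sum). Fewer than two windows give 0, and the ratio metrics are
smoothed with the same additive ε.

## Interpretation choices

Several of the defining formulas are underdetermined at the edges; the
package resolves them as follows and exposes each choice as configuration.

* **Width-0 term.** The pair-similarity sum starts at v = 0, where both
  context strings equal the term itself, so every pair contributes a
  constant 1. This floor is included by default (it is what the summation
  says); `include_v0=False` starts at v = 1. The floor matters: it makes
  sim_context grow like the number of window pairs regardless of how
  dissimilar the contexts are, which is exactly why high-frequency
  random-context terms still need the *ratio* structure of the metrics to
  be demoted.
* **CDM/Acc2 sign.** For two categories the signed CDM sum is identically
  zero and the signed Acc2 sum collapses; both are taken as absolute values
  per summand (signed CDM is available via `cdm_signed=True`).
* **GI_cs denominator.** The second factor of GI_cs divides a similarity
  sum by the document count doc(t) — dimensionally a mixture, but it is
  implemented as written; the alternative readings do not change the
  planted-contrast rankings the tests check.
* **Smoothing.** ε = 1e-6 added to numerator and denominator of every
  ratio that can reach zero. This preserves the ordering of nonzero ratios
  and keeps all scores finite; ε only shifts the (large) scores of terms
  that are entirely absent from one class.
* **Logarithms** are natural; the base rescales CDM/TFIDF without
  affecting ranks.
* **Jaro-Winkler parameters** default to the standard prefix scale 0.1,
  prefix cap 4 and boost threshold 0.7; the validity condition
  p·lmax ≤ 1 is enforced. W defaults to 3, the usual working value for
  this measure.
* **Window enumeration.** One window per document (first occurrence) by
  default, so pairs range over distinct documents; `occurrence_mode="all"`
  also pairs multiple occurrences, including within one document. An
  optional deterministic cap (`max_windows_per_term`) bounds the quadratic
  pair sum; it is off by default.
* **Tokenization.** Lower-case, split on maximal non-alphanumeric runs,
  bundled stop-word list, no stemming; digits are kept so symbols like
  "b7" survive. Whether purely numeric or single-character tokens survive
  is configurable rather than guessed.

The pairwise sums are O(n²·W) Jaro-Winkler calls per (term, category);
they run as numba kernels over padded code-point arrays, and a literal
double-loop reference path (`method="naive"`) is kept both as readable
documentation and as the oracle the tests compare against (agreement to
1e-12; the accumulation order is identical, so agreement is in practice
bitwise).

## Evaluation

Precision = TP/(TP+FP), Recall = TP/(TP+FN), F1 their harmonic mean;
degenerate denominators yield 0 (the standard retrieval convention, which
keeps sweeps total). F1 is stored on 0–1 and printed ×100 at the CLI. A
feature-count sweep feeds the dimension-reduction rate score
Score = (1/k) Σ (dim_N/dim_i)·F1_i with F1 on the 0–100 scale — linear in
the F1s, collapsing to their mean when all trials use dim_N features.

The built-in classifier is a deterministic nearest-centroid baseline over
projected count vectors with a cosine decision rule. A document with none
of the selected features is assigned to the class whose centroid carries
the least mass on them — absence of the selected signal is evidence —
with remaining ties resolved to the majority training class and finally to
the positive class. Heavier models (the natural choice for real corpora is
a polynomial-kernel SVM with cross-validated hyperparameters) plug in
through the same fit/predict contract; the repository deliberately does not
re-implement or wrap SVM training, and all repository experiments use the
baseline.

## Synthetic corpora

The generator emulates the structure the method's argument rests on, with
three planted roles plus background noise:

* discriminative terms, embedded in a fixed 2W-token phrase template in a
  `disc_doc_rate` fraction of their class's documents (a
  `template_fidelity` fraction verbatim, the rest with shuffled template
  tokens) and appearing bare in a `cross_class_rate` fraction of
  other-class documents;
* ubiquitous terms, appearing bare at a high rate in both classes with
  random neighbors — excellent document frequency, no recurring context;
* template filler tokens (role "template"), class-correlated by
  construction and tracked as their own role so tests about the
  discriminative/ubiquitous contrast are not diluted by
  partially-templated edge tokens;
* uniform background noise from a disjoint vocabulary of random letter
  strings.

Rates are realized as **exact host counts** (round(rate·n) documents drawn
without replacement, stratified by the train/test split, with an exact
verbatim count per term). This balanced design was chosen after a pilot
simulation study: per-document Bernoulli planting leaves binomial tails
that (a) let one term's entire template dominate a 4th-power metric like
GI_cs, collapsing top-N selections onto few distinct terms, and (b) blur
the discriminative-over-ubiquitous margin at desk-scale corpus sizes. With
exact counts the planted contrasts are properties of the *conditions*, not
of the seed.

Default conditions (ranking experiments): 60 documents per class, 48
tokens each; 4 discriminative terms per class at disc_doc_rate 0.9, cross
rate 0.15, fidelity 0.95; 6 ubiquitous terms at rate 0.6; 40 noise terms;
W = 3. Under these conditions, across seeds: every context-similarity
metric ranks all discriminative terms above all ubiquitous terms with a
wide margin (worst observed DF_cs margin ≈ 30%), document frequency puts
the ubiquitous terms at the top of its ranking, and their DF_cs falls
below the vocabulary median.

Classification benchmarks use `benchmark_config()`: 200 documents per
class (80 tokens), 6 discriminative terms per class at disc_doc_rate 0.6,
24 ubiquitous terms, 300 noise terms. The change is deliberate: with the
template-rich ranking defaults, informative tokens are ~65% of the
vocabulary and *any* small feature subset classifies nearly perfectly, so
no selection strategy can demonstrate an advantage. Feature selection has
room to matter precisely when informative terms are sparse (~20% here) and
no single term covers its class; under these conditions the top-5% GI_cs
features reach mean F1 ≈ 1.0 while top-5% DF features (all ubiquitous)
stay near chance and random 5% subsets land in between.

What the generator does **not** emulate: real biomedical language
(morphology, Zipfian frequencies, protein-name variation), class skew, or
correlated noise phrases. Passing tests therefore demonstrate that the
implementation realizes the intended contrasts, not that the method wins
on any particular real corpus.

## Problem sizes and numerics

Repository experiments are desk-scale by design: ranking studies use
120-document corpora (seconds per seed) and classification benchmarks
400-document corpora (a few seconds per seed); 20 seeds per claim. Paired
comparisons use exact sign tests (ties dropped). Floating-point tolerances:
1e-12 for oracle-vs-optimized similarity sums, 1e-9 for hand-evaluated
metric values. Ties in rankings and selections are broken
lexicographically by term, making every table and selection deterministic;
all randomness flows from explicit integer seeds.

## Known limitations

* Quadratic cost in occurrences per (term, category); the optional window
  cap trades exactness for speed on large corpora.
* Character-level Jaro-Winkler saturates for long windows and shares a
  floor among all string pairs (two random contexts still score ≈ 0.4–0.6),
  which compresses the contrast available to the _cs ratios; the
  token-level mode is sharper but departs from the short-string rationale
  of the measure.
* Multi-class support follows the same formulas (complement = pooled other
  categories) but has only been exercised on two-class problems.
* The nearest-centroid baseline understates achievable F1 on hard corpora;
  it exists to compare feature sets, not to maximize accuracy.
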