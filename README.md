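# ctxsel — context similarity-based feature selection for article triage

Protein-interaction article classification (deciding which papers describe
protein–protein interactions, so curators only read the relevant ones) is a
binary text-classification problem with a huge bag-of-words feature space.
Classical univariate filters rank each term by frequency statistics and keep
the top N, but frequency is blind to *context*: a word like "protein"
appears in relevant and irrelevant abstracts alike, in ever-changing
surroundings, yet tops every document-frequency ranking, while genuinely
discriminative words recur inside similar multiword phrases within the
relevant class.

`ctxsel` implements a family of filter metrics that replace the per-category
document frequency doc(t, c) with a **context similarity**. For each
occurrence of term *t* take a window of up to *W* tokens on each side; for a
pair of windows from documents *d*, *d′* define

    sim(context_d(t, w), context_d'(t, w)) = Σ_{v=0..W}  JW(s_d(v), s_d'(v)) / (v + 1)

where `s(v)` is the width-`v` context string (v tokens, the term, v tokens)
and `JW` is Jaro–Winkler similarity, well suited to short strings. Summing
over all window pairs of *t* inside category *c* gives `sim_context(t, c)`,
and substituting it for doc(t, c) turns the four document-frequency filters
into their context-similarity counterparts:

    DF_cs(t)   = Σ_i sim_context(t, c_i) / doc(c_i)
    Acc2_cs(t) = Σ_i | sim_context(t, c_i)/doc(c_i) − sim_context(t, c̄_i)/doc(c̄_i) |
    CDM_cs(t)  = Σ_i | log( sim_context(t, c_i)/doc(c_i) · doc(c̄_i)/sim_context(t, c̄_i) ) |
    GI_cs(t)   = Σ_i ( sim_context(t, c_i)/doc(c_i) )² · ( sim_context(t, c_i)/doc(t) )²

The six frequency-based baselines (DF, GI, CDM, Acc2, TFIDF, GINI_NTF),
top-N selection, precision/recall/F1 evaluation, the dimension-reduction
rate score `(1/k) Σ_i (dim_N / dim_i) · F1_i`, and a synthetic labeled-corpus
generator with planted ground truth round out the package. A terms-in-
recurring-phrases vs frequent-terms-in-random-contexts contrast is exactly
what the generator plants, so every claim is testable without external
corpora.

## Worked example

Generate a synthetic two-class collection (60 abstracts per class; four
discriminative terms per class planted inside fixed phrase templates, six
ubiquitous both-class terms, background noise), then score and select:

```bash
$ ctxsel simulate --out-corpus corpus.tsv --out-truth truth.tsv --seed 7
wrote 120 documents (|vocabulary|=102) to corpus.tsv

$ ctxsel score corpus.tsv --metrics DF,GI_cs --out scores.tsv
corpus: 120 documents, |vocabulary|=102, categories=['irrelevant', 'relevant']
wrote 204 rows (2 metrics) to scores.tsv

$ ctxsel select scores.tsv --metric DF --n 5
ubi0
ubi1
ubi2
ubi3
ubi4

$ ctxsel select scores.tsv --metric GI_cs --n 5
tplirr3x3
tplrel1x3
tplrel0x3
tplirr2x3
tplirr0x3
```

Document frequency promotes the planted ubiquitous terms (`ubi*` — the
"protein"/"cell" phenomenon: present in most documents of both classes),
which carry no class signal. GI_cs instead promotes tokens of the planted
class-specific phrase templates (`tplrel*`/`tplirr*`), whose context windows
recur almost verbatim within one class. The downstream effect shows up in a
feature-count sweep with the built-in nearest-centroid baseline (F1 ×100 on
the held-out split; the final line is the dimension-reduction rate score,
which rewards accuracy at small feature counts):

```bash
$ ctxsel sweep corpus.tsv --metric GI_cs --grid 0.02,0.05,0.1,0.5,1.0
metric_id   n_features  fraction  precision  recall  f1
GI_cs       2           0.02      100.00     100.00  100.00
GI_cs       5           0.05      100.00     100.00  100.00
GI_cs       10          0.1       100.00     100.00  100.00
GI_cs       51          0.5       100.00     100.00  100.00
GI_cs       102         1         100.00     100.00  100.00
reduction_score 1692.00

$ ctxsel sweep corpus.tsv --metric DF --grid 0.02,0.05,0.1,0.5,1.0
metric_id   n_features  fraction  precision  recall  f1
DF          2           0.02      50.00      100.00  66.67
DF          5           0.05      50.00      100.00  66.67
DF          10          0.1       100.00     86.67   92.86
DF          51          0.5       100.00     100.00  100.00
DF          102         1         100.00     100.00  100.00
reduction_score 1201.43
```

With only 2–5 features, DF's ubiquitous picks cannot separate the classes
(F1 66.67) while GI_cs is already perfect; the reduction scores (1692 vs
1201) summarize that gap. The same machinery is available as a library:

```python
from ctxsel import jaro_winkler, generate, GeneratorConfig, score_all

jaro_winkler("MARTHA", "MARHTA")   # 0.9611111111111111
corpus, truth = generate(GeneratorConfig(seed=7))
table = score_all(corpus, ["DF", "DF_cs", "GI_cs"])
```

Further commands: `ctxsel overlap` (common-vs-special feature comparison of
two metrics' top-N lists) and flat `key=value` config files for the window
size, Jaro–Winkler parameters and smoothing (see `ctxsel score --help`).

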