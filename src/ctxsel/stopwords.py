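"""Bundled English stop-word list.

A compact list of closed-class English words.  Preprocessing lower-cases
text, strips punctuation and removes these words; no stemming is applied.
The list is deliberately small and user-overridable (pass any iterable of
lowercase words to :func:`ctxsel.corpus_io.tokenize` or use the
``stopword_file`` config key of the CLI).
"""

DEFAULT_STOPWORDS = frozenset(
    """
    a about above after again against all am an and any are as at be because
    been before being below between both but by cannot could did do does
    doing down during each few for from further had has have having he her
    here hers herself him himself his how i if in into is it its itself me
    more most my myself no nor not of off on once only or other ought our
    ours ourselves out over own same she should so some such than that the
    their theirs them themselves then there these they this those through to
    too under until up very was we were what when where which while who whom
    why with would you your yours yourself yourselves
    """.split()
)


def load_stopwords(path):
    """Read a stop-word file: one lowercase word per line, ``#`` comments."""
    words = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            word = line.strip().lower()
            if word and not word.startswith("#"):
                words.add(word)
    return frozenset(words)
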