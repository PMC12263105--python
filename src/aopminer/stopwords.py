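"""Fixed English stopword list.

The list shipped here (version ``en-1``) is the conventional English
function-word inventory used by mainstream NLP toolkits: pronouns,
auxiliaries, determiners, conjunctions and high-frequency adverbs and
prepositions, plus the single-letter remnants produced by splitting
contractions and possessives at punctuation ("event's" -> "event", "s").
It can be replaced wholesale via ``load_stopwords``.
"""

from __future__ import annotations

from pathlib import Path

STOPWORDS_VERSION = "en-1"

DEFAULT_STOPWORDS: frozenset[str] = frozenset("""
i me my myself we our ours ourselves you your yours yourself yourselves
he him his himself she her hers herself it its itself they them their
theirs themselves what which who whom this that these those am is are
was were be been being have has had having do does did doing a an the
and but if or because as until while of at by for with about against
between into through during before after above below to from up down in
out on off over under again further then once here there when where why
how all any both each few more most other some such no nor not only own
same so than too very s t d ll m o re ve y can will just don should now
ain aren couldn didn doesn hadn hasn haven isn ma mightn mustn needn
shan shouldn wasn weren won wouldn
""".split())


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Read a user stopword file: one word per line, '#' comments allowed."""
    words = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        word = line.split("#", 1)[0].strip().lower()
        if word:
            words.append(word)
    return frozenset(words)
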