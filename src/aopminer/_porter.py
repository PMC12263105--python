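"""Porter stemmer for English.

Implements the original 1980 suffix-stripping algorithm (the five-step
rule cascade over the word measure m in [C](VC)^m[V]) without the later
revisions some toolkits apply.  Tokens shorter than three letters and
tokens containing non-alphabetic characters (gene symbols such as
``tp53``) are returned unchanged.
"""

from __future__ import annotations

__all__ = ["PorterStemmer"]

_VOWELS = frozenset("aeiou")

# (suffix, replacement) rule tables; first matching suffix wins and ends
# the step, whether or not its measure condition allows the replacement.
_STEP2_RULES = (
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
)

_STEP3_RULES = (
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
)

_STEP4_SUFFIXES = (
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
)


class PorterStemmer:
    """Deterministic, dependency-free Porter (1980) stemmer."""

    id = "porter"

    def stem(self, word: str) -> str:
        if len(word) <= 2 or not word.isalpha() or not word.islower():
            # symbols with digits / mixed content are matched verbatim
            return word
        w = self._step1ab(word)
        w = self._step1c(w)
        w = self._step2(w)
        w = self._step3(w)
        w = self._step4(w)
        w = self._step5(w)
        return w

    # -- character classification -------------------------------------

    @staticmethod
    def _is_cons(w: str, i: int) -> bool:
        ch = w[i]
        if ch in _VOWELS:
            return False
        if ch == "y":
            return True if i == 0 else not PorterStemmer._is_cons(w, i - 1)
        return True

    @classmethod
    def _measure(cls, w: str) -> int:
        """Number of VC sequences in [C](VC)^m[V]."""
        i, n, ln = 0, 0, len(w)
        while i < ln and cls._is_cons(w, i):
            i += 1
        while True:
            if i >= ln:
                return n
            while i < ln and not cls._is_cons(w, i):
                i += 1
            if i >= ln:
                return n
            while i < ln and cls._is_cons(w, i):
                i += 1
            n += 1

    @classmethod
    def _has_vowel(cls, w: str) -> bool:
        return any(not cls._is_cons(w, i) for i in range(len(w)))

    @classmethod
    def _ends_double_cons(cls, w: str) -> bool:
        return len(w) >= 2 and w[-1] == w[-2] and cls._is_cons(w, len(w) - 1)

    @classmethod
    def _ends_cvc(cls, w: str) -> bool:
        if len(w) < 3:
            return False
        return (
            cls._is_cons(w, len(w) - 3)
            and not cls._is_cons(w, len(w) - 2)
            and cls._is_cons(w, len(w) - 1)
            and w[-1] not in "wxy"
        )

    # -- steps ---------------------------------------------------------

    def _step1ab(self, w: str) -> str:
        if w.endswith("s"):
            if w.endswith("sses") or w.endswith("ies"):
                w = w[:-2]
            elif not w.endswith("ss"):
                w = w[:-1]
        if w.endswith("eed"):
            if self._measure(w[:-3]) > 0:
                w = w[:-1]
        elif w.endswith("ed") and self._has_vowel(w[:-2]):
            w = self._step1b_fixup(w[:-2])
        elif w.endswith("ing") and self._has_vowel(w[:-3]):
            w = self._step1b_fixup(w[:-3])
        return w

    def _step1b_fixup(self, w: str) -> str:
        if w.endswith(("at", "bl", "iz")):
            return w + "e"
        if self._ends_double_cons(w) and w[-1] not in "lsz":
            return w[:-1]
        if self._measure(w) == 1 and self._ends_cvc(w):
            return w + "e"
        return w

    def _step1c(self, w: str) -> str:
        if w.endswith("y") and self._has_vowel(w[:-1]):
            return w[:-1] + "i"
        return w

    def _apply_rules(self, w: str, rules, min_measure: int) -> str:
        for suffix, repl in rules:
            if w.endswith(suffix):
                stem = w[: len(w) - len(suffix)]
                if self._measure(stem) > min_measure:
                    return stem + repl
                return w
        return w

    def _step2(self, w: str) -> str:
        return self._apply_rules(w, _STEP2_RULES, 0)

    def _step3(self, w: str) -> str:
        return self._apply_rules(w, _STEP3_RULES, 0)

    def _step4(self, w: str) -> str:
        for suffix in _STEP4_SUFFIXES:
            if w.endswith(suffix):
                stem = w[: len(w) - len(suffix)]
                if self._measure(stem) > 1:
                    if suffix == "ion" and not stem.endswith(("s", "t")):
                        return w
                    return stem
                return w
        return w

    def _step5(self, w: str) -> str:
        if w.endswith("e"):
            m = self._measure(w)
            if m > 1 or (m == 1 and not self._ends_cvc(w[:-1])):
                w = w[:-1]
        if w.endswith("ll") and self._measure(w) > 1:
            w = w[:-1]
        return w
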