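"""Porter suffix-stripping stemmer.

Implements the classic five-step Porter algorithm (1980) in the form
maintained by its author, i.e. including the two later revisions that every
modern reference implementation carries (``bli`` -> ``ble`` rather than
``abli`` -> ``able`` in step 2, and the additional ``logi`` -> ``log`` rule).
Words of length one or two are returned unchanged.

The stemmer is deliberately self-contained: it operates on lowercase ASCII
words and treats any character outside ``aeiou`` (including digits) as a
consonant, so synthetic vocabulary tokens such as ``term00042`` pass through
unharmed while their pluralised variants (``term00042s``) reduce to the same
form.
"""

from __future__ import annotations

__all__ = ["stem_word"]

_VOWELS = "aeiou"


class _Stemmer:
    """Mutable buffer/end-pointer state for one word, Porter-paper style.

    ``b`` is the word buffer, ``k`` the offset of its current last letter and
    ``j`` the offset set by :meth:`_ends` to just before a matched suffix.
    """

    __slots__ = ("b", "k", "j")

    def __init__(self, word: str) -> None:
        self.b = list(word)
        self.k = len(word) - 1
        self.j = 0

    # -- character classification -------------------------------------------

    def _cons(self, i: int) -> bool:
        ch = self.b[i]
        if ch in _VOWELS:
            return False
        if ch == "y":
            return True if i == 0 else not self._cons(i - 1)
        return True

    def _m(self) -> int:
        """Number of VC sequences in b[0:j+1] (the Porter measure)."""
        n = 0
        i = 0
        while True:
            if i > self.j:
                return n
            if not self._cons(i):
                break
            i += 1
        i += 1
        while True:
            while True:
                if i > self.j:
                    return n
                if self._cons(i):
                    break
                i += 1
            i += 1
            n += 1
            while True:
                if i > self.j:
                    return n
                if not self._cons(i):
                    break
                i += 1
            i += 1

    def _vowel_in_stem(self) -> bool:
        return any(not self._cons(i) for i in range(self.j + 1))

    def _doublec(self, i: int) -> bool:
        if i < 1 or self.b[i] != self.b[i - 1]:
            return False
        return self._cons(i)

    def _cvc(self, i: int) -> bool:
        """consonant-vowel-consonant ending at i, last consonant not w/x/y."""
        if i < 2 or not self._cons(i) or self._cons(i - 1) or not self._cons(i - 2):
            return False
        return self.b[i] not in "wxy"

    # -- suffix plumbing -----------------------------------------------------

    def _ends(self, s: str) -> bool:
        length = len(s)
        if length > self.k + 1:
            return False
        if self.b[self.k - length + 1 : self.k + 1] != list(s):
            return False
        self.j = self.k - length
        return True

    def _setto(self, s: str) -> None:
        self.b[self.j + 1 : self.k + 1] = list(s)
        self.k = self.j + len(s)

    def _r(self, s: str) -> None:
        if self._m() > 0:
            self._setto(s)

    # -- the five steps ------------------------------------------------------

    def _step1ab(self) -> None:
        if self.b[self.k] == "s":
            if self._ends("sses"):
                self.k -= 2
            elif self._ends("ies"):
                self._setto("i")
            elif self.b[self.k - 1] != "s":
                self.k -= 1
        if self._ends("eed"):
            if self._m() > 0:
                self.k -= 1
        elif (self._ends("ed") or self._ends("ing")) and self._vowel_in_stem():
            self.k = self.j
            if self._ends("at"):
                self._setto("ate")
            elif self._ends("bl"):
                self._setto("ble")
            elif self._ends("iz"):
                self._setto("ize")
            elif self._doublec(self.k):
                self.k -= 1
                if self.b[self.k] in "lsz":
                    self.k += 1
            elif self._m() == 1 and self._cvc(self.k):
                self._setto("e")

    def _step1c(self) -> None:
        if self._ends("y") and self._vowel_in_stem():
            self.b[self.k] = "i"

    _STEP2 = {
        "a": (("ational", "ate"), ("tional", "tion")),
        "c": (("enci", "ence"), ("anci", "ance")),
        "e": (("izer", "ize"),),
        "l": (("bli", "ble"), ("alli", "al"), ("entli", "ent"), ("eli", "e"),
              ("ousli", "ous")),
        "o": (("ization", "ize"), ("ation", "ate"), ("ator", "ate")),
        "s": (("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
              ("ousness", "ous")),
        "t": (("aliti", "al"), ("iviti", "ive"), ("biliti", "ble")),
        "g": (("logi", "log"),),
    }

    def _step2(self) -> None:
        for suffix, repl in self._STEP2.get(self.b[self.k - 1], ()):
            if self._ends(suffix):
                self._r(repl)
                return

    _STEP3 = {
        "e": (("icate", "ic"), ("ative", ""), ("alize", "al")),
        "i": (("iciti", "ic"),),
        "l": (("ical", "ic"), ("ful", "")),
        "s": (("ness", ""),),
    }

    def _step3(self) -> None:
        for suffix, repl in self._STEP3.get(self.b[self.k], ()):
            if self._ends(suffix):
                self._r(repl)
                return

    _STEP4 = {
        "a": ("al",),
        "c": ("ance", "ence"),
        "e": ("er",),
        "i": ("ic",),
        "l": ("able", "ible"),
        "n": ("ant", "ement", "ment", "ent"),
        "o": ("ion", "ou"),
        "s": ("ism",),
        "t": ("ate", "iti"),
        "u": ("ous",),
        "v": ("ive",),
        "z": ("ize",),
    }

    def _step4(self) -> None:
        for suffix in self._STEP4.get(self.b[self.k - 1], ()):
            if self._ends(suffix):
                # 'ion' only counts as a suffix after s or t
                if suffix == "ion" and (self.j < 0 or self.b[self.j] not in "st"):
                    continue
                if self._m() > 1:
                    self.k = self.j
                return

    def _step5(self) -> None:
        self.j = self.k
        if self.b[self.k] == "e":
            a = self._m()
            if a > 1 or (a == 1 and not self._cvc(self.k - 1)):
                self.k -= 1
        if self.b[self.k] == "l" and self._doublec(self.k) and self._m() > 1:
            self.k -= 1

    def run(self) -> str:
        if self.k <= 1:
            return "".join(self.b)
        self._step1ab()
        self._step1c()
        self._step2()
        self._step3()
        self._step4()
        self._step5()
        return "".join(self.b[: self.k + 1])


def stem_word(word: str) -> str:
    """Return the Porter stem of a single lowercase word."""
    return _Stemmer(word).run()
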