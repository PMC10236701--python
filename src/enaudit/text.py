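"""Tokenization, stemming and the generic preprocessing chain.

The stemmer is a self-contained implementation of the classic Porter
(1980) suffix-stripping algorithm; the lemmatizer is a deliberately
small rule-based fallback (plural and inflection suffixes only).  Both
identities are recorded in run metadata because they affect exact-match
results downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Callable, Sequence

__all__ = [
    "tokenize",
    "porter_stem",
    "simple_lemmatize",
    "load_stopwords",
    "PreprocConfig",
    "apply_preproc",
    "register_hook",
    "normalize_surface",
]

_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Split on whitespace and punctuation; punctuation tokens dropped."""
    return _TOKEN_RE.findall(text)


# ---------------------------------------------------------------------------
# Porter stemmer
# ---------------------------------------------------------------------------

_VOWELS = "aeiou"


def _is_consonant(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of VC sequences ("m" in Porter's notation)."""
    forms = "".join(
        "C" if _is_consonant(stem, i) else "V" for i in range(len(stem))
    )
    return forms.count("VC") if "VC" in forms else len(re.findall("VC", forms))


def _contains_vowel(stem: str) -> bool:
    return any(not _is_consonant(stem, i) for i in range(len(stem)))


def _ends_double_consonant(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_consonant(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    return (
        _is_consonant(word, len(word) - 3)
        and not _is_consonant(word, len(word) - 2)
        and _is_consonant(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("bli", "ble"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
    ("logi", "log"),
]

_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]

_STEP4 = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


@lru_cache(maxsize=65536)
def porter_stem(word: str) -> str:
    """Stem a single lowercase token with the Porter algorithm."""
    if len(word) <= 2:
        return word
    w = word

    # Step 1a
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif w.endswith("ss"):
        pass
    elif w.endswith("s"):
        w = w[:-1]

    # Step 1b
    flag_1b = False
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    elif w.endswith("ed"):
        if _contains_vowel(w[:-2]):
            w = w[:-2]
            flag_1b = True
    elif w.endswith("ing"):
        if _contains_vowel(w[:-3]):
            w = w[:-3]
            flag_1b = True
    if flag_1b:
        if w.endswith(("at", "bl", "iz")):
            w += "e"
        elif _ends_double_consonant(w) and not w.endswith(("l", "s", "z")):
            w = w[:-1]
        elif _measure(w) == 1 and _ends_cvc(w):
            w += "e"

    # Step 1c
    if w.endswith("y") and _contains_vowel(w[:-1]):
        w = w[:-1] + "i"

    # Step 2
    for suffix, replacement in _STEP2:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if _measure(stem) > 0:
                w = stem + replacement
            break

    # Step 3
    for suffix, replacement in _STEP3:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if _measure(stem) > 0:
                w = stem + replacement
            break

    # Step 4
    for suffix in _STEP4:
        if w.endswith(suffix):
            stem = w[: -len(suffix)]
            if suffix == "ion" and not stem.endswith(("s", "t")):
                continue
            if _measure(stem) > 1:
                w = stem
            break

    # Step 5a
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            w = stem

    # Step 5b
    if _measure(w) > 1 and _ends_double_consonant(w) and w.endswith("l"):
        w = w[:-1]

    return w


_LEMMA_RULES = [
    ("ies", "y"), ("sses", "ss"), ("shes", "sh"), ("ches", "ch"),
    ("xes", "x"), ("zes", "z"), ("ing", ""), ("ed", ""), ("s", ""),
]


def simple_lemmatize(word: str) -> str:
    """Minimal rule-based English lemmatizer (inflection suffixes only)."""
    if len(word) <= 3:
        return word
    for suffix, replacement in _LEMMA_RULES:
        if word.endswith(suffix) and len(word) - len(suffix) >= 2:
            if suffix == "s" and word.endswith("ss"):
                continue
            candidate = word[: -len(suffix)] + replacement
            if len(candidate) >= 2:
                return candidate
    return word


def load_stopwords() -> frozenset[str]:
    """The packaged, versioned stopword list (lowercase)."""
    text = (
        resources.files("enaudit").joinpath("data/stopwords_en.txt").read_text("utf-8")
    )
    return frozenset(
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


# ---------------------------------------------------------------------------
# Preprocessing chain
# ---------------------------------------------------------------------------

_HOOKS: dict[str, Callable[[str], str]] = {}


def register_hook(name: str, func: Callable[[str], str]) -> None:
    """Register an external text transform (acronym/typo resolution, ...)
    addressable by name from a :class:`PreprocConfig`."""
    _HOOKS[name] = func


@dataclass(frozen=True)
class PreprocConfig:
    """Generic preprocessing toggles applied in a fixed, documented order:
    hooks, lowercase, punctuation removal, stopword removal, stem/lemma.
    """

    lowercase: bool = False
    punctuation_removal: bool = False
    stemming: bool = False
    lemmatization: bool = False
    stopword_removal: bool = False
    hooks: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.stemming and self.lemmatization:
            raise ValueError("stemming and lemmatization are mutually exclusive")

    def describe(self) -> dict[str, object]:
        """Serializable record of the chain, for run metadata."""
        return {
            "order": ["hooks", "lowercase", "punctuation", "stopwords", "stem/lemma"],
            "lowercase": self.lowercase,
            "punctuation_removal": self.punctuation_removal,
            "stemming": self.stemming,
            "stemmer": "porter-1980" if self.stemming else None,
            "lemmatization": self.lemmatization,
            "stopword_removal": self.stopword_removal,
            "hooks": list(self.hooks),
            "tokenizer": "unicode-word, punctuation dropped",
        }


_PUNCT_RE = re.compile(r"[^\w\s]|_", re.UNICODE)
_WS_RE = re.compile(r"\s+")


def apply_preproc(text: str, config: PreprocConfig) -> str:
    """Apply the configured chain to one string; identity when all flags
    are off and no hooks are set."""
    for hook_name in config.hooks:
        if hook_name not in _HOOKS:
            raise KeyError(f"unknown preprocessing hook {hook_name!r}")
        text = _HOOKS[hook_name](text)
    if config.lowercase:
        text = text.lower()
    if config.punctuation_removal:
        text = _WS_RE.sub(" ", _PUNCT_RE.sub(" ", text)).strip()
    if config.stopword_removal:
        stopwords = load_stopwords()
        kept = [t for t in text.split() if t.lower() not in stopwords]
        text = " ".join(kept)
    if config.stemming:
        text = " ".join(porter_stem(t.lower()) if config.lowercase else
                        porter_stem(t) for t in text.split())
    elif config.lemmatization:
        text = " ".join(simple_lemmatize(t) for t in text.split())
    return text


#: Chain used by the baseline lexicon: lowercase + per-token Porter stem,
#: tokens joined by single spaces.
BASELINE_PREPROC = PreprocConfig(lowercase=True, punctuation_removal=True,
                                 stemming=True)


def normalize_surface(surface: str, config: PreprocConfig = BASELINE_PREPROC) -> str:
    """Tokenize then run the chain per token; the single point of truth
    for baseline "same string" comparisons."""
    tokens = tokenize(surface)
    out: list[str] = []
    for token in tokens:
        transformed = apply_preproc(token, config)
        if transformed:
            out.append(transformed)
    return " ".join(out)
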