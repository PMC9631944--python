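"""Per-language text normalization: case-folding, punctuation and hyphen
handling, stemming/lemmatization, and coarse POS filtering.

Non-English text is reduced to stems (suffix stripping); English text is
lemmatized and may be POS-filtered to content words (nouns including proper
nouns, verbs, adjectives).  German headline matching works on case-folded
raw strings, so its profile uses ``mode="raw"``.

Stemmers, lemmatizers and POS taggers are adapters: any object with the
right method can be plugged in (e.g. Snowball stemmers or a TreeTagger
wrapper).  The bundled implementations are small, deterministic rule
systems so the whole pipeline runs hermetically; they are crude linguistics
but exact software, which is what the tests need.  The bundled stemmer
strips suffixes to a fixpoint, which makes normalization idempotent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

from .corpus import SUPPORTED_LANGUAGES

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_HYPHEN_RE = re.compile(r"[-‐‑‒–—]")
# keep letters/digits/underscore, whitespace, apostrophes; drop the rest
_PUNCT_RE = re.compile(r"[^\w\s'’]", re.UNICODE)
_EDGE_APOS_RE = re.compile(r"(?:^['’]+)|(?:['’]+$)")


class ConfigurationError(RuntimeError):
    """A normalization adapter is missing or misconfigured for a language."""


class Stemmer(Protocol):
    def stem(self, token: str) -> str: ...


class Lemmatizer(Protocol):
    def lemmatize(self, token: str) -> str: ...


class PosTagger(Protocol):
    def tag(self, tokens: Sequence[str]) -> list[tuple[str, str]]: ...


# --------------------------------------------------------------------------
# Bundled deterministic adapters


#: Per-language suffix lists for the bundled stemmer, longest first.  The
#: lists are tuned to the vaccine-keyword equivalence classes (plural and
#: verbal inflections of vaccination vocabulary), not to general coverage.
_SUFFIXES: dict[str, tuple[str, ...]] = {
    "fr": ("ations", "ation", "ements", "ement", "ées", "ée", "és", "é",
           "er", "ez", "es", "e", "s"),
    "it": ("azioni", "azione", "are", "ato", "ata", "ati", "ate",
           "i", "o", "a", "e"),
    "es": ("aciones", "ación", "acion", "ados", "adas", "ado", "ada",
           "ar", "os", "as", "es", "o", "a", "s", "e"),
    "ru": ("ть", "ия", "ами", "ах", "ам", "ов", "ой",
           "ы", "и", "а", "я", "у", "е", "о"),
    # English and German never go through the stemmer in the default
    # profiles; identity keeps the adapter total.
    "en": (),
    "de": (),
}

_VOWELS = set("aeiouyàâäéèêëîïôöùûüáíóúаеёиоуыэюя")

_MIN_STEM = 3


@dataclass(frozen=True)
class SuffixStemmer:
    """Iterated longest-match suffix stripper.

    Stripping repeats until no listed suffix applies, so ``stem`` is
    idempotent by construction.  A final ``s``/``es`` is only removed after
    a consonant (plural-like), which keeps stems such as ``immunis`` stable.
    Stems shorter than three characters are never produced.
    """

    language: str

    def stem(self, token: str) -> str:
        suffixes = _SUFFIXES.get(self.language)
        if suffixes is None:
            raise ConfigurationError(f"no bundled stemmer for {self.language!r}")
        word = token
        while True:
            stripped = self._strip_once(word, suffixes)
            if stripped == word:
                return word
            word = stripped

    @staticmethod
    def _strip_once(word: str, suffixes: tuple[str, ...]) -> str:
        for suf in suffixes:
            if word.endswith(suf) and len(word) - len(suf) >= _MIN_STEM:
                if suf in ("s", "es") and word[-len(suf) - 1] in _VOWELS:
                    continue
                return word[: -len(suf)]
        return word


#: Minimal irregular-form table for the bundled lemmatizer.
_IRREGULAR_LEMMAS = {
    "children": "child", "men": "man", "women": "woman", "people": "person",
    "mice": "mouse", "feet": "foot", "geese": "goose", "teeth": "tooth",
    "was": "be", "were": "be", "is": "be", "are": "be", "been": "be",
    "has": "have", "had": "have", "said": "say", "went": "go",
    "begins": "begin", "began": "begin", "begun": "begin",
    "got": "get", "gave": "give", "given": "give", "made": "make",
    "took": "take", "taken": "take", "ran": "run", "rose": "rise",
    "grows": "grow", "grew": "grow", "grown": "grow",
}


class RuleLemmatizer:
    """English lemmatizer: irregular table, then conservative ``-s``
    plural stripping.  Identity elsewhere — deliberately cautious so that
    lemmatization is idempotent and never invents forms."""

    def lemmatize(self, token: str) -> str:
        if token in _IRREGULAR_LEMMAS:
            return _IRREGULAR_LEMMAS[token]
        if (
            len(token) > 4
            and token.endswith("s")
            and not token.endswith(("ss", "us", "is", "news"))
        ):
            return token[:-1]
        return token


_FUNCTION_WORDS: dict[str, str] = {}
for _tag, _words in {
    "det": "the a an this that these those some any no every each",
    "adp": "of in on at by for with from to into over under about after "
           "before against between during through among across",
    "pron": "he she it they we you i them him her us who whom which what "
            "its their his our your my",
    "conj": "and or but nor so yet because although while if when than",
    "part": "not to n't",
    "aux": "be is are was were been am do does did have has had will would "
           "can could may might must shall should",
}.items():
    for _w in _words.split():
        _FUNCTION_WORDS[_w] = _tag

_ADJ_SUFFIXES = ("ous", "ful", "ive", "able", "ible", "ical", "less", "ish")
_VERB_SUFFIXES = ("ing", "ise", "ize", "ify")
_COMMON_VERBS = frozenset(
    "say get make go know take see come think want give use find tell ask "
    "work call need begin grow rise report announce approve launch warn "
    "urge delay halt expand demand reject back face hit plan start "
    "roll surge fall drop".split()
)


class RulePosTagger:
    """Coarse deterministic POS tagger for English.

    Closed-class words from a stoplist; ``-ly`` adverbs; suffix-based
    adjectives and verbs; a small common-verb list; capitalized non-initial
    tokens as proper nouns; everything else a noun.  Crude, but stable, and
    the content/function split it induces is the only property downstream
    code relies on.
    """

    def tag(self, tokens: Sequence[str]) -> list[tuple[str, str]]:
        out: list[tuple[str, str]] = []
        for i, tok in enumerate(tokens):
            low = tok.casefold()
            if low in _FUNCTION_WORDS:
                tag = _FUNCTION_WORDS[low]
            elif low.replace(".", "").replace(",", "").isdigit():
                tag = "num"
            elif low.endswith("ly") and len(low) > 3:
                tag = "adv"
            elif low in _COMMON_VERBS or low.endswith(_VERB_SUFFIXES):
                tag = "verb"
            elif low.endswith(_ADJ_SUFFIXES):
                tag = "adj"
            elif i > 0 and tok[:1].isupper():
                tag = "propn"
            else:
                tag = "noun"
            out.append((tok, tag))
        return out


# --------------------------------------------------------------------------
# Profiles and the normalize pipeline


#: Coarse content-word tags retained for topic input and n-grams.
CONTENT_POS = frozenset({"noun", "propn", "verb", "adj"})


@dataclass(frozen=True)
class TokenSequence:
    """Ordered normalized word forms from one text field."""

    tokens: tuple[str, ...]
    source_field: str = "title"

    def __iter__(self):
        return iter(self.tokens)

    def __len__(self):
        return len(self.tokens)

    def joined(self) -> str:
        return " ".join(self.tokens)


@dataclass(frozen=True)
class NormalizationProfile:
    """How to normalize text in one language.

    ``mode`` is ``"stem"`` (suffix stripping; fr/it/ru/es), ``"lemma"``
    (English), or ``"raw"`` (case-folded string kept whole; German keyword
    matching).  Case-folding is always applied.
    """

    language: str
    mode: str  # {"stem", "lemma", "raw"}
    split_hyphens: bool = True
    strip_punct: bool = True
    strip_urls: bool = True
    stemmer: Stemmer | None = None
    lemmatizer: Lemmatizer | None = None
    tagger: PosTagger | None = None

    def __post_init__(self):
        if self.language not in SUPPORTED_LANGUAGES:
            raise ConfigurationError(f"unsupported language: {self.language!r}")
        if self.mode not in ("stem", "lemma", "raw"):
            raise ConfigurationError(f"unknown normalization mode: {self.mode!r}")


def default_profiles() -> dict[str, NormalizationProfile]:
    """Bundled per-language profiles: lemmatize English, stem French,
    Italian, Russian and Spanish, and keep German raw for pattern search."""
    profs = {}
    for lang in ("fr", "it", "ru", "es"):
        profs[lang] = NormalizationProfile(lang, "stem", stemmer=SuffixStemmer(lang))
    profs["en"] = NormalizationProfile(
        "en", "lemma", lemmatizer=RuleLemmatizer(), tagger=RulePosTagger()
    )
    profs["de"] = NormalizationProfile("de", "raw")
    return profs


def casefold_text(text: str) -> str:
    """Unicode-aware lowercasing used everywhere matching is case-blind."""
    return text.casefold()


def _pretokenize(text: str, profile: NormalizationProfile) -> list[str]:
    if profile.strip_urls:
        text = _URL_RE.sub(" ", text)
    text = casefold_text(text)
    if profile.split_hyphens:
        text = _HYPHEN_RE.sub(" ", text)
    if profile.strip_punct:
        text = _PUNCT_RE.sub(" ", text)
    tokens = []
    for tok in text.split():
        tok = _EDGE_APOS_RE.sub("", tok)
        if tok:
            tokens.append(tok)
    return tokens


def normalize(
    text: str, profile: NormalizationProfile, source_field: str = "title"
) -> TokenSequence:
    """Normalize free text to a :class:`TokenSequence` under ``profile``.

    Deterministic and idempotent: normalizing the space-joined output
    again returns the same tokens.
    """
    if profile.mode == "raw":
        # raw mode still tokenizes (for n-gram use) but applies no
        # stemming; pattern matching happens on casefold_text() directly.
        return TokenSequence(tuple(_pretokenize(text, profile)), source_field)
    tokens = _pretokenize(text, profile)
    if profile.mode == "stem":
        if profile.stemmer is None:
            raise ConfigurationError(
                f"profile for {profile.language!r} has no stemmer adapter"
            )
        tokens = [profile.stemmer.stem(t) for t in tokens]
    else:  # lemma
        if profile.lemmatizer is None:
            raise ConfigurationError(
                f"profile for {profile.language!r} has no lemmatizer adapter"
            )
        tokens = [profile.lemmatizer.lemmatize(t) for t in tokens]
    return TokenSequence(tuple(t for t in tokens if t), source_field)


def tag_tokens(
    tokens: Sequence[str], profile: NormalizationProfile
) -> list[tuple[str, str]]:
    """POS-tag a token sequence with the profile's tagger adapter."""
    if profile.tagger is None:
        raise ConfigurationError(
            f"profile for {profile.language!r} has no POS tagger adapter"
        )
    return profile.tagger.tag(list(tokens))


def pos_filter(
    tagged: Iterable[tuple[str, str]], keep: frozenset[str] | set[str] = CONTENT_POS
) -> TokenSequence:
    """Keep only tokens whose coarse POS tag is in ``keep``, preserving
    order.  Proper nouns count as nouns: if ``"noun"`` is kept, ``"propn"``
    is kept too."""
    keep = set(keep)
    if "noun" in keep:
        keep.add("propn")
    kept = []
    for item in tagged:
        try:
            tok, tag = item
        except (TypeError, ValueError) as exc:
            raise ValueError("pos_filter requires (token, tag) pairs") from exc
        if tag in keep:
            kept.append(tok)
    return TokenSequence(tuple(kept))
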