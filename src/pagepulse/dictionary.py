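"""Category→keyword dictionary: loading, validation, and editing.

The classifier is driven by a dictionary mapping content-analysis categories
to sets of complete word forms. Two hard rules hold at all times:

* a word may belong to at most one category (disjointness), and
* every keyword is a single word, stored normalized (NFC + casefold,
  diacritics preserved).

There is no stemming and no root matching, so all inflections of a word
(singular/plural, masculine/feminine) must be enumerated explicitly;
:func:`expand_inflections` normalizes a caller-supplied list of forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional
import warnings

import yaml

from ._text import normalize_word

#: The default 8-category content-analysis scheme for cancer-related pages.
DEFAULT_CATEGORIES = (
    "testimonies_or_real_life_stories",
    "solidarity",
    "anniversaries",
    "science_and_health",
    "events",
    "institutional",
    "risk_factors",
    "beauty",
)


class DictionaryError(ValueError):
    """A dictionary config violates a structural rule."""


def _check_single_word(word: str) -> str:
    norm = normalize_word(word.strip())
    if not norm:
        raise DictionaryError("empty keyword")
    if any(ch.isspace() for ch in norm):
        raise DictionaryError(
            f"keyword {word!r} contains whitespace; only single complete words are allowed"
        )
    return norm


@dataclass(frozen=True)
class KeywordDictionary:
    """Immutable category→keyword mapping with pairwise-disjoint word sets."""

    categories: tuple[str, ...]
    keywords: Mapping[str, frozenset[str]]

    @classmethod
    def from_mapping(
        cls,
        mapping: Mapping[str, Iterable[str]],
        generic_words: Optional[Iterable[str]] = None,
    ) -> "KeywordDictionary":
        """Build a validated dictionary from ``{category: [word, ...]}``.

        ``generic_words`` is an optional author-maintained list of words too
        general to discriminate between categories (e.g. the disease name
        itself); entries found in it are kept but trigger a warning, since
        excluding them is an editorial decision, not a software rule.
        """
        categories: list[str] = []
        keywords: dict[str, frozenset[str]] = {}
        owner: dict[str, str] = {}
        generic = {normalize_word(w) for w in generic_words} if generic_words else set()
        for name, words in mapping.items():
            cat = str(name).strip()
            if not cat:
                raise DictionaryError("empty category name")
            if cat in keywords:
                raise DictionaryError(f"duplicate category name {cat!r}")
            normed: set[str] = set()
            for word in words or []:
                norm = _check_single_word(str(word))
                if norm in owner and owner[norm] != cat:
                    raise DictionaryError(
                        f"word {norm!r} appears in both {owner[norm]!r} and {cat!r}; "
                        "a word may belong to only one category"
                    )
                if norm in generic:
                    warnings.warn(
                        f"keyword {norm!r} in category {cat!r} is flagged as a "
                        "generic word; consider removing it",
                        stacklevel=2,
                    )
                owner.setdefault(norm, cat)
                normed.add(norm)
            if not normed:
                warnings.warn(f"category {cat!r} has no keywords", stacklevel=2)
            categories.append(cat)
            keywords[cat] = frozenset(normed)
        return cls(categories=tuple(categories), keywords=keywords)

    def category_of(self, word: str) -> Optional[str]:
        norm = normalize_word(word)
        for cat in self.categories:
            if norm in self.keywords[cat]:
                return cat
        return None

    def all_words(self) -> frozenset[str]:
        out: set[str] = set()
        for words in self.keywords.values():
            out |= words
        return frozenset(out)

    def to_mapping(self) -> dict[str, list[str]]:
        return {cat: sorted(self.keywords[cat]) for cat in self.categories}


def load_dictionary(path, generic_words: Optional[Iterable[str]] = None) -> KeywordDictionary:
    """Load and validate a dictionary config (YAML or JSON mapping)."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise DictionaryError(f"{path.name}: expected a mapping of category to word list")
    return KeywordDictionary.from_mapping(raw, generic_words=generic_words)


def save_dictionary(dictionary: KeywordDictionary, path) -> None:
    """Write a dictionary config readable by :func:`load_dictionary`."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        yaml.safe_dump(
            dictionary.to_mapping(), fh, allow_unicode=True, sort_keys=False
        )


def default_dictionary() -> KeywordDictionary:
    """The packaged demonstration dictionary for the 8 default categories.

    Small and illustrative: it ships so that every pipeline stage can run
    out of the box, not as a validated instrument for real pages.
    """
    ref = resources.files("pagepulse").joinpath("data/default_dictionary.yaml")
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return KeywordDictionary.from_mapping(raw)


def add_keyword(dictionary: KeywordDictionary, category: str, word: str) -> KeywordDictionary:
    """Return a dictionary with ``word`` added to ``category``.

    Adding a word already in the category is a no-op; adding a word owned by
    another category is rejected, preserving disjointness.
    """
    if category not in dictionary.keywords:
        raise DictionaryError(f"unknown category {category!r}")
    norm = _check_single_word(word)
    owner = dictionary.category_of(norm)
    if owner is not None and owner != category:
        raise DictionaryError(
            f"cannot add {norm!r} to {category!r}: already in {owner!r}"
        )
    if owner == category:
        return dictionary
    keywords = dict(dictionary.keywords)
    keywords[category] = keywords[category] | {norm}
    return KeywordDictionary(categories=dictionary.categories, keywords=keywords)


def remove_keyword(dictionary: KeywordDictionary, category: str, word: str) -> KeywordDictionary:
    """Return a dictionary with ``word`` removed from ``category`` (no-op if absent)."""
    if category not in dictionary.keywords:
        raise DictionaryError(f"unknown category {category!r}")
    norm = normalize_word(word)
    if norm not in dictionary.keywords[category]:
        return dictionary
    keywords = dict(dictionary.keywords)
    keywords[category] = keywords[category] - {norm}
    return KeywordDictionary(categories=dictionary.categories, keywords=keywords)


def expand_inflections(word: str, forms: Iterable[str]) -> list[str]:
    """Normalize and deduplicate a list of inflected forms of ``word``.

    The caller enumerates the forms (singular, plural, masculine, feminine,
    …); no morphology is generated here. Multi-word forms are rejected.
    Order of first appearance is kept; the base word is included.
    """
    out: list[str] = []
    seen: set[str] = set()
    for form in [word, *forms]:
        norm = _check_single_word(str(form))
        if norm not in seen:
            seen.add(norm)
            out.append(norm)
    return out
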