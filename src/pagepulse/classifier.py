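"""Dictionary-based post classification.

Each post is tokenized into complete words and assigned to the category
whose keyword set matches the highest number of token *occurrences* (a
keyword appearing twice counts twice). There is no context, negation or
typo handling: a post whose tokens match no category at all is labelled
``UNCATEGORIZED``, and exact ties are broken deterministically (alphabetical
category order by default, or a caller-supplied priority list) with the tie
recorded so reports can surface the ambiguity.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from ._text import normalize_word
from .dictionary import KeywordDictionary
from .posts_io import Corpus, Post

#: Label for posts with zero keyword matches in every category.
UNCATEGORIZED = "UNCATEGORIZED"

# URLs are dropped before tokenization so host/path fragments never match.
_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)

# Maximal runs of Unicode letters; digits, punctuation and underscores are
# separators, so internal hyphens split ("pré-natal" -> "pré", "natal").
_TOKEN_RE = re.compile(r"[^\W\d_]+", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Split ``text`` into normalized word tokens.

    Total function: any string (including empty) yields a, possibly empty,
    token list. Tokens are normalized exactly like dictionary keywords.
    """
    stripped = _URL_RE.sub(" ", text)
    return [normalize_word(tok) for tok in _TOKEN_RE.findall(stripped)]


@dataclass
class CategoryAssignment:
    """The classifier's verdict for one post.

    ``counts`` holds the per-category occurrence counts (every dictionary
    category present, zeros included); ``matched_keywords`` the matching
    tokens per category in text order; ``tie`` is True when more than one
    category shared the maximal nonzero count and the tie-break rule chose.
    """

    post_id: str
    assigned_category: str
    counts: dict[str, int]
    matched_keywords: dict[str, list[str]]
    tie: bool = False


def count_matches(tokens: Sequence[str], dictionary: KeywordDictionary) -> dict[str, int]:
    """Occurrence count of each category's keywords among ``tokens``."""
    occurrences = Counter(tokens)
    return {
        cat: sum(occurrences[w] for w in dictionary.keywords[cat] if w in occurrences)
        for cat in dictionary.categories
    }


def _resolve_tie(
    candidates: list[str], tie_break: str, priority: Optional[Sequence[str]]
) -> str:
    if tie_break == "alpha":
        return min(candidates)
    if tie_break == "priority":
        if not priority:
            raise ValueError("tie_break='priority' requires a priority list")
        order = {cat: i for i, cat in enumerate(priority)}
        return min(candidates, key=lambda c: (order.get(c, len(order)), c))
    raise ValueError(f"unknown tie_break policy {tie_break!r}")


def classify(
    post: Post,
    dictionary: KeywordDictionary,
    tie_break: str = "alpha",
    priority: Optional[Sequence[str]] = None,
) -> CategoryAssignment:
    """Assign ``post`` to the category with the most keyword occurrences."""
    tokens = tokenize(post.text)
    counts = count_matches(tokens, dictionary)
    matched = {
        cat: [t for t in tokens if t in dictionary.keywords[cat]]
        for cat in dictionary.categories
    }
    best = max(counts.values(), default=0)
    if best == 0:
        return CategoryAssignment(
            post_id=post.post_id,
            assigned_category=UNCATEGORIZED,
            counts=counts,
            matched_keywords=matched,
        )
    candidates = [cat for cat, n in counts.items() if n == best]
    tie = len(candidates) > 1
    chosen = candidates[0] if not tie else _resolve_tie(candidates, tie_break, priority)
    return CategoryAssignment(
        post_id=post.post_id,
        assigned_category=chosen,
        counts=counts,
        matched_keywords=matched,
        tie=tie,
    )


def classify_corpus(
    corpus: Corpus,
    dictionary: KeywordDictionary,
    tie_break: str = "alpha",
    priority: Optional[Sequence[str]] = None,
) -> list[CategoryAssignment]:
    """Classify every post; stateless, so order-preserving and permutation-safe."""
    return [classify(p, dictionary, tie_break=tie_break, priority=priority) for p in corpus]


def assignments_to_frame(
    assignments: Sequence[CategoryAssignment], dictionary: KeywordDictionary
):
    """Tabulate assignments: post_id, assigned_category, tie, one count column per category."""
    import pandas as pd

    rows = []
    for a in assignments:
        row = {"post_id": a.post_id, "assigned_category": a.assigned_category, "tie": a.tie}
        for cat in dictionary.categories:
            row[f"count_{cat}"] = a.counts.get(cat, 0)
        rows.append(row)
    columns = ["post_id", "assigned_category", "tie"] + [
        f"count_{c}" for c in dictionary.categories
    ]
    return pd.DataFrame(rows, columns=columns)
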