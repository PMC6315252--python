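"""Posting-time heat map and word-frequency aggregations.

The heat map bins posts by local weekday and hour of publication and
aggregates engagement per cell, which is how page administrators find the
posting slots that historically engage best. The word-frequency table is the
data behind a word cloud: occurrence counts of normalized tokens across all
post texts after stopword removal.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from ._text import normalize_word
from .classifier import tokenize
from .engagement import EngagementScore
from .posts_io import Corpus

WEEKDAYS = range(1, 8)  # ISO: 1 = Monday .. 7 = Sunday
HOURS = range(24)


@dataclass
class HeatMapCell:
    n_posts: int = 0
    total_engagement: float = 0.0

    @property
    def mean_engagement(self) -> Optional[float]:
        if self.n_posts == 0:
            return None
        return self.total_engagement / self.n_posts


@dataclass
class HeatMapGrid:
    """All 168 weekday×hour cells, addressable as ``grid[(iso_weekday, hour)]``."""

    cells: dict[tuple[int, int], HeatMapCell] = field(
        default_factory=lambda: {(d, h): HeatMapCell() for d in WEEKDAYS for h in HOURS}
    )
    aggregate: str = "mean"

    def __getitem__(self, key: tuple[int, int]) -> HeatMapCell:
        return self.cells[key]

    @property
    def n_posts(self) -> int:
        return sum(c.n_posts for c in self.cells.values())

    def to_frame(self):
        """Long-format table: weekday, hour, n_posts, mean and total engagement."""
        import pandas as pd

        rows = []
        for (day, hour), cell in sorted(self.cells.items()):
            rows.append(
                {
                    "weekday": day,
                    "hour": hour,
                    "n_posts": cell.n_posts,
                    "total_engagement": cell.total_engagement,
                    "mean_engagement": cell.mean_engagement,
                }
            )
        return pd.DataFrame(rows)


def heatmap(
    corpus: Corpus, scores: Sequence[EngagementScore], aggregate: str = "mean"
) -> HeatMapGrid:
    """Bin posts by local weekday/hour of their timestamp, aggregating engagement.

    ``aggregate`` selects which statistic represents the cell's shade when the
    grid is rendered ('mean' or 'total'); the grid always carries both.
    """
    if aggregate not in ("mean", "total"):
        raise ValueError(f"unknown aggregate {aggregate!r}; expected 'mean' or 'total'")
    by_id = {s.post_id: s for s in scores}
    missing = [p.post_id for p in corpus if p.post_id not in by_id]
    if missing:
        raise ValueError(f"scores do not cover post(s): {missing[:5]}")
    grid = HeatMapGrid(aggregate=aggregate)
    for post in corpus:
        key = (post.timestamp.isoweekday(), post.timestamp.hour)
        cell = grid.cells[key]
        cell.n_posts += 1
        cell.total_engagement += by_id[post.post_id].engagement
    return grid


@dataclass
class WordFrequencyTable:
    """Occurrence counts of normalized words across a corpus, stopwords removed."""

    entries: Counter

    def most_common(self, n: Optional[int] = None) -> list[tuple[str, int]]:
        return self.entries.most_common(n)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.most_common(), columns=["word", "count"])


def load_stopwords(path=None) -> frozenset[str]:
    """Stopword set from a one-word-per-line file; packaged Portuguese list by default."""
    if path is None:
        text = (
            resources.files("pagepulse")
            .joinpath("data/stopwords_pt.txt")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    words = set()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.add(normalize_word(line))
    return frozenset(words)


def word_frequencies(
    corpus: Corpus, stopwords: Optional[Iterable[str]] = None
) -> WordFrequencyTable:
    """Token occurrence counts over all post texts, minus stopwords.

    Uses the classifier's tokenizer, so frequencies and keyword matches agree
    on what counts as a word. Pass ``stopwords=()`` to keep everything.
    """
    stop = (
        load_stopwords()
        if stopwords is None
        else {normalize_word(w) for w in stopwords}
    )
    counts: Counter = Counter()
    for post in corpus:
        counts.update(t for t in tokenize(post.text) if t not in stop)
    return WordFrequencyTable(entries=counts)
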