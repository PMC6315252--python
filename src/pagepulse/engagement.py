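"""Weighted engagement scoring, per-category summaries, rankings, prediction.

The engagement score of a post is

    engagement = clicks + 0.05·reactions + 0.2·shares + 0.75·comments

with the clicks term dropped when only public metrics are available. The
weights encode the effort hierarchy of interactions: reacting is cheap,
sharing costs more, commenting costs the most. The engagement *rate* divides
the score by reach and is therefore only defined when reach is known and
positive.

Because the score is linear in the counts, the mean score of a set of posts
equals the score of the componentwise mean counts; per-category summary
tables exploit this and report the weighted engagement of the category means.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from statistics import fmean
from typing import Optional, Sequence

from ._text import round_half_up
from .classifier import CategoryAssignment, UNCATEGORIZED, tokenize
from .dictionary import KeywordDictionary
from .posts_io import Corpus, Post


@dataclass(frozen=True)
class EngagementWeights:
    """Interaction weights; defaults follow the effort hierarchy."""

    w_reactions: float = 0.05
    w_shares: float = 0.2
    w_comments: float = 0.75
    include_clicks: bool = True

    def __post_init__(self):
        if min(self.w_reactions, self.w_shares, self.w_comments) < 0:
            raise ValueError("engagement weights must be non-negative")

    def public_only(self) -> "EngagementWeights":
        return replace(self, include_clicks=False)


DEFAULT_WEIGHTS = EngagementWeights()


@dataclass(frozen=True)
class EngagementScore:
    post_id: str
    engagement: float
    engagement_rate: Optional[float] = None


def weighted_engagement(
    reactions: float,
    shares: float,
    comments: float,
    clicks: float = 0.0,
    weights: EngagementWeights = DEFAULT_WEIGHTS,
) -> float:
    """The core score on raw (or mean) counts; ``clicks`` ignored unless enabled."""
    score = (
        weights.w_reactions * reactions
        + weights.w_shares * shares
        + weights.w_comments * comments
    )
    if weights.include_clicks:
        score += clicks
    return score


def score_post(post: Post, weights: EngagementWeights = DEFAULT_WEIGHTS) -> EngagementScore:
    """Score one post; rate present only when reach is known and positive."""
    engagement = weighted_engagement(
        post.reactions,
        post.shares,
        post.comments,
        clicks=post.clicks or 0,
        weights=weights,
    )
    rate = engagement / post.reach if post.reach else None
    return EngagementScore(post_id=post.post_id, engagement=engagement, engagement_rate=rate)


def score_corpus(
    corpus: Corpus, weights: EngagementWeights = DEFAULT_WEIGHTS
) -> list[EngagementScore]:
    return [score_post(p, weights) for p in corpus]


@dataclass
class CategorySummary:
    """Per (group, category) aggregate, one row of a summary table.

    Means and engagement are ``None`` for empty cells (the table convention
    is N/A, not zero). ``pct_posts`` is the category's share of the group's
    posts, in percent, at full precision.
    """

    group: str
    category: str
    n_posts: int
    pct_posts: float
    mean_reactions: Optional[float]
    mean_shares: Optional[float]
    mean_comments: Optional[float]
    weighted_avg_engagement: Optional[float]

    def rounded(self, ndigits: int = 1) -> "CategorySummary":
        """Display copy with half-up rounding at ``ndigits`` decimals."""
        def r(v):
            return None if v is None else round_half_up(v, ndigits)

        return replace(
            self,
            pct_posts=r(self.pct_posts),
            mean_reactions=r(self.mean_reactions),
            mean_shares=r(self.mean_shares),
            mean_comments=r(self.mean_comments),
            weighted_avg_engagement=r(self.weighted_avg_engagement),
        )


def summarize(
    corpus: Corpus,
    assignments: Sequence[CategoryAssignment],
    weights: EngagementWeights = DEFAULT_WEIGHTS,
    categories: Optional[Sequence[str]] = None,
) -> list[CategorySummary]:
    """Per (group, category) post counts, mean interaction counts, engagement.

    ``categories`` fixes the rows reported for every group (defaults to the
    categories seen in the assignments, plus UNCATEGORIZED if it occurs);
    empty cells are reported with ``None`` means. The summary uses public
    counts only — clicks vary in availability across posts and would make
    group means incomparable — so ``weights.include_clicks`` is ignored here.
    """
    by_id = {a.post_id: a for a in assignments}
    missing = [p.post_id for p in corpus if p.post_id not in by_id]
    if missing:
        raise ValueError(f"assignments do not cover post(s): {missing[:5]}")
    unknown = set(by_id) - set(corpus.ids())
    if unknown:
        raise ValueError(f"assignment references unknown post_id(s): {sorted(unknown)[:5]}")

    if categories is None:
        seen = {a.assigned_category for a in assignments}
        categories = sorted(seen - {UNCATEGORIZED}) + (
            [UNCATEGORIZED] if UNCATEGORIZED in seen else []
        )

    groups: dict[str, list[Post]] = {}
    for post in corpus:
        groups.setdefault(post.group, []).append(post)

    summaries: list[CategorySummary] = []
    for group in sorted(groups):
        members = groups[group]
        total = len(members)
        by_cat: dict[str, list[Post]] = {c: [] for c in categories}
        for post in members:
            cat = by_id[post.post_id].assigned_category
            by_cat.setdefault(cat, []).append(post)
        for cat in categories:
            posts = by_cat[cat]
            n = len(posts)
            if n == 0:
                summaries.append(
                    CategorySummary(group, cat, 0, 0.0, None, None, None, None)
                )
                continue
            mr = fmean(p.reactions for p in posts)
            ms = fmean(p.shares for p in posts)
            mc = fmean(p.comments for p in posts)
            engagement = weighted_engagement(mr, ms, mc, weights=weights.public_only())
            summaries.append(
                CategorySummary(group, cat, n, 100.0 * n / total, mr, ms, mc, engagement)
            )
    return summaries


_RANKABLE = {
    "n_posts",
    "pct_posts",
    "mean_reactions",
    "mean_shares",
    "mean_comments",
    "weighted_avg_engagement",
}


def rank_categories(
    summaries: Sequence[CategorySummary], metric: str = "weighted_avg_engagement"
) -> list[CategorySummary]:
    """Summaries in descending order of ``metric``; N/A last, ties alphabetical."""
    if metric not in _RANKABLE:
        raise ValueError(f"unknown metric {metric!r}; expected one of {sorted(_RANKABLE)}")

    def key(s: CategorySummary):
        value = getattr(s, metric)
        return (value is None, -(value if value is not None else 0.0), s.category)

    return sorted(summaries, key=key)


def summaries_to_frame(summaries: Sequence[CategorySummary], ndigits: Optional[int] = 1):
    """Summary table as a DataFrame; ``ndigits=None`` for full precision."""
    import pandas as pd

    rows = [s.rounded(ndigits) if ndigits is not None else s for s in summaries]
    return pd.DataFrame(
        [
            {
                "group": s.group,
                "category": s.category,
                "n_posts": s.n_posts,
                "pct_posts": s.pct_posts,
                "mean_reactions": s.mean_reactions,
                "mean_shares": s.mean_shares,
                "mean_comments": s.mean_comments,
                "weighted_avg_engagement": s.weighted_avg_engagement,
            }
            for s in rows
        ]
    )


@dataclass
class EngagementPrediction:
    """Predicted engagement for a draft text, with per-keyword contributions.

    ``contributions`` maps each matched keyword with history to the mean
    engagement of past posts containing it; ``fallback`` is True when no
    matched keyword had history and the corpus mean was used instead.
    """

    prediction: float
    contributions: dict[str, float]
    fallback: bool


def predict_engagement(
    text: str,
    history: Corpus,
    dictionary: KeywordDictionary,
    weights: EngagementWeights = DEFAULT_WEIGHTS,
    scores: Optional[Sequence[EngagementScore]] = None,
    mode: str = "mean",
) -> EngagementPrediction:
    """Predict a draft post's engagement from keyword history.

    Each dictionary keyword's historical value is the mean engagement of past
    posts whose text contains it; the prediction averages the historical
    values of the keywords matched in ``text``. ``mode='mean'`` (default)
    averages over distinct matched keywords; ``mode='occurrence'`` weights
    each keyword by its number of occurrences in the draft. A draft matching
    no keyword with history falls back to the corpus mean engagement.
    """
    if len(history) == 0:
        raise ValueError("history corpus is empty")
    if mode not in ("mean", "occurrence"):
        raise ValueError(f"unknown mode {mode!r}; expected 'mean' or 'occurrence'")
    if scores is None:
        scores = score_corpus(history, weights)
    engagement_by_id = {s.post_id: s.engagement for s in scores}
    missing = [p.post_id for p in history if p.post_id not in engagement_by_id]
    if missing:
        raise ValueError(f"scores do not cover post(s): {missing[:5]}")

    vocabulary = dictionary.all_words()
    history_tokens = [(p.post_id, set(tokenize(p.text)) & vocabulary) for p in history]

    draft_tokens = tokenize(text)
    matched = [t for t in draft_tokens if t in vocabulary]
    contributions: dict[str, float] = {}
    occurrences: dict[str, int] = {}
    for token in matched:
        occurrences[token] = occurrences.get(token, 0) + 1
        if token in contributions:
            continue
        past = [engagement_by_id[pid] for pid, toks in history_tokens if token in toks]
        if past:
            contributions[token] = fmean(past)

    if not contributions:
        corpus_mean = fmean(engagement_by_id.values())
        return EngagementPrediction(prediction=corpus_mean, contributions={}, fallback=True)

    if mode == "mean":
        prediction = fmean(contributions.values())
    else:
        total = sum(occurrences[k] for k in contributions)
        prediction = sum(contributions[k] * occurrences[k] for k in contributions) / total
    return EngagementPrediction(prediction=prediction, contributions=contributions, fallback=False)
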