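"""Evaluation of automatic assignments against manual content-analysis labels.

Human coders' category labels are the ground truth; the report counts a post
as an error whenever the assigned category differs from the manual one,
giving an overall error rate / accuracy, a manual×assigned confusion matrix,
and a per-assigned-category error breakdown of the kind published alongside
rule-based classifiers. Rates are kept at full precision; display rounding
is half-up to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from ._text import round_half_up
from .classifier import CategoryAssignment


@dataclass
class EvaluationReport:
    """Agreement between automatic and manual labels.

    ``confusion`` has one row per manual category and one column per assigned
    category (including UNCATEGORIZED when it occurs); row sums are the
    manual label counts, column sums the assigned counts.
    """

    n_posts: int
    n_errors: int
    confusion: pd.DataFrame

    @property
    def error_rate(self) -> float:
        """Percent of posts assigned a category other than the manual one."""
        return 100.0 * self.n_errors / self.n_posts

    @property
    def accuracy(self) -> float:
        return 100.0 - self.error_rate


def evaluate(
    assignments: Sequence[CategoryAssignment], manual: Mapping[str, str]
) -> EvaluationReport:
    """Compare assignments with manual labels, one label per assigned post."""
    if not assignments:
        raise ValueError("no assignments to evaluate")
    missing = [a.post_id for a in assignments if a.post_id not in manual]
    if missing:
        raise ValueError(f"missing manual label for post(s): {missing[:5]}")
    pairs = [(manual[a.post_id], a.assigned_category) for a in assignments]
    manual_labels = [m for m, _ in pairs]
    assigned_labels = [a for _, a in pairs]
    labels = sorted(set(manual_labels) | set(assigned_labels))
    confusion = pd.crosstab(
        pd.Series(manual_labels, name="manual"),
        pd.Series(assigned_labels, name="assigned"),
    ).reindex(index=labels, columns=labels, fill_value=0)
    n_posts = len(pairs)
    n_errors = sum(1 for m, a in pairs if m != a)
    return EvaluationReport(n_posts=n_posts, n_errors=n_errors, confusion=confusion)


def error_breakdown(report: EvaluationReport) -> pd.DataFrame:
    """Per assigned category: volume and error share.

    Columns: category, n_assigned, pct_of_assigned (share of all posts,
    half-up 1 d.p.), n_errors (posts assigned there whose manual label
    differs), pct_of_total_errors (half-up 1 d.p.; absent when the report
    has no errors at all).
    """
    rows = []
    for category in report.confusion.columns:
        col = report.confusion[category]
        n_assigned = int(col.sum())
        diagonal = int(col.get(category, 0))
        n_errors = n_assigned - diagonal
        pct_errors: Optional[float]
        if report.n_errors == 0:
            pct_errors = None
        else:
            pct_errors = round_half_up(100.0 * n_errors / report.n_errors, 1)
        rows.append(
            {
                "category": category,
                "n_assigned": n_assigned,
                "pct_of_assigned": round_half_up(100.0 * n_assigned / report.n_posts, 1),
                "n_errors": n_errors,
                "pct_of_total_errors": pct_errors,
            }
        )
    return pd.DataFrame(
        rows, columns=["category", "n_assigned", "pct_of_assigned", "n_errors", "pct_of_total_errors"]
    )


def report_to_dict(report: EvaluationReport, ndigits: int = 1) -> dict:
    """JSON-ready summary of a report (rates displayed half-up)."""
    return {
        "n_posts": report.n_posts,
        "n_errors": report.n_errors,
        "error_rate": round_half_up(report.error_rate, ndigits),
        "accuracy": round_half_up(report.accuracy, ndigits),
        "confusion": {
            str(m): {str(a): int(v) for a, v in row.items()}
            for m, row in report.confusion.iterrows()
        },
        "per_assigned_category": error_breakdown(report).to_dict(orient="records"),
    }
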