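# Methods

## Post model and I/O

A post carries a page id, a page-profile group (hospitals/foundations,
informative, NGO, personal — free labels are allowed), a timezone-aware
timestamp, one of Facebook's five post types (photo, video, event, status,
link), its text, and interaction counts. Reactions, shares and comments are
always required; clicks, reach and hides exist only in administrator
exports and are modelled as *absent*, not zero, when missing — the
distinction matters because the engagement rate `E/reach` is undefined
without reach, and treating absent reach as 0 would silently drop or
corrupt rate statistics. CSV serialization therefore writes absent counts
as empty cells, and the readers reject negative counts, unknown post types
and duplicate post ids with messages naming the offending record.

Naive timestamps are localized to a configurable default zone
(`America/Sao_Paulo`, since the motivating corpora are Brazilian pages);
heat maps bin by local wall-clock time.

## Keyword dictionary

The dictionary maps categories to sets of complete word forms under two
invariants enforced at load time and after every edit: word sets are
pairwise disjoint across categories, and each keyword is a single word.
Normalization is deliberately minimal — Unicode NFC composition plus
casefolding, diacritics preserved — because the matching model is exact
complete-word comparison: stripping accents would merge distinct Portuguese
words (e.g. "câncer"/"cancer"). There is no stemming or morphological
generation; `expand_inflections` only normalizes and deduplicates a
caller-enumerated list of forms. Words too generic to discriminate between
categories (the disease name itself, common treatment terms) are an
*editorial* exclusion: the loader warns when a user-supplied generic-word
list flags an entry but never removes it.

`KeywordDictionary` is immutable; edits return new instances, which makes
the disjointness invariant easy to property-test over random edit
sequences.

## Classifier

Tokenization takes maximal runs of Unicode letters after removing URLs;
digits, punctuation and underscores separate tokens, so internal hyphens
split ("pré-natal" → "pré", "natal"). Tokens are normalized identically to
dictionary words.

A post's score for category *c* is the number of token *occurrences* that
belong to *c*'s keyword set — occurrences, not distinct types, because
repeated mentions are evidence of topical focus (and a repeated generic
word can legitimately dominate, which is exactly the documented failure
mode of dictionary classifiers). The post is assigned to the argmax; an
all-zero profile yields `UNCATEGORIZED` rather than a forced label, so
summary tables are not polluted by unclassifiable posts. Ties are broken
deterministically — alphabetical category order by default, or a
caller-supplied priority list — and flagged in the output, since a tie is
ambiguity the analyst should see. Classification is stateless per post.

Known limitations, inherent to the method: no context, negation, irony or
typo handling; a post whose text is carried by an attached image or video
classifies only on whatever caption text exists.

## Engagement

`E = clicks + 0.05·reactions + 0.2·shares + 0.75·comments`, with the
clicks term dropped when clicks are absent or public-only weights are
requested. The weights encode the user-effort hierarchy (reacting is
cheap; commenting requires composing text publicly). The engagement rate
is `E/reach`, reported as absent — never 0 or ∞ — when reach is absent or
zero.

Per-(group, category) summaries report post counts, the category's percent
share of its group, arithmetic means of the public counts, and the weighted
engagement *of the means*; by linearity this equals the mean of the
per-post scores (tested to 1e-9 relative). Summaries always use public
counts only: clicks availability varies post-by-post within real exports,
and mixing cells with and without a clicks term would make group means
incomparable. Empty cells are reported with absent means (N/A), not zeros.
All computation is at full float precision; report display rounds half-up
to one decimal, the convention of the published tables.

Rankings sort summaries by any numeric summary field, descending, absent
values last, ties alphabetical.

### Engagement prediction

The historical value of a keyword is the mean engagement of past posts
whose text contains it. A draft's prediction is the unweighted mean of its
matched keywords' historical values (per-keyword contributions are returned
for explainability); `mode="occurrence"` instead weights each keyword by
its occurrence count in the draft. A draft matching no keyword with history
falls back to the corpus mean. The unweighted mean was chosen as the
simplest rule consistent with the idea that keywords associated with
high-engagement history predict high engagement; it is translation-
consistent (shifting all historical engagements by *c* shifts every
prediction by *c*), which the suite verifies.

## Analytics

The heat map is the full 168-cell ISO-weekday × hour grid; each post falls
in the cell of its local publication time, and cells carry n, total and
mean engagement (mean is the default shade since it answers "when does a
post do best", with totals available where volume itself matters; the mean
is absent for empty cells). Cell counts always sum to the corpus size.

Word frequencies use the classifier's tokenizer — so the word cloud and
the keyword matcher agree on what a word is — minus a stopword set; a
~100-entry Portuguese function-word list ships as the default and is
user-overridable. Frequencies are additive over corpus concatenation and
order-invariant.

## Evaluation

Manual coder labels are ground truth; an error is any post whose assigned
category differs from its manual label, with `UNCATEGORIZED` counted as a
(necessarily wrong) category of its own. The report exposes full-precision
error rate and accuracy, the manual×assigned confusion matrix, and a
per-assigned-category breakdown (volume share, error count, share of total
errors). Display rounding is half-up at one decimal; published tables of
this kind sometimes truncate instead (e.g. printing 14/34 as 41.1 where
half-up gives 41.2), and the suite compares such quantities at the printed
precision (±0.1) rather than mimicking truncation.

## Reference summary table

The published per-group per-category table (4 groups × 8 categories: post
counts, mean reactions/shares/comments, weighted engagement) is encoded as
a fixture so the engagement arithmetic can be regression-tested without any
corpus. Recomputing each row's engagement from its printed means reproduces
the printed value within 0.1 for 25 of the 27 non-empty rows — the slack is
exactly what rounding the printed means to one decimal propagates
(0.05·(0.05+0.2+0.75) = 0.05, plus 0.05 from rounding the printed score).
Two cells, personal/solidarity (printed 135.5, recomputed 137.5) and
personal/beauty (printed 16.6, recomputed 13.6), are inconsistent with
their own printed means by amounts no rounding can explain and are carried
as documented misprints (`TABLE1_INCONSISTENT_CELLS`); the suite asserts
the discrepancy rather than silently patching either number.

## Synthetic corpora

The generator emulates the structure of the study corpora, not real
Portuguese. Each post draws a true category uniformly; its first token is
always a keyword draw and subsequent tokens are keyword draws with
probability `keyword_density` (default 0.3) — of which a `cross_noise`
fraction comes from *other* categories' pools — and deterministic
pseudo-word filler otherwise. Filler words are built with a fixed marker
prefix and checked against the dictionary, so at `cross_noise = 0` perfect
label recovery is a provable property of the classifier, not a
probabilistic one. Posts default to 8–30 words, roughly short social-media
post length.

Interaction counts are negative-binomial with per-category mean vectors
and variance `dispersion × mean` (default 2, since real social-media counts
are heavy-tailed); the default means are taken from the informative-pages
block of the reference table, the only group with every category populated.
Timestamps are uniform over a one-month window in the page's local zone
(matching the study's collection windows); the generated label is also
stored as each post's `manual_category`, standing in for a perfectly
agreeing human coder. Everything is determined by a single integer seed.

What passing synthetic tests does *not* show: robustness to real Portuguese
morphology, typos, context-dependent meaning, class imbalance between
categories, or correlation between text length and engagement — none of
which the generator models.

## Problem sizes and numerical choices

The suite's simulations use 100–1,000 posts (10,000 for the
count-distribution convergence check, within 5% relative), 5 seeds per
point for the noise-degradation curve, and a Bonferroni-adjusted binomial
band for heat-map uniformity; these sizes make every probabilistic check
stable at fixed seeds while the whole suite runs in seconds. Tie-breaks,
absent-value ordering and rounding are specified exactly (alphabetical;
absent last; half-up) so identical inputs always produce byte-identical
outputs.

## Command-line interface

`pagepulse` wires the stages as subcommands (synth, classify, summarize,
rank, predict, heatmap, wordcloud, evaluate) over plain CSV/JSON/YAML
files: diagnostics to stderr, data to files, so stages compose in shell
pipelines and rerunning an invocation reproduces its outputs byte for byte.
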