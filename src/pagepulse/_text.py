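"""Shared text normalization and display-rounding helpers.

Keyword matching works on *complete words*: a dictionary entry matches a
token only if the two are identical after normalization. Normalization is
deliberately minimal — Unicode NFC composition plus casefolding — so that
diacritics are preserved ("câncer" and "cancer" remain distinct strings).
"""

from __future__ import annotations

import unicodedata
from decimal import ROUND_HALF_UP, Decimal


def normalize_word(word: str) -> str:
    """Return the canonical form of a single word: NFC-composed, casefolded.

    Diacritics are kept; no stemming or accent stripping is performed.
    """
    return unicodedata.normalize("NFC", word).casefold()


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round for report display: half-up at `ndigits` decimals.

    Python's built-in ``round`` uses banker's rounding; published summary
    tables in this domain conventionally round halves up, so reports do too.
    Computation elsewhere stays at full float precision.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
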