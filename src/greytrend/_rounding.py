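"""Half-away-from-zero rounding used for all displayed values.

Python's built-in ``round`` is banker's rounding; published tables in this
domain round halves away from zero (102.45 -> 102.5), so every rounded
number the package reports goes through :func:`round_half_away`.
"""

from __future__ import annotations

import decimal


def round_half_away(x: float, digits: int = 1) -> float:
    """Round ``x`` to ``digits`` decimals, ties away from zero."""
    q = decimal.Decimal(1).scaleb(-digits)
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))
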