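"""Half-up decimal rounding used for report-facing numbers.

Python's built-in ``round`` is banker's rounding; published survey tables
use conventional half-up rounding, so every value that gets compared to a
printed table goes through :func:`round_half_up`.
"""

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(x: float, ndigits: int) -> float:
    """Round ``x`` half-up to ``ndigits`` decimal places."""
    q = Decimal("1").scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
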