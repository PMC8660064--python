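"""Small numeric helpers used across modules."""

from __future__ import annotations

import decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (reported indices use half-up, not banker's)."""
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def mean(values) -> float:
    values = list(values)
    return sum(values) / len(values)
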