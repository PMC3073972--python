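"""Shared reporting helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round to `ndigits` decimals with ties going away from zero.

    Printed tables in classical bioassay/assembly reports use commercial
    (half-up) rounding, not banker's rounding, so ``round()`` is not used.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
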