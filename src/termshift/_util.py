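"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


class ConfigurationError(ValueError):
    """Invalid configuration value or unregistered component."""


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero at ``ndigits`` decimals (report convention).

    Uses the decimal string representation so 0.3315 -> 0.332 regardless of
    binary floating-point artifacts.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
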