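"""Half-up decimal rounding used at every serialization/display boundary.

Internal computation is always carried out unrounded; these helpers are applied
only when a number is presented (reports, CSV cells, published-table
comparisons), matching the convention of the source tables (93.33, 0.83, 96%).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` half away from zero at ``ndigits`` decimal places.

    Python's builtin ``round`` is banker's rounding (0.5 ties go to even);
    clinical-report tables round ties upward, so 84.75 -> 84.8 -> 85, not 84.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_percent(x: float) -> int:
    """Round a percentage half-up to an integer."""
    return int(round_half_up(x, 0))
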