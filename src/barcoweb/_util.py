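"""Small shared helpers."""

from __future__ import annotations

import math


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (table-style rounding).

    Python's built-in ``round`` uses banker's rounding; published ecology
    tables conventionally round 0.05 up, which matters when checking
    printed percentages.
    """
    if math.isnan(x):
        return x
    factor = 10.0 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def percentage(count: float, total: float, ndigits: int = 1) -> float:
    """``count / total`` as a percentage rounded half-up; NaN when total is 0."""
    if total == 0:
        return float("nan")
    return round_half_up(100.0 * count / total, ndigits)
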