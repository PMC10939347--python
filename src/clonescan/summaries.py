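"""Small shared summary arithmetic (fractions reported to two decimals)."""

from __future__ import annotations


def percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """Percentage on the 0-100 scale, rounded to ``decimals`` places.

    Returns 0.0 for an empty denominator so that empty analysis sets
    summarise cleanly.
    """
    if denominator == 0:
        return 0.0
    return round(100.0 * numerator / denominator, decimals)
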