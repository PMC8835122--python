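"""Display formatting for report tables.

All rounding conventions live here so machine-readable outputs stay at full
precision while printed tables are internally consistent:

* percentages are rounded half-up to one decimal;
* lift is printed with one decimal at or above 10, two decimals below;
* displayed lift is derived from the *displayed* (two-decimal) confidence
  divided by the consequent's support, so a printed confidence of 0.67 over
  a consequent support of 0.5 prints as lift 1.34 — the printed metrics
  stay mutually consistent even where full-precision lift (1.33…) would
  round differently.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = ["round_half_up", "fmt_pct", "fmt_lift", "display_lift", "format_rule_table"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (python's round() is banker's rounding)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))


def fmt_pct(fraction: float, ndigits: int = 1) -> str:
    """A proportion as a percentage string, half-up to *ndigits* decimals."""
    return f"{round_half_up(fraction * 100.0, ndigits):.{ndigits}f}%"


def fmt_lift(value: float) -> str:
    """One decimal for large lifts (>= 10), two below."""
    if value >= 10:
        return f"{round_half_up(value, 1):.1f}"
    return f"{round_half_up(value, 2):.2f}"


def display_lift(confidence: float, consequent_support: float) -> float:
    """Lift recomputed from the two-decimal displayed confidence.

    Keeps printed lift consistent with printed confidence: a confidence of
    2/3 prints as 0.67, and the displayed lift over a consequent support of
    0.5 is 0.67 / 0.5 = 1.34 (the full-precision 4/3 would print 1.33).
    """
    if consequent_support <= 0:
        raise ValueError("consequent support must be positive")
    return round_half_up(round_half_up(confidence, 2) / consequent_support, 2)


def format_rule_table(rules: pd.DataFrame) -> pd.DataFrame:
    """Human-readable companion of a machine-precision rule table."""
    out = rules.copy()
    out["support"] = out["support"].map(fmt_pct)
    out["confidence"] = out["confidence"].map(fmt_pct)
    out["confidence_complement"] = out["confidence_complement"].map(fmt_pct)
    out["lift"] = out["lift"].map(fmt_lift)
    return out
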