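"""Small numeric helpers shared across modules."""

from __future__ import annotations

from fractions import Fraction

__all__ = ["exact_fraction", "round_half_away", "percent"]


def exact_fraction(x) -> Fraction:
    """Exact rational from int/Fraction/str; floats via their decimal form.

    Interpreting floats through ``str`` means 0.95 becomes 19/20 (what
    the user wrote), not the nearest binary fraction — thresholds like
    "95% consistency" then compare exactly.
    """
    if isinstance(x, float):
        return Fraction(str(x))
    return Fraction(x)


def round_half_away(x, ndigits: int = 0) -> float:
    """Round half away from zero, exactly.

    Exact :class:`~fractions.Fraction` arithmetic throughout; float
    inputs are interpreted via their decimal string form so 22.515
    rounds like the printed number it denotes. This is the rounding
    convention of the program's printed tables (e.g. a 24.5% median
    prints as 25%).
    """
    q = Fraction(str(x)) if isinstance(x, float) else Fraction(x)
    scale = Fraction(10) ** ndigits
    q *= scale
    sign = 1 if q >= 0 else -1
    magnitude = abs(q)
    whole = magnitude.numerator // magnitude.denominator
    if magnitude - whole >= Fraction(1, 2):
        whole += 1
    return float(sign * whole / scale)


def percent(rate) -> int:
    """A proportion as a whole percent, half away from zero (0.195 -> 20)."""
    return int(round_half_away(Fraction(rate) * 100, 0))
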