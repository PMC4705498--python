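"""The 1-9 pairwise-comparison intensity scale and log-space rounding."""

from __future__ import annotations

import math
from fractions import Fraction

__all__ = ["SAATY_FRACTIONS", "SAATY_VALUES", "round_to_saaty"]

#: Admissible matrix entries: 1/9 .. 1/2, 1, 2 .. 9, as exact rationals.
SAATY_FRACTIONS: tuple[Fraction, ...] = tuple(
    [Fraction(1, k) for k in range(9, 1, -1)] + [Fraction(k) for k in range(1, 10)]
)

#: The same values as floats, ascending.
SAATY_VALUES: tuple[float, ...] = tuple(float(f) for f in SAATY_FRACTIONS)


def round_to_saaty(x: float) -> Fraction:
    """Round a positive ratio to the nearest scale value in log-space.

    The scale is multiplicative, so "nearest" is measured on log(x); ties
    are broken toward 1 (the weaker judgment).

    >>> round_to_saaty(1.06)
    Fraction(1, 1)
    >>> round_to_saaty(8.7)
    Fraction(9, 1)
    """
    if not x > 0:
        raise ValueError(f"ratio must be positive, got {x}")
    lx = math.log(x)
    # key: (log distance, distance of candidate from 1 in log-space) — the
    # second component breaks exact ties toward 1.
    return min(
        SAATY_FRACTIONS,
        key=lambda f: (abs(lx - math.log(f)), abs(math.log(f))),
    )
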