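"""Independent direct-formula oracles for the disproportionality statistics.

Everything here is computed with exact rational arithmetic (``fractions``)
and converted to float only at the end, so agreement with the package's
floating-point implementations genuinely checks the algebra.  These
functions are deliberately kept independent of :mod:`faerspv.stats`.
"""

from __future__ import annotations

import math
from fractions import Fraction

Z975 = 1.959963984540054  # Phi^{-1}(0.975)


def ror_oracle(a: int, b: int, c: int, d: int,
               haldane: bool = False) -> tuple[float, float, float] | None:
    """(point, ci_low, ci_high) or None when undefined without correction."""
    if haldane and min(a, b, c, d) == 0:
        a2, b2, c2, d2 = (Fraction(2 * a + 1, 2), Fraction(2 * b + 1, 2),
                          Fraction(2 * c + 1, 2), Fraction(2 * d + 1, 2))
    elif min(a, b, c, d) == 0:
        return None
    else:
        a2, b2, c2, d2 = Fraction(a), Fraction(b), Fraction(c), Fraction(d)
    est = (a2 * d2) / (b2 * c2)
    var = Fraction(1) / a2 + Fraction(1) / b2 + Fraction(1) / c2 + Fraction(1) / d2
    half = Z975 * math.sqrt(var)
    return (float(est), float(est) * math.exp(-half), float(est) * math.exp(half))


def prr_oracle(a: int, b: int, c: int, d: int) -> float | None:
    if a + b == 0 or c == 0:
        return None
    return float(Fraction(a, a + b) / Fraction(c, c + d))


def chi2_oracle(a: int, b: int, c: int, d: int, yates: bool = True) -> float | None:
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return None
    dev = Fraction(abs(a * d - b * c))
    if yates:
        dev = max(dev - Fraction(n, 2), Fraction(0))
    return float(Fraction(n) * dev * dev / denom)


def ic_oracle(a: int, b: int, c: int, d: int,
              gamma11: float = 1.0, alpha1: float = 1.0, beta1: float = 1.0,
              alpha: float = 2.0, beta: float = 2.0) -> tuple[float, float]:
    """(E(IC), V(IC)) from the closed-form posterior moments."""
    g11, a1, b1 = Fraction(gamma11), Fraction(alpha1), Fraction(beta1)
    al, be = Fraction(alpha), Fraction(beta)
    n = Fraction(a + b + c + d)
    af, m1, m2 = Fraction(a), Fraction(a + b), Fraction(a + c)
    gamma = g11 * (n + al) * (n + be) / ((m1 + a1) * (m2 + b1))
    ratio = ((af + g11) * (n + al) * (n + be)) / ((n + gamma) * (m1 + a1) * (m2 + b1))
    e_ic = math.log2(float(ratio))
    var = (
        (n - af + gamma - g11) / ((af + g11) * (1 + n + gamma))
        + (n - m1 + al - a1) / ((m1 + a1) * (1 + n + al))
        + (n - m2 + be - b1) / ((m2 + b1) * (1 + n + be))
    )
    return e_ic, float(var) / math.log(2.0) ** 2


def random_tables(rng, n_tables: int, max_cell: int = 100_000):
    """Mixed-magnitude random 2x2 tables, zeros included."""
    tables = []
    for _ in range(n_tables):
        cells = []
        for _ in range(4):
            if rng.random() < 0.1:
                cells.append(0)
            else:
                exp = rng.uniform(0, math.log10(max_cell))
                cells.append(int(10 ** exp))
        tables.append(tuple(cells))
    return tables
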