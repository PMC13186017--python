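"""Independent exact oracle for the two-sided Fisher's exact test.

Enumerates the full hypergeometric distribution over tables with the
observed margins using exact rational arithmetic, and sums the
probabilities of all tables no more probable than the observed one.
Kept free of any phoscoreg import so it can never share a code path with
the implementation it checks.
"""

from fractions import Fraction
from math import comb


def fet_two_sided(a: int, b: int, c: int, d: int) -> Fraction:
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        raise ValueError("all-zero table")
    denom = comb(n, c1)

    def pmf(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    observed = pmf(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum((p for x in range(lo, hi + 1) if (p := pmf(x)) <= observed), Fraction(0))


def all_tables(max_margin: int):
    """Yield every non-empty 2x2 table whose four margins are all <= max_margin."""
    m = max_margin
    for a in range(m + 1):
        for b in range(m - a + 1):  # row 1 margin <= m
            for c in range(m - a + 1):  # column 1 margin <= m
                for d in range(min(m - c, m - b) + 1):  # row 2 / column 2 margins
                    if a + b + c + d == 0:
                        continue
                    yield a, b, c, d
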