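"""Exact rational oracle for the windowed hypergeometric probabilities.

Independent of the package: tail probabilities are exact Fractions built by
enumerating the hypergeometric pmf with integer binomial coefficients.
"""
from fractions import Fraction
from math import comb


def tail_exact(x: int, N: int, k: int, K: int) -> Fraction:
    """P(X >= x), X ~ Hypergeometric(population K, successes k, draws N)."""
    total = comb(K, N)
    s = sum(comb(k, i) * comb(K - k, N - i) for i in range(max(x, 0), min(N, k) + 1))
    return Fraction(s, total)


def conditional_exact(x: int, N: int, k: int, K: int) -> Fraction:
    """P(X >= x | X >= 1) as an exact rational."""
    ge1 = comb(K, N) - comb(K - k, N)
    if ge1 == 0:
        return Fraction(1)
    s = sum(comb(k, i) * comb(K - k, N - i) for i in range(max(x, 1), min(N, k) + 1))
    return Fraction(s, ge1)
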