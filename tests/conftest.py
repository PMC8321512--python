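from fractions import Fraction
from math import comb

import numpy as np
import pytest

from mutexm import BinaryMutationMatrix


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Brute-force two-sided Fisher p as an exact rational.

    Enumerates the full hypergeometric support of the (1,1) cell conditional
    on the margins and sums the probabilities of all tables no more likely
    than the observed one. Independent of the log-space implementation.
    """
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return Fraction(1)
    denom = comb(n, c1)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {k: Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom)
             for k in range(lo, hi + 1)}
    obs = probs[a]
    return sum(p for p in probs.values() if p <= obs)


def hypergeom_tail_exact(k: int, n_universe: int, n_a: int, n_b: int) -> Fraction:
    """Brute-force upper-tail hypergeometric P[X >= k] as an exact rational."""
    denom = comb(n_universe, n_b)
    lo = max(k, max(0, n_a + n_b - n_universe))
    hi = min(n_a, n_b)
    return sum(
        Fraction(comb(n_a, j) * comb(n_universe - n_a, n_b - j), denom)
        for j in range(lo, hi + 1)
    )


def matrix_from_columns(columns: dict[str, list[int]]) -> BinaryMutationMatrix:
    """Build a matrix from {gene: indicator list}; samples auto-named."""
    genes = list(columns)
    n = len(next(iter(columns.values())))
    values = np.column_stack([columns[g] for g in genes])
    return BinaryMutationMatrix(
        samples=[f"S{i}" for i in range(n)], genes=genes, values=values
    )


@pytest.fixture
def four_sample_matrix() -> BinaryMutationMatrix:
    """Rows (A,B): (1,1), (1,0), (0,1), (0,0)."""
    return matrix_from_columns({"A": [1, 1, 0, 0], "B": [1, 0, 1, 0]})
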