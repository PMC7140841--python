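"""Independent brute-force oracles used only by tests."""

from fractions import Fraction
from math import comb


def fisher_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact two-sided Fisher p by integer enumeration of all tables with the
    observed margins (minimum-likelihood convention; ties exact)."""
    r1, r2, k = a + b, c + d, a + c
    lo, hi = max(0, k - r2), min(r1, k)
    weights = [comb(r1, x) * comb(r2, k - x) for x in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    return Fraction(sum(w for w in weights if w <= w_obs), comb(r1 + r2, k))


def fisher_oracle_margin(r1: int, r2: int, k: int) -> list[Fraction]:
    """Oracle p-values for every observed ``a`` in the support of the margins."""
    lo, hi = max(0, k - r2), min(r1, k)
    weights = [comb(r1, x) * comb(r2, k - x) for x in range(lo, hi + 1)]
    total = comb(r1 + r2, k)
    sorted_w = sorted(weights)
    # prefix sums over the sorted weights give each table's tail mass
    import bisect

    prefix = [0]
    for w in sorted_w:
        prefix.append(prefix[-1] + w)
    return [
        Fraction(prefix[bisect.bisect_right(sorted_w, w)], total) for w in weights
    ]
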