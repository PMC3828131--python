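"""Independent brute-force oracles used by the test suite.

Deliberately naive: plain dictionaries, ``math.log2`` and explicit loops,
sharing no code with the package implementation.
"""

import math
from collections import Counter
from itertools import combinations


def entropy_oracle(column: str) -> float:
    counts = Counter(column)
    n = len(column)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def joint_entropy_oracle(col_a: str, col_b: str) -> float:
    counts = Counter(zip(col_a, col_b))
    n = len(col_a)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def mi_oracle(col_a: str, col_b: str) -> float:
    return (
        entropy_oracle(col_a)
        + entropy_oracle(col_b)
        - joint_entropy_oracle(col_a, col_b)
    )


def hypergeom_tail_oracle(c: int, universe: int, n_a: int, n_b: int) -> float:
    """P(X >= c) by direct summation of binomial-coefficient ratios."""
    denom = math.comb(universe, n_b)
    total = 0
    for k in range(c, min(n_a, n_b) + 1):
        if n_b - k > universe - n_a:
            continue
        total += math.comb(n_a, k) * math.comb(universe - n_a, n_b - k)
    return total / denom


def phi_oracle(pairs: list[tuple[bool, bool]]) -> float:
    """Phi coefficient from a list of (u, v) boolean observations."""
    n11 = sum(1 for u, v in pairs if u and v)
    n10 = sum(1 for u, v in pairs if u and not v)
    n01 = sum(1 for u, v in pairs if not u and v)
    n00 = sum(1 for u, v in pairs if not u and not v)
    denom = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    if denom == 0:
        return 0.0
    return (n11 * n00 - n10 * n01) / math.sqrt(denom)


def pearson_oracle(xs: list[float], ys: list[float]) -> float:
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    vx = sum((x - mx) ** 2 for x in xs)
    vy = sum((y - my) ** 2 for y in ys)
    return cov / math.sqrt(vx * vy)


def min_distance_oracle(coords_a, coords_b) -> float:
    best = float("inf")
    for xa, ya, za in coords_a:
        for xb, yb, zb in coords_b:
            d = math.sqrt((xa - xb) ** 2 + (ya - yb) ** 2 + (za - zb) ** 2)
            best = min(best, d)
    return best
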