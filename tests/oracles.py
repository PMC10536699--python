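"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected values through different code paths
than the package implementation (candidate-by-candidate enumeration,
direct formula evaluation), so agreement is informative.
"""

from __future__ import annotations

from itertools import combinations


def eq2_scalar(y: float, z: list[float]) -> int:
    """Literal scalar rescaling rule for strictly ordered anchors."""
    J = len(z)
    if y < z[0]:
        return 1
    for j in range(J):
        if y == z[j]:
            return 2 * (j + 1)
        if j + 1 < J and z[j] < y < z[j + 1]:
            return 2 * (j + 1) + 1
    assert y > z[-1]
    return 2 * J + 1


def _consistent_subsets(z: list[float]):
    """All inclusion-maximal slot subsets with weakly increasing anchors."""
    J = len(z)
    cons = []
    for r in range(1, J + 1):
        for T in combinations(range(J), r):
            vals = [z[i] for i in T]
            if all(b >= a for a, b in zip(vals, vals[1:])):
                cons.append(set(T))
    return [T for T in cons if not any(T < U for U in cons)]


def _attainable(y: float, z: list[float], T: set[int], c: int) -> bool:
    """Can rescaled category c hold when only the anchors in T are read as
    trustworthy?  Checks the relation c implies for each retained slot."""
    J = len(z)
    if c % 2 == 0:  # y == anchor at slot c/2
        k = c // 2
        if (k - 1) in T and z[k - 1] != y:
            return False
        if not any(z[i] == y for i in T):
            return False
        # slot k must be compatible: below-slots <= y, above-slots >= y
        for i in T:
            if i + 1 < k and z[i] > y:
                return False
            if i + 1 > k and z[i] < y:
                return False
        return True
    k = (c - 1) // 2  # y strictly between slot k and slot k+1
    for i in T:
        if i + 1 <= k and not z[i] < y:
            return False
        if i + 1 >= k + 1 and not z[i] > y:
            return False
    return True


def interval_by_enumeration(y: float, z: list[float]) -> tuple[int, int]:
    """[Cs, Ce] by exhaustive enumeration over candidate C values 1..2J+1
    and maximal consistent anchor subsets."""
    J = len(z)
    attained = [
        c
        for c in range(1, 2 * J + 2)
        if any(_attainable(y, z, T, c) for T in _consistent_subsets(z))
    ]
    return min(attained), max(attained)
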