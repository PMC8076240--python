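"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by exhaustive enumeration (or a closed
form from a different mathematical route) so that it shares no code path
with the implementation it checks.
"""

from __future__ import annotations

import itertools
import math

from scipy.special import betainc


def lcs_bruteforce(a: str, b: str) -> int:
    """Longest common subsequence by enumerating all subsequences of a.

    Exponential in len(a); fine for len <= 10.
    """
    subs_b = subsequence_set(b)
    best = 0
    for s in subsequence_set(a):
        if s in subs_b and len(s) > best:
            best = len(s)
    return best


def subsequence_set(s: str) -> set[str]:
    out: set[str] = set()
    for r in range(len(s) + 1):
        for idx in itertools.combinations(range(len(s)), r):
            out.add("".join(s[i] for i in idx))
    return out


def local_bruteforce_linear(
    a: str, b: str, match: float = 1.0, mismatch: float = -0.5, gap: float = -1.0
) -> float:
    """Best local alignment score under a LINEAR gap model (-|gap| per gap
    position) by enumerating every monotone matching of positions.

    A local alignment with linear gaps is fully determined by the ordered
    set of aligned position pairs: aligned pairs score match/mismatch, and
    every unaligned position between the first and last aligned pair (in
    either sequence) is a gap position. Dangling ends are trimmed, which
    can only help since gaps score negatively. Valid only when the affine
    open and extend penalties are equal.
    """
    best = 0.0
    la, lb = len(a), len(b)
    for k in range(1, min(la, lb) + 1):
        for ia in itertools.combinations(range(la), k):
            for ib in itertools.combinations(range(lb), k):
                score = 0.0
                for i, j in zip(ia, ib):
                    score += match if a[i] == b[j] else mismatch
                span_a = ia[-1] - ia[0] + 1
                span_b = ib[-1] - ib[0] + 1
                score += gap * (span_a - k) + gap * (span_b - k)
                if score > best:
                    best = score
    return best


def local_bruteforce_affine(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -0.5,
    gap_open: float = -1.0,
    gap_extend: float = -1.0,
) -> float:
    """Best local affine-gap alignment by recursive enumeration of every
    alignment of every substring pair. Exponential; keep len <= 5."""

    def extend(i: int, j: int, i_end: int, j_end: int, state: int) -> float:
        # best score of continuing an alignment that must consume
        # a[i:i_end] and b[j:j_end]; state 0 = diagonal, 1 = gap in b
        # (consuming a), 2 = gap in a (consuming b)
        if i == i_end and j == j_end:
            return 0.0
        best = -math.inf
        if i < i_end and j < j_end:
            sub = match if a[i] == b[j] else mismatch
            best = max(best, sub + extend(i + 1, j + 1, i_end, j_end, 0))
        if i < i_end:
            cost = gap_extend if state == 1 else gap_open
            best = max(best, cost + extend(i + 1, j, i_end, j_end, 1))
        if j < j_end:
            cost = gap_extend if state == 2 else gap_open
            best = max(best, cost + extend(i, j + 1, i_end, j_end, 2))
        return best

    best = 0.0
    for i0 in range(len(a)):
        for i1 in range(i0 + 1, len(a) + 1):
            for j0 in range(len(b)):
                for j1 in range(j0 + 1, len(b) + 1):
                    best = max(best, extend(i0, j0, i1, j1, 0))
    return best


def t_upper_tail(t: float, df: int) -> float:
    """Upper tail of Student's t via the regularized incomplete beta
    function: P(T > t) = I_{df/(df+t^2)}(df/2, 1/2) / 2 for t >= 0."""
    x = df / (df + t * t)
    half = 0.5 * betainc(df / 2.0, 0.5, x)
    return half if t >= 0 else 1.0 - half


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) by enumerating all C(N, n)
    draws from a labelled universe. Feasible for N <= 12."""
    universe = list(range(N))
    successes = set(range(K))
    total = 0
    hits = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(successes.intersection(draw)) >= k:
            hits += 1
    return hits / total
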