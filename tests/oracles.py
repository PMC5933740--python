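"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid scipy.stats and networkx path routines: the
hypergeometric tail is computed by literally enumerating draws, and simple
paths by a hand-written recursive DFS.
"""

from fractions import Fraction
from itertools import combinations


def exact_upper_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws.

    Items 0..K-1 are the 'special' (regulon) items; every n-subset of
    range(N) is enumerated and those containing at least k special items
    are counted. Exact rational arithmetic.
    """
    hits = 0
    total = 0
    for draw in combinations(range(N), n):
        total += 1
        if sum(1 for x in draw if x < K) >= k:
            hits += 1
    return Fraction(hits, total) if total else Fraction(1)


def upper_tail_histograms(N: int, n: int) -> dict[int, list[int]]:
    """For each K, the histogram of overlap counts over all C(N, n) draws.

    Returns {K: counts} where counts[i] = number of draws with exactly i
    items below K. Lets a full (k, K) sweep reuse one subset enumeration.
    """
    draws = list(combinations(range(N), n))
    out: dict[int, list[int]] = {}
    for K in range(N + 1):
        counts = [0] * (n + 1)
        for draw in draws:
            counts[sum(1 for x in draw if x < K)] += 1
        out[K] = counts
    return out


def brute_force_simple_paths(
    nodes, edges, sources, target, max_len: int
) -> list[tuple[str, ...]]:
    """All simple paths from any source to target with <= max_len nodes,
    by recursive DFS, sorted lexicographically. Paths end at the first
    arrival at target (a simple path cannot revisit it)."""
    adj: dict[str, list[str]] = {n: [] for n in nodes}
    for s, t in edges:
        adj[s].append(t)
    for n in adj:
        adj[n].sort()
    found: list[tuple[str, ...]] = []

    def dfs(path: list[str], seen: set[str]) -> None:
        cur = path[-1]
        if cur == target:
            if len(path) >= 2:
                found.append(tuple(path))
            return
        if len(path) == max_len:
            return
        for nxt in adj[cur]:
            if nxt not in seen:
                seen.add(nxt)
                path.append(nxt)
                dfs(path, seen)
                path.pop()
                seen.remove(nxt)

    for s in sorted(set(sources)):
        if s == target or s not in adj:
            continue
        dfs([s], {s})
    return sorted(found)
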