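"""Independent oracles used only by the tests.

These deliberately avoid the package's own algorithms: the event-distance
oracle is exhaustive shortest-path search over the profile graph, and the
Fisher oracle enumerates hypergeometric tables in exact rational
arithmetic.
"""

from __future__ import annotations

import heapq
import math
from collections import deque
from fractions import Fraction
from functools import lru_cache


def _expand(state: tuple, cnmax: int):
    """Forward moves: +/-1 on a contiguous run, zero bins untouchable."""
    n = len(state)
    for i in range(n):
        for j in range(i + 1, n + 1):
            seg = state[i:j]
            if all(0 < v < cnmax for v in seg):
                yield state[:i] + tuple(v + 1 for v in seg) + state[j:]
            if all(v > 0 for v in seg):
                yield state[:i] + tuple(v - 1 for v in seg) + state[j:]


def med_bfs(a: tuple, b: tuple, cnmax: int = 4) -> float:
    """Plain breadth-first shortest path; use only on tiny instances."""
    if a == b:
        return 0
    if any(x == 0 and y != 0 for x, y in zip(a, b)):
        return math.inf
    seen = {a}
    frontier = deque([(a, 0)])
    while frontier:
        state, d = frontier.popleft()
        for nb in _expand(state, cnmax):
            if nb == b:
                return d + 1
            if nb not in seen:
                seen.add(nb)
                frontier.append((nb, d + 1))
    return math.inf


def med_search(a: tuple, b: tuple, cnmax: int = 4) -> float:
    """Exact minimum event count by A* with an admissible heuristic.

    The heuristic max(positive diff) + max(negative diff) never
    overestimates (one event moves a bin by at most 1 and cannot mix gains
    with losses), so the search returns the true BFS minimum while visiting
    far fewer states.
    """
    if a == b:
        return 0
    if any(x == 0 and y != 0 for x, y in zip(a, b)):
        return math.inf

    def h(state):
        mp = mq = 0
        for x, y in zip(state, b):
            d = y - x
            if d > mp:
                mp = d
            elif -d > mq:
                mq = -d
        return mp + mq

    best = {a: 0}
    pq = [(h(a), 0, a)]
    while pq:
        f, g, state = heapq.heappop(pq)
        if state == b:
            return g
        if g > best.get(state, 1 << 30):
            continue
        for nb in _expand(state, cnmax):
            ng = g + 1
            if ng < best.get(nb, 1 << 30):
                best[nb] = ng
                heapq.heappush(pq, (ng + h(nb), ng, nb))
    return math.inf


@lru_cache(maxsize=None)
def _fact(n: int) -> int:
    return math.factorial(n)


def _table_prob(a: int, b: int, c: int, d: int) -> Fraction:
    n = a + b + c + d
    num = (_fact(a + b) * _fact(c + d) * _fact(a + c) * _fact(b + d))
    den = _fact(n) * _fact(a) * _fact(b) * _fact(c) * _fact(d)
    return Fraction(num, den)


def fisher_enumeration(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided exact p as an exact rational, by full table enumeration."""
    n = a + b + c + d
    if n == 0:
        return Fraction(1)
    r1, c1, r2 = a + b, a + c, c + d
    obs = _table_prob(a, b, c, d)
    p = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = _table_prob(k, r1 - k, c1 - k, r2 - c1 + k)
        if pk <= obs:
            p += pk
    return min(p, Fraction(1))
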