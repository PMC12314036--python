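"""Independent brute-force oracles.

Everything here is written from the definitions, in plain Python loops,
deliberately sharing no code with the library implementations it
cross-checks: naive dict-based propagation, exhaustive simple-path
enumeration for distances and pathway supports, rank-sum enumeration,
and hand step-up BH.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Mapping, Sequence


def naive_propagate(net, weights: Mapping, steps: int, stimulus: Mapping[str, int]) -> dict[str, float]:
    """Dict-loop synchronous propagation: y <- tanh(sum_in w * y_src)."""
    y = {p: 0.0 for p in net.proteins}
    for p, c in stimulus.items():
        y[p] = float(c)
    incoming: dict[str, list[tuple[str, float]]] = {p: [] for p in net.proteins}
    for u, v, _ in net.edges:
        incoming[v].append((u, weights.get((u, v), 0.0)))
    for _ in range(steps):
        nxt = {}
        for p in net.proteins:
            if p in stimulus:
                nxt[p] = float(stimulus[p])
            else:
                nxt[p] = math.tanh(sum(w * y[u] for u, w in incoming[p]))
        y = nxt
    return y


def all_simple_paths(net, source: str, target: str, max_len: int) -> list[tuple[str, ...]]:
    """Exhaustive DFS enumeration of simple directed paths up to max_len edges."""
    succ: dict[str, list[str]] = {p: [] for p in net.proteins}
    for u, v, _ in net.edges:
        succ[u].append(v)
    out: list[tuple[str, ...]] = []

    def walk(path: list[str]) -> None:
        if len(path) - 1 > max_len:
            return
        if path[-1] == target and len(path) > 1:
            out.append(tuple(path))
            return
        if len(path) - 1 == max_len:
            return
        for nxt in succ[path[-1]]:
            if nxt not in path:
                path.append(nxt)
                walk(path)
                path.pop()

    if source in net.proteins and target in net.proteins and source != target:
        walk([source])
    return out


def brute_distance(net, source: str, target: str, max_len: int = 10) -> int | None:
    """Shortest directed distance by exhaustive path enumeration."""
    if source == target:
        return 0
    paths = all_simple_paths(net, source, target, max_len)
    return min((len(p) - 1 for p in paths), default=None)


def brute_raw_score(net, ensemble, source: str, mode: str, effs,
                    weights: Sequence[float] = (1.0, 0.5, 1.0 / 3.0)) -> float:
    """Per-solution recomputation of the distance-weighted triggering score."""
    clamp = -1 if mode == "inhibited" else 1
    scores = []
    for sol in ensemble.solutions:
        y = naive_propagate(net, sol.params.weights, sol.params.steps, {source: clamp})
        s = 0.0
        for p, v in effs.effectors.items():
            d = brute_distance(net, source, p)
            if d is None or not 1 <= d <= 3:
                continue
            if abs(y[p]) >= sol.params.tau_act and math.copysign(1, y[p]) == v:
                s += weights[d - 1]
        scores.append(s)
    return sum(scores) / len(scores)


def brute_pathway_supports(net, ensemble, stimulus: Mapping[str, int],
                           sources: Sequence[str], effectors: Sequence[str],
                           max_len: int) -> dict[tuple[str, ...], float]:
    """Support of every simple path from any source to any effector:
    fraction of solutions where all nodes are suprathreshold and each
    step flips/propagates sign per the edge sign."""
    sign_of = {(u, v): s for u, v, s in net.edges}
    paths: set[tuple[str, ...]] = set()
    for s in sources:
        for e in effectors:
            paths.update(all_simple_paths(net, s, e, max_len))
    supports: dict[tuple[str, ...], float] = {}
    for path in paths:
        active = 0
        for sol in ensemble.solutions:
            y = naive_propagate(net, sol.params.weights, sol.params.steps, dict(stimulus))
            tau = sol.params.tau_act
            ok = all(abs(y[p]) >= tau for p in path)
            if ok:
                for k in range(len(path) - 1):
                    lhs = math.copysign(1, y[path[k + 1]])
                    rhs = sign_of[(path[k], path[k + 1])] * math.copysign(1, y[path[k]])
                    if lhs != rhs:
                        ok = False
                        break
            active += ok
        supports[path] = active / len(ensemble.solutions)
    return supports


def brute_ranksum_exact(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided exact rank-sum p by enumerating every rank assignment."""
    pooled = sorted(list(a) + list(b))
    assert len(set(pooled)) == len(pooled), "exact enumeration assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n_a = len(a)
    obs = sum(ranks[v] for v in a)
    mean = n_a * (len(pooled) + 1) / 2
    count = total = 0
    for combo in combinations(range(1, len(pooled) + 1), n_a):
        total += 1
        if abs(sum(combo) - mean) >= abs(obs - mean):
            count += 1
    return count / total


def brute_bh(p_values: Sequence[float]) -> list[float]:
    """Step-up BH by hand: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        q[i] = min(1.0, running)
    return q
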