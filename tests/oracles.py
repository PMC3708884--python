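"""Independent brute-force oracles used across the test suite.

Each oracle deliberately avoids the implementation path it checks:
breadth-first search instead of Dijkstra, restricted-growth-string
partition enumeration instead of the sympy-backed generator, explicit
repertoire enumeration instead of the additive-entropy shortcut, and
direct double sums for MI/KL.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np


def bfs_distances(maze) -> np.ndarray:
    """BFS distance-to-exit oracle on the reversed move graph."""
    H, W = maze.height, maze.width
    dist = np.full((H, W), -1, dtype=int)
    q = deque()
    for r in range(H):
        if not maze.wall[r, W - 1]:
            dist[r, W - 1] = 0
            q.append((r, W - 1))
    while q:
        r, c = q.popleft()
        preds = [(r - 1, c), (r + 1, c)]
        if c - 1 >= 0:
            preds.append((r, c - 1))
        for rr, cc in preds:
            if 0 <= rr < H and not maze.wall[rr, cc] and dist[rr, cc] < 0:
                dist[rr, cc] = dist[r, c] + 1
                q.append((rr, cc))
    return dist


def mi_bruteforce(p: np.ndarray) -> float:
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    total = 0.0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            if p[i, j] > 0:
                total += p[i, j] * math.log2(p[i, j] / (px[i] * py[j]))
    return total


def kl_bruteforce(p, q) -> float:
    return sum(pi * math.log2(pi / qi) for pi, qi in zip(p, q) if pi > 0)


def rgs_partitions(n: int):
    """All set partitions of range(n) via restricted growth strings."""
    a = [0] * n
    b = [1] * n

    def emit():
        parts: dict[int, list[int]] = {}
        for i, lab in enumerate(a):
            parts.setdefault(lab, []).append(i)
        return [tuple(p) for p in parts.values()]

    yield emit()
    while True:
        i = n - 1
        while i > 0 and a[i] == b[i]:
            i -= 1
        if i == 0:
            return
        a[i] += 1
        for j in range(i + 1, n):
            a[j] = 0
            b[j] = max(b[j - 1], a[j - 1] + 1)
        yield emit()


def ei_enumeration_oracle(model, parts_nodes) -> float:
    """Exhaustive effective-information oracle.

    Builds every repertoire explicitly from the dense subset matrix:
    whole p(x1 | x0) and, for each part, p(m1 | m0) as the uniform
    average over all completions of m0, then sums the KL terms state by
    state.
    """
    n = model.n
    nodes = model.nodes
    mat = model.matrix
    pos = {v: k for k, v in enumerate(nodes)}

    def substate(x, part):
        return tuple((x >> pos[v]) & 1 for v in part)

    part_reps = []
    for part in parts_nodes:
        k = len(part)
        rep = {}
        for m0 in itertools.product((0, 1), repeat=k):
            rows = [x for x in range(1 << n) if substate(x, part) == m0]
            dist = {}
            for m1 in itertools.product((0, 1), repeat=k):
                dist[m1] = np.mean(
                    [
                        sum(
                            mat[x0, x1]
                            for x1 in range(1 << n)
                            if substate(x1, part) == m1
                        )
                        for x0 in rows
                    ]
                )
            rep[m0] = dist
        part_reps.append(rep)

    total = 0.0
    for x0 in range(1 << n):
        for x1 in range(1 << n):
            p = mat[x0, x1]
            if p <= 0:
                continue
            q = 1.0
            for part, rep in zip(parts_nodes, part_reps):
                q *= rep[substate(x0, part)][substate(x1, part)]
            total += p * math.log2(p / q)
    return total / (1 << n)
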