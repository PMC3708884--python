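"""Information-theoretic circuit-complexity measures for Markov brains.

Four measures are computed for an agent:

* **SMMI** — sensory-motor mutual information, the plug-in estimate of
  ``I(S_t ; M_{t+1})`` between the six sensor bits at time t and the two
  actuator bits one step later, pooled over recorded maze runs.  Bounded
  above by 2 bits.
* **Predictive information** — ``I(X_t ; X_{t+1})`` between consecutive
  full 12-bit brain states; bounded above by 12 bits.
* **Integrated information (phi)** — the effective information of the
  exact state-transition model evaluated at the *minimal information
  partition* (MIP).  Effective information of a partition is the
  state-averaged Kullback-Leibler divergence between the whole system's
  next-state repertoire and the product of the parts' independently
  perturbed repertoires; the MIP minimizes it after normalization, and
  phi is the non-normalized value there.  The *main complex* is the node
  subset maximizing phi, found by greedy single-node removal.
* **Stochastic interaction (atomic phi)** — the effective information at
  the finest (all-singletons) partition, computable without a partition
  search as ``sum_i H(X'_i | X_i) - H(X' | X)``.

Repertoires are exact (derived analytically from the gate tables, no
sampling); the state average defaults to the maximum-entropy
(perturbational) distribution over current substates, with an empirical
weighting available.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import xlogy
from sympy.utilities.iterables import multiset_partitions

from . import _sim
from .brain import (
    Brain,
    N_NODES,
    TransitionModel,
    WRITABLE_NODES,
    exact_transition_model,
)

__all__ = [
    "ActivityRecord",
    "JointDistribution",
    "Partition",
    "PhiResult",
    "record_activity",
    "mutual_information",
    "mutual_information_from_pairs",
    "smmi",
    "predictive_info",
    "kl_divergence",
    "effective_information",
    "mip_normalization",
    "find_mip",
    "main_complex",
    "phi_atomic",
]

LOG2 = np.log(2.0)


# ---------------------------------------------------------------------------
# activity records


@dataclass
class ActivityRecord:
    """Full 12-bit brain states recorded during a battery of maze runs.

    ``states`` concatenates all runs; ``episode_starts`` marks where each
    run begins.  Consecutive-pair statistics never straddle an episode
    boundary.
    """

    states: np.ndarray
    episode_starts: np.ndarray

    @property
    def n_episodes(self) -> int:
        return len(self.episode_starts)

    def pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """(x_t, x_{t+1}) over all within-episode consecutive steps."""
        if len(self.states) == 0:
            raise ValueError("empty activity record")
        bounds = np.append(self.episode_starts, len(self.states))
        xs, ys = [], []
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b - a >= 2:
                xs.append(self.states[a : b - 1])
                ys.append(self.states[a + 1 : b])
        if not xs:
            raise ValueError("no consecutive pairs in record")
        return np.concatenate(xs), np.concatenate(ys)


def record_activity(
    brain: Brain,
    mazes,
    lifetime: int = 300,
    seed=None,
) -> ActivityRecord:
    """Record the full brain state at every step of one run per maze."""
    if not mazes:
        raise ValueError("need at least one maze")
    rng = np.random.default_rng(seed)
    states, starts = [], []
    pos = 0
    for maze in mazes:
        start_row = int(rng.integers(maze.height))
        kseed = int(rng.integers(2**31))
        _, _, _, rec = _sim.run_trials(
            brain, maze, lifetime, [start_row], [kseed], record=True
        )
        starts.append(pos)
        states.append(rec[0])
        pos += lifetime
    return ActivityRecord(
        states=np.concatenate(states), episode_starts=np.array(starts)
    )


# ---------------------------------------------------------------------------
# elementary estimators


@dataclass(frozen=True)
class JointDistribution:
    """Dense joint probability table p(x, y)."""

    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=np.float64)
        object.__setattr__(self, "probs", p)
        if p.ndim != 2 or (p < 0).any():
            raise ValueError("joint must be a non-negative 2-D table")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("joint distribution is not normalized")


def mutual_information(joint) -> float:
    """I(X;Y) in bits from a joint table; 0*log terms are 0."""
    if not isinstance(joint, JointDistribution):
        joint = JointDistribution(np.asarray(joint))
    p = joint.probs
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float(
        (p[mask] * (np.log(p[mask]) - np.log((px * py)[mask]))).sum() / LOG2
    )


def mutual_information_from_pairs(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in MI between two discrete sample sequences."""
    x = np.asarray(x)
    y = np.asarray(y)
    if len(x) != len(y) or len(x) == 0:
        raise ValueError("need two equal-length non-empty sequences")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    counts = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(counts, (xi, yi), 1)
    return mutual_information(counts / counts.sum())


def smmi(record: ActivityRecord) -> float:
    """Sensory-motor mutual information I(S_t ; M_{t+1}) in bits."""
    x, y = record.pairs()
    return mutual_information_from_pairs(x & 0b111111, (y >> 10) & 0b11)


def predictive_info(record: ActivityRecord) -> float:
    """One-step predictive information I(X_t ; X_{t+1}) in bits."""
    x, y = record.pairs()
    return mutual_information_from_pairs(x, y)


def kl_divergence(p, q) -> float:
    """Relative entropy D(p || q) in bits; requires supp(p) within supp(q)."""
    p = np.asarray(p, dtype=np.float64).ravel()
    q = np.asarray(q, dtype=np.float64).ravel()
    if p.shape != q.shape:
        raise ValueError("distributions must have equal support size")
    mask = p > 0
    if (q[mask] <= 0).any():
        raise ValueError("support of p is not contained in support of q")
    return float((p[mask] * (np.log(p[mask]) - np.log(q[mask]))).sum() / LOG2)


# ---------------------------------------------------------------------------
# partitions


@dataclass(frozen=True)
class Partition:
    """Disjoint, covering, non-empty parts (tuples of node ids)."""

    parts: tuple[tuple[int, ...], ...]

    def __post_init__(self):
        parts = tuple(tuple(sorted(p)) for p in self.parts)
        parts = tuple(sorted(parts))
        object.__setattr__(self, "parts", parts)
        allnodes = [v for p in parts for v in p]
        if not parts or any(len(p) == 0 for p in parts):
            raise ValueError("parts must be non-empty")
        if len(set(allnodes)) != len(allnodes):
            raise ValueError("parts must be disjoint")

    @property
    def n_parts(self) -> int:
        return len(self.parts)

    def nodes(self) -> tuple[int, ...]:
        return tuple(sorted(v for p in self.parts for v in p))


@dataclass
class PhiResult:
    subset: tuple[int, ...]
    mip: Partition | None
    phi: float
    normalized_phi: float


def mip_normalization(partition: Partition) -> float:
    """Normalization K(P) = (m - 1) * min_k Hmax(M_k), with Hmax the part
    size in bits; used only to rank candidate partitions."""
    if partition.n_parts < 2:
        raise ValueError("normalization requires at least 2 parts")
    return (partition.n_parts - 1) * min(len(p) for p in partition.parts)


# ---------------------------------------------------------------------------
# effective information


def _row_axis_view(probs: np.ndarray, n: int) -> np.ndarray:
    """View of (2**n, C) with one axis per row bit; axis k = bit k
    (= k-th subset node, ascending)."""
    C = probs.shape[1]
    v = probs.reshape((2,) * n + (C,))
    # C-order reshape puts bit n-1 on axis 0; reverse row axes so that
    # axis k corresponds to bit k.
    return np.transpose(v, axes=tuple(range(n - 1, -1, -1)) + (n,))


def _part_model(model: TransitionModel, positions: tuple[int, ...]) -> np.ndarray:
    """Perturbed repertoire of a part: p(part' | part) with every node
    outside the part (inside or outside the subset) at max entropy.

    Returns (2**k, 2**kw); row bit j = positions[j], column bit j = j-th
    writable member of the part.
    """
    n = model.n
    probs = model.probs
    v = _row_axis_view(probs, n)  # axis k = row bit k
    drop = tuple(a for a in range(n) if a not in positions)
    r = v.mean(axis=drop) if drop else v
    # remaining row axes are in ascending position order; flatten so the
    # first retained position is the least significant bit
    k = len(positions)
    r = np.transpose(r, axes=tuple(range(k - 1, -1, -1)) + (k,))
    r = r.reshape(-1, probs.shape[1])
    # marginalize columns onto the part's writable members
    wpos = [j for j, node in enumerate(model.writable) if _posof(model, node) in positions]
    m = len(wpos)
    C = probs.shape[1]
    colmap = np.zeros(C, dtype=np.int64)
    for cidx in range(C):
        out = 0
        for jj, j in enumerate(wpos):
            out |= ((cidx >> j) & 1) << jj
        colmap[cidx] = out
    res = np.zeros((1 << k, 1 << m))
    np.add.at(res, (slice(None), colmap), r)
    return res


def _posof(model: TransitionModel, node: int) -> int:
    return model.nodes.index(node)


def _partition_positions(model: TransitionModel, partition: Partition):
    if partition.nodes() != model.nodes:
        raise ValueError("partition does not cover the model's subset")
    return [tuple(sorted(_posof(model, v) for v in p)) for p in partition.parts]


def _ei_positions(
    model: TransitionModel,
    parts_pos,
    weights: np.ndarray | None,
    cache: dict | None = None,
) -> float:
    """Effective information (bits) for parts given as position tuples."""
    n = model.n
    probs = model.probs
    nrows, C = probs.shape
    rows = np.arange(nrows)
    cols = np.arange(C)
    wpos_of_node = {node: j for j, node in enumerate(model.writable)}
    logq = np.zeros((nrows, C))
    for pos in parts_pos:
        if cache is not None and pos in cache:
            pm = cache[pos]
        else:
            pm = _part_model(model, pos)
            if cache is not None:
                cache[pos] = pm
        # row index of the part for every whole-system row
        ri = np.zeros(nrows, dtype=np.int64)
        for jj, p in enumerate(pos):
            ri |= ((rows >> p) & 1) << jj
        # column index of the part for every whole-system column
        wp = [wpos_of_node[model.nodes[p]] for p in pos if model.nodes[p] in wpos_of_node]
        ci = np.zeros(C, dtype=np.int64)
        for jj, j in enumerate(wp):
            ci |= ((cols >> j) & 1) << jj
        with np.errstate(divide="ignore"):
            lpm = np.log(pm)
        logq += lpm[ri[:, None], ci[None, :]]
    if weights is None:
        wt = np.full(nrows, 1.0 / nrows)
    else:
        wt = np.asarray(weights, dtype=np.float64)
        if wt.shape != (nrows,) or abs(wt.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be a distribution over substates")
    mask = probs > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(mask, probs * (np.log(probs) - logq), 0.0)
    ei = float((wt[:, None] * terms).sum() / LOG2)
    return max(ei, 0.0)


def effective_information(
    model: TransitionModel,
    partition: Partition,
    input_dist: str = "max-entropy",
    weights: np.ndarray | None = None,
) -> float:
    """Effective information of a partition, in bits.

    The whole repertoire p(X' | x) is compared (KL) with the product of
    the parts' independently perturbed repertoires p(M_k' | m_k), and the
    result averaged over current substates x — uniformly by default, or
    with ``weights`` when ``input_dist="empirical"``.
    """
    if model.conditioning != "max-entropy":
        raise ValueError(
            "effective information requires a max-entropy-conditioned model"
        )
    if input_dist == "max-entropy":
        weights = None
    elif input_dist == "empirical":
        if weights is None:
            raise ValueError("empirical input_dist requires weights")
    else:
        raise ValueError(f"unknown input_dist {input_dist!r}")
    parts_pos = _partition_positions(model, partition)
    return _ei_positions(model, parts_pos, weights)


# ---------------------------------------------------------------------------
# MIP search and phi
#
# Under the uniform (max-entropy) state average the effective information
# decomposes additively: because every part repertoire is the uniform
# average of the whole repertoire's marginal, the cross terms of the KL
# divergence collapse to the parts' conditional entropies, giving
#
#     ei(P) = sum_k H(M'_k | M_k) - H(X' | X).
#
# One conditional entropy per submask therefore scores every candidate
# partition; the submask entropies are computed by a single lattice
# descent in which each part model is derived from a parent model by
# marginalizing out one node.  ``effective_information`` keeps the direct
# KL evaluation, which doubles as an internal cross-check and handles
# empirical state weighting.


def _cond_entropy_uniform(probs: np.ndarray) -> float:
    """H(X' | X) in bits of a row-stochastic table under uniform rows."""
    return float(-xlogy(probs, probs).sum() / (probs.shape[0] * LOG2))


def _drop_position(
    probs: np.ndarray, positions: list[int], wpositions: list[int], v: int
):
    """Marginalize node position ``v`` out of a part model: average the
    row bit, sum the column bit (if writable)."""
    m = len(positions)
    i = positions.index(v)
    C = probs.shape[1]
    r = probs.reshape((2,) * m + (C,)).mean(axis=m - 1 - i)
    r = r.reshape(-1, C)
    if v in wpositions:
        mw = len(wpositions)
        j = wpositions.index(v)
        r = (
            r.reshape((-1,) + (2,) * mw)
            .sum(axis=1 + (mw - 1 - j))
            .reshape(r.shape[0], -1)
        )
        new_w = [p for p in wpositions if p != v]
    else:
        new_w = wpositions
    return r, [p for p in positions if p != v], new_w


def _part_entropies(model: TransitionModel) -> np.ndarray:
    """H(M'_k | M_k) for every non-empty submask of the model's positions.

    Index: bit p of the mask corresponds to subset position p.
    """
    n = model.n
    wpositions = [
        k for k, node in enumerate(model.nodes) if node in WRITABLE_NODES
    ]
    H = np.zeros(1 << n)

    def rec(probs, positions, wpos, min_removed):
        mask = 0
        for p in positions:
            mask |= 1 << p
        H[mask] = _cond_entropy_uniform(probs)
        if len(positions) == 1:
            return
        for v in positions:
            if v >= min_removed:
                continue
            child = _drop_position(probs, positions, wpos, v)
            rec(child[0], child[1], child[2], v)

    rec(model.probs, list(range(n)), wpositions, n)
    return H


def _bipartition_masks(n: int):
    """All 2-part splits of n positions; part A always contains position 0."""
    for m in range((1 << (n - 1)) - 1):
        yield (m << 1) | 1


def _candidate_partitions(n: int, search: str):
    if search == "auto":
        search = "exhaustive" if n <= 8 else "bipartitions"
    if search == "exhaustive":
        for parts in multiset_partitions(list(range(n))):
            if len(parts) >= 2:
                yield [tuple(p) for p in parts]
    elif search == "bipartitions":
        for mask in _bipartition_masks(n):
            a = tuple(i for i in range(n) if (mask >> i) & 1)
            b = tuple(i for i in range(n) if not (mask >> i) & 1)
            yield [a, b]
    else:
        raise ValueError(f"unknown search mode {search!r}")


def find_mip(
    model: TransitionModel,
    search: str = "auto",
    input_dist: str = "max-entropy",
    weights: np.ndarray | None = None,
) -> PhiResult:
    """Minimal information partition and phi of a transition model.

    Minimizes ei/K over candidate partitions (the one-part total
    partition is excluded); phi is the *non-normalized* ei at the argmin.
    Exhaustive search enumerates all set partitions (practical to ~8
    nodes, the Bell number grows super-exponentially); ``bipartitions``
    restricts to 2-part splits.  Ties break toward fewer parts, then
    lexicographically.
    """
    n = model.n
    if n < 2:
        raise ValueError("phi requires at least 2 nodes")
    if input_dist == "max-entropy":
        weights = None
    part_H = _part_entropies(model) if weights is None else None
    h_whole = _cond_entropy_uniform(model.probs) if weights is None else None
    cache: dict = {}
    best = None  # (norm, n_parts, canonical, ei, parts_pos)
    for parts_pos in _candidate_partitions(n, search):
        if weights is None:
            ei = -h_whole
            for part in parts_pos:
                mask = 0
                for p in part:
                    mask |= 1 << p
                ei += part_H[mask]
            ei = max(ei, 0.0)
        else:
            ei = _ei_positions(model, parts_pos, weights, cache)
        K = (len(parts_pos) - 1) * min(len(p) for p in parts_pos)
        norm = ei / K
        key = (len(parts_pos), tuple(sorted(parts_pos)))
        if (
            best is None
            or norm < best[0] - 1e-12
            or (abs(norm - best[0]) <= 1e-12 and key < (best[1], best[2]))
        ):
            best = (norm, key[0], key[1], ei, parts_pos)
    parts_nodes = tuple(
        tuple(model.nodes[p] for p in part) for part in best[4]
    )
    return PhiResult(
        subset=model.nodes,
        mip=Partition(parts_nodes),
        phi=best[3],
        normalized_phi=best[0],
    )


def phi_atomic(
    model: TransitionModel,
    input_dist: str = "max-entropy",
    weights: np.ndarray | None = None,
) -> float:
    """Stochastic interaction: sum_i H(X'_i | X_i) - H(X' | X), in bits.

    Computed from conditional entropies of the exact model; equals the
    effective information at the atomic partition under the default
    maximum-entropy state average (an internal cross-check enforces
    this).
    """
    if model.conditioning != "max-entropy":
        raise ValueError("phi_atomic requires a max-entropy-conditioned model")
    n = model.n
    if n < 2:
        raise ValueError("stochastic interaction requires at least 2 nodes")
    probs = model.probs
    nrows, C = probs.shape
    if input_dist == "max-entropy":
        wt = np.full(nrows, 1.0 / nrows)
    elif input_dist == "empirical":
        if weights is None:
            raise ValueError("empirical input_dist requires weights")
        wt = np.asarray(weights, dtype=np.float64)
    else:
        raise ValueError(f"unknown input_dist {input_dist!r}")
    # whole-system conditional entropy H(X' | X)
    h_whole = float(-(wt[:, None] * xlogy(probs, probs)).sum() / LOG2)
    # per-node conditional entropies from the weighted pair distributions
    rows = np.arange(nrows)
    cols = np.arange(C)
    wpos_of_node = {node: j for j, node in enumerate(model.writable)}
    h_parts = 0.0
    for k in range(n):
        node = model.nodes[k]
        if node not in wpos_of_node:
            continue  # sensor: next state is deterministically 0
        j = wpos_of_node[node]
        joint = np.zeros((2, 2))
        np.add.at(
            joint,
            (
                np.broadcast_to(((rows >> k) & 1)[:, None], (nrows, C)),
                np.broadcast_to(((cols >> j) & 1)[None, :], (nrows, C)),
            ),
            wt[:, None] * probs,
        )
        marg = joint.sum(axis=1, keepdims=True)
        cond = np.divide(joint, marg, out=np.zeros_like(joint), where=marg > 0)
        with np.errstate(divide="ignore"):
            logc = np.where(cond > 0, np.log(cond), 0.0)
        h_parts += float(-(joint * logc).sum() / LOG2)
    return max(h_parts - h_whole, 0.0)


# ---------------------------------------------------------------------------
# main complex


def _components(nodes: tuple[int, ...], edges) -> list[tuple[int, ...]]:
    """Connected components of the causal graph restricted to ``nodes``."""
    nodes = tuple(sorted(nodes))
    idx = {v: i for i, v in enumerate(nodes)}
    rows, cols = [], []
    for a, b in edges:
        if a in idx and b in idx:
            rows += [idx[a], idx[b]]
            cols += [idx[b], idx[a]]
    adj = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(nodes), len(nodes))
    )
    ncomp, labels = connected_components(adj, directed=False)
    return [
        tuple(v for v in nodes if labels[idx[v]] == c) for c in range(ncomp)
    ]


def _phi_of_subset(brain: Brain, subset, edges, search: str) -> PhiResult:
    subset = tuple(sorted(subset))
    if len(subset) < 2:
        return PhiResult(subset=subset, mip=None, phi=0.0, normalized_phi=0.0)
    comps = _components(subset, edges)
    if len(comps) > 1:
        # a cut between disconnected components carries zero effective
        # information, so phi vanishes without any model evaluation
        return PhiResult(
            subset=subset,
            mip=Partition(tuple(comps)),
            phi=0.0,
            normalized_phi=0.0,
        )
    model = exact_transition_model(brain, subset)
    return find_mip(model, search=search)


def main_complex(
    brain: Brain,
    search: str = "auto",
    subset_search: str = "auto",
    restrict_to_active: bool = True,
) -> PhiResult:
    """Node subset maximizing phi (the *main complex*) and its phi.

    ``subset_search="greedy"`` uses iterative single-node removal:
    starting from the full candidate set, phi is evaluated for every
    node-removed sub-network, the search moves to the best and repeats
    down to 2 nodes, returning the best subset seen.  ``"exhaustive"``
    scans the whole power set (exact but exponential); ``"auto"`` is
    exhaustive for causal components of up to 6 nodes and greedy above.
    Causally inert nodes admit a zero-information cut, so the search
    runs inside each connected component of the causal graph (exact, not
    a heuristic); ``search`` selects the MIP search mode per subset.
    """
    edges = brain.causal_edges()
    if restrict_to_active:
        base = brain.active_nodes()
    else:
        base = tuple(range(N_NODES))
    best = PhiResult(subset=(), mip=None, phi=0.0, normalized_phi=0.0)
    for comp in _components(base, edges):
        if len(comp) < 2:
            continue
        mode = subset_search
        if mode == "auto":
            mode = "exhaustive" if len(comp) <= 6 else "greedy"
        if mode == "exhaustive":
            for k in range(2, len(comp) + 1):
                for sub in itertools.combinations(comp, k):
                    r = _phi_of_subset(brain, sub, edges, search)
                    if r.phi > best.phi + 1e-12:
                        best = r
        elif mode == "greedy":
            current = comp
            res = _phi_of_subset(brain, current, edges, search)
            if res.phi > best.phi:
                best = res
            while len(current) > 2:
                cand_best = None
                for v in current:
                    sub = tuple(x for x in current if x != v)
                    r = _phi_of_subset(brain, sub, edges, search)
                    if cand_best is None or r.phi > cand_best.phi + 1e-12:
                        cand_best = r
                current = cand_best.subset
                if cand_best.phi > best.phi:
                    best = cand_best
        else:
            raise ValueError(f"unknown subset_search mode {subset_search!r}")
    return best
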