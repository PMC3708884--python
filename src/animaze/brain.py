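"""Markov brains: genomes, stochastic logic gates, and exact dynamics.

An animat brain is a network of 12 binary nodes updated in discrete time
by genome-encoded stochastic logic gates (hidden Markov units):

====  =========================================
b0    retina, wall straight ahead
b1    retina, front-left diagonal
b2    retina, front-right diagonal
b3    door-information sensor
b4    lateral collision sensor, -row side
b5    lateral collision sensor, +row side
b6-9  internal logic units
b10   actuator bit 1
b11   actuator bit 2
====  =========================================

Sensor nodes b0-b5 are written by the environment only; gates may read
any node but write only b6-b11.  At each update every gate reads its
input bits from the current state and samples one row of its stochastic
table; writes from several gates to the same node combine by OR, and
nodes written by no gate fall to 0.

The genome is a circular byte string.  A gate is expressed wherever the
start codon (byte pair 42, 213) occurs; the bytes that follow encode
fan-in and fan-out (1-4 each), input node ids (mod 12), output node ids
(mod 6, mapped into b6-b11), and the raw transition table, which is
normalized row-wise (an all-zero row becomes uniform).  Any byte string
decodes; junk regions are skipped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .maze import SensorFrame

__all__ = [
    "N_NODES",
    "N_STATES",
    "SENSOR_NODES",
    "INTERNAL_NODES",
    "MOTOR_NODES",
    "WRITABLE_NODES",
    "START_CODON",
    "Genome",
    "Gate",
    "Brain",
    "TransitionModel",
    "random_genome",
    "decode_genome",
    "step",
    "exact_transition_model",
]

N_NODES = 12
N_STATES = 1 << N_NODES
SENSOR_NODES = (0, 1, 2, 3, 4, 5)
INTERNAL_NODES = (6, 7, 8, 9)
MOTOR_NODES = (10, 11)
WRITABLE_NODES = INTERNAL_NODES + MOTOR_NODES  # gates may write only these
N_WRITABLE = len(WRITABLE_NODES)

START_CODON = (42, 213)
MAX_FAN = 4


@dataclass(frozen=True)
class Genome:
    """Circular byte string; ``data[i % len]`` is always defined."""

    data: bytes

    def __len__(self) -> int:
        return len(self.data)

    def byte(self, i: int) -> int:
        return self.data[i % len(self.data)]


@dataclass
class Gate:
    """One stochastic logic unit.

    ``table`` has shape ``(2**n_in, 2**n_out)``; row index encodes the
    input bits with ``inputs[0]`` least significant, column index the
    output bits with ``outputs[0]`` least significant.  Rows sum to 1.
    """

    inputs: tuple[int, ...]
    outputs: tuple[int, ...]
    table: np.ndarray

    @property
    def n_in(self) -> int:
        return len(self.inputs)

    @property
    def n_out(self) -> int:
        return len(self.outputs)

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=np.float64)
        if self.table.shape != (1 << self.n_in, 1 << self.n_out):
            raise ValueError("gate table shape does not match fan-in/out")
        if not np.allclose(self.table.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("gate table rows must sum to 1")
        if any(o not in WRITABLE_NODES for o in self.outputs):
            raise ValueError("gates may only write nodes 6-11")
        if any(not 0 <= i < N_NODES for i in self.inputs):
            raise ValueError("gate input node id out of range")


@dataclass
class Brain:
    gates: list[Gate]
    # lazy caches
    _packed: tuple | None = field(default=None, repr=False, compare=False)
    _full_next: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_gates(self) -> int:
        return len(self.gates)

    def active_nodes(self) -> tuple[int, ...]:
        """Nodes read or written by at least one gate."""
        s: set[int] = set()
        for g in self.gates:
            s.update(g.inputs)
            s.update(g.outputs)
        return tuple(sorted(s))

    def causal_edges(self) -> set[tuple[int, int]]:
        """Undirected coupling edges: input-output pairs of every gate
        plus pairs of co-written outputs (joint sampling correlates them)."""
        edges: set[tuple[int, int]] = set()
        for g in self.gates:
            for i in g.inputs:
                for o in g.outputs:
                    if i != o:
                        edges.add((min(i, o), max(i, o)))
            outs = sorted(set(g.outputs))
            for a in range(len(outs)):
                for b in range(a + 1, len(outs)):
                    edges.add((outs[a], outs[b]))
        return edges

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "inputs": list(g.inputs),
                    "outputs": list(g.outputs),
                    "table": g.table.tolist(),
                }
                for g in self.gates
            ]
        )

    @classmethod
    def from_json(cls, text: str) -> "Brain":
        gates = [
            Gate(
                inputs=tuple(d["inputs"]),
                outputs=tuple(d["outputs"]),
                table=np.array(d["table"], dtype=np.float64),
            )
            for d in json.loads(text)
        ]
        return cls(gates=gates)


def random_genome(
    length: int = 5000, n_seeded_codons: int = 4, seed: int | None = None
) -> Genome:
    """Uniform random genome with ``n_seeded_codons`` start codons written
    at random positions so that generation 0 already expresses gates."""
    if length < 100:
        raise ValueError("genome length must be >= 100")
    rng = np.random.default_rng(seed)
    data = bytearray(rng.integers(0, 256, size=length, dtype=np.uint8).tobytes())
    for _ in range(n_seeded_codons):
        p = int(rng.integers(length))
        data[p] = START_CODON[0]
        data[(p + 1) % length] = START_CODON[1]
    return Genome(bytes(data))


def decode_genome(genome: Genome) -> Brain:
    """Decode a genome into a brain; a pure function of the bytes."""
    L = len(genome.data)
    if L < 2:
        return Brain(gates=[])
    arr = np.frombuffer(genome.data, dtype=np.uint8)
    hits = np.nonzero(
        (arr == START_CODON[0]) & (np.roll(arr, -1) == START_CODON[1])
    )[0]
    return Brain(gates=[_parse_gate(genome, int(i) + 2) for i in hits])


def _parse_gate(genome: Genome, offset: int) -> Gate:
    pos = offset
    n_in = genome.byte(pos) % MAX_FAN + 1
    n_out = genome.byte(pos + 1) % MAX_FAN + 1
    pos += 2
    inputs = tuple(genome.byte(pos + k) % N_NODES for k in range(n_in))
    pos += n_in
    outputs = tuple(genome.byte(pos + k) % 6 + 6 for k in range(n_out))
    pos += n_out
    n_rows, n_cols = 1 << n_in, 1 << n_out
    arr = np.frombuffer(genome.data, dtype=np.uint8)
    idx = (pos + np.arange(n_rows * n_cols)) % len(arr)
    raw = arr[idx].astype(np.float64).reshape(n_rows, n_cols)
    sums = raw.sum(axis=1, keepdims=True)
    zero = sums[:, 0] == 0
    raw[zero] = 1.0
    sums[zero] = n_cols
    return Gate(inputs=inputs, outputs=outputs, table=raw / sums)


# ---------------------------------------------------------------------------
# state helpers


def pack_state(bits) -> int:
    """12-bit state index from a bit sequence, b0 least significant."""
    return int(sum(int(b) << k for k, b in enumerate(bits)))


def unpack_state(index: int) -> tuple[int, ...]:
    return tuple((index >> k) & 1 for k in range(N_NODES))


def with_sensors(state: int, sensors: SensorFrame) -> int:
    """Overwrite sensor bits b0-b5 of a state index."""
    s = 0
    for k, b in enumerate(sensors.as_bits()):
        s |= int(b) << k
    return (state & ~0b111111) | s


def step(
    brain: Brain,
    state: int,
    sensors: SensorFrame,
    rng: np.random.Generator,
) -> int:
    """One brain update: write sensors, fire all gates, OR-combine.

    Returns the state at t+1; its sensor bits are 0 until the environment
    writes them at the next step.
    """
    cur = with_sensors(state, sensors)
    nxt = 0
    for gate in brain.gates:
        row = 0
        for k, node in enumerate(gate.inputs):
            row |= ((cur >> node) & 1) << k
        word = int(rng.choice(1 << gate.n_out, p=gate.table[row]))
        for k, node in enumerate(gate.outputs):
            nxt |= ((word >> k) & 1) << node
    return nxt


# ---------------------------------------------------------------------------
# exact transition models


@dataclass
class TransitionModel:
    """Exact conditional distribution over next substates of ``nodes``.

    ``probs[s, w]`` is the probability that the writable members of the
    subset (nodes >= 6, ascending, first = least significant bit of
    ``w``) assume pattern ``w`` one step after substate ``s`` (all subset
    nodes, ascending, first = least significant bit).  Sensor members of
    the subset deterministically fall to 0, so the full subset-to-subset
    matrix is ``probs`` scattered into the columns whose sensor bits are
    all zero; ``matrix`` materializes it.
    """

    nodes: tuple[int, ...]
    probs: np.ndarray
    conditioning: str = "max-entropy"

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def writable(self) -> tuple[int, ...]:
        return tuple(v for v in self.nodes if v in WRITABLE_NODES)

    @property
    def matrix(self) -> np.ndarray:
        """Dense ``(2**n, 2**n)`` row-stochastic matrix (small n only)."""
        n = self.n
        full = np.zeros((1 << n, 1 << n))
        wpos = [k for k, v in enumerate(self.nodes) if v in WRITABLE_NODES]
        m = len(wpos)
        cols = np.zeros(1 << m, dtype=np.int64)
        for w in range(1 << m):
            col = 0
            for k, p in enumerate(wpos):
                col |= ((w >> k) & 1) << p
            cols[w] = col
        full[:, cols] = self.probs
        return full


def full_next_distribution(brain: Brain) -> np.ndarray:
    """``(4096, 64)`` array: for every full 12-bit state, the exact
    distribution of the 6 writable bits (b6 least significant) at t+1.

    Gates sample independently given the current state; outputs combine
    by OR.  Cached on the brain.
    """
    if brain._full_next is not None:
        return brain._full_next
    states = np.arange(N_STATES)
    dist = np.zeros((N_STATES, 1 << N_WRITABLE))
    dist[:, 0] = 1.0
    for gate in brain.gates:
        rows = np.zeros(N_STATES, dtype=np.int64)
        for k, node in enumerate(gate.inputs):
            rows |= ((states >> node) & 1) << k
        # map each gate output word to its mask over the 6 writable bits
        masks = np.zeros(1 << gate.n_out, dtype=np.int64)
        for word in range(1 << gate.n_out):
            m = 0
            for k, node in enumerate(gate.outputs):
                if (word >> k) & 1:
                    m |= 1 << (node - 6)
            masks[word] = m
        p_word = gate.table[rows]  # (4096, 2**n_out)
        new = np.zeros_like(dist)
        for word in range(1 << gate.n_out):
            m = masks[word]
            pw = p_word[:, word]
            if m == 0:
                new += dist * pw[:, None]
            else:
                for w in range(1 << N_WRITABLE):
                    new[:, w | m] += dist[:, w] * pw
        dist = new
    brain._full_next = dist
    return dist


def exact_transition_model(
    brain: Brain,
    subset,
    conditioning: str = "max-entropy",
) -> TransitionModel:
    """Analytic transition model for a node subset.

    Out-of-subset input nodes are handled by the conditioning rule:
    ``"max-entropy"`` averages them uniformly (the perturbational
    convention used for integrated information), ``"frozen-zero"`` pins
    them at 0.
    """
    nodes = tuple(sorted(set(int(v) for v in subset)))
    if not nodes:
        raise ValueError("subset must be non-empty")
    if any(not 0 <= v < N_NODES for v in nodes):
        raise ValueError(f"unknown node id in subset {subset!r}")
    if conditioning not in ("max-entropy", "frozen-zero"):
        raise ValueError(f"unknown conditioning rule {conditioning!r}")

    F = full_next_distribution(brain)  # (4096, 64)
    # Reshape rows to one axis per node (b0 first = last axis after C-order
    # reshape of the index?  index bit k = node k; reshape to (2,)*12 puts
    # node 11 on axis 0).  Use explicit axis mapping: axis a corresponds to
    # node 11 - a.
    T = F.reshape((2,) * N_NODES + (1 << N_WRITABLE,))
    out_axes = tuple(a for a in range(N_NODES) if (N_NODES - 1 - a) not in nodes)
    if conditioning == "max-entropy":
        R = T.mean(axis=out_axes) if out_axes else T
    else:
        idx = [slice(None)] * (N_NODES + 1)
        for a in out_axes:
            idx[a] = 0
        R = T[tuple(idx)]
    # R axes: subset nodes in descending node order, then the 64 columns.
    # Bring rows to "ascending node = least significant bit" indexing.
    n = len(nodes)
    R = R.reshape((2,) * n + (1 << N_WRITABLE,)) if n else R
    # axis k of R corresponds to nodes[n-1-k]; flattening C-order makes
    # nodes[0] the most significant bit, so reverse axes first.
    R = np.transpose(R, axes=tuple(range(n - 1, -1, -1)) + (n,))
    # now axis k corresponds to nodes[k]; flatten with nodes[0] slowest,
    # then bit-reverse via reshape in Fortran order instead: simpler to
    # flatten explicitly.
    R = R.reshape(-1, 1 << N_WRITABLE, order="F")
    # marginalize the 64 writable columns onto the subset's writable nodes
    wnodes = [v for v in nodes if v in WRITABLE_NODES]
    m = len(wnodes)
    colmap = np.zeros(1 << N_WRITABLE, dtype=np.int64)
    for w in range(1 << N_WRITABLE):
        cw = 0
        for k, v in enumerate(wnodes):
            cw |= ((w >> (v - 6)) & 1) << k
        colmap[w] = cw
    probs = np.zeros((1 << n, 1 << m))
    np.add.at(probs, (slice(None), colmap), R)
    return TransitionModel(nodes=nodes, probs=probs, conditioning=conditioning)
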