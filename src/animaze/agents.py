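"""Hand-specified fixture brains.

These synthetic connectomes are authored gate tables (not evolved and
not taken from any published agent).  They provide analytically
tractable test cases and a competent reference navigator:

* :func:`copy_gate_brain` — a single deterministic 1-in/1-out copy gate.
* :func:`mutual_copy_brain` — two nodes copying each other, the minimal
  integrated system.
* :func:`pathfinder_brain` — a hand-designed maze solver with a one-bit
  door memory, the package's stand-in for a near-optimal agent.
"""

from __future__ import annotations

import numpy as np

from .brain import Brain, Gate

__all__ = [
    "copy_gate_brain",
    "mutual_copy_brain",
    "disconnected_pairs_brain",
    "pathfinder_brain",
]


def _det_table(n_in: int, n_out: int, fn) -> np.ndarray:
    """Deterministic table from a row -> output-word function."""
    t = np.zeros((1 << n_in, 1 << n_out))
    for row in range(1 << n_in):
        t[row, fn(row)] = 1.0
    return t


def copy_gate_brain(src: int = 3, dst: int = 6) -> Brain:
    """One deterministic copy gate src -> dst."""
    return Brain(
        gates=[
            Gate(
                inputs=(src,),
                outputs=(dst,),
                table=_det_table(1, 1, lambda r: r),
            )
        ]
    )


def mutual_copy_brain(a: int = 6, b: int = 7) -> Brain:
    """Two nodes deterministically copying each other each step."""
    t = _det_table(1, 1, lambda r: r)
    return Brain(
        gates=[
            Gate(inputs=(a,), outputs=(b,), table=t.copy()),
            Gate(inputs=(b,), outputs=(a,), table=t.copy()),
        ]
    )


def disconnected_pairs_brain() -> Brain:
    """Two mutually copying pairs with no interaction between the pairs."""
    t = _det_table(1, 1, lambda r: r)
    return Brain(
        gates=[
            Gate(inputs=(6,), outputs=(7,), table=t.copy()),
            Gate(inputs=(7,), outputs=(6,), table=t.copy()),
            Gate(inputs=(8,), outputs=(9,), table=t.copy()),
            Gate(inputs=(9,), outputs=(8,), table=t.copy()),
        ]
    )


def pathfinder_brain(noise: float = 0.0) -> Brain:
    """Synthetic hand-designed navigator with a one-bit door memory.

    Strategy: node b6 latches the door bit whenever both lateral sensors
    fire (true inside every doorway, where walls flank the agent on both
    sides) and holds its value otherwise; a single firing lateral sensor
    (the maze border) flips the stored direction so a blocked sweep
    reverses instead of jamming against the border.  The motor gate
    steps forward when the front retina is clear and otherwise sidesteps
    toward the remembered door direction.

    ``noise`` mixes each deterministic motor row with that probability of
    the complementary action, giving a near-optimal but stochastic agent.
    """
    if not 0.0 <= noise < 0.5:
        raise ValueError("noise must be in [0, 0.5)")

    # memory gate: inputs (b3 door, b4 lat-left, b5 lat-right, b6 memory)
    def mem_fn(row: int) -> int:
        door = row & 1
        lat_l = (row >> 1) & 1
        lat_r = (row >> 2) & 1
        mem = (row >> 3) & 1
        if lat_l and lat_r:  # in a doorway: latch the cue
            return door
        if mem == 0 and lat_l:  # bounced off the -row border
            return 1
        if mem == 1 and lat_r:  # bounced off the +row border
            return 0
        return mem

    mem_gate = Gate(
        inputs=(3, 4, 5, 6),
        outputs=(6,),
        table=_det_table(4, 1, mem_fn),
    )

    # motor gate: inputs (b0 front, b4 lat-left, b5 lat-right, b6 memory)
    # output word bit0 -> b10, bit1 -> b11:
    # word 3 = forward, 1 = -row (left), 2 = +row (right)
    def motor_fn(row: int) -> int:
        front = row & 1
        lat_l = (row >> 1) & 1
        lat_r = (row >> 2) & 1
        mem = (row >> 3) & 1
        if not front:
            return 3
        if mem:  # remembered: door to the right (+row)
            return 2 if not lat_r else 1
        return 1 if not lat_l else 2

    table = _det_table(4, 2, motor_fn)
    if noise > 0.0:
        flip = {3: 0, 2: 1, 1: 2, 0: 3}
        noisy = np.zeros_like(table)
        for row in range(table.shape[0]):
            w = int(np.argmax(table[row]))
            noisy[row, w] = 1.0 - noise
            noisy[row, flip[w]] = noise
        table = noisy
    motor_gate = Gate(inputs=(0, 4, 5, 6), outputs=(10, 11), table=table)
    return Brain(gates=[mem_gate, motor_gate])
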