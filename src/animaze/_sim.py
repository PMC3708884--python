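"""Fast trial simulation shared by fitness evaluation and activity recording.

The inner loop (sense -> gate update -> move, 300 steps per trial, tens of
millions of trials per evolutionary history) is written as a single kernel
that numba can JIT-compile.  Without numba the identical code runs as pure
Python/numpy, so results are bit-identical either way: both paths draw from
the legacy MT19937 stream seeded per trial.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def _trials_kernel(
    wall,  # (H, W) uint8
    door_grid,  # (H, W) int8: -1 off-doorway, else the door bit
    dist,  # (H, W) int32
    d_max,  # int
    in_count,  # (G,) int64
    in_ids,  # (G, 4) int64
    out_count,  # (G,) int64
    out_ids,  # (G, 4) int64
    row_off,  # (G,) int64  offsets into cum_table
    row_len,  # (G,) int64  2**n_out per gate
    cum_table,  # flat float64 cumulative rows
    lifetime,
    start_rows,  # (T,) int64
    seeds,  # (T,) int64
    record,  # bool
    rec_out,  # (T, lifetime) int32 (or (1,1) dummy)
):
    H, W = wall.shape
    T = start_rows.shape[0]
    G = in_count.shape[0]
    d0s = np.zeros(T, dtype=np.int64)
    dTs = np.zeros(T, dtype=np.int64)
    n_exits = np.zeros(T, dtype=np.int64)
    for trial in range(T):
        np.random.seed(seeds[trial])
        r = start_rows[trial]
        c = 0
        state = 0
        n_exit = 0
        d0s[trial] = dist[r, 0]
        for t in range(lifetime):
            # --- sense (borders count as walls; front column wraps)
            fc = (c + 1) % W
            s = 0
            if wall[r, fc]:
                s |= 1
            if r == 0 or wall[r - 1, fc]:
                s |= 2
            if r == H - 1 or wall[r + 1, fc]:
                s |= 4
            if door_grid[r, c] > 0:
                s |= 8
            if r == 0 or wall[r - 1, c]:
                s |= 16
            if r == H - 1 or wall[r + 1, c]:
                s |= 32
            state = (state & 0b111111000000) | s
            if record:
                rec_out[trial, t] = state
            # --- gate update (OR-combined writes, unwritten nodes -> 0)
            nxt = 0
            for g in range(G):
                row = 0
                for k in range(in_count[g]):
                    row |= ((state >> in_ids[g, k]) & 1) << k
                base = row_off[g] + row * row_len[g]
                u = np.random.random()
                word = row_len[g] - 1
                for w in range(row_len[g]):
                    if u <= cum_table[base + w]:
                        word = w
                        break
                for k in range(out_count[g]):
                    if (word >> k) & 1:
                        nxt |= 1 << out_ids[g, k]
            state = nxt
            # --- move: (b10, b11) = (0,0) stay, (0,1) +row, (1,0) -row,
            #     (1,1) forward; wrap past the last column is an exit
            b10 = (state >> 10) & 1
            b11 = (state >> 11) & 1
            if b10 == 0 and b11 == 1:
                if r + 1 < H and not wall[r + 1, c]:
                    r += 1
            elif b10 == 1 and b11 == 0:
                if r - 1 >= 0 and not wall[r - 1, c]:
                    r -= 1
            elif b10 == 1 and b11 == 1:
                if c == W - 1:
                    c = 0
                    n_exit += 1
                elif not wall[r, c + 1]:
                    c += 1
        dTs[trial] = dist[r, c]
        n_exits[trial] = n_exit
    return d0s, dTs, n_exits


def pack_brain(brain) -> tuple:
    """Flatten a Brain's gates into the kernel's array form (cached)."""
    if brain._packed is not None:
        return brain._packed
    G = len(brain.gates)
    in_count = np.zeros(G, dtype=np.int64)
    in_ids = np.zeros((G, 4), dtype=np.int64)
    out_count = np.zeros(G, dtype=np.int64)
    out_ids = np.zeros((G, 4), dtype=np.int64)
    row_off = np.zeros(G, dtype=np.int64)
    row_len = np.zeros(G, dtype=np.int64)
    chunks = []
    off = 0
    for g, gate in enumerate(brain.gates):
        in_count[g] = gate.n_in
        in_ids[g, : gate.n_in] = gate.inputs
        out_count[g] = gate.n_out
        out_ids[g, : gate.n_out] = gate.outputs
        row_off[g] = off
        row_len[g] = 1 << gate.n_out
        cum = np.cumsum(gate.table, axis=1)
        cum[:, -1] = 1.0  # guard against fp undershoot in sampling
        chunks.append(cum.ravel())
        off += cum.size
    cum_table = (
        np.concatenate(chunks) if chunks else np.zeros(0, dtype=np.float64)
    )
    brain._packed = (
        in_count,
        in_ids,
        out_count,
        out_ids,
        row_off,
        row_len,
        cum_table,
    )
    return brain._packed


def maze_arrays(maze) -> tuple:
    """uint8 wall grid and int8 door-bit grid for the kernel (cached)."""
    cached = maze._oracle_cache.get("_arrays")
    if cached is not None:
        return cached
    wall = maze.wall.astype(np.uint8)
    door_grid = np.full((maze.height, maze.width), -1, dtype=np.int8)
    for w, c in enumerate(maze.wall_columns):
        door_grid[maze.door_rows[w], c] = maze.door_bits[w]
    maze._oracle_cache["_arrays"] = (wall, door_grid)
    return wall, door_grid


def run_trials(
    brain,
    maze,
    lifetime: int,
    start_rows: np.ndarray,
    seeds: np.ndarray,
    record: bool = False,
):
    """Run a batch of maze trials; returns (d0, dT, n_exit[, states]).

    ``states`` has shape (n_trials, lifetime): the full 12-bit state at
    every step, captured after the sensor write (the state the gates saw).
    """
    wall, door_grid = maze_arrays(maze)
    packed = pack_brain(brain)
    start_rows = np.asarray(start_rows, dtype=np.int64)
    seeds = np.asarray(seeds, dtype=np.int64)
    if record:
        rec = np.zeros((len(start_rows), lifetime), dtype=np.int32)
    else:
        rec = np.zeros((1, 1), dtype=np.int32)
    d0, dT, n_exit = _trials_kernel(
        wall,
        door_grid,
        maze.dist,
        maze.d_max,
        *packed,
        lifetime,
        start_rows,
        seeds,
        record,
        rec,
    )
    if record:
        return d0, dT, n_exit, rec
    return d0, dT, n_exit


def optimal_progress(maze, start_row: int, lifetime: int) -> int:
    """Raw progress score of a scripted walker that follows the shortest-
    distance gradient greedily for ``lifetime`` steps; defines the trial
    fitness normalizer.  Cached per (start_row, lifetime)."""
    key = ("opt", start_row, lifetime)
    if key in maze._oracle_cache:
        return maze._oracle_cache[key]
    H, W = maze.height, maze.width
    dist = maze.dist
    d_max = maze.d_max
    r, c = start_row, 0
    d0 = int(dist[r, 0])
    n_exit = 0
    for _ in range(lifetime):
        best_gain = 0
        best = None
        # forward first so it wins ties (wrapping beats dithering)
        if c == W - 1:
            gain = d_max - int(dist[r, 0])
            if gain >= best_gain:
                best_gain, best = gain, ("wrap",)
        elif not maze.wall[r, c + 1]:
            gain = int(dist[r, c]) - int(dist[r, c + 1])
            if gain > best_gain:
                best_gain, best = gain, (r, c + 1)
        for dr in (-1, 1):
            rr = r + dr
            if 0 <= rr < H and not maze.wall[rr, c]:
                gain = int(dist[r, c]) - int(dist[rr, c])
                if gain > best_gain:
                    best_gain, best = gain, (rr, c)
        if best is None:
            continue
        if best == ("wrap",):
            c = 0
            n_exit += 1
        else:
            r, c = best
    score = d0 - int(dist[r, c]) + n_exit * d_max
    maze._oracle_cache[key] = score
    return score
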