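"""Procedural maze world for the animat navigation task.

The maze is a planar grid corridor traversed left to right.  Full lateral
walls stand at regular column intervals, each pierced by a single randomly
placed door.  Every doorway carries a one-bit cue (the *door bit*): 1 when
the next wall's door lies laterally to the right (increasing row), 0
otherwise.  An agent that learns to store this bit can steer straight for
the next door instead of scanning the wall.

Geometry conventions (fixed for reproducibility):

* the agent always travels in the +column direction; "right" is +row;
* rows 0 and ``height - 1`` behave as walls for lateral sensing and
  movement (no vertical wrap);
* the corridor wraps horizontally: stepping forward past the last column
  re-enters the maze at column 0 (an *exit* event);
* all coordinates are 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

__all__ = [
    "Maze",
    "AgentPosition",
    "SensorFrame",
    "generate_maze",
    "shortest_distances",
    "sense",
    "apply_action",
    "ACTION_STAY",
    "ACTION_RIGHT",
    "ACTION_LEFT",
    "ACTION_FORWARD",
]

# Actuator pair (b10, b11) decoding.  The four actions are fixed by
# convention; only their existence is prescribed by the task.
ACTION_STAY = (0, 0)
ACTION_RIGHT = (0, 1)  # lateral +row
ACTION_LEFT = (1, 0)  # lateral -row
ACTION_FORWARD = (1, 1)


@dataclass(frozen=True)
class AgentPosition:
    row: int
    col: int
    in_doorway: bool = False


@dataclass(frozen=True)
class SensorFrame:
    """Binary sensor readout at one position.

    ``retina_front*`` report walls in the three cells ahead (straight,
    front-left = -row diagonal, front-right = +row diagonal);
    ``lateral_*`` report walls or the maze border in the two lateral
    neighbours; ``door`` is the door bit, readable only in a doorway.
    """

    retina_front: int = 0
    retina_front_left: int = 0
    retina_front_right: int = 0
    door: int = 0
    lateral_left: int = 0
    lateral_right: int = 0

    def as_bits(self) -> tuple[int, int, int, int, int, int]:
        """Sensor bits in brain-node order b0..b5."""
        return (
            self.retina_front,
            self.retina_front_left,
            self.retina_front_right,
            self.door,
            self.lateral_left,
            self.lateral_right,
        )


@dataclass
class Maze:
    height: int
    width: int
    wall_columns: list[int]
    door_rows: list[int]
    door_bits: list[int]
    seed: int | None = None
    # Derived fields, filled in by __post_init__.
    wall: np.ndarray = field(default=None, repr=False)  # (H, W) bool
    dist: np.ndarray = field(default=None, repr=False)  # (H, W) int32, -1 on walls
    d_max: int = field(default=0)
    _oracle_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.height < 2 or self.width < 2:
            raise ValueError("maze must be at least 2x2")
        wall = np.zeros((self.height, self.width), dtype=bool)
        for c, r in zip(self.wall_columns, self.door_rows):
            wall[:, c] = True
            wall[r, c] = False
        self.wall = wall
        self.dist = shortest_distances(self)
        self.d_max = int(self.dist[self.dist >= 0].max())

    # -- geometry helpers -------------------------------------------------
    def wall_index(self, col: int) -> int:
        """Index of the wall occupying ``col``, or -1."""
        try:
            return self.wall_columns.index(col)
        except ValueError:
            return -1

    def is_doorway(self, row: int, col: int) -> bool:
        w = self.wall_index(col)
        return w >= 0 and self.door_rows[w] == row

    def position(self, row: int, col: int) -> AgentPosition:
        return AgentPosition(row, col, self.is_doorway(row, col))

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "height": self.height,
                "width": self.width,
                "wall_columns": self.wall_columns,
                "door_rows": self.door_rows,
                "door_bits": self.door_bits,
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Maze":
        d = json.loads(text)
        return cls(
            height=d["height"],
            width=d["width"],
            wall_columns=list(d["wall_columns"]),
            door_rows=list(d["door_rows"]),
            door_bits=list(d["door_bits"]),
            seed=d.get("seed"),
        )


def door_bits_from_rows(door_rows: list[int]) -> list[int]:
    """Door-bit rule: 1 iff the next wall's door is strictly to the right
    (+row); the last wall has no successor and gets 0."""
    bits = []
    for w, r in enumerate(door_rows):
        if w + 1 < len(door_rows) and door_rows[w + 1] > r:
            bits.append(1)
        else:
            bits.append(0)
    return bits


def generate_maze(
    height: int = 16,
    n_walls: int = 20,
    wall_spacing: int = 4,
    seed: int | None = None,
) -> Maze:
    """Generate a random maze with ``n_walls`` single-door walls.

    Walls stand at columns ``wall_spacing, 2*wall_spacing, ...``; the
    total width is ``(n_walls + 1) * wall_spacing`` so the corridor ends
    one spacing after the last wall.  Door rows are drawn uniformly.
    """
    if height < 2 or n_walls < 1 or wall_spacing < 2:
        raise ValueError(
            "invalid maze configuration: need height >= 2, n_walls >= 1, "
            "wall_spacing >= 2"
        )
    rng = np.random.default_rng(seed)
    wall_columns = [wall_spacing * (w + 1) for w in range(n_walls)]
    door_rows = [int(rng.integers(height)) for _ in range(n_walls)]
    return Maze(
        height=height,
        width=(n_walls + 1) * wall_spacing,
        wall_columns=wall_columns,
        door_rows=door_rows,
        door_bits=door_bits_from_rows(door_rows),
        seed=seed,
    )


def shortest_distances(maze: Maze) -> np.ndarray:
    """Shortest step count from every open cell to the exit column.

    Distances follow the agent's move set — one step forward (+col) or one
    lateral step (±row) — and are computed with Dijkstra's algorithm on
    the reversed move graph, sourced at the exit column.  Wall cells are
    marked -1.
    """
    H, W = maze.height, maze.width
    if maze.wall is None:
        wall = np.zeros((H, W), dtype=bool)
        for c, r in zip(maze.wall_columns, maze.door_rows):
            wall[:, c] = True
            wall[r, c] = False
    else:
        wall = maze.wall

    n = H * W
    rows_i, cols_j = [], []

    def cid(r: int, c: int) -> int:
        return r * W + c

    for r in range(H):
        for c in range(W):
            if wall[r, c]:
                continue
            # Agent moves from (r, c); record the reversed edge target->source
            # so Dijkstra from the exit follows moves backwards.
            if c + 1 < W and not wall[r, c + 1]:
                rows_i.append(cid(r, c + 1))
                cols_j.append(cid(r, c))
            for dr in (-1, 1):
                rr = r + dr
                if 0 <= rr < H and not wall[rr, c]:
                    rows_i.append(cid(rr, c))
                    cols_j.append(cid(r, c))

    graph = csr_matrix(
        (np.ones(len(rows_i)), (rows_i, cols_j)), shape=(n, n)
    )
    sources = [cid(r, W - 1) for r in range(H) if not wall[r, W - 1]]
    d = _csgraph_dijkstra(graph, directed=True, indices=sources).min(axis=0)
    dist = np.full((H, W), -1, dtype=np.int32)
    open_cells = ~wall
    dgrid = d.reshape(H, W)
    reachable = open_cells & np.isfinite(dgrid)
    dist[reachable] = dgrid[reachable].astype(np.int32)
    return dist


def sense(maze: Maze, pos: AgentPosition) -> SensorFrame:
    """Sensor readout at ``pos``; maze borders count as walls, the front
    column wraps horizontally."""
    H, W = maze.height, maze.width
    r, c = pos.row, pos.col
    fc = (c + 1) % W

    def blocked(rr: int, cc: int) -> int:
        if rr < 0 or rr >= H:
            return 1
        return int(maze.wall[rr, cc])

    door = 0
    if maze.is_doorway(r, c):
        door = maze.door_bits[maze.wall_index(c)]
    return SensorFrame(
        retina_front=blocked(r, fc),
        retina_front_left=blocked(r - 1, fc),
        retina_front_right=blocked(r + 1, fc),
        door=door,
        lateral_left=blocked(r - 1, c),
        lateral_right=blocked(r + 1, c),
    )


def apply_action(
    maze: Maze, pos: AgentPosition, motor: tuple[int, int]
) -> tuple[AgentPosition, bool, bool]:
    """Apply one decoded action; returns ``(new_pos, collided, exited)``.

    A move into a wall or border is a collision and leaves the position
    unchanged.  A forward step from the last column wraps to column 0 of
    the same maze and counts as an exit.
    """
    H, W = maze.height, maze.width
    r, c = pos.row, pos.col
    if motor == ACTION_STAY:
        return maze.position(r, c), False, False
    if motor in (ACTION_RIGHT, ACTION_LEFT):
        rr = r + (1 if motor == ACTION_RIGHT else -1)
        if rr < 0 or rr >= H or maze.wall[rr, c]:
            return maze.position(r, c), True, False
        return maze.position(rr, c), False, False
    if motor == ACTION_FORWARD:
        if c == W - 1:
            return maze.position(r, 0), False, True
        if maze.wall[r, c + 1]:
            return maze.position(r, c), True, False
        return maze.position(r, c + 1), False, False
    raise ValueError(f"invalid motor pair {motor!r}")
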