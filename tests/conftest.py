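"""Shared fixtures: small mazes and analytically tractable brains."""

from __future__ import annotations

import numpy as np
import pytest

from animaze.agents import (
    copy_gate_brain,
    disconnected_pairs_brain,
    mutual_copy_brain,
    pathfinder_brain,
)
from animaze.brain import decode_genome, random_genome
from animaze.maze import generate_maze


@pytest.fixture(scope="session")
def small_maze():
    return generate_maze(height=8, n_walls=5, wall_spacing=4, seed=1)


@pytest.fixture(scope="session")
def default_maze():
    return generate_maze(seed=3)


@pytest.fixture(scope="session")
def corridor_maze():
    """Single far-away wall: columns 0..wall-1 form an open corridor."""
    return generate_maze(height=6, n_walls=1, wall_spacing=12, seed=0)


@pytest.fixture
def mutual_copy():
    return mutual_copy_brain()


@pytest.fixture
def copy_gate():
    return copy_gate_brain()


@pytest.fixture
def disconnected_pairs():
    return disconnected_pairs_brain()


@pytest.fixture
def pathfinder():
    return pathfinder_brain()


@pytest.fixture
def random_brains():
    """Factory: decoded random-genome brains, deterministic per index."""

    def make(i, length=2000, codons=4):
        return decode_genome(random_genome(length, codons, seed=1000 + i))

    return make
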