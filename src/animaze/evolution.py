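"""Fitness evaluation, the elitist genetic algorithm, and line-of-descent
bookkeeping.

Fitness is shortest-path based.  Every open maze cell scores
``1 - d(p)/d_max`` where ``d`` is the Dijkstra distance to the exit
column and ``d_max`` its maximum over the maze.  A trial runs the agent
for a fixed lifetime from a random row of column 0; its raw progress is

    (d(p_0) - d(p_T)) + n_exit * d_max

(the start term removes the offset of a non-zero starting score, and
``n_exit`` counts completed traversals, each worth a full ``d_max``).
Trial fitness is this progress divided by the progress of a scripted
shortest-path walker from the same start — the optimal score — clipped
to [0, 1].  The reported fitness of an agent is the geometric mean over
repeated trials.

Selection is elitist and fitness-proportional: the fittest genome is
copied byte-for-byte into the next generation; the remaining slots draw
parents with probability proportional to fitness (uniformly when all
fitnesses vanish) and mutate the copies.  Substitutions hit each site
independently at 2.5%; deletion (5%) and insertion (2.5%) are per-genome
chunk events.  Reproduction is asexual, so the line of descent of any
individual is a single chain of parent pointers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _sim
from .brain import Brain, Genome, decode_genome, random_genome
from .maze import AgentPosition, Maze, generate_maze

__all__ = [
    "OperatorRates",
    "Individual",
    "Population",
    "LodSample",
    "HistoryResult",
    "position_score",
    "trial_fitness",
    "evaluate_fitness",
    "mutate_genome",
    "next_generation",
    "run_history",
]

TRIAL_FLOOR = 1e-6  # per-trial floor inside the geometric mean


@dataclass(frozen=True)
class OperatorRates:
    """Mutation-operator rates: per-site substitution probability and
    per-genome chunk deletion / insertion probabilities."""

    substitution: float = 0.025
    deletion: float = 0.05
    insertion: float = 0.025
    chunk_min: int = 16
    chunk_max: int = 256


@dataclass
class Individual:
    genome: Genome
    fitness: float | None = None
    parent: int | None = None
    # persistent chain of (generation, genome) samples along the ancestry
    lod_chain: tuple | None = field(default=None, repr=False)


@dataclass
class Population:
    members: list[Individual]
    generation: int = 0

    def __len__(self) -> int:
        return len(self.members)

    def fittest_index(self) -> int:
        return int(
            np.argmax([m.fitness if m.fitness is not None else -1 for m in self.members])
        )


@dataclass(frozen=True)
class LodSample:
    generation: int
    genome: Genome


@dataclass
class HistoryResult:
    population: Population
    lod: list[LodSample]
    log: pd.DataFrame


# ---------------------------------------------------------------------------
# fitness


def position_score(maze: Maze, pos: AgentPosition) -> float:
    """Per-cell score 1 - d(pos)/d_max; exit cells score 1."""
    d = int(maze.dist[pos.row, pos.col])
    if d < 0:
        raise ValueError(f"position {pos} is a wall or unreachable")
    return 1.0 - d / maze.d_max


def trial_fitness(
    brain: Brain,
    maze: Maze,
    lifetime: int = 300,
    seed=None,
    start_row: int | None = None,
) -> float:
    """Normalized net progress of one trial run, in [0, 1]."""
    if lifetime < 1:
        raise ValueError("lifetime must be >= 1")
    rng = np.random.default_rng(seed)
    if start_row is None:
        start_row = int(rng.integers(maze.height))
    kseed = int(rng.integers(2**31))
    d0, dT, n_exit = _sim.run_trials(brain, maze, lifetime, [start_row], [kseed])
    raw = float(d0[0] - dT[0] + n_exit[0] * maze.d_max)
    opt = _sim.optimal_progress(maze, start_row, lifetime)
    if opt <= 0:
        return 0.0
    return float(np.clip(raw / opt, 0.0, 1.0))


def evaluate_fitness(
    brain: Brain,
    mazes,
    n_repeats: int = 10,
    lifetime: int = 300,
    seed=None,
) -> float:
    """Geometric mean of trial fitnesses over ``n_repeats`` trials per
    maze, floored per trial so a single zero does not annihilate it."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    logs = []
    for maze in mazes:
        start_rows = rng.integers(maze.height, size=n_repeats)
        seeds = rng.integers(2**31, size=n_repeats)
        d0, dT, n_exit = _sim.run_trials(brain, maze, lifetime, start_rows, seeds)
        for t in range(n_repeats):
            raw = float(d0[t] - dT[t] + n_exit[t] * maze.d_max)
            opt = _sim.optimal_progress(maze, int(start_rows[t]), lifetime)
            f = float(np.clip(raw / opt, 0.0, 1.0)) if opt > 0 else 0.0
            logs.append(np.log(max(f, TRIAL_FLOOR)))
    return float(np.exp(np.mean(logs)))


# ---------------------------------------------------------------------------
# variation and selection


def mutate_genome(
    genome: Genome,
    rates: OperatorRates,
    rng: np.random.Generator,
    min_len: int = 500,
    max_len: int = 20000,
) -> Genome:
    """Apply substitution, chunk deletion, and chunk insertion."""
    data = bytearray(genome.data)
    L = len(data)
    # per-site substitution
    n_sub = rng.binomial(L, rates.substitution)
    if n_sub:
        sites = rng.integers(L, size=n_sub)
        vals = rng.integers(0, 256, size=n_sub)
        for s, v in zip(sites, vals):
            data[s] = int(v)
    # chunk deletion (per-genome event)
    if rng.random() < rates.deletion:
        size = int(rng.integers(rates.chunk_min, rates.chunk_max + 1))
        if len(data) - size >= min_len:
            p = int(rng.integers(len(data) - size + 1))
            del data[p : p + size]
    # chunk duplication-insertion (per-genome event)
    if rng.random() < rates.insertion:
        size = int(rng.integers(rates.chunk_min, rates.chunk_max + 1))
        if len(data) + size <= max_len and len(data) >= size:
            src = int(rng.integers(len(data) - size + 1))
            chunk = data[src : src + size]
            p = int(rng.integers(len(data) + 1))
            data[p:p] = chunk
    return Genome(bytes(data))


def next_generation(
    pop: Population,
    rates: OperatorRates,
    seed=None,
    selection_mode: str = "fitness",
    min_len: int = 500,
    max_len: int = 20000,
) -> Population:
    """Produce the next generation.

    Under ``fitness`` selection, slot 0 holds a byte-identical copy of
    the elite genome and the remaining slots draw parents proportionally
    to fitness.  Under ``random`` selection (control mode) every slot
    draws a uniform parent and there is no elite copy; mutation applies
    as usual.
    """
    rng = np.random.default_rng(seed)
    n = len(pop.members)
    fits = np.array([m.fitness for m in pop.members], dtype=np.float64)
    if np.any(np.isnan(fits)):
        raise ValueError("all fitnesses must be evaluated before selection")
    new: list[Individual] = []
    if selection_mode == "fitness":
        elite = pop.fittest_index()
        total = fits.sum()
        p = fits / total if total > 0 else np.full(n, 1.0 / n)
        parents = rng.choice(n, size=n - 1, p=p)
        new.append(
            Individual(
                genome=Genome(pop.members[elite].genome.data),
                parent=elite,
                lod_chain=pop.members[elite].lod_chain,
            )
        )
    elif selection_mode == "random":
        parents = rng.integers(n, size=n)
    else:
        raise ValueError(f"unknown selection mode {selection_mode!r}")
    for pi in parents:
        pi = int(pi)
        new.append(
            Individual(
                genome=mutate_genome(
                    pop.members[pi].genome, rates, rng, min_len, max_len
                ),
                parent=pi,
                lod_chain=pop.members[pi].lod_chain,
            )
        )
    return Population(members=new, generation=pop.generation + 1)


# ---------------------------------------------------------------------------
# evolutionary histories


def _evaluate_population(pop: Population, maze: Maze, config, rng) -> None:
    for m in pop.members:
        brain = decode_genome(m.genome)
        m.fitness = evaluate_fitness(
            brain,
            [maze],
            n_repeats=config.fitness_repeats,
            lifetime=config.lifetime,
            seed=int(rng.integers(2**31)),
        )


def run_history(
    config,
    seed=None,
    initial_population: Population | None = None,
    selection_mode: str | None = None,
) -> HistoryResult:
    """Evolve a population and trace the line of descent.

    The test maze is regenerated every ``config.maze_renewal_interval``
    generations; the elite fitness is logged per generation; LOD genome
    samples are taken every ``config.lod_sample_interval`` generations
    and at the final generation.
    """
    rng = np.random.default_rng(seed)
    mode = selection_mode or config.selection_mode
    rates = config.rates

    if initial_population is None:
        pop = Population(
            members=[
                Individual(
                    genome=random_genome(
                        config.genome_length,
                        config.seeded_codons,
                        seed=int(rng.integers(2**31)),
                    )
                )
                for _ in range(config.pop_size)
            ]
        )
    else:
        pop = initial_population

    maze = None
    maze_seed = None
    rows = []
    for gen in range(config.n_generations + 1):
        if maze is None or (
            config.maze_renewal_interval
            and gen % config.maze_renewal_interval == 0
        ):
            maze_seed = int(rng.integers(2**31))
            maze = generate_maze(
                height=config.maze_height,
                n_walls=config.maze_n_walls,
                wall_spacing=config.maze_wall_spacing,
                seed=maze_seed,
            )
        _evaluate_population(pop, maze, config, rng)
        fits = np.array([m.fitness for m in pop.members])
        rows.append(
            {
                "generation": gen,
                "elite_fitness": float(fits.max()),
                "mean_fitness": float(fits.mean()),
                "maze_seed": maze_seed,
            }
        )
        sample_now = (
            gen % config.lod_sample_interval == 0
            or gen == config.n_generations
        )
        if sample_now:
            for m in pop.members:
                m.lod_chain = (m.lod_chain, LodSample(gen, m.genome))
        if gen == config.n_generations:
            break
        pop = next_generation(
            pop,
            rates,
            seed=int(rng.integers(2**31)),
            selection_mode=mode,
            min_len=config.genome_min_length,
            max_len=config.genome_max_length,
        )

    fittest = pop.members[pop.fittest_index()]
    lod: list[LodSample] = []
    chain = fittest.lod_chain
    while chain is not None:
        chain, sample = chain
        lod.append(sample)
    lod.reverse()
    return HistoryResult(population=pop, lod=lod, log=pd.DataFrame(rows))
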