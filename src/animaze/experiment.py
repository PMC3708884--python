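"""Experiment orchestration: measurement sweeps along lines of descent,
rank correlations, controls, and the minimal-complexity boundary summary.

A *sweep* evolves one or more histories, traces the line of descent
(LOD) of each final fittest agent, and measures every LOD sample on a
fresh battery of random mazes: fitness, SMMI, predictive information,
main-complex phi, and atomic phi (stochastic interaction).

The headline observation — that the *minimal* complexity at any fitness
level increases with fitness — is operationalized here as a boundary
statistic: pool the LOD samples, bin them into fitness deciles, and take
the per-decile minimum of each measure; the claim holds when that
minimum is non-decreasing across deciles (up to a stated inversion
tolerance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .brain import decode_genome
from .config import ExperimentConfig
from .evolution import HistoryResult, evaluate_fitness, run_history
from .info import main_complex, phi_atomic, predictive_info, record_activity, smmi
from .brain import exact_transition_model
from .maze import generate_maze

__all__ = [
    "SweepResult",
    "DegenerationResult",
    "measure_brain",
    "measure_lod",
    "run_sweep",
    "control_no_selection",
    "control_degeneration",
    "spearman_rho",
    "boundary_minima",
    "boundary_is_nondecreasing",
]


@dataclass
class SweepResult:
    records: pd.DataFrame  # pooled MeasureRecords with a `history` column
    spearman: list[float]  # per-history rank correlation (fitness vs phi)
    config: ExperimentConfig


@dataclass
class DegenerationResult:
    pre: pd.DataFrame
    post: pd.DataFrame
    pre_max_fitness: float
    post_max_fitness: float


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(x, y).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def measure_brain(brain, mazes, lifetime: int, seed, config: ExperimentConfig) -> dict:
    """All four complexity measures plus fitness for one agent on a maze
    battery."""
    rng = np.random.default_rng(seed)
    fitness = evaluate_fitness(
        brain, mazes, n_repeats=1, lifetime=lifetime, seed=int(rng.integers(2**31))
    )
    record = record_activity(
        brain, mazes, lifetime=lifetime, seed=int(rng.integers(2**31))
    )
    out = {
        "fitness": fitness,
        "smmi_bits": smmi(record),
        "ipred_bits": predictive_info(record),
    }
    model = exact_transition_model(brain, range(12))
    out["phi_atomic_bits"] = phi_atomic(model)
    if config.measure_phi_mc:
        mc = main_complex(brain, search=config.mip_search)
        out["phi_mc_bits"] = mc.phi
        out["mc_subset"] = ",".join(map(str, mc.subset))
    else:
        out["phi_mc_bits"] = np.nan
        out["mc_subset"] = ""
    return out


def measure_lod(
    history: HistoryResult, config: ExperimentConfig, seed
) -> pd.DataFrame:
    """Measure every LOD sample of a history on fresh 20-maze batteries."""
    rng = np.random.default_rng(seed)
    rows = []
    for sample in history.lod:
        mazes = [
            generate_maze(
                height=config.maze_height,
                n_walls=config.maze_n_walls,
                wall_spacing=config.maze_wall_spacing,
                seed=int(rng.integers(2**31)),
            )
            for _ in range(config.measure_maze_count)
        ]
        brain = decode_genome(sample.genome)
        row = {"generation": sample.generation}
        row.update(
            measure_brain(
                brain, mazes, config.lifetime, int(rng.integers(2**31)), config
            )
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _history_spearman(df: pd.DataFrame, config: ExperimentConfig) -> float:
    col = "phi_mc_bits" if config.measure_phi_mc else "phi_atomic_bits"
    if len(df) < 3:
        return float("nan")
    return spearman_rho(df["fitness"].to_numpy(), df[col].to_numpy())


def run_sweep(config: ExperimentConfig, seed=None) -> SweepResult:
    """Evolve ``config.n_histories`` histories and measure their LODs."""
    rng = np.random.default_rng(seed)
    frames, rhos = [], []
    for h in range(config.n_histories):
        history = run_history(config, seed=int(rng.integers(2**31)))
        df = measure_lod(history, config, seed=int(rng.integers(2**31)))
        df.insert(0, "history", h)
        rhos.append(_history_spearman(df, config))
        frames.append(df)
    return SweepResult(
        records=pd.concat(frames, ignore_index=True),
        spearman=rhos,
        config=config,
    )


def control_no_selection(config: ExperimentConfig, seed=None) -> SweepResult:
    """Identical pipeline with uniform parent choice and no elite copy."""
    return run_sweep(config.with_updates(selection_mode="random"), seed=seed)


def control_degeneration(
    config: ExperimentConfig, seed=None, checkpoint: HistoryResult | None = None
) -> DegenerationResult:
    """Evolve under fitness selection, then let the population drift.

    Runs ``config.n_generations`` of ordinary selection (or continues
    from ``checkpoint``), then ``config.drift_generations`` of random
    selection, and measures the LOD before and after the switch.
    """
    rng = np.random.default_rng(seed)
    if checkpoint is None:
        checkpoint = run_history(config, seed=int(rng.integers(2**31)))
    if len(checkpoint.population.members) != config.pop_size:
        raise ValueError("checkpoint population size does not match config")
    pre = measure_lod(checkpoint, config, seed=int(rng.integers(2**31)))

    drift_config = config.with_updates(
        n_generations=config.drift_generations,
        selection_mode="random",
        lod_sample_interval=min(
            config.lod_sample_interval, max(config.drift_generations, 1)
        ),
    )
    # reset LOD chains so the post-drift LOD spans only the drift phase
    for m in checkpoint.population.members:
        m.lod_chain = None
    drifted = run_history(
        drift_config,
        seed=int(rng.integers(2**31)),
        initial_population=checkpoint.population,
    )
    post = measure_lod(drifted, drift_config, seed=int(rng.integers(2**31)))
    return DegenerationResult(
        pre=pre,
        post=post,
        pre_max_fitness=float(pre["fitness"].max()),
        post_max_fitness=float(post["fitness"].tail(1).iloc[0]),
    )


# ---------------------------------------------------------------------------
# boundary statistic


def boundary_minima(
    fitness, values, n_bins: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Per-fitness-decile minima of a complexity measure.

    Bins are fitness quantile deciles (duplicate edges merged); returns
    (bin upper edges, per-bin minimum).  Bins with no points are dropped.
    """
    fitness = np.asarray(fitness, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    edges = np.unique(np.quantile(fitness, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 3:
        raise ValueError("fitness values too degenerate to bin")
    idx = np.clip(np.searchsorted(edges, fitness, side="right") - 1, 0, len(edges) - 2)
    uppers, minima = [], []
    for b in range(len(edges) - 1):
        sel = idx == b
        if sel.any():
            uppers.append(edges[b + 1])
            minima.append(values[sel].min())
    return np.array(uppers), np.array(minima)


def boundary_is_nondecreasing(minima, tol_inversions: int = 1) -> bool:
    """True when the per-decile minima rise monotonically, allowing up to
    ``tol_inversions`` strict decreases."""
    minima = np.asarray(minima, dtype=np.float64)
    return int((np.diff(minima) < -1e-12).sum()) <= tol_inversions
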