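"""Experiment configuration.

The default profile is the desk-scale study: 3 histories of 2,000
generations with populations of 100, lifetimes of 300 steps, the test
maze renewed every 100 generations, fitness from 10 trial repetitions,
and measurement on fresh 20-maze batteries every 200 generations.
``paper_profile`` returns the cluster-scale setting (126 histories x
60,000 generations x 300 agents, LOD sampled every 1,000 generations).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import yaml

from .evolution import OperatorRates


@dataclass
class ExperimentConfig:
    # evolutionary scale
    n_histories: int = 3
    n_generations: int = 2000
    pop_size: int = 100
    lifetime: int = 300
    lod_sample_interval: int = 200
    maze_renewal_interval: int = 100
    fitness_repeats: int = 10
    selection_mode: str = "fitness"
    # measurement
    measure_maze_count: int = 20
    measure_phi_mc: bool = True
    mip_search: str = "auto"
    # genome
    genome_length: int = 5000
    seeded_codons: int = 4
    genome_min_length: int = 500
    genome_max_length: int = 20000
    rates: OperatorRates = field(default_factory=OperatorRates)
    # maze geometry
    maze_height: int = 16
    maze_n_walls: int = 20
    maze_wall_spacing: int = 4
    # drift control
    drift_generations: int = 1000

    def __post_init__(self) -> None:
        for name in (
            "n_histories",
            "n_generations",
            "pop_size",
            "lifetime",
            "lod_sample_interval",
            "fitness_repeats",
            "measure_maze_count",
        ):
            if name == "n_generations":
                if getattr(self, name) < 0:
                    raise ValueError(f"{name} must be >= 0")
            elif getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.selection_mode not in ("fitness", "random"):
            raise ValueError(f"invalid selection_mode {self.selection_mode!r}")

    # -- profiles ---------------------------------------------------------
    @classmethod
    def paper_profile(cls) -> "ExperimentConfig":
        return cls(
            n_histories=126,
            n_generations=60000,
            pop_size=300,
            lod_sample_interval=1000,
        )

    def with_updates(self, **kw) -> "ExperimentConfig":
        return replace(self, **kw)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "rates" in d and isinstance(d["rates"], dict):
            d["rates"] = OperatorRates(**d["rates"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
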