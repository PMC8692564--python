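"""Particle-swarm neural architecture search over DBN depth and width.

Each particle is a point in the continuous 2-D space (layers-coordinate,
nodes-coordinate).  Velocity and position evolve by the standard PSO
update,

    v_i <- w * v_i + c1 * Rand1 * (pbest_i - x_i) + c2 * Rand2 * (gbest - x_i)
    x_i <- x_i + v_i

with fresh Rand1, Rand2 ~ U(0,1) per particle per dimension.  Positions
are decoded to integer architectures (round half away from zero, clip to
the search ranges) only when a DBN must actually be trained; fitness is
the full-stack reconstruction error of a briefly trained DBN.  An
aging-evolution flavour keeps the swarm diverse: every ``aging_period``
generations the oldest particle is re-initialized uniformly at random
(the global best record is untouched).

Defaults w=0.7298, c1=c2=1.49618 are the standard constriction-coefficient
values; search ranges default to layers in [2, 10] and nodes in
[100, 800].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dbn import Architecture, dbn_reconstruction_error, train_greedy
from .io_volume import FMRIMatrix
from .rbm import TrainConfig

__all__ = [
    "Particle",
    "SwarmConfig",
    "SwarmState",
    "decode",
    "evaluate_fitness",
    "init_swarm",
    "pso_step",
    "run_nas",
    "aggregate_runs",
]


@dataclass
class Particle:
    position: np.ndarray       # (layers-coord, nodes-coord), continuous
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_fitness: float = np.inf
    age: int = 0


@dataclass
class SwarmConfig:
    """Search settings; ranges and coefficients are all overridable."""

    n_particles: int = 30
    n_generations: int = 10
    w: float = 0.7298
    c1: float = 1.49618
    c2: float = 1.49618
    rand_seed: int = 0
    layer_range: tuple[int, int] = (2, 10)
    node_range: tuple[int, int] = (100, 800)
    fitness_epochs: int = 3
    aging_period: int = 5
    voxel_cap: int | None = 2000   # subsample voxel-samples for fitness
    fitness_train: TrainConfig | None = None

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if self.layer_range[0] > self.layer_range[1] or self.node_range[0] > self.node_range[1]:
            raise ValueError("invalid search ranges")


@dataclass
class SwarmState:
    particles: list[Particle]
    gbest_position: np.ndarray
    gbest_fitness: float
    generation: int = 0
    history: list[dict] = field(default_factory=list)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def decode(position: np.ndarray, cfg: SwarmConfig | None = None) -> Architecture:
    """Continuous position -> integer architecture.

    Rounds half away from zero, then clips into the configured ranges.
    """
    cfg = cfg or SwarmConfig()
    p = _round_half_away(np.asarray(position, dtype=float))
    layers = int(np.clip(p[0], *cfg.layer_range))
    nodes = int(np.clip(p[1], *cfg.node_range))
    return Architecture(layers, nodes, validate=False)


def evaluate_fitness(
    arch: Architecture,
    data: FMRIMatrix | np.ndarray,
    cfg: SwarmConfig,
) -> float:
    """Reconstruction-error fitness of one candidate architecture.

    Trains a DBN of ``arch`` for ``fitness_epochs`` epochs with a fixed
    seed (so the same architecture always scores identically within a
    search) and returns the full-stack reconstruction MSE.  Voxel samples
    are capped at ``voxel_cap`` (deterministic subsample) to keep the
    search affordable.
    """
    x = data.values.T if isinstance(data, FMRIMatrix) else np.asarray(data, dtype=float)
    if cfg.voxel_cap is not None and x.shape[0] > cfg.voxel_cap:
        sub_rng = np.random.default_rng(cfg.rand_seed)
        idx = sub_rng.choice(x.shape[0], size=cfg.voxel_cap, replace=False)
        x = x[np.sort(idx)]
    base = cfg.fitness_train or TrainConfig()
    tc = replace(base, epochs=cfg.fitness_epochs, seed=cfg.rand_seed)
    w = train_greedy(x, arch, tc)
    return dbn_reconstruction_error(w, x)


def _random_position(rng: np.random.Generator, cfg: SwarmConfig) -> np.ndarray:
    return np.array(
        [
            rng.uniform(cfg.layer_range[0], cfg.layer_range[1]),
            rng.uniform(cfg.node_range[0], cfg.node_range[1]),
        ]
    )


def _velocity_limits(cfg: SwarmConfig) -> np.ndarray:
    # velocities clamped to +-20% of each range
    return 0.2 * np.array(
        [
            cfg.layer_range[1] - cfg.layer_range[0],
            cfg.node_range[1] - cfg.node_range[0],
        ]
    )


class _FitnessCache:
    """Within-run memo: identical decoded architectures score identically."""

    def __init__(self, data, cfg: SwarmConfig):
        self.data = data
        self.cfg = cfg
        self._cache: dict[tuple[int, int], float] = {}
        self.n_evaluations = 0

    def __call__(self, position: np.ndarray) -> float:
        arch = decode(position, self.cfg)
        key = (arch.n_layers, arch.n_nodes)
        if key not in self._cache:
            self._cache[key] = evaluate_fitness(arch, self.data, self.cfg)
            self.n_evaluations += 1
        return self._cache[key]


def init_swarm(cfg: SwarmConfig, rng: np.random.Generator) -> SwarmState:
    """Uniform random initialization of the particle population."""
    particles = [
        Particle(
            position=(pos := _random_position(rng, cfg)),
            velocity=np.zeros(2),
            pbest_position=pos.copy(),
        )
        for _ in range(cfg.n_particles)
    ]
    return SwarmState(
        particles=particles,
        gbest_position=particles[0].position.copy(),
        gbest_fitness=np.inf,
    )


def _evaluate_swarm(state: SwarmState, fitness, cfg: SwarmConfig) -> None:
    for p in state.particles:
        f = fitness(p.position)
        if f < p.pbest_fitness:
            p.pbest_fitness = f
            p.pbest_position = p.position.copy()
        if f < state.gbest_fitness:
            state.gbest_fitness = f
            state.gbest_position = p.position.copy()


def pso_step(
    state: SwarmState,
    cfg: SwarmConfig,
    rng: np.random.Generator,
    fitness=None,
) -> SwarmState:
    """One PSO generation: move, (optionally) evaluate, update bests, age.

    Mutates ``state`` in place and returns it.  ``fitness`` is a callable
    position -> float; omit it to move particles without re-scoring
    (useful for unit-level stepping with controlled random draws).
    """
    vmax = _velocity_limits(cfg)
    for p in state.particles:
        r1 = rng.random(2)
        r2 = rng.random(2)
        p.velocity = (
            cfg.w * p.velocity
            + cfg.c1 * r1 * (p.pbest_position - p.position)
            + cfg.c2 * r2 * (state.gbest_position - p.position)
        )
        p.velocity = np.clip(p.velocity, -vmax, vmax)
        p.position = p.position + p.velocity
        p.age += 1
    if fitness is not None:
        _evaluate_swarm(state, fitness, cfg)
    state.generation += 1
    # aging evolution: periodically retire the oldest particle
    if cfg.aging_period > 0 and state.generation % cfg.aging_period == 0:
        oldest = max(state.particles, key=lambda q: q.age)
        oldest.position = _random_position(rng, cfg)
        oldest.velocity = np.zeros(2)
        oldest.pbest_position = oldest.position.copy()
        oldest.pbest_fitness = fitness(oldest.position) if fitness is not None else np.inf
        oldest.age = 0
        if oldest.pbest_fitness < state.gbest_fitness:
            state.gbest_fitness = oldest.pbest_fitness
            state.gbest_position = oldest.pbest_position.copy()
    return state


def run_nas(
    data: FMRIMatrix | np.ndarray,
    cfg: SwarmConfig,
) -> tuple[Architecture, SwarmState]:
    """Full search: init -> evaluate -> step loop over generations.

    Returns the decoded global-best architecture and the final state,
    whose ``history`` holds one record per generation (gbest fitness is
    non-increasing by construction).  Identical ``rand_seed`` reproduces
    the search bit-for-bit.
    """
    rng = np.random.default_rng(cfg.rand_seed)
    fitness = _FitnessCache(data, cfg)
    state = init_swarm(cfg, rng)
    _evaluate_swarm(state, fitness, cfg)
    state.history.append(_record(state, cfg))
    for _ in range(cfg.n_generations):
        pso_step(state, cfg, rng, fitness)
        state.history.append(_record(state, cfg))
    return decode(state.gbest_position, cfg), state


def _record(state: SwarmState, cfg: SwarmConfig) -> dict:
    arch = decode(state.gbest_position, cfg)
    return {
        "generation": state.generation,
        "gbest_fitness": float(state.gbest_fitness),
        "gbest_layers": arch.n_layers,
        "gbest_nodes": arch.n_nodes,
    }


def aggregate_runs(archs: list[Architecture]) -> Architecture:
    """Consensus architecture over repeated searches: rounded means."""
    if not archs:
        raise ValueError("no architectures to aggregate")
    layers = int(_round_half_away(np.array([np.mean([a.n_layers for a in archs])]))[0])
    nodes = int(_round_half_away(np.array([np.mean([a.n_nodes for a in archs])]))[0])
    return Architecture(layers, nodes, validate=False)
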