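"""Synthetic Trustee populations with the statistical structure of the task.

Agents embody the moral-strategy model: each agent holds a (theta, phi)
pair drawn from the interior of one strategy zone of a fitted
:class:`~trustmotives.classify.StrategyMap`, and returns tokens by the
model's exhaustive argmax plus additive Gaussian decision noise, rounded
and clipped to the feasible range.  The default population mixes the four
strategies 40% IA / 10% GA / 40% MO / 10% GR, the mixture reported for
student samples on this task family.

Blocks use exact condition counts (e.g. 20/40/20 trials for the 25/50/25
design) with a seeded stratified shuffle, and investments drawn uniformly
from {1..10}; a study reuses one investment sequence across all its blocks,
mirroring designs where investment sets are identical between contexts.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import minimum_filter

from .classify import STRATEGY_LABELS, StrategyMap
from .tasks import BehaviorRecord, GameConfig, TrialSpec
from .utility import predict_behavior_vector

__all__ = [
    "Agent",
    "PopulationSpec",
    "DEFAULT_MIXTURE",
    "sample_population",
    "generate_investment_schedule",
    "simulate_agent",
    "generate_study",
]

#: Strategy mixture of the reference population.
DEFAULT_MIXTURE: dict[str, float] = {"IA": 0.4, "GA": 0.1, "MO": 0.4, "GR": 0.1}


@dataclass(frozen=True)
class Agent:
    """A synthetic Trustee: generating strategy, MS parameters, noise level."""

    agent_id: str
    strategy: str
    theta: float
    phi: float
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGY_LABELS:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class PopulationSpec:
    """Size, strategy mixture, zone-interior margin and noise of a population."""

    n_agents: int
    proportions: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    margin: int = 3  # grid steps from any differently-labelled point
    noise_sd: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be positive")
        props = dict(self.proportions)
        if any(p < 0 for p in props.values()):
            raise ValueError("proportions must be nonnegative")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        unknown = set(props) - set(STRATEGY_LABELS)
        if unknown:
            raise ValueError(f"unknown strategies in proportions: {sorted(unknown)}")


def _seed_sequence(seed, *tags) -> np.random.SeedSequence:
    entropy = [] if seed is None else [int(seed)]
    for tag in tags:
        entropy.append(zlib.crc32(str(tag).encode()))
    return np.random.SeedSequence(entropy or None)


def largest_remainder_counts(proportions: Sequence[float], n: int) -> list[int]:
    """Integer counts summing to n, closest to ``proportions * n``."""
    raw = np.asarray(proportions, dtype=float) * n
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base.tolist()


def _interior_mask(strategy_map: StrategyMap, margin: int) -> dict[str, np.ndarray]:
    """Per-label boolean grids of points >= margin steps from other zones.

    The domain edge counts as interior (nearest-neighbor padding), so zones
    touching the boundary of the parameter space are not eaten by the margin.
    """
    sim = strategy_map.simulation_
    shape = (len(sim.theta_values), len(sim.phi_values))
    grid = strategy_map.labels_.reshape(shape)
    size = 2 * margin + 1
    interiors = {}
    for label in STRATEGY_LABELS:
        mask = (grid == label).astype(np.int8)
        interiors[label] = minimum_filter(mask, size=size, mode="nearest").astype(bool)
    return interiors


def sample_population(spec: PopulationSpec,
                      strategy_map: StrategyMap | Sequence[StrategyMap]) -> list[Agent]:
    """Draw agents from zone interiors at the spec's strategy mixture.

    Strategy counts are the largest-remainder rounding of ``proportions *
    n_agents``; (theta, phi) pairs are sampled uniformly (with replacement)
    from the grid points of the target zone that are at least ``margin``
    grid steps from any differently-labelled point.  Deterministic given
    ``spec.seed``.

    A sequence of maps (one per block of a study) restricts sampling to the
    intersection of the zone interiors: zone boundaries move with the
    multiplier set, and an agent's generating strategy is only well defined
    in every context if its parameters fall in that strategy's zone of each
    context's map.
    """
    maps = ([strategy_map] if isinstance(strategy_map, StrategyMap)
            else list(strategy_map))
    shapes = {(len(m.simulation_.theta_values), len(m.simulation_.phi_values))
              for m in maps}
    if len(shapes) != 1:
        raise ValueError("all maps must share the same grid resolution")
    rng = np.random.default_rng(_seed_sequence(spec.seed, "population"))
    labels = list(spec.proportions)
    counts = largest_remainder_counts([spec.proportions[l] for l in labels],
                                      spec.n_agents)
    interiors_by_map = [_interior_mask(m, spec.margin) for m in maps]
    interiors = {
        label: np.logical_and.reduce([im[label] for im in interiors_by_map])
        for label in STRATEGY_LABELS
    }
    points = maps[0].simulation_.points
    agents: list[Agent] = []
    serial = 0
    for label, count in zip(labels, counts):
        if count == 0:
            continue
        candidates = np.flatnonzero(interiors[label].ravel())
        if candidates.size == 0:
            raise ValueError(
                f"zone {label} is empty after applying margin={spec.margin}"
            )
        picks = rng.choice(candidates, size=count, replace=True)
        for p in picks:
            agents.append(
                Agent(
                    agent_id=f"agent{serial:03d}",
                    strategy=label,
                    theta=float(points[p, 0]),
                    phi=float(points[p, 1]),
                    noise_sd=spec.noise_sd,
                )
            )
            serial += 1
    return agents


def generate_investment_schedule(
    config: GameConfig,
    seed=None,
    investments: Sequence[int] | None = None,
    block_id: str = "",
) -> list[TrialSpec]:
    """A block's trials: exact condition counts, seeded stratified shuffle.

    Investments are drawn uniformly from {1..10} unless an explicit
    ``investments`` sequence (length ``n_trials``) is supplied, which lets a
    study reuse the same investment set across blocks.
    """
    rng = np.random.default_rng(_seed_sequence(seed, "schedule", block_id))
    counts = config.trial_counts()
    condition_idx = np.repeat(np.arange(len(config.conditions)), counts)
    rng.shuffle(condition_idx)
    if investments is None:
        investments = rng.integers(1, 11, size=config.n_trials)
    investments = np.asarray(investments, dtype=int)
    if len(investments) != config.n_trials:
        raise ValueError("investments must have one entry per trial")
    return [
        TrialSpec(
            investment=int(inv),
            true_multiplier=config.conditions[c].true_multiplier,
            believed_multiplier=config.conditions[c].believed_multiplier,
            trial_index=i,
            block_id=block_id,
        )
        for i, (inv, c) in enumerate(zip(investments, condition_idx))
    ]


def simulate_agent(agent: Agent, schedule: Sequence[TrialSpec],
                   config: GameConfig, seed=None) -> BehaviorRecord:
    """One agent's returns on a schedule: MS argmax plus rounded token noise."""
    preds = predict_behavior_vector(
        "MS", (agent.theta, agent.phi), schedule, config.endowment
    )
    totals = np.array([t.investment * t.true_multiplier for t in schedule])
    if agent.noise_sd > 0:
        rng = np.random.default_rng(_seed_sequence(seed, "returns", agent.agent_id))
        noise = rng.normal(0.0, agent.noise_sd, size=len(schedule))
        returns = np.clip(np.rint(preds + noise), 0, totals).astype(int)
    else:
        returns = preds.astype(int)
    block = schedule[0].block_id if schedule else ""
    return BehaviorRecord(agent.agent_id, block, list(schedule), returns)


def generate_study(
    spec: PopulationSpec,
    configs: Sequence[GameConfig],
    seed=None,
    strategy_map: StrategyMap | None = None,
) -> tuple[list[BehaviorRecord], pd.DataFrame]:
    """Simulate one agent population through every block of a study.

    The same agents play every block (enabling test-retest and transition
    analyses) on a shared investment sequence with per-block condition
    order.  Agents are sampled from the intersection of the zone interiors
    of every block's strategy map, so each agent's generating strategy is
    well defined in all contexts; ``strategy_map`` may supply those maps
    (one per config, or a single shared map) and defaults to building one
    per distinct config.  Returns the behavior records plus a ground-truth
    table (agent, strategy, theta, phi, noise_sd).
    """
    if not configs:
        raise ValueError("need at least one game config")
    if strategy_map is None:
        cache: dict[tuple, StrategyMap] = {}
        maps = []
        for config in configs:
            key = tuple(
                (c.true_multiplier, c.believed_multiplier, c.proportion)
                for c in config.conditions
            )
            if key not in cache:
                cache[key] = StrategyMap(config=config).fit()
            maps.append(cache[key])
    elif isinstance(strategy_map, StrategyMap):
        maps = [strategy_map]
    else:
        maps = list(strategy_map)
    spec = PopulationSpec(
        spec.n_agents, dict(spec.proportions), spec.margin, spec.noise_sd,
        spec.seed if spec.seed is not None else seed,
    )
    agents = sample_population(spec, maps)
    rng = np.random.default_rng(_seed_sequence(seed, "investments"))
    n_trials = configs[0].n_trials
    if any(c.n_trials != n_trials for c in configs):
        raise ValueError("all blocks must share n_trials to reuse investments")
    investments = rng.integers(1, 11, size=n_trials)
    records: list[BehaviorRecord] = []
    for b, config in enumerate(configs):
        block_id = f"block{b}"
        schedule = generate_investment_schedule(
            config, seed=seed, investments=investments, block_id=block_id
        )
        for agent in agents:
            child = int(_seed_sequence(seed, "agent", agent.agent_id, b)
                        .generate_state(1)[0])
            records.append(simulate_agent(agent, schedule, config, seed=child))
    truth = pd.DataFrame(
        {
            "agent_id": [a.agent_id for a in agents],
            "strategy": [a.strategy for a in agents],
            "theta": [a.theta for a in agents],
            "phi": [a.phi for a in agents],
            "noise_sd": [a.noise_sd for a in agents],
        }
    )
    return records, truth
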