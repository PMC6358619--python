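"""Full simulation runs: wiring the environment to the demography loop.

A run holds a fixed-capacity population of asexual individuals for
``t_max`` steps in a fluctuating environment, recording population-mean
trajectories at a fixed stride, full individual panels for the final few
steps (used for the mismatch~age senescence regression), and an end-of-run
snapshot.  Everything is driven by one integer seed: the environment and
the demography consume independent child streams of it, so the same
environment realisation can be replayed against different life-history
variants.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .agents import MutationParams, Population
from .environment import EnvParams, generate_series
from .lifecycle import LifeHistoryParams, step_population

__all__ = ["SimConfig", "RunResult", "PAPER_U_INIT", "PAPER_R_INIT",
           "initialize_population", "run", "run_grid"]

logger = logging.getLogger(__name__)

#: standard grid of founding updating-schedule values (log-spaced, 10^-2..10^1)
PAPER_U_INIT = (0.0100, 0.0316, 0.1000, 0.3162, 1.0000, 3.1623, 10.000)
#: standard grid of founding reproductive-effort values
PAPER_R_INIT = (1.0, 4.0, 7.0)


@dataclass(frozen=True)
class SimConfig:
    """Complete parameterisation of one run."""

    N: int = 2000
    t_max: int = 50_000
    env: EnvParams = field(default_factory=EnvParams)
    epsilon: float = 0.0
    life: LifeHistoryParams = field(default_factory=LifeHistoryParams)
    mutation: MutationParams = field(default_factory=MutationParams)
    u_init: float = 1.0
    r_init: float = 4.0
    seed: int = 0
    record_every: int = 50
    record_last: int = 10
    env_start: Optional[float] = None  # None -> stationary draw for E_0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("population capacity N must be >= 1")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        if self.u_init <= 0 or self.r_init <= 0:
            raise ValueError("initial genotype values must be positive")
        if self.epsilon < 0:
            raise ValueError("update error sd epsilon must be non-negative")
        if self.record_every < 1 or self.record_last < 1:
            raise ValueError("recording strides must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if isinstance(d.get("env"), dict):
            d["env"] = EnvParams(**d["env"])
        if isinstance(d.get("life"), dict):
            d["life"] = LifeHistoryParams(**d["life"])
        if isinstance(d.get("mutation"), dict):
            d["mutation"] = MutationParams(**d["mutation"])
        return cls(**d)


@dataclass
class RunResult:
    """Everything recorded from one run.

    ``final_snapshot`` is the reproduction-time cross-section of the
    population at the last completed step (columns id, age, u, r, x, m,
    updated); ``trajectory`` holds population means at the recording
    stride; ``last_steps_panel`` pools the individual records of the final
    ``record_last`` steps.
    """

    status: str
    config: SimConfig
    trajectory: pd.DataFrame
    last_steps_panel: pd.DataFrame
    final_snapshot: Optional[pd.DataFrame]
    t_final: int

    @property
    def seed(self) -> int:
        return self.config.seed


def initialize_population(config: SimConfig) -> Population:
    """Monomorphic founders: N newborns with genotype (u_init, r_init)."""
    return Population.founders(config.N, config.u_init, config.r_init)


def _outcome_frame(t: int, outcome) -> pd.DataFrame:
    return pd.DataFrame({
        "t": t, "id": outcome.ids, "age": outcome.age, "u": outcome.u,
        "r": outcome.r, "x": outcome.x, "m": outcome.mismatch,
        "updated": outcome.updated_flags, "clutch": outcome.clutch_sizes,
        "died": outcome.death_flags,
    })


def run(config: SimConfig, log_every: int = 0) -> RunResult:
    """Execute one full simulation.

    The run terminates early with ``status="extinct"`` if the population
    size hits zero; extinction is a reportable outcome, not an error.
    Identical configs (seed included) produce identical results.
    """
    ss = np.random.SeedSequence(config.seed)
    env_ss, demo_ss = ss.spawn(2)
    env_rng = np.random.default_rng(env_ss)
    demo_rng = np.random.default_rng(demo_ss)

    env = generate_series(config.env, config.t_max, rng=env_rng,
                          e0=config.env_start)
    pop = initialize_population(config)

    traj_rows: list[dict] = []
    panel_start = config.t_max - config.record_last + 1
    panel_frames: list[pd.DataFrame] = []
    status, t_final = "completed", config.t_max
    last_outcome = None

    for t in range(1, config.t_max + 1):
        pop, outcome = step_population(pop, env[t], config.life,
                                       config.epsilon, config.mutation,
                                       demo_rng)
        last_outcome = (t, outcome)
        if t % config.record_every == 0 or t == config.t_max or outcome.extinct:
            traj_rows.append({
                "t": t,
                "mean_u": float(outcome.u.mean()),
                "mean_r": float(outcome.r.mean()),
                "mean_m": float(outcome.mismatch.mean()),
                "mean_age": float(outcome.age.mean()),
                "update_freq": float(outcome.updated_flags.mean()),
                "pop_size": pop.size,
            })
        if t >= panel_start:
            panel_frames.append(_outcome_frame(t, outcome))
        if log_every and t % log_every == 0:
            logger.info("t=%d mean_u=%.4g mean_r=%.4g mean_m=%.4g", t,
                        outcome.u.mean(), outcome.r.mean(),
                        outcome.mismatch.mean())
        if outcome.extinct:
            status, t_final = "extinct", t
            logger.warning("population extinct at step %d", t)
            break

    trajectory = pd.DataFrame(traj_rows)
    panel = (pd.concat(panel_frames, ignore_index=True)
             if panel_frames else _outcome_frame(0, last_outcome[1]).iloc[0:0])
    if status == "completed":
        final_snapshot = _outcome_frame(*last_outcome)
    else:
        final_snapshot = None
    return RunResult(status=status, config=config, trajectory=trajectory,
                     last_steps_panel=panel, final_snapshot=final_snapshot,
                     t_final=t_final)


def _child_seed(master_seed: int, index: int) -> int:
    """Counter-based per-run seed, independent across indices, < 2**31."""
    return int(np.random.SeedSequence((master_seed, index))
               .generate_state(1)[0] % (2**31))


def run_grid(
    base: SimConfig,
    u_inits: Sequence[float] = PAPER_U_INIT,
    r_inits: Sequence[float] = PAPER_R_INIT,
    seeds: Sequence[int] | int = 1,
) -> list[RunResult]:
    """Run one simulation per (u_init, r_init, replicate) grid cell.

    ``seeds`` may be an explicit sequence of replicate labels or an integer
    number of replicates.  Each cell gets its own statistically independent
    RNG stream derived from ``base.seed`` and the cell index, so the grid
    is reproducible as a whole.  With the default grids this is 7 x 3 runs
    per replicate.
    """
    if not len(u_inits) or not len(r_inits):
        raise ValueError("initial-value grids must be non-empty")
    if isinstance(seeds, int):
        seeds = range(seeds)
    results = []
    idx = 0
    for rep in seeds:
        for u0 in u_inits:
            for r0 in r_inits:
                cfg = replace(base, u_init=float(u0), r_init=float(r0),
                              seed=_child_seed(base.seed, idx))
                logger.info("grid run %d: u_init=%g r_init=%g rep=%s",
                            idx, u0, r0, rep)
                results.append(run(cfg))
                idx += 1
    return results
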