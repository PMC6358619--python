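"""One time step of demography: fecundity, mortality, recruitment.

Within each step, phenotype updating is followed by reproduction, then
mortality, then recruitment of newborns into the vacancies left by deaths.
Expected clutch size

    c = min(r_cap, r) * exp(-m^2) * (1 - kappa * U)

combines reproductive effort r (capped), the mismatch penalty, and the
fecundity cost kappa paid by individuals that updated this step (U = 1).
Mortality is alpha0 + m + rho * r^2, clamped to [0, 1]: a baseline, the
mismatch, and a quadratic cost of reproductive effort.

``mismatch_mode`` switches the robustness variants: "both" (main model),
"mortality_only" (mismatch removed from fecundity), "fecundity_only"
(mismatch removed from mortality), and "none" (removed from both; used for
neutrality controls).  Clutch sizes act as continuous sampling weights in a
recruitment lottery, not integer offspring counts.

By default the lottery draws parents from those that survived the mortality
phase (clutch weights are still computed before death, so reproduction
precedes mortality); if every adult dies in a step the population goes
extinct, which is a reachable outcome at a high cost of reproduction.  Set
``recruit_pool="all_parents"`` to let dead parents of the current step
contribute recruits, in which case a positive total clutch weight always
refills the population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .agents import NEWBORN, MutationParams, Population, mutate_genotype, \
    update_probability

__all__ = [
    "LifeHistoryParams",
    "StepOutcome",
    "clutch_size",
    "mortality_prob",
    "recruit",
    "step_population",
    "MISMATCH_MODES",
]

MISMATCH_MODES = ("both", "mortality_only", "fecundity_only", "none")
RECRUIT_POOLS = ("survivors", "all_parents")


@dataclass(frozen=True)
class LifeHistoryParams:
    """Costs and switches of the life cycle.

    kappa : fecundity cost of performing an update, in [0, 1] (default 0.4)
    rho : coefficient of the r^2 mortality cost of reproduction (default 0.01)
    alpha0 : baseline per-step mortality probability (default 0.05)
    r_cap : upper bound on realised reproductive effort in the clutch (10)
    mismatch_mode : which vital rates the mismatch penalises
    recruit_pool : who is eligible as a recruit source after mortality
    """

    kappa: float = 0.4
    rho: float = 0.01
    alpha0: float = 0.05
    r_cap: float = 10.0
    mismatch_mode: str = "both"
    recruit_pool: str = "survivors"

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must be in [0, 1]")
        if self.rho < 0:
            raise ValueError("rho must be non-negative")
        if not 0.0 <= self.alpha0 <= 1.0:
            raise ValueError("alpha0 must be in [0, 1]")
        if self.mismatch_mode not in MISMATCH_MODES:
            raise ValueError(f"mismatch_mode must be one of {MISMATCH_MODES}")
        if self.recruit_pool not in RECRUIT_POOLS:
            raise ValueError(f"recruit_pool must be one of {RECRUIT_POOLS}")


@dataclass
class StepOutcome:
    """Per-individual results of one step, recorded at reproduction time."""

    ids: np.ndarray
    age: np.ndarray
    u: np.ndarray
    r: np.ndarray
    x: np.ndarray
    mismatch: np.ndarray
    updated_flags: np.ndarray
    clutch_sizes: np.ndarray
    death_flags: np.ndarray
    n_recruits: int
    extinct: bool


def clutch_size(r, m, updated, kappa=0.4, r_cap=10.0, mode="both"):
    """Expected clutch size min(r_cap, r) * exp(-m^2) * (1 - kappa*updated).

    In the ``mortality_only`` and ``none`` variants the mismatch term is
    dropped (mismatch then has no effect on fecundity); the updating cost
    is retained in every variant.  Vectorised over all arguments.
    """
    base = np.minimum(r_cap, r) * (1.0 - kappa * np.asarray(updated))
    if mode in ("both", "fecundity_only"):
        base = base * np.exp(-np.square(np.asarray(m, dtype=float)))
    out = base
    return float(out) if np.isscalar(r) and np.isscalar(m) else out


def mortality_prob(m, r, rho=0.01, alpha0=0.05, mode="both"):
    """Per-step death probability clamp(alpha0 + m + rho*r^2, 0, 1).

    In the ``fecundity_only`` and ``none`` variants the mismatch term is
    dropped (mismatch then has no effect on survival).  The printed sum can
    exceed 1, so it is clamped to remain a probability.
    """
    p = alpha0 + rho * np.square(np.asarray(r, dtype=float))
    if mode in ("both", "mortality_only"):
        p = p + np.asarray(m, dtype=float)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if np.isscalar(m) and np.isscalar(r) else p


def recruit(
    vacancies: int,
    pop: Population,
    clutch_sizes: np.ndarray,
    mutation: MutationParams,
    rng: np.random.Generator,
    eligible: np.ndarray | None = None,
):
    """Draw newborns to fill vacancies, weighted by expected clutch size.

    Parents are sampled with replacement with probability proportional to
    their clutch size (restricted to ``eligible`` if given).  Each draw
    yields one newborn with an independently mutated genotype, age 0, the
    newborn T_u sentinel, and the parent's phenotype (irrelevant in
    practice: newborns update with probability 1 before reproducing).
    Returns parallel arrays ``(u, r, x, parent_idx)``; all empty when the
    total eligible clutch weight is 0, in which case vacancies stay
    unfilled and the population may shrink.
    """
    if vacancies < 0:
        raise ValueError("vacancies must be non-negative")
    empty = (np.empty(0), np.empty(0), np.empty(0), np.empty(0, dtype=np.int64))
    if vacancies == 0:
        return empty
    weights = np.asarray(clutch_sizes, dtype=float)
    if np.any(weights < 0):
        raise ValueError("clutch sizes must be non-negative")
    if eligible is not None:
        weights = np.where(eligible, weights, 0.0)
    total = weights.sum()
    if total <= 0.0:
        return empty
    # multinomial draw with replacement by inverting the cumulative weights
    cdf = np.cumsum(weights)
    parent_idx = np.searchsorted(cdf, rng.random(vacancies) * cdf[-1],
                                 side="right")
    parent_idx = np.minimum(parent_idx, pop.size - 1)
    u_child, r_child = mutate_genotype(pop.u[parent_idx], pop.r[parent_idx],
                                       mutation, rng, size=vacancies)
    return (np.asarray(u_child, dtype=float), np.asarray(r_child, dtype=float),
            pop.x[parent_idx].copy(), parent_idx.astype(np.int64))


def step_population(
    pop: Population,
    E_t: float,
    life: LifeHistoryParams,
    epsilon: float,
    mutation: MutationParams,
    rng: np.random.Generator,
) -> tuple[Population, StepOutcome]:
    """Advance the population by one time step.

    Order of events: (1) ages and times-since-update increment; (2) each
    individual updates its phenotype with probability 1 - e^(-u*T_u)
    (newborns with probability 1), updated phenotypes become E_t + N(0,
    epsilon); (3) mismatch is measured against E_t; (4) expected clutch
    sizes; (5) Bernoulli deaths; (6) recruits fill the vacancies.  Returns
    the next population and the full per-individual outcome record taken at
    reproduction time (so it includes individuals that die in phase 5).
    """
    if pop.size == 0:
        raise ValueError("cannot step an extinct population")
    n = pop.size

    # (1) ageing
    age = pop.age + 1
    newborn = pop.T_u == NEWBORN
    T_u = np.where(newborn, NEWBORN, pop.T_u + 1)

    # (2) stochastic updating
    p_upd = update_probability(pop.u, T_u)
    updated = rng.random(n) < p_upd
    x = pop.x.copy()
    n_upd = int(updated.sum())
    if n_upd:
        err = rng.normal(0.0, epsilon, size=n_upd) if epsilon > 0 else 0.0
        x[updated] = E_t + err
    T_u = np.where(updated, 0, T_u)

    # (3)-(5) vital rates
    m = np.abs(x - E_t)
    c = clutch_size(pop.r, m, updated.astype(float), kappa=life.kappa,
                    r_cap=life.r_cap, mode=life.mismatch_mode)
    p_death = mortality_prob(m, pop.r, rho=life.rho, alpha0=life.alpha0,
                             mode=life.mismatch_mode)
    died = rng.random(n) < p_death

    # (6) recruitment into vacancies
    vacancies = int(died.sum())
    eligible = ~died if life.recruit_pool == "survivors" else None
    interim = Population(u=pop.u, r=pop.r, x=x, T_u=T_u, age=age, ids=pop.ids,
                         capacity=pop.capacity, next_id=pop.next_id)
    u_new, r_new, x_new, _ = recruit(vacancies, interim, c, mutation, rng,
                                     eligible=eligible)
    k = len(u_new)

    alive = ~died
    next_ids = np.arange(pop.next_id, pop.next_id + k, dtype=np.int64)
    new_pop = Population(
        u=np.concatenate([pop.u[alive], u_new]),
        r=np.concatenate([pop.r[alive], r_new]),
        x=np.concatenate([x[alive], x_new]),
        T_u=np.concatenate([T_u[alive], np.full(k, NEWBORN, dtype=np.int64)]),
        age=np.concatenate([age[alive], np.zeros(k, dtype=np.int64)]),
        ids=np.concatenate([pop.ids[alive], next_ids]),
        capacity=pop.capacity,
        next_id=pop.next_id + k,
    )
    outcome = StepOutcome(
        ids=pop.ids.copy(), age=age, u=pop.u.copy(), r=pop.r.copy(), x=x,
        mismatch=m, updated_flags=updated.astype(np.int8),
        clutch_sizes=np.asarray(c, dtype=float),
        death_flags=died.astype(np.int8), n_recruits=k,
        extinct=new_pop.size == 0,
    )
    return new_pop, outcome
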