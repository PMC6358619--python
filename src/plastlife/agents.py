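"""Individuals, phenotype updating, mismatch, and inheritance.

Each individual carries a two-locus genotype: ``u``, the updating schedule
(how steeply the per-step probability of refreshing the phenotype rises with
the time ``T_u`` since the last refresh), and ``r``, the reproductive
effort.  Both are positive reals inherited asexually with multiplicative
log-normal mutation.  The phenotype ``x`` is compared against the current
environmental optimum; the absolute difference is the mismatch that
penalises fecundity and survival.

Newborns have no defined ``T_u``; they are flagged with the sentinel
:data:`NEWBORN` and perform their first update with probability 1 regardless
of ``u``.  Note that the second argument of every N(mu, .) here is a
standard deviation (MATLAB ``normrnd`` convention), not a variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NEWBORN",
    "Individual",
    "MutationParams",
    "Population",
    "update_probability",
    "apply_update",
    "mismatch",
    "mutate_genotype",
]

#: sentinel value of T_u marking a newborn whose time-since-update is undefined
NEWBORN = -1


@dataclass
class Individual:
    """A single organism: genotype (u, r), phenotype x, and bookkeeping."""

    id: int
    u: float
    r: float
    x: float = 0.0
    T_u: int = NEWBORN
    age: int = 0

    def __post_init__(self) -> None:
        if self.u <= 0 or self.r <= 0:
            raise ValueError("genotype values u and r must be positive")
        if self.age < 0:
            raise ValueError("age must be non-negative")
        if self.T_u < NEWBORN:
            raise ValueError("T_u must be >= 0 or the newborn sentinel")

    def to_record(self) -> dict:
        return {"id": self.id, "age": self.age, "u": self.u, "r": self.r,
                "x": self.x, "T_u": self.T_u}


@dataclass(frozen=True)
class MutationParams:
    """Scale of the additive log-scale mutation, sd of mu in e^(log g + mu)."""

    sd: float = 0.01

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("mutation sd must be non-negative")


def update_probability(u, T_u):
    """Per-step probability of a phenotype update, 1 - exp(-u * T_u).

    ``T_u`` equal to :data:`NEWBORN` yields probability 1 exactly (newborns
    always update).  Accepts scalars or arrays; with arrays the sentinel is
    handled element-wise.
    """
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr <= 0):
        raise ValueError("updating gene u must be positive")
    t_arr = np.asarray(T_u)
    if np.any((t_arr < 0) & (t_arr != NEWBORN)):
        raise ValueError("T_u must be >= 0 or the newborn sentinel")
    prob = np.where(t_arr == NEWBORN, 1.0, -np.expm1(-u_arr * np.maximum(t_arr, 0)))
    if np.isscalar(T_u) and np.isscalar(u):
        return float(prob)
    return prob


def mismatch(x, E_t):
    """Phenotypic mismatch m = |x - E_t| (element-wise for arrays)."""
    return np.abs(np.asarray(x, dtype=float) - E_t) if not np.isscalar(x) \
        else abs(x - E_t)


def apply_update(individual: Individual, E_t: float, epsilon: float,
                 rng: np.random.Generator) -> int:
    """Refresh an individual's phenotype to the current optimum plus error.

    Sets ``x = E_t + N(0, epsilon)`` (exactly ``E_t`` when epsilon is 0) and
    resets ``T_u`` to 0.  Returns 1, the updated-flag value.
    """
    if epsilon < 0:
        raise ValueError("update error sd epsilon must be non-negative")
    err = float(rng.normal(0.0, epsilon)) if epsilon > 0 else 0.0
    individual.x = E_t + err
    individual.T_u = 0
    return 1


def mutate_genotype(u_parent, r_parent, params: MutationParams,
                    rng: np.random.Generator, size=None):
    """Mutated offspring genotype: each locus multiplied by e^mu, mu ~ N(0, sd).

    The two loci mutate independently.  Vectorised: pass ``size`` to draw a
    batch of offspring from scalar or array parents.
    """
    if np.any(np.asarray(u_parent) <= 0) or np.any(np.asarray(r_parent) <= 0):
        raise ValueError("parental genotype values must be positive")
    if size is None and np.ndim(u_parent) > 0:
        size = np.shape(u_parent)  # independent draw per parent
    if params.sd == 0:
        if size is None:
            return u_parent, r_parent
        return (np.broadcast_to(u_parent, size).copy(),
                np.broadcast_to(r_parent, size).copy())
    mu_u = rng.normal(0.0, params.sd, size=size)
    mu_r = rng.normal(0.0, params.sd, size=size)
    u_child = u_parent * np.exp(mu_u)
    r_child = r_parent * np.exp(mu_r)
    if size is None and np.isscalar(u_parent):
        return float(u_child), float(r_child)
    return u_child, r_child


@dataclass
class Population:
    """Fixed-capacity population stored as parallel arrays.

    The struct-of-arrays layout keeps the per-step demography vectorised;
    :meth:`individuals` materialises :class:`Individual` objects when the
    record-level view is needed.
    """

    u: np.ndarray
    r: np.ndarray
    x: np.ndarray
    T_u: np.ndarray
    age: np.ndarray
    ids: np.ndarray
    capacity: int
    next_id: int = 0

    @classmethod
    def founders(cls, n: int, u_init: float, r_init: float,
                 capacity: int | None = None) -> "Population":
        """A monomorphic founding population of newborns."""
        if n < 1:
            raise ValueError("population must have at least one individual")
        if u_init <= 0 or r_init <= 0:
            raise ValueError("initial genotype values must be positive")
        return cls(
            u=np.full(n, float(u_init)),
            r=np.full(n, float(r_init)),
            x=np.zeros(n),
            T_u=np.full(n, NEWBORN, dtype=np.int64),
            age=np.zeros(n, dtype=np.int64),
            ids=np.arange(n, dtype=np.int64),
            capacity=capacity if capacity is not None else n,
            next_id=n,
        )

    @property
    def size(self) -> int:
        return len(self.u)

    def individuals(self) -> list[Individual]:
        return [Individual(id=int(i), u=float(u), r=float(r), x=float(x),
                           T_u=int(t), age=int(a))
                for i, u, r, x, t, a
                in zip(self.ids, self.u, self.r, self.x, self.T_u, self.age)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"id": self.ids, "age": self.age, "u": self.u,
                             "r": self.r, "x": self.x, "T_u": self.T_u})
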