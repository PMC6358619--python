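"""Fluctuating environmental optimum.

The environment is a single scalar, the phenotype that would have zero
mismatch at time ``t``.  The main process is an AR(1) recursion

    E_t = p * E_{t-1} + (1 - p) * zeta_t,    zeta_t ~ N(0, 1)

whose autocorrelation is controlled by ``p``.  Because the innovation is
scaled by ``(1 - p)``, changing ``p`` also changes the stationary variance,
(1-p)/(1+p); an ARMA(2,1) generator is therefore provided as well, built by
targeting a lag-1 autocorrelation and a stationary variance independently,
so that autocorrelation effects can be separated from variance effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.signal import lfilter
from statsmodels.tsa.arima_process import arma_acovf, arma_generate_sample

__all__ = [
    "EnvParams",
    "EnvironmentSeries",
    "step_ar1",
    "generate_series",
    "stationary_moments_ar1",
    "arma21_from_target",
    "lag1_autocorr",
]

#: steps discarded before an ARMA(2,1) series is recorded, so the recorded
#: part is effectively a draw from the stationary distribution
_ARMA_BURNIN = 1000


@dataclass(frozen=True)
class EnvParams:
    """Parameters of the environment process.

    kind
        ``"ar1"`` or ``"arma21"``.
    p
        AR(1) autocorrelation weight, in [0, 1).  Ignored for ARMA(2,1).
    ar1, ar2, ma1
        ARMA(2,1) coefficients in the convention
        ``E_t = ar1*E_{t-1} + ar2*E_{t-2} + eta_t + ma1*eta_{t-1}``.
    innovation_sd
        Standard deviation of the innovation (``zeta`` for AR(1), ``eta``
        for ARMA).
    """

    kind: str = "ar1"
    p: float = 0.5
    ar1: float = 0.0
    ar2: float = 0.0
    ma1: float = 0.0
    innovation_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("ar1", "arma21"):
            raise ValueError(f"unknown environment kind {self.kind!r}")
        if self.innovation_sd <= 0:
            raise ValueError("innovation_sd must be positive")
        if self.kind == "ar1":
            if not 0.0 <= self.p < 1.0:
                raise ValueError(f"AR(1) requires 0 <= p < 1, got p={self.p}")
        else:
            # stationarity: roots of 1 - ar1 z - ar2 z^2 outside unit circle
            ar_roots = np.roots([-self.ar2, -self.ar1, 1.0]) if self.ar2 != 0 \
                else (np.array([1.0 / self.ar1]) if self.ar1 != 0 else np.array([]))
            if ar_roots.size and np.abs(ar_roots).min() <= 1.0 + 1e-12:
                raise ValueError(
                    f"non-stationary ARMA coefficients ar1={self.ar1}, ar2={self.ar2}"
                )
            if abs(self.ma1) >= 1.0:
                raise ValueError(f"non-invertible MA coefficient ma1={self.ma1}")

    @property
    def ar_poly(self) -> np.ndarray:
        """AR lag polynomial [1, -ar1, -ar2] (statsmodels convention)."""
        return np.array([1.0, -self.ar1, -self.ar2])

    @property
    def ma_poly(self) -> np.ndarray:
        """MA lag polynomial [1, ma1]."""
        return np.array([1.0, self.ma1])

    def stationary_moments(self) -> tuple[float, float]:
        """Return (variance, lag-1 autocorrelation) of the stationary process."""
        if self.kind == "ar1":
            var, rho1 = stationary_moments_ar1(self.p)
            return var * self.innovation_sd**2, rho1
        acov = arma_acovf(self.ar_poly, self.ma_poly, nobs=2,
                          sigma2=self.innovation_sd**2)
        return float(acov[0]), float(acov[1] / acov[0])


@dataclass(frozen=True)
class EnvironmentSeries:
    """A realised environment trajectory E_0 .. E_{t_max}."""

    values: np.ndarray
    params: EnvParams
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("environment series contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, t):
        return self.values[t]

    def to_csv(self, path) -> None:
        """Write the series as a two-column CSV (t, E_t)."""
        import pandas as pd

        pd.DataFrame(
            {"t": np.arange(len(self.values)), "E_t": self.values}
        ).to_csv(path, index=False)


def step_ar1(E_prev: float, p: float, noise: float) -> float:
    """One AR(1) transition: ``p * E_prev + (1 - p) * noise``."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"AR(1) requires 0 <= p < 1, got p={p}")
    return p * E_prev + (1.0 - p) * noise


def stationary_moments_ar1(p: float) -> tuple[float, float]:
    """Stationary (variance, lag-1 autocorrelation) of the unit-innovation AR(1).

    With E_t = p E_{t-1} + (1-p) zeta_t and Var(zeta)=1 the stationary
    variance is (1-p)^2 / (1-p^2) = (1-p)/(1+p) and the lag-1
    autocorrelation is p.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError(f"AR(1) requires 0 <= p < 1, got p={p}")
    return (1.0 - p) / (1.0 + p), p


def generate_series(
    params: EnvParams,
    t_max: int,
    seed=None,
    rng: Optional[np.random.Generator] = None,
    e0: Optional[float] = None,
) -> EnvironmentSeries:
    """Generate an environment series of length ``t_max + 1``.

    By default E_0 is drawn from the stationary distribution so the series
    has no burn-in transient; pass ``e0=0.0`` to pin the start instead.
    Either a ``seed`` or an existing ``rng`` may be supplied; a given seed
    always reproduces the same series.
    """
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    if params.kind == "ar1":
        p, sd = params.p, params.innovation_sd
        if e0 is None:
            stat_var, _ = stationary_moments_ar1(p)
            E0 = float(rng.normal(0.0, np.sqrt(stat_var) * sd))
        else:
            E0 = float(e0)
        z = rng.normal(0.0, sd, size=t_max)
        # E_t = p E_{t-1} + (1-p) z_t as an IIR filter seeded with E_0
        rest, _ = lfilter([1.0 - p], [1.0, -p], z, zi=np.array([p * E0]))
        values = np.concatenate([[E0], rest])
    else:
        x = arma_generate_sample(
            params.ar_poly,
            params.ma_poly,
            nsample=t_max + 1,
            scale=params.innovation_sd,
            distrvs=rng.standard_normal,
            burnin=_ARMA_BURNIN,
        )
        values = x if e0 is None else x - x[0] + e0

    return EnvironmentSeries(values=values, params=params,
                             seed=seed if isinstance(seed, int) else None)


def arma21_from_target(
    lag1_autocorr: float,
    variance: float = 1.0,
    ar2: float = 0.2,
    ma1: float = 0.3,
) -> EnvParams:
    """Construct ARMA(2,1) parameters hitting a target lag-1 autocorrelation
    and stationary variance.

    The shape coefficients ``ar2`` and ``ma1`` are held fixed; ``ar1`` is
    solved so the theoretical lag-1 autocorrelation matches the target, then
    the innovation sd is rescaled to hit the target variance.  This decouples
    the autocorrelation from the total environmental variance, which the
    plain AR(1) recursion cannot do.
    """
    if not -1.0 < lag1_autocorr < 1.0:
        raise ValueError("target lag-1 autocorrelation must be in (-1, 1)")
    if variance <= 0:
        raise ValueError("target variance must be positive")
    if not -1.0 < ar2 < 1.0 or not -1.0 < ma1 < 1.0:
        raise ValueError("shape coefficients must satisfy |ar2| < 1, |ma1| < 1")

    # AR(2) stationarity triangle: ar1 in (-(1 - ar2), 1 - ar2)
    lo, hi = -(1.0 - ar2) + 1e-6, (1.0 - ar2) - 1e-6

    def rho1(a1: float) -> float:
        acov = arma_acovf(np.array([1.0, -a1, -ar2]), np.array([1.0, ma1]),
                          nobs=2, sigma2=1.0)
        return float(acov[1] / acov[0])

    f_lo, f_hi = rho1(lo) - lag1_autocorr, rho1(hi) - lag1_autocorr
    if f_lo * f_hi > 0:
        raise ValueError(
            "infeasible target: lag-1 autocorrelation "
            f"{lag1_autocorr} outside attainable range "
            f"[{rho1(lo):.4f}, {rho1(hi):.4f}] for ar2={ar2}, ma1={ma1}"
        )
    a1 = brentq(lambda a: rho1(a) - lag1_autocorr, lo, hi, xtol=1e-12)

    unit_var = float(arma_acovf(np.array([1.0, -a1, -ar2]),
                                np.array([1.0, ma1]), nobs=1, sigma2=1.0)[0])
    sd = float(np.sqrt(variance / unit_var))
    return EnvParams(kind="arma21", ar1=float(a1), ar2=ar2, ma1=ma1,
                     innovation_sd=sd)


def lag1_autocorr(values: np.ndarray) -> float:
    """Sample lag-1 autocorrelation of a series (mean-centred)."""
    x = np.asarray(values, dtype=float)
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0.0:
        return np.nan
    return float(x[1:] @ x[:-1]) / denom
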