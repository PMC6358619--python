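"""End-of-run and cross-run statistics.

For a single run: cross-sectional means of age (the lifespan proxy), the
two gene values, and mismatch over the standing population at the end of
the simulation, plus the senescence statistic — the OLS slope of individual
mismatch on individual age pooled over the final steps of the run, positive
when older individuals are more mismatched to the current environment.

Across runs: a tidy table (one row per run) and pattern tests for the
comparative predictions — reproductive effort covaries negatively with
plasticity, long lifespan occurs only at high plasticity, evolved updating
schedules cluster into discrete regimes, and the same environment can
harbour alternative equilibria reached from different starting genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import RunResult

__all__ = ["RunSummary", "summarize_run", "mismatch_age_slope",
           "sweep_table", "pattern_tests"]

SUMMARY_COLUMNS = [
    "env_kind", "p", "epsilon", "kappa", "rho", "variant",
    "u_init", "r_init", "seed", "status",
    "mean_age_at_tmax", "mean_u", "mean_r", "mean_mismatch",
    "mismatch_age_slope",
]


@dataclass(frozen=True)
class RunSummary:
    """One row of the sweep table."""

    env_kind: str
    p: float
    epsilon: float
    kappa: float
    rho: float
    variant: str
    u_init: float
    r_init: float
    seed: int
    status: str
    mean_age_at_tmax: float = np.nan
    mean_u: float = np.nan
    mean_r: float = np.nan
    mean_mismatch: float = np.nan
    mismatch_age_slope: float = np.nan

    def to_row(self) -> dict:
        return {k: getattr(self, k) for k in SUMMARY_COLUMNS}


def mismatch_age_slope(panel: pd.DataFrame) -> float:
    """OLS slope of mismatch on age over a pooled individual-step panel.

    Every individual-step record counts as one observation (an individual
    alive for all of the final 10 steps contributes 10 rows); no clustering
    correction is applied.  Returns NaN when the panel is empty or all ages
    are identical, where the slope is undefined.
    """
    if len(panel) == 0:
        return np.nan
    age = np.asarray(panel["age"], dtype=float)
    m = np.asarray(panel["m"], dtype=float)
    if np.ptp(age) == 0:
        return np.nan
    return float(stats.linregress(age, m).slope)


def summarize_run(result: RunResult) -> RunSummary:
    """Reduce one run to its end-of-run summary statistics.

    Means are taken over the living individuals in the final snapshot; the
    senescence slope pools the final-steps panel.  Extinct runs yield a row
    with status "extinct" and missing statistics.
    """
    cfg = result.config
    labels = dict(
        env_kind=cfg.env.kind,
        p=cfg.env.p if cfg.env.kind == "ar1" else np.nan,
        epsilon=cfg.epsilon, kappa=cfg.life.kappa, rho=cfg.life.rho,
        variant=cfg.life.mismatch_mode, u_init=cfg.u_init, r_init=cfg.r_init,
        seed=cfg.seed, status=result.status,
    )
    snap = result.final_snapshot
    if result.status != "completed" or snap is None or len(snap) == 0:
        return RunSummary(**labels, )
    return RunSummary(
        **labels,
        mean_age_at_tmax=float(snap["age"].mean()),
        mean_u=float(snap["u"].mean()),
        mean_r=float(snap["r"].mean()),
        mean_mismatch=float(snap["m"].mean()),
        mismatch_age_slope=mismatch_age_slope(result.last_steps_panel),
    )


def sweep_table(results: Sequence[RunResult]) -> pd.DataFrame:
    """Tidy table of run summaries, one row per run."""
    return pd.DataFrame([summarize_run(r).to_row() for r in results],
                        columns=SUMMARY_COLUMNS)


def _cluster_log_u(log_u: np.ndarray, k: int, seed: int = 0):
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(log_u.reshape(-1, 1))
    centers = km.cluster_centers_.ravel()
    order = np.argsort(centers)
    remap = np.empty_like(order)
    remap[order] = np.arange(k)
    return remap[labels], np.sort(centers)


def pattern_tests(table: pd.DataFrame, n_clusters: int = 3,
                  equilibria_gap: float = 1.0) -> dict:
    """Cross-run pattern report for a sweep table.

    Returns a dict with (a) the Spearman correlation of evolved mean r vs
    mean u, (b) of mean age vs mean u, (c) a k-means clustering of runs on
    log10 evolved u into ``n_clusters`` regimes (2 or 3), and (d) per-
    scenario flags for alternative equilibria: within one (p, epsilon,
    variant) scenario, evolved u values splitting into groups whose log10
    centres are more than ``equilibria_gap`` apart (an order of magnitude
    by default).  Requires at least 5 completed runs; otherwise a
    diagnostics-only report is returned.
    """
    if n_clusters not in (2, 3):
        raise ValueError("n_clusters must be 2 or 3")
    done = table[table["status"] == "completed"].dropna(subset=["mean_u"])
    report: dict = {"n_runs": int(len(table)), "n_completed": int(len(done))}
    if len(done) < 5:
        report["error"] = "fewer than 5 completed runs; no tests computed"
        return report

    rho_ru = stats.spearmanr(done["mean_r"], done["mean_u"])
    rho_au = stats.spearmanr(done["mean_age_at_tmax"], done["mean_u"])
    report["spearman_r_vs_u"] = float(rho_ru.statistic)
    report["spearman_r_vs_u_pvalue"] = float(rho_ru.pvalue)
    report["spearman_age_vs_u"] = float(rho_au.statistic)
    report["spearman_age_vs_u_pvalue"] = float(rho_au.pvalue)

    log_u = np.log10(np.asarray(done["mean_u"], dtype=float))
    k = min(n_clusters, len(np.unique(log_u)))
    if k >= 2:
        labels, centers = _cluster_log_u(log_u, k)
        report["u_clusters"] = {
            "k": int(k),
            "log10_centers": [float(c) for c in centers],
            "sizes": [int((labels == i).sum()) for i in range(k)],
        }
    else:
        report["u_clusters"] = {"k": 1, "log10_centers": [float(log_u[0])],
                                "sizes": [int(len(log_u))]}

    flags = {}
    for key, grp in done.groupby(["p", "epsilon", "variant"], dropna=False):
        lu = np.log10(np.asarray(grp["mean_u"], dtype=float))
        if len(lu) >= 2 and len(np.unique(lu)) >= 2:
            lab, cen = _cluster_log_u(lu, 2)
            bimodal = (cen[1] - cen[0] > equilibria_gap
                       and (lab == 0).any() and (lab == 1).any())
        else:
            bimodal = False
        name = f"p={key[0]}, eps={key[1]}, variant={key[2]}"
        flags[name] = bool(bimodal)
    report["alternative_equilibria"] = flags
    return report


def plot_patterns(table: pd.DataFrame, path) -> None:
    """Four-panel comparative scatter (age, r, mismatch, senescence vs u)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    done = table[table["status"] == "completed"]
    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    panels = [("mean_age_at_tmax", "mean age at t_max"),
              ("mean_r", "mean reproductive effort r"),
              ("mean_mismatch", "mean mismatch"),
              ("mismatch_age_slope", "mismatch ~ age slope")]
    markers = {e: m for e, m in zip(sorted(done["epsilon"].unique()),
                                    ["o", "s", "D", "^", "v"])}
    for ax, (col, label) in zip(axes.ravel(), panels):
        for eps, grp in done.groupby("epsilon"):
            sc = ax.scatter(grp["mean_u"], grp[col], c=grp["p"],
                            marker=markers.get(eps, "o"), cmap="viridis",
                            label=f"eps={eps}", alpha=0.8)
        ax.set_xscale("log")
        ax.set_xlabel("evolved updating schedule u")
        ax.set_ylabel(label)
    axes[0, 0].legend(fontsize=8)
    fig.colorbar(sc, ax=axes, label="environmental autocorrelation p",
                 shrink=0.8)
    fig.savefig(path, dpi=150)
    plt.close(fig)
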