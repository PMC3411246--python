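"""Rejection-rate grids: false-positive and power surfaces for both sign tests.

For every cell of a (selection coefficient s, effect-size variance, selection
mode) grid, simulate many 10-locus QTL datasets, apply the QTLST and the
QTLST-EE at level alpha, and tally rejections overall and stratified by the
number of + alleles.  The s = 0 row is the false-positive rate; s > 0 rows
are power.  All randomness descends from one root seed; each dataset gets its
own counter-derived stream so any single replicate can be reproduced in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .effects import EffectDistribution, simulate_dataset
from .selection import SelectionRegime
from .signtest import qtlst_ee_pvalue, qtlst_exact, qtlst_mc

__all__ = [
    "GridConfig",
    "PowerCell",
    "run_cell",
    "run_grid",
    "cells_to_frame",
    "stratified_report",
    "false_positive_curve",
    "plot_false_positive_curve",
    "plot_power_curves",
]

#: the suite of selection coefficients spanning pi = 0.5 .. ~1 at N = 1e6
DEFAULT_S_VALUES = (0.0, 1.25e-7, 2.5e-7, 5e-7, 1e-6, 2e-6)

#: 14 evenly spaced SDs covering the study's variance range 0.06 .. 3.8
DEFAULT_SD_GRID = tuple(np.round(np.linspace(0.24, 1.95, 14), 6))


@dataclass(frozen=True)
class GridConfig:
    """Simulation design for the rejection-rate study."""

    n_loci: int = 10
    N: int = 1_000_000
    s_values: tuple = DEFAULT_S_VALUES
    sd_grid: tuple = DEFAULT_SD_GRID
    modes: tuple = ("constant", "proportional")
    replicates: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    qtlst_engine: str = "exact"
    mc_draws: int = 100_000

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(s < 0 for s in self.s_values):
            raise ValueError("selection coefficients must be >= 0")
        if any(sd <= 0 for sd in self.sd_grid):
            raise ValueError("effect-size SDs must be > 0")
        if not set(self.modes) <= {"constant", "proportional"}:
            raise ValueError(f"unknown modes in {self.modes}")
        if self.qtlst_engine not in ("exact", "mc"):
            raise ValueError(f"unknown engine {self.qtlst_engine!r}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    def cells(self):
        """Deterministic cell order: (cell_index, mode, s, sd)."""
        idx = 0
        for mode in self.modes:
            for s in self.s_values:
                for sd in self.sd_grid:
                    yield idx, mode, float(s), float(sd)
                    idx += 1


@dataclass
class PowerCell:
    """Rejection tallies for one (s, variance, mode) grid cell.

    ``by_nplus_*`` arrays are indexed by the post-orientation + count k:
    ``by_nplus_count[k]`` datasets landed in stratum k, of which
    ``by_nplus_reject_qtlst[k]`` / ``by_nplus_reject_ee[k]`` were rejected.
    """

    mode: str
    s: float
    variance: float
    sd: float
    replicates: int
    by_nplus_count: np.ndarray
    by_nplus_reject_qtlst: np.ndarray
    by_nplus_reject_ee: np.ndarray

    @property
    def rejection_rate_qtlst(self) -> float:
        return float(self.by_nplus_reject_qtlst.sum() / self.replicates)

    @property
    def rejection_rate_ee(self) -> float:
        return float(self.by_nplus_reject_ee.sum() / self.replicates)


def _dataset_rng(seed: int, cell_index: int, replicate: int) -> np.random.Generator:
    """Counter-derived stream: any replicate is reproducible in isolation."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(cell_index, replicate))
    )


def run_cell(config: GridConfig, s: float, sd: float, mode: str, cell_index: int) -> PowerCell:
    """Simulate one grid cell and tally rejections for both tests."""
    n = config.n_loci
    dist = EffectDistribution.from_sd(sd)
    regime = SelectionRegime(s=s, N=config.N, proportional=(mode == "proportional"))
    ee_p = np.array([qtlst_ee_pvalue(k, n) for k in range(n + 1)])
    ee_rej = ee_p < config.alpha
    counts = np.zeros(n + 1, dtype=int)
    rej_q = np.zeros(n + 1, dtype=int)
    rej_e = np.zeros(n + 1, dtype=int)
    for i in range(config.replicates):
        rng = _dataset_rng(config.seed, cell_index, i)
        ds = simulate_dataset(n, regime, dist, rng)
        k = ds.n_plus
        counts[k] += 1
        if config.qtlst_engine == "exact":
            res = qtlst_exact(ds, alpha=config.alpha)
        else:
            res = qtlst_mc(ds, M=config.mc_draws, rng=rng, alpha=config.alpha)
        rej_q[k] += res.reject
        rej_e[k] += ee_rej[k]
    return PowerCell(
        mode=mode, s=s, variance=sd * sd, sd=sd, replicates=config.replicates,
        by_nplus_count=counts, by_nplus_reject_qtlst=rej_q, by_nplus_reject_ee=rej_e,
    )


def run_grid(config: GridConfig, progress: bool = False) -> list:
    """All (mode, s, sd) cells of the design, in deterministic order.

    Each cell's replicates use streams derived from (seed, cell_index,
    replicate), so results are independent of the order cells are computed in.
    """
    cells = list(config.cells())
    if progress:
        from tqdm import tqdm

        cells = tqdm(cells, desc="grid cells")
    return [run_cell(config, s, sd, mode, idx) for idx, mode, s, sd in cells]


def cells_to_frame(cells) -> pd.DataFrame:
    """Long-format rejection-rate table: one row per (cell, test)."""
    rows = []
    for c in cells:
        for test, rate in (
            ("QTLST", c.rejection_rate_qtlst),
            ("QTLST-EE", c.rejection_rate_ee),
        ):
            rows.append(
                {
                    "mode": c.mode, "s": c.s, "variance": c.variance, "sd": c.sd,
                    "test": test, "rejection_rate": rate, "n_reps": c.replicates,
                }
            )
    return pd.DataFrame(rows)


def stratified_report(cells) -> pd.DataFrame:
    """Rejection tallies broken down by the number of + alleles detected."""
    rows = []
    for c in cells:
        for k, (cnt, rq, re_) in enumerate(
            zip(c.by_nplus_count, c.by_nplus_reject_qtlst, c.by_nplus_reject_ee)
        ):
            if cnt == 0:
                continue
            rows.append(
                {
                    "mode": c.mode, "s": c.s, "variance": c.variance, "sd": c.sd,
                    "n_plus": k, "n_datasets": int(cnt),
                    "n_rejected_qtlst": int(rq), "n_rejected_ee": int(re_),
                }
            )
    return pd.DataFrame(rows)


def false_positive_curve(cells) -> pd.DataFrame:
    """The s = 0 row of the grid: (sd, variance, fpr_qtlst, fpr_ee) per mode."""
    rows = [
        {
            "mode": c.mode, "sd": c.sd, "variance": c.variance,
            "fpr_qtlst": c.rejection_rate_qtlst, "fpr_ee": c.rejection_rate_ee,
        }
        for c in cells
        if c.s == 0
    ]
    if not rows:
        raise ValueError("no s = 0 cells in the grid")
    return pd.DataFrame(rows)


def _require_pyplot():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_false_positive_curve(cells, path) -> None:
    """False-positive rates vs. SD of effect sizes, one marker set per test."""
    plt = _require_pyplot()
    fpc = false_positive_curve(cells)
    fig, ax = plt.subplots(figsize=(5, 4))
    for mode, sub in fpc.groupby("mode"):
        ax.plot(sub["sd"], sub["fpr_ee"], "o-", label=f"QTLST-EE ({mode})")
        ax.plot(sub["sd"], sub["fpr_qtlst"], "x--", label=f"QTLST ({mode})")
    ax.set_xlabel("SD of QTL effect sizes")
    ax.set_ylabel("false-positive rate")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_power_curves(cells, path, mode: str = "constant") -> None:
    """Rejection rate vs. SD for each s, one panel per test."""
    plt = _require_pyplot()
    frame = cells_to_frame([c for c in cells if c.mode == mode])
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, test in zip(axes, ("QTLST", "QTLST-EE")):
        sub = frame[frame["test"] == test]
        for s, g in sub.groupby("s"):
            ax.plot(g["sd"], g["rejection_rate"], "o-", label=f"s = {s:g}")
        ax.set_title(test)
        ax.set_xlabel("SD of QTL effect sizes")
    axes[0].set_ylabel("proportion rejecting neutrality")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
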