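"""Simulate QTL datasets: gamma effect magnitudes plus allele directions.

A dataset is the outcome of a QTL study contrasting a high line and a low
line: for each of ``n`` loci, a positive effect magnitude and a direction
(+1 if the allele increasing the trait is fixed in the high line, -1
otherwise).  Magnitudes are drawn from a mean-1 gamma family indexed by its
variance (shape = rate = a, so mean = 1 and variance = 1/a), directions from
the selection model's per-locus + probability.  Datasets are oriented so the
high line is the line with the larger trait value (R >= 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .selection import SelectionRegime

__all__ = [
    "EffectDistribution",
    "QTLDataset",
    "draw_magnitudes",
    "draw_directions",
    "orient_dataset",
    "simulate_dataset",
]


@dataclass(frozen=True)
class EffectDistribution:
    """Mean-1 gamma family of QTL effect magnitudes, indexed by variance.

    With shape and rate both equal to ``a = 1/variance`` the mean is fixed at
    1 for every variance, so the variance axis can be explored without moving
    the mean.  The study range of variances is [0.06, 3.8] (SD 0.24 .. 1.95).
    """

    variance: float

    def __post_init__(self) -> None:
        if not (self.variance > 0 and np.isfinite(self.variance)):
            raise ValueError(f"variance must be positive, got {self.variance}")

    @property
    def shape_rate(self) -> float:
        """The single gamma parameter a (shape = rate = a = 1/variance)."""
        return 1.0 / self.variance

    @property
    def mean(self) -> float:
        return 1.0

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))

    @classmethod
    def from_sd(cls, sd: float) -> "EffectDistribution":
        return cls(variance=float(sd) ** 2)


@dataclass
class QTLDataset:
    """Oriented QTL effect table: magnitudes |z_i| and directions in {+1, -1}.

    ``n_plus`` counts the + alleles and ``R = 2 * sum(magnitude * direction)``
    is the phenotypic difference between the lines (the factor 2 because the
    high line carries +G1 and the low line -G1 under additivity).
    """

    magnitudes: np.ndarray
    directions: np.ndarray
    locus_ids: tuple = field(default=None)

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        self.directions = np.asarray(self.directions, dtype=int)
        if self.magnitudes.ndim != 1 or self.directions.shape != self.magnitudes.shape:
            raise ValueError("magnitudes and directions must be 1-D and equal length")
        if self.magnitudes.size == 0:
            raise ValueError("dataset must contain at least one locus")
        if not np.all(np.isfinite(self.magnitudes)) or np.any(self.magnitudes <= 0):
            raise ValueError("effect magnitudes must be positive and finite")
        if not np.all(np.isin(self.directions, (-1, 1))):
            raise ValueError("directions must be +1 or -1")
        if self.locus_ids is not None:
            self.locus_ids = tuple(str(x) for x in self.locus_ids)
            if len(self.locus_ids) != self.magnitudes.size:
                raise ValueError("locus_ids length mismatch")

    @property
    def n(self) -> int:
        return int(self.magnitudes.size)

    @property
    def n_plus(self) -> int:
        return int(np.sum(self.directions == 1))

    @property
    def R(self) -> float:
        return 2.0 * float(np.sum(self.magnitudes * self.directions))

    def __eq__(self, other) -> bool:
        if not isinstance(other, QTLDataset):
            return NotImplemented
        return (
            np.array_equal(self.magnitudes, other.magnitudes)
            and np.array_equal(self.directions, other.directions)
            and self.locus_ids == other.locus_ids
        )


def draw_magnitudes(dist: EffectDistribution, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` iid gamma(shape=a, rate=a) effect magnitudes (mean 1, var 1/a)."""
    if n < 1 or int(n) != n:
        raise ValueError(f"locus count must be a positive integer, got {n}")
    a = dist.shape_rate
    return rng.gamma(shape=a, scale=1.0 / a, size=int(n))


def draw_directions(
    magnitudes: np.ndarray,
    regime: SelectionRegime,
    rng: np.random.Generator,
    z_bar: float = 1.0,
) -> np.ndarray:
    """Draw per-locus allele directions, +1 with probability pi per locus.

    Constant mode: pi = pi(s) for every locus.  Proportional mode:
    pi_i = pi(s * z_i / z_bar) with z_bar the distribution mean (1), so
    large-effect loci are more likely to carry the + allele.
    """
    magnitudes = np.asarray(magnitudes, dtype=float)
    p = regime.plus_probability(magnitudes, z_bar=z_bar)
    u = rng.random(magnitudes.size)
    return np.where(u < p, 1, -1)


def orient_dataset(magnitudes, raw_directions, locus_ids=None) -> QTLDataset:
    """Label lines so the high line is high: flip all signs if R < 0.

    If the signed sum is exactly zero (possible only for hand-built discrete
    magnitudes), keep the orientation with ``n_plus >= n/2``.
    """
    magnitudes = np.asarray(magnitudes, dtype=float)
    directions = np.asarray(raw_directions, dtype=int)
    if magnitudes.shape != directions.shape:
        raise ValueError("magnitudes and directions must have equal length")
    signed = float(np.sum(magnitudes * directions))
    if signed < 0:
        directions = -directions
    elif signed == 0 and np.sum(directions == 1) < directions.size / 2:
        directions = -directions
    return QTLDataset(magnitudes=magnitudes, directions=directions, locus_ids=locus_ids)


def simulate_dataset(
    n: int,
    regime: SelectionRegime,
    dist: EffectDistribution,
    rng: np.random.Generator,
) -> QTLDataset:
    """One simulated, oriented QTL dataset (magnitudes then directions)."""
    mags = draw_magnitudes(dist, n, rng)
    dirs = draw_directions(mags, regime, rng)
    return orient_dataset(mags, dirs)
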