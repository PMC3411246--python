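"""Map selection coefficients to fixation probabilities of + alleles.

The model: in a diploid population of size ``N`` under directional selection
with coefficient ``s``, the equilibrium probability that a locus is in the
selected (+) allelic state is

    pi(s) = e^{4Ns} / (e^{4Ns} + e^{2s})

which is 1/2 at neutrality (s = 0) and approaches 1 under strong selection.
Across ``n`` independent loci the number of + alleles that fix is then
binomial(n, pi(s)); at s = 0 this reduces to the fair-coin neutral model
binomial(n, 1/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "SelectionRegime",
    "FixationPMF",
    "equilibrium_plus_probability",
    "fixation_pmf",
    "proportional_coefficient",
]


def _validate_s_N(s: float, N: float) -> None:
    if not np.all(np.isfinite(s)):
        raise ValueError(f"selection coefficient must be finite, got {s}")
    if not np.isfinite(N):
        raise ValueError(f"population size must be finite, got {N}")
    if np.any(np.asarray(s) < 0):
        raise ValueError(
            f"negative selection coefficient s={s}: only directional selection "
            "toward the + state is modelled"
        )
    if N < 1:
        raise ValueError(f"population size must be >= 1, got {N}")


def equilibrium_plus_probability(s, N):
    """Equilibrium probability pi(s) that a locus carries the + allele.

    Parameters
    ----------
    s : float or array-like
        Selection coefficient, ``s >= 0``.
    N : float
        Population size, ``N >= 1``.  Treated as real-valued.

    Returns
    -------
    float or ndarray
        ``pi(s) = e^{4Ns} / (e^{4Ns} + e^{2s})``, evaluated as the logistic
        ``1 / (1 + e^{2s - 4Ns})`` so that large ``4Ns`` returns 1.0 cleanly
        instead of overflowing.  ``pi(0) == 0.5`` exactly.
    """
    _validate_s_N(s, N)
    s = np.asarray(s, dtype=float)
    out = expit(2.0 * s * (2.0 * N - 1.0))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SelectionRegime:
    """Selection acting on the + direction of a trait.

    Attributes
    ----------
    s : float
        Selection coefficient (>= 0); 0 is the neutral model.
    N : int
        Population size (integer >= 1).
    proportional : bool
        If True, the per-locus coefficient scales with effect magnitude,
        ``s' = (z / z_bar) s``, so large-effect loci feel stronger selection.
    """

    s: float
    N: int
    proportional: bool = False

    def __post_init__(self) -> None:
        _validate_s_N(self.s, self.N)
        if int(self.N) != self.N:
            raise ValueError(f"population size must be an integer, got {self.N}")

    def plus_probability(self, magnitudes=None, z_bar: float = 1.0):
        """Per-locus probability of the + allelic state.

        In constant mode returns the scalar ``pi(s)``; in proportional mode
        requires ``magnitudes`` and returns ``pi(s * z_i / z_bar)`` per locus.
        """
        if not self.proportional:
            return equilibrium_plus_probability(self.s, self.N)
        if magnitudes is None:
            raise ValueError("proportional regime needs effect magnitudes")
        s_prime = proportional_coefficient(np.asarray(magnitudes, float), z_bar, self.s)
        return equilibrium_plus_probability(s_prime, self.N)


@dataclass(frozen=True)
class FixationPMF:
    """Distribution of the number of + alleles fixing across ``n`` loci."""

    n: int
    probs: np.ndarray

    def __post_init__(self) -> None:
        if len(self.probs) != self.n + 1:
            raise ValueError("probs must have length n + 1")


def fixation_pmf(n: int, s: float, N: float) -> FixationPMF:
    """Binomial(n, pi(s)) distribution of the count of fixed + alleles.

    At ``s = 0`` the entries are exactly ``C(n, k) / 2^n`` (the neutral model);
    the probabilities are assembled from exact integer binomial coefficients so
    that this identity is bit-exact.
    """
    if n < 1 or int(n) != n:
        raise ValueError(f"locus count must be a positive integer, got {n}")
    pi = equilibrium_plus_probability(s, N)
    k = np.arange(n + 1)
    coefs = np.array([math.comb(n, int(kk)) for kk in k], dtype=float)
    probs = coefs * pi**k * (1.0 - pi) ** (n - k)
    return FixationPMF(n=int(n), probs=probs)


def proportional_coefficient(z, z_bar: float, s: float):
    """Effect-size-proportional selection coefficient ``s' = (z / z_bar) s``.

    ``z`` is the locus effect magnitude and ``z_bar`` the mean effect of the
    distribution magnitudes are drawn from (1 for the mean-1 gamma family).
    """
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0) or not np.all(np.isfinite(z)):
        raise ValueError("effect magnitudes must be positive and finite")
    if z_bar <= 0 or not np.isfinite(z_bar):
        raise ValueError(f"mean effect must be positive, got {z_bar}")
    if s < 0 or not np.isfinite(s):
        raise ValueError(f"selection coefficient must be >= 0, got {s}")
    out = s * (z / z_bar)
    return float(out) if out.ndim == 0 else out
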