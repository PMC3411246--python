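"""The QTL sign tests: equal-effects binomial test and conditional resampling test.

Both tests ask whether the observed number of + alleles ``n_plus`` among the
``n`` QTL distinguishing a high and a low line is too large to be explained
by drift.

QTLST-EE
    An exact two-sided binomial sign test on ``n_plus`` with X ~ Bin(n, 1/2):
    ``P = min(1, 2 * Pr{X >= max(n_plus, n - n_plus)})``.  Effect magnitudes
    are ignored.

QTLST
    The resampling test conditions on the observed phenotypic difference R.
    Under its null model each locus independently draws a magnitude uniformly
    *with replacement* from the observed magnitudes and a fair +/- sign; the
    P-value is the conditional tail

        P = Pr{ n_plus(resample) >= n_plus_obs | 2*sum(G1) >= R }.

    Writing k for the resampled + count, the engine computes
    ``q_k = Pr{A_k - B_{n-k} >= R/2}`` where ``A_k`` (``B_{n-k}``) is the sum
    of k (n-k) with-replacement magnitude draws, then combines the strata
    ``C(n,k) 2^{-n} q_k``.  The exact engine builds every j-fold sum
    distribution by enumerating combinations-with-repetition of the observed
    magnitudes with multinomial weights; the Monte-Carlo engine estimates each
    ``q_k`` from M stratified draws and combines with the same exact binomial
    weights, avoiding the rare-event waste of naive rejection sampling.

All resampled sums, and the observed R/2 itself, are evaluated in a single
canonical order (accumulating count*value over ascending distinct magnitudes)
so that identical multisets produce bit-identical floating-point sums; the
weak conditioning inequality then contains the observed configuration exactly,
and a dataset of equal magnitudes yields P = 1.0 exactly for every n_plus.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, factorial

import numpy as np

from .effects import QTLDataset

__all__ = [
    "SignTestResult",
    "qtlst_ee_pvalue",
    "qtlst_exact",
    "qtlst_mc",
    "qtlst",
    "qtlst_conditional_tail",
    "canonical_multiset_sum",
    "signed_half_difference",
    "decide",
]

#: largest n for which the exact enumeration engine is the default
EXACT_ENGINE_MAX_N = 12


# ---------------------------------------------------------------------------
# canonical floating-point conventions
# ---------------------------------------------------------------------------

def canonical_multiset_sum(values) -> float:
    """Sum a multiset of floats in canonical order.

    Accumulates ``count * value`` over the distinct values in ascending
    order.  Every routine in this module that sums a multiset of observed
    magnitudes uses this convention, so identical multisets always give
    bit-identical sums regardless of how they were assembled.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return 0.0
    v, c = np.unique(values, return_counts=True)
    acc = 0.0
    for vv, cc in zip(v, c):
        acc = acc + cc * vv
    return acc


def signed_half_difference(dataset: QTLDataset) -> float:
    """Observed R/2 in canonical order: sum(+ magnitudes) - sum(- magnitudes)."""
    plus = dataset.magnitudes[dataset.directions == 1]
    minus = dataset.magnitudes[dataset.directions == -1]
    return canonical_multiset_sum(plus) - canonical_multiset_sum(minus)


# ---------------------------------------------------------------------------
# QTLST-EE
# ---------------------------------------------------------------------------

def qtlst_ee_pvalue(n_plus: int, n: int) -> float:
    """Two-sided exact binomial sign-test P-value (the equal-effects test).

    Computed with integer arithmetic, so e.g. P(9 of 10) is exactly 22/1024
    and P(8 of 10) exactly 112/1024.  Symmetric in ``n_plus <-> n - n_plus``.
    """
    if n < 1 or int(n) != n:
        raise ValueError(f"locus count must be a positive integer, got {n}")
    if not (0 <= n_plus <= n) or int(n_plus) != n_plus:
        raise ValueError(f"n_plus must be an integer in [0, {n}], got {n_plus}")
    m = max(int(n_plus), int(n) - int(n_plus))
    tail = sum(comb(n, i) for i in range(m, n + 1))  # exact integer tail
    return min(1.0, 2 * tail / 2**n)


# ---------------------------------------------------------------------------
# exact resampling engine
# ---------------------------------------------------------------------------

def _sum_distributions(magnitudes: np.ndarray):
    """Exact distributions of j-fold with-replacement sums, j = 0 .. n.

    Returns (sums, probs): for each j an array of the distinct-multiset sums
    (each multiset of observed magnitudes summed once, in canonical order)
    and the matching multinomial probabilities.  Built by dynamic programming
    over ascending distinct values: a multiset containing m copies of value v
    contributes the factor p_v^m / m!, and the total probability of a multiset
    of size j is j! times the product of its factors.
    """
    n = magnitudes.size
    v, c = np.unique(magnitudes, return_counts=True)
    p = c / n
    fact = [factorial(m) for m in range(n + 1)]
    sums = [np.zeros(1)] + [np.empty(0) for _ in range(n)]
    wts = [np.ones(1)] + [np.empty(0) for _ in range(n)]
    for vd, pd in zip(v, p):
        coeff = [pd**m / fact[m] for m in range(n + 1)]
        add = [m * vd for m in range(n + 1)]
        new_sums, new_wts = [], []
        for j in range(n + 1):
            ps = [sums[j - m] + add[m] for m in range(j + 1) if sums[j - m].size]
            pw = [wts[j - m] * coeff[m] for m in range(j + 1) if wts[j - m].size]
            new_sums.append(np.concatenate(ps) if ps else np.empty(0))
            new_wts.append(np.concatenate(pw) if pw else np.empty(0))
        sums, wts = new_sums, new_wts
    probs = [wts[j] * fact[j] for j in range(n + 1)]
    return sums, probs

# direct outer-product evaluation below this many (a, b) pairs
_DIRECT_PAIR_LIMIT = 4096
_MAX_BOUNDARY_FIXUPS = 8


def _tail_prob(sa, pa, sb, pb, r2: float) -> float:
    """P(a - b >= r2) for independent discrete a ~ (sa, pa), b ~ (sb, pb).

    The predicate is the floating-point comparison fl(a - b) >= r2 in every
    branch.  Small problems use a direct outer product; large ones sort the
    smaller support, binary-search the larger, and then repair the boundary
    index so the effective predicate is identical to the direct one (the
    searchsorted key fl(a - r2) can be an ulp off fl(a - b)).
    """
    if sa.size == 0 or sb.size == 0:
        return 0.0
    if sb.size == 1:
        return float(pb[0] * (pa @ ((sa - sb[0]) >= r2)))
    if sa.size == 1:
        return float(pa[0] * (pb @ ((sa[0] - sb) >= r2)))
    if sa.size * sb.size <= _DIRECT_PAIR_LIMIT:
        return float(pa @ ((sa[:, None] - sb[None, :]) >= r2) @ pb)
    if sb.size <= sa.size:
        order = np.argsort(sb, kind="stable")
        sbs = sb[order]
        cum = np.concatenate(([0.0], np.cumsum(pb[order])))
        pos = np.searchsorted(sbs, sa - r2, side="right")
        for _ in range(_MAX_BOUNDARY_FIXUPS):  # admit b just right of the key
            mask = (pos < sbs.size) & (sa - sbs[np.minimum(pos, sbs.size - 1)] >= r2)
            if not mask.any():
                break
            pos[mask] += 1
        for _ in range(_MAX_BOUNDARY_FIXUPS):  # evict b that fails the predicate
            mask = (pos > 0) & (sa - sbs[np.maximum(pos, 1) - 1] < r2)
            if not mask.any():
                break
            pos[mask] -= 1
        return float(pa @ cum[pos])
    order = np.argsort(sa, kind="stable")
    sas = sa[order]
    suffix = np.concatenate((np.cumsum(pa[order][::-1])[::-1], [0.0]))
    pos = np.searchsorted(sas, sb + r2, side="left")
    for _ in range(_MAX_BOUNDARY_FIXUPS):
        mask = (pos > 0) & (sas[np.maximum(pos, 1) - 1] - sb >= r2)
        if not mask.any():
            break
        pos[mask] -= 1
    for _ in range(_MAX_BOUNDARY_FIXUPS):
        mask = (pos < sas.size) & (sas[np.minimum(pos, sas.size - 1)] - sb < r2)
        if not mask.any():
            break
        pos[mask] += 1
    return float(pb @ suffix[pos])


def qtlst_conditional_tail(magnitudes, n_plus: int, r_half: float):
    """Core of the exact engine, on raw (magnitudes, n_plus, R/2).

    Returns ``(p_value, event_probability, strata)`` where ``strata[k] =
    C(n,k) 2^{-n} Pr{A_k - B_{n-k} >= R/2}``, ``event_probability`` is their
    sum (the probability of the conditioning event {2*sum(G1) >= R}), and
    ``p_value = sum_{k >= n_plus} strata[k] / event_probability``.
    """
    magnitudes = np.asarray(magnitudes, dtype=float)
    n = magnitudes.size
    if not (0 <= n_plus <= n):
        raise ValueError(f"n_plus must be in [0, {n}], got {n_plus}")
    sums, probs = _sum_distributions(magnitudes)
    weight = 0.5**n
    strata = np.empty(n + 1)
    for k in range(n + 1):
        q = _tail_prob(sums[k], probs[k], sums[n - k], probs[n - k], r_half)
        strata[k] = comb(n, k) * weight * q
    event = float(strata.sum())
    if not event > 0.0:  # the all-plus observed-multiset draw always qualifies
        raise AssertionError("conditioning event has zero probability")
    p = min(1.0, float(strata[int(n_plus):].sum()) / event)
    return p, event, strata


# ---------------------------------------------------------------------------
# results and public engines
# ---------------------------------------------------------------------------

@dataclass
class SignTestResult:
    """Outcome of one sign test applied to one QTL dataset."""

    method: str  # "QTLST-EE" | "QTLST-exact" | "QTLST-MC"
    p_value: float
    reject: bool
    alpha: float
    n: int
    n_plus: int
    R: float
    event_probability: float = None
    strata: np.ndarray = None
    mc_draws: int = None

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "n": self.n,
            "n_plus": self.n_plus,
            "R": self.R,
            "p_value": self.p_value,
            "reject": bool(self.reject),
        }
        if self.event_probability is not None:
            out["event_probability"] = self.event_probability
        if self.mc_draws is not None:
            out["mc_draws"] = self.mc_draws
        return out


def decide(result: SignTestResult, alpha: float) -> bool:
    """Reject neutrality iff ``p_value < alpha`` (strict)."""
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return result.p_value < alpha


def _check_oriented(dataset: QTLDataset) -> float:
    r_half = signed_half_difference(dataset)
    if r_half < 0:
        raise ValueError(
            "dataset is not oriented (R < 0); orient so the high line is high"
        )
    return r_half


def qtlst_ee(dataset: QTLDataset, alpha: float = 0.05) -> SignTestResult:
    """Equal-effects binomial sign test applied to a dataset."""
    p = qtlst_ee_pvalue(dataset.n_plus, dataset.n)
    return SignTestResult(
        method="QTLST-EE", p_value=p, reject=p < alpha, alpha=alpha,
        n=dataset.n, n_plus=dataset.n_plus, R=dataset.R,
    )


def qtlst_exact(dataset: QTLDataset, alpha: float = 0.05) -> SignTestResult:
    """Exact-enumeration QTLST: the conditional resampling P-value."""
    r_half = _check_oriented(dataset)
    p, event, strata = qtlst_conditional_tail(dataset.magnitudes, dataset.n_plus, r_half)
    return SignTestResult(
        method="QTLST-exact", p_value=p, reject=p < alpha, alpha=alpha,
        n=dataset.n, n_plus=dataset.n_plus, R=dataset.R,
        event_probability=event, strata=strata,
    )


def qtlst_mc(
    dataset: QTLDataset,
    M: int = 100_000,
    rng: np.random.Generator = None,
    alpha: float = 0.05,
) -> SignTestResult:
    """Stratified Monte-Carlo QTLST.

    For each + count k, ``q_k`` is estimated from ``M`` draws of the two
    with-replacement sums; the strata are then combined with the same exact
    binomial weights as the exact engine.  Reproducible given ``rng``.
    """
    if M < 1 or int(M) != M:
        raise ValueError(f"replicate count M must be a positive integer, got {M}")
    if rng is None:
        rng = np.random.default_rng()
    r_half = _check_oriented(dataset)
    mags = dataset.magnitudes
    n = dataset.n
    weight = 0.5**n
    strata = np.empty(n + 1)
    for k in range(n + 1):
        a = mags[rng.integers(0, n, size=(int(M), k))].sum(axis=1) if k else np.zeros(int(M))
        b = mags[rng.integers(0, n, size=(int(M), n - k))].sum(axis=1) if k < n else np.zeros(int(M))
        strata[k] = comb(n, k) * weight * float(np.mean((a - b) >= r_half))
    event = float(strata.sum())
    if not event > 0.0:
        raise RuntimeError(
            "no Monte-Carlo draw met the conditioning event; increase M or "
            "use the exact engine (the event always has positive probability)"
        )
    p = min(1.0, float(strata[dataset.n_plus:].sum()) / event)
    return SignTestResult(
        method="QTLST-MC", p_value=p, reject=p < alpha, alpha=alpha,
        n=dataset.n, n_plus=dataset.n_plus, R=dataset.R,
        event_probability=event, strata=strata, mc_draws=int(M),
    )


def qtlst(
    dataset: QTLDataset,
    engine: str = "auto",
    alpha: float = 0.05,
    M: int = 100_000,
    rng: np.random.Generator = None,
) -> SignTestResult:
    """Dispatch: exact engine for n <= 12, Monte-Carlo above (engine='auto')."""
    if engine == "auto":
        engine = "exact" if dataset.n <= EXACT_ENGINE_MAX_N else "mc"
    if engine == "exact":
        return qtlst_exact(dataset, alpha=alpha)
    if engine == "mc":
        return qtlst_mc(dataset, M=M, rng=rng, alpha=alpha)
    raise ValueError(f"unknown engine {engine!r}; use 'auto', 'exact' or 'mc'")
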