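# Methods

## The problem

A QTL study of two divergent lines (a "high" and a "low" line) yields, for
each of `n` mapped loci, an effect magnitude `|z_i|` and a direction: a
**+ allele** increases the trait in the high line, a **− allele** decreases
it. If the trait difference arose by drift, + and − alleles should be
interleaved at random; directional selection instead drives an excess of
+ alleles. `qtlsign` implements two tests of the neutral hypothesis built on
this idea, the selection model used to simulate data under the alternative,
and a simulation pipeline that measures both tests' false-positive rates and
power.

## The selection-to-fixation model

Under directional selection with coefficient `s ≥ 0` in a population of size
`N`, the equilibrium probability that a locus is in the + allelic state is

    π(s) = e^{4Ns} / (e^{4Ns} + e^{2s})

and the number of + alleles among `n` independent loci is Binomial(n, π(s)).
At `s = 0`, π = 1/2 exactly (the neutral model); as `s` grows, π → 1.
`π` is evaluated as the logistic `1/(1 + e^{2s − 4Ns})` so that `4Ns` in the
hundreds returns exactly 1.0 instead of overflowing; negative `s` is rejected
(only selection toward the + state is modelled). `N` is validated as an
integer on user input but treated as real-valued internally. The default
suite of coefficients `{0, 1.25·10⁻⁷, 2.5·10⁻⁷, 5·10⁻⁷, 10⁻⁶, 2·10⁻⁶}` at
`N = 10⁶` spans π from 0.50 to 0.9997; larger coefficients change π only
asymptotically.

In **proportional mode** the per-locus coefficient scales with effect
magnitude, `s′ = (z/z̄)·s`, coupling effect size to the probability of the
+ state. `z̄` is the *distribution* mean of the effect magnitudes (1 for
the gamma family below), not the per-dataset sample mean; this keeps loci
independent.

## The effect-size distribution

Effect magnitudes are drawn from a gamma family with shape and **rate** both
equal to `a`, so the mean is fixed at 1 for every variance and the variance
is `1/a`. (Setting shape equal to the *scale* parameter would not hold the
mean fixed and would not reproduce the intended SD range endpoints
0.24–1.95, i.e. variances 0.06–3.8, which pin this parameterization down.)
The variance axis is therefore a pure nuisance axis: it moves the spread of
locus effects without moving the expected trait difference.

## Datasets and orientation

A dataset holds magnitudes, directions, the + count `n_plus`, and the
phenotypic difference `R = 2·Σ(magnitude × direction)` (the factor 2 because
the high line carries `+G₁` and the low line `−G₁` under additivity).
Which line is called "high" is a labelling choice, so datasets are
**oriented**: if the signed sum is negative all directions are flipped, so
`R ≥ 0` always. If the signed sum is exactly zero — possible only for
hand-built discrete magnitudes, a measure-zero event under gamma draws — the
orientation with `n_plus ≥ n/2` is kept, for deterministic behaviour.

Orientation has one subtle consequence for the *distribution* of `n_plus`
under neutrality: the flip is decided by the magnitude-weighted sum, not by
the + count, so a dataset with 6 + alleles but a negative weighted sum
orients to 4 + alleles. The post-orientation `n_plus` therefore follows the
folded Binomial(n, 1/2) only up to a leakage of order 0.5% at the smallest
study variance (and more at large variance). The goodness-of-fit test in the
suite pools the lower bins accordingly.

## The tests

**QTLST-EE** (equal effects): exact two-sided binomial sign test,
`P = min(1, 2·Pr{X ≥ max(n_plus, n − n_plus)})`, `X ~ Bin(n, 1/2)`, computed
with integer arithmetic (so for `n = 10`: P(9) = 22/1024 ≈ 0.021,
P(8) = 112/1024 ≈ 0.11 — the test rejects at 9 but not 8 + alleles at
α = 0.05). Magnitudes are ignored.

**QTLST** (conditional resampling): conditions on the observed difference.
Under the null resampling model each locus independently draws a magnitude
uniformly **with replacement** from the `n` observed magnitudes and a fair
± sign; the P-value is

    P = Pr{ n₊(resample) ≥ n_plus_obs | 2ΣG₁ ≥ R }.

Given `k` + signs the resampled difference is `A_k − B_{n−k}` (sums of `k`
and `n−k` magnitude draws), so with `q_k = Pr{A_k − B_{n−k} ≥ R/2}` the
strata are `C(n,k)·2⁻ⁿ·q_k`, the conditioning event's probability is their
sum, and `P` is the normalized upper tail from `n_plus_obs`. The weak
inequality (≥) means the observed configuration itself is always in the
event, so the event probability is strictly positive (≥ (2n)⁻ⁿ) and
`0 < P ≤ 1`.

### Engines

*Exact*: the distribution of every `j`-fold sum is built by dynamic
programming over ascending distinct magnitudes — each multiset of draws
appears exactly once with its multinomial probability
`j!·Π p_v^{m_v}/m_v!`. Support sizes are `C(j+d−1, d−1)` for `d` distinct
values (92,378 at `j = d = 10`), so the engine is the default up to `n = 12`.
Tail probabilities `q_k` are evaluated by sorting the smaller support and
binary-searching the larger, with a bounded boundary-repair pass so the
effective predicate is the plain floating-point comparison
`fl(a − b) ≥ R/2` everywhere; small or degenerate supports use a direct
outer product with that same predicate.

*Monte Carlo*: for each `k`, `q_k` is estimated from `M` stratified draws
(default 10⁵) and combined with the same exact binomial weights. This avoids
the rare-event waste of naive rejection sampling (unconditioned draws almost
never meet the event when it is improbable) and converges at the usual
`M^{−1/2}` rate; it is the default for `n > 12`.

### Floating-point conventions

All multiset sums — the DP's resampled sums and the observed `R/2` itself
(canonical sum of + magnitudes minus canonical sum of − magnitudes) — are
accumulated in one canonical order: `count × value` over ascending distinct
values. Identical multisets therefore produce bit-identical floats, the
observed configuration satisfies the conditioning inequality exactly, and a
dataset of equal magnitudes yields `P = 1.0` exactly for every `n_plus` and
both engines, at any magnitude value (the degenerate case is additionally
protected by the 2·magnitude gap between adjacent resampled sums, which
floating-point rounding cannot bridge). Rejection uses the strict rule
`P < α`.

## Behaviour of the conditional test

Two structural facts follow directly from the definition and are worth
stating because they drive everything the simulation study shows:

1. **Zero variance ⇒ zero power.** With equal magnitudes, the only
   resamples meeting `2ΣG₁ ≥ R` are those with at least the observed number
   of + signs, so `P = 1` no matter how many + alleles are observed. The
   conditioning absorbs the entire signal.
2. **Continuity in the magnitudes.** `P` depends only on the magnitude
   multiset, `n_plus` and `R`; as the variance of effect sizes shrinks, the
   P-value of an all-+ dataset rises continuously toward 1. Measured with
   this package, the median P of neutral all-+ ten-locus datasets is ≈ 0.99
   at variance 0.06, crosses 0.05 near variance ≈ 1–2, and is ≈ 0.01 at
   variance 3.8. Consequently, even datasets in which *every* allele points
   the same way are only rejected when the spread of effect sizes is large —
   rejection is driven by the variance of effects, not by the strength of
   selection that produced them. Within an `n_plus` stratum the P-value does
   not depend on `s` at all (the test never sees `s`), which the stratified
   pipeline output makes explicit.

Point 2 also bounds what the false-positive curve can do: at variance 0.06
essentially no neutral dataset is rejected by the conditional test, and at
variance 3.8 the rate reaches only a few per mille under this exact
resampling dialect (rejections come from the `n_plus ∈ {9, 10}` strata).
Reports of conditional-sign-test false-positive rates as high as 0.035 at
the top of this variance range are not reproducible from the test as defined
here; they would require the conditioning threshold to sit at about half the
observed difference (which would, in turn, destroy the equal-effects
degeneracy in point 1). This package implements the test exactly as defined;
the exact engine is verified against full `(2n)ⁿ` brute-force enumeration.

## The simulation pipeline

A grid cell is one (mode, `s`, SD) combination. Per cell, `replicates`
datasets (default 10,000) are simulated and both tests applied at
`alpha = 0.05`; tallies are kept overall and stratified by `n_plus`. The
default grid uses `n = 10` loci, `N = 10⁶`, the six-coefficient suite, 14
evenly spaced SDs from 0.24 to 1.95, and both selection modes. The QTLST
engine inside the grid is the exact engine, so the only stochasticity is
dataset simulation. Randomness: every dataset's generator is derived as
`SeedSequence(root_seed, spawn_key=(cell_index, replicate))`, so results are
bit-reproducible, independent of the order cells are computed in, and any
single replicate can be regenerated in isolation.

The test suite runs a reduced study (2,000 replicates per cell; s ∈ {0,
2.5·10⁻⁷, 10⁻⁶}; SD ∈ {0.24, 1.10, 1.95}; both modes) sized so the whole
suite stays in the minutes range at ~13 ms per exact ten-locus test;
statistical assertions use 3-binomial-SE tolerances at the replicate count
actually run. `scripts/acceptance.py` uses the full 10,000 replicates per
reported condition.

## What the generator does and does not emulate

The simulator produces additive, independent, fully observed loci with a
fixed count `n`, gamma magnitudes and binomial directions. It does not model
linkage, dominance, epistasis, measurement error in effect estimates, QTL
detection thresholds, or ascertainment of traits by large observed
divergence. Passing tests therefore validate the statistical machinery and
its documented behaviour under the stated model, not robustness of the tests
on real QTL studies, where detection bias and estimation error are known
additional forces.

## Numerical and design choices

- Exact engine default for `n ≤ 12`; MC beyond (support growth is
  combinatorial). `M` defaults to 10⁵.
- EE and fixation PMFs use exact integer binomial coefficients; the neutral
  PMF is bit-exactly `C(n,k)/2ⁿ`.
- Orientation tie rule as above; rejection threshold strict.
- TSV throughout (tab-delimited, UTF-8, Unix newlines); dataset writers
  record seed/regime in a comment line; results floats carry 6 significant
  digits; every pipeline output directory gets a `run.json` manifest
  (command, config, root seed, package version, timestamp).
- The variance grid is expressed as SDs (matching how rejection surfaces
  are usually plotted); endpoints 0.24 and 1.95 are fixed, the 14-point
  default density is a package choice and configurable.

## Known limitations

- The exact engine's memory/time grow combinatorially with `n` and the
  number of distinct magnitudes; beyond `n ≈ 12` use the MC engine.
- The MC engine can fail on datasets whose conditioning event is so rare
  that no stratum draw meets it at the chosen `M`; the exact engine has no
  such failure mode.
- Under the proportional regime the per-locus + probability uses the
  distribution mean `z̄ = 1`; applying the proportional regime to magnitudes
  from a different, non-mean-1 distribution requires passing `z_bar`
  explicitly.
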