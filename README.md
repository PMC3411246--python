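# qtlsign

Sign tests for distinguishing natural selection from genetic drift using
quantitative trait locus (QTL) data, together with the population-genetic
model and simulation machinery needed to study the tests themselves.

## The problem

A QTL study contrasting a high line and a low line yields, per locus, an
effect magnitude and a direction: a **+ allele** increases the trait in the
high line. Under neutral evolution the directions are fair coin flips; under
directional selection + alleles predominate. Two tests formalize this:

- **QTLST-EE** — exact two-sided binomial sign test on the + count `n₊`:
  `P = min(1, 2·Pr{X ≥ max(n₊, n−n₊)})`, `X ~ Bin(n, ½)`.
- **QTLST** — the conditional resampling test. Each null resample draws, per
  locus, a magnitude uniformly with replacement from the observed magnitudes
  and a fair ± sign; the P-value conditions on the observed phenotypic
  difference `R = 2ΣG₁`:

  `P = Pr{ n₊ ≥ n₊,obs | 2ΣG₁ ≥ R }`.

  `qtlsign` provides an exact enumeration engine (default for n ≤ 12) and a
  stratified Monte-Carlo engine, verified against each other and against
  brute-force enumeration.

The package also implements the selection-to-fixation map
`π(s) = e^{4Ns}/(e^{4Ns}+e^{2s})` (the probability a locus fixes the
+ allele under selection coefficient `s` in a population of size `N`), a
mean-1 gamma effect-size family indexed by variance, an optional
effect-proportional selection mode `s′ = (z/z̄)s`, and a seeded pipeline
measuring false-positive rates and power of both tests over a
(s × variance × mode) grid, stratified by `n₊`. See `docs/methods.md` for
the full model account, including the conditional test's structural
variance sensitivity (zero effect-size variance ⇒ P = 1, i.e. zero power).

## Worked example

Three mapped QTL, all + alleles, magnitudes 1, 1 and 4 (table format:
`locus_id  effect  direction`, tab-separated):

```python
from qtlsign import orient_dataset, qtlst_exact, qtlst_ee

ds = orient_dataset([1.0, 1.0, 4.0], [1, 1, 1])
r = qtlst_exact(ds)
print(r.p_value, r.event_probability)   # 0.76 0.11574074074074073
print(qtlst_ee(ds).p_value)             # 0.25
```

The conditional P-value is exactly 19/25: of the 6³ = 216 equally likely
(magnitude, sign) resamples, 25 reach a difference of at least R = 12, and
19 of those have all three + alleles — so even a unanimous sign pattern is
unremarkable once the observed difference is conditioned on. The same
computation from a shell:

```sh
qtlsign test --input qtl.tsv --method exact
```

```json
{
  "method": "QTLST-exact",
  "n": 3,
  "n_plus": 3,
  "R": 12.0,
  "p_value": 0.76,
  "reject": false,
  "event_probability": 0.11574074074074073
}
```

Other entry points: `qtlsign simulate` (synthetic oriented datasets),
`qtlsign power` (full rejection-rate grid → `grid.tsv`, `strata.tsv`,
`run.json`, optional `--plots`), `qtlsign table1` (the π(s) table), and the
narrative scripts in `examples/`. For instance
`python examples/equal_effects.py` prints:

```
       equal effects: n_plus = 10/10, R = 20  ->  QTLST P = 1.0000 (no reject), QTLST-EE P = 0.0020 (reject)
  one dominant locus: n_plus = 10/10, R = 21.8  ->  QTLST P = 0.0106 (reject), QTLST-EE P = 0.0020 (reject)
```

— the conditional test cannot reject neutrality at zero effect-size
variance no matter how lopsided the sign pattern, while unequal magnitudes
restore its power.

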