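"""Independent brute-force oracle for the conditional resampling test.

Enumerates every per-locus (magnitude choice, sign) outcome — all (2n)^n of
them — and tallies the conditioning event {2*sum(G1) >= R} and its n_plus
tail directly.  Multiset sums use the same canonical convention as the
package (accumulate count*value over ascending distinct values), implemented
here from scratch, so both sides evaluate the identical statistic.
"""

from itertools import product


def canonical_sum(values):
    acc = 0.0
    for v in sorted(set(values)):
        acc = acc + values.count(v) * v
    return acc


def brute_force_qtlst(magnitudes, n_plus_obs, r_half):
    """(p_value, event_probability) by full enumeration; feasible for n <= 5."""
    mags = [float(m) for m in magnitudes]
    n = len(mags)
    event = tail = 0
    for combo in product(range(2 * n), repeat=n):
        plus = [mags[c % n] for c in combo if c < n]
        minus = [mags[c % n] for c in combo if c >= n]
        if canonical_sum(plus) - canonical_sum(minus) >= r_half:
            event += 1
            if len(plus) >= n_plus_obs:
                tail += 1
    return tail / event, event / (2 * n) ** n
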