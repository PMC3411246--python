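"""The conditional sign test's blind spot: equal effect sizes.

Ten loci, all + alleles. If every locus has the same magnitude, the only
resample meeting the conditioning event {2*sum(G1) >= R} is the all-plus
one, so P = 1.0 and neutrality can never be rejected -- no matter how
extreme the allele count. Spreading the same total effect unevenly restores
power.
"""

import numpy as np

from qtlsign import orient_dataset, qtlst_ee, qtlst_exact

equal = orient_dataset(np.full(10, 1.0), np.ones(10, int))
spread = orient_dataset([0.1] * 9 + [10.0], np.ones(10, int))

for label, ds in (("equal effects", equal), ("one dominant locus", spread)):
    r = qtlst_exact(ds)
    ee = qtlst_ee(ds)
    print(
        f"{label:>20}: n_plus = {r.n_plus}/10, R = {r.R:g}  ->  "
        f"QTLST P = {r.p_value:.4f} ({'reject' if r.reject else 'no reject'}), "
        f"QTLST-EE P = {ee.p_value:.4f} ({'reject' if ee.reject else 'no reject'})"
    )

print(
    "\nBoth datasets show 10 of 10 + alleles. The equal-effects test rejects\n"
    "neutrality in both (P = 2/1024), but the conditional resampling test\n"
    "only rejects when the effect magnitudes are variable: conditioning on\n"
    "the observed difference absorbs the entire signal at zero variance."
)
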