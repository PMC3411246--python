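"""Run the sign tests on a QTL table supplied as a TSV file.

Writes a small example table (the format used for real QTL study outputs:
locus_id / effect / direction), reads it back, and applies the exact
conditional test, its Monte-Carlo engine, and the equal-effects test.
"""

import tempfile
from pathlib import Path

import numpy as np

from qtlsign import qtlst_ee, qtlst_exact, qtlst_mc, read_qtl_table

table = """\
locus_id	effect	direction
chr1@12	1.0	+
chr2@88	1.0	+
chr3@41	4.0	+
"""

path = Path(tempfile.mkdtemp()) / "qtl.tsv"
path.write_text(table)
ds = read_qtl_table(path)
print(f"read {ds.n} loci: n_plus = {ds.n_plus}, trait difference R = {ds.R:g}")

exact = qtlst_exact(ds)
mc = qtlst_mc(ds, M=100_000, rng=np.random.default_rng(0))
ee = qtlst_ee(ds)
print(f"QTLST (exact engine): P = {exact.p_value:.4f}   (= 19/25)")
print(f"QTLST (Monte Carlo) : P = {mc.p_value:.4f}   ({mc.mc_draws} draws/stratum)")
print(f"QTLST-EE            : P = {ee.p_value:.4f}   (3 of 3 + alleles, two-sided)")
print(
    f"conditioning event probability = {exact.event_probability:.4f} (= 25/216)\n"
    "\nThe conditional P is the chance a random reassignment of magnitudes and\n"
    "signs shows >= 3 + alleles, given its implied difference reaches R = 12;\n"
    "none of the tests rejects neutrality for this 3-locus table."
)
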