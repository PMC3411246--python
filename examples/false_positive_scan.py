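"""False-positive rates of both tests across the effect-size variance axis.

Simulates neutral (s = 0) ten-locus datasets at three effect-size SDs and
reports how often each test rejects at alpha = 0.05. A reduced replicate
count keeps this illustration fast; scripts/acceptance.py runs the full
10,000-replicate version.
"""

from qtlsign import GridConfig, false_positive_curve, run_grid

config = GridConfig(
    s_values=(0.0,),
    sd_grid=(0.24, 1.10, 1.95),
    modes=("constant",),
    replicates=1_000,
    seed=42,
)
cells = run_grid(config, progress=True)
curve = false_positive_curve(cells)
print()
print(curve.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
print(
    "\nThe equal-effects test holds its discrete-binomial rate (~22/1024 =\n"
    "0.021) at every variance. The conditional test's rate instead depends\n"
    "on the variance of effect sizes: at SD 0.24 it almost never rejects a\n"
    "neutral dataset, and its rate rises with SD -- variance sensitivity\n"
    "that has nothing to do with selection."
)
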