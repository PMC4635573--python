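"""Calibrate a trait→SNPP line from five samples and score the rest.

Simulates one variety of 40 panicles, measures every scan, fits the
5-point area calibration (five panicles chosen uniformly over the area
scale), and evaluates the predictions on the 35 held-out panicles.
"""

from spikescan import calibrate_and_evaluate
from spikescan.experiments import measure_variety

traits = measure_variety(seed=5, n_panicles=40, mean_snpp=150.0, variety="A")
samples = list(zip(traits.panicle_id, traits.total_area_px.astype(float),
                   traits.snpp_manual))

model, report = calibrate_and_evaluate(samples, trait="area", mode="five_point", k=5)

print(f"calibration line:   SNPP = {model.slope:.5f} * area + {model.intercept:.2f}")
print(f"R^2:                {model.r_squared:.4f}")
print(f"held-out panicles:  {report.n}")
print(f"error < 5%:         {report.frac_within_5:.1f}% of panicles")
print(f"error < 10%:        {report.frac_within_10:.1f}% of panicles")
print(f"SNPS deviation:     {report.deviation_pct:+.2f}%")

# The slope is spikelets per pixel of branch-region area.  The SNPS
# deviation compares the mean estimated count against the mean manual
# count — the quantity used for per-area yield assessment — and should
# stay well inside +-5%.
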