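"""Detect excitatory and inhibitory connections in a small noisy cohort.

Generates a miniature cohort of pairs with log-normal gains, bursting, and
shared rate co-modulation, classifies each pair with the hollow-median
predictor on the deconvolved CCH, and scores detection with the pooled f1.
"""

from spikedeconv import CohortSpec
from spikedeconv.protocols import f1_table, mse_table, run_cohort_benchmark

spec = CohortSpec(
    n_excitatory=12, n_inhibitory=12, n_unconnected=6,
    duration_range=(3600.0, 7200.0),
)
df = run_cohort_benchmark(spec, seed=7, predictors=("median",))

for deconv in (False, True):
    sub = df[df.deconvolved == deconv]
    tag = "dcCCH" if deconv else "raw CCH"
    correct = (sub.label == sub.truth).mean()
    print(f"{tag:8}: {correct:.0%} of {len(sub)} pairs labelled correctly")
print()
print(mse_table(df).to_string(index=False))
print()
print(f1_table(df)[["method", "deconvolved", "f1"]].to_string(index=False))
print()
print(
    "f1 pools false positives and negatives over both connection classes;\n"
    "deconvolution lowers the gain error (MSE) and raises f1 by removing\n"
    "burst-induced structure before the Poisson test."
)
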