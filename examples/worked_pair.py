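"""Recover a known synaptic gain from a bursty spike-train pair.

Simulates two coupled point-process neurons (bursty presynaptic unit at
2 spk/s, second-order-gamma postsynaptic unit at 8 spk/s, true gain 0.04)
and estimates the spike transmission gain with the three baseline
predictors, before and after deconvolving the autocorrelograms from the
cross-correlogram.
"""

from spikedeconv.pointproc import simulate_pair
from spikedeconv.protocols import estimate_all_methods, burst_pair_config

cfg = burst_pair_config(br1=0.4, stg=0.04, duration=833 * 60.0, seed=1)
pair = simulate_pair(cfg)
print(f"simulated {cfg.duration / 60:.0f} min, true gain rSTG = {cfg.stg12}")
print(f"presynaptic rate {pair.s1.rate:.2f} spk/s, postsynaptic {pair.s2.rate:.2f} spk/s")
print()
print(f"{'predictor':<10} {'histogram':<6} {'eSTG':>8} {'vs truth':>9}")
for row in estimate_all_methods(pair, sign="excitatory"):
    tag = "dcCCH" if row["deconvolved"] else "CCH"
    pct = 100 * row["estg"] / cfg.stg12
    print(f"{row['method']:<10} {tag:<6} {row['estg']:8.4f} {pct:8.0f}%")
print()
print(
    "Burst spiking distorts the raw-CCH estimates (tails too high, jitter\n"
    "and median too low); after deconvolution all three land near the true\n"
    "gain of 0.04 extra postsynaptic spikes per presynaptic spike."
)
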