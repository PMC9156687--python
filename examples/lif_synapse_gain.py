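"""Ground-truth gain of a conductance-based LIF synapse, and its estimate.

Calibrates the synaptic conductance to a 1 mV unitary EPSP, runs the
two-cell model with the synapse on and off (shared noise), computes the
exact gain from the paired rates, and compares it with the tails-predictor
estimate read off the cross-correlogram alone.
"""

from spikedeconv import LifSynConfig, calibrate_uepsp, compute_cch, estimate_stg
from spikedeconv.lifsyn import run_rstg_experiment

g = calibrate_uepsp(1.0)
print(f"conductance for a 1.0 mV uEPSP: g_syn = {g:.4f} mS/cm^2")

cfg = LifSynConfig(sigma=3.5, g_syn=g, duration=3600.0, seed=3)
res = run_rstg_experiment(cfg)
cch = compute_cch(res["presyn"], res["postsyn_syn"])
est = estimate_stg(cch, "tails", sign="excitatory")

print(f"postsynaptic rate with synapse    : {res['lambda2_syn']:.2f} spk/s")
print(f"postsynaptic rate without synapse : {res['lambda2_nosyn']:.2f} spk/s")
print(f"ground-truth gain (paired rates)  : rSTG = {res['rstg']:.4f}")
print(f"estimate from spike times alone   : eSTG = {est.estg:.4f}")
print()
print(
    "The eSTG integrates the above-baseline transmission curve of the CCH\n"
    "over its causal support; with one hour of data it recovers the gain\n"
    "measured by the (experimentally inaccessible) synapse-removal contrast."
)
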