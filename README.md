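# spikedeconv

Detection and quantification of monosynaptic spike transmission between
neurons, from spike times alone, with correlogram deconvolution.

## The problem

Whether one neuron drives another is usually read off the spike-to-spike
cross-correlation histogram (CCH): a synaptic connection shows up as a
fast causal peak (or trough) at 1–5 ms lag. Two confounds corrupt the
readout. Slow co-modulation by shared inputs raises the baseline, which
timescale-separation baselines ("tails" mean, jittered-spike convolution,
hollow median filter) handle well. But the CCH also contains each unit's
own autocorrelation structure — burst spiking and refractoriness —
convolved with the transmission curve, and that structure lives at the
*same* fast timescale as transmission, so no baseline can remove it.

Writing the CCH (to small loop gain) as

```
CCH = ACH1 * STC21  +  other-inputs  +  ACH2 * STC12(-t)
```

(`*` convolution, `STC` the causal spike-transmission curve) suggests the
fix: scale each autocorrelogram (ACH) to unit sum and divide it out of
the CCH in the Fourier domain. The deconvolved CCH (dcCCH) keeps the
baseline and the transmission curves but sheds burst-induced side lobes.
The gain of a connection — the **spike transmission gain (STG)**, extra
postsynaptic spikes per presynaptic spike — is then the integral of the
above-baseline curve over its causal support:

```
crCCH[m] = (CCH[m] - pred[m]) / (N1 B),      eSTG = sum_m STC[m] * B
```

The package implements the full pipeline (correlograms, baseline
predictors, deconvolution, curve extraction, Poisson detection at
`alpha = 0.001`, f1/bootstrap/permutation scoring) plus the ground-truth
generators that make it testable by parameter recovery: point-process
pairs with exactly known gains, bursts, gamma-order refractoriness and
shared rate co-modulation; a conductance-based LIF-synapse pair; and a
CA1-like network of bursty quadratic E-cells and Wang–Buzsáki I-cells.
It is aimed at systems neuroscientists working with long extracellular
recordings of sorted units.

## A worked example

`examples/worked_pair.py` simulates a bursty presynaptic unit (2 spk/s,
burst fraction 0.4) driving a second-order-gamma unit (8 spk/s) with a
true gain of 0.04 over 833 minutes, then estimates the gain six ways:

```
predictor  histogram     eSTG  vs truth
tails      CCH      0.0560      140%
tails      dcCCH    0.0394       98%
jitter     CCH      0.0218       55%
jitter     dcCCH    0.0248       62%
median     CCH      0.0275       69%
median     dcCCH    0.0367       92%
```

On the raw CCH the burst side lobes inflate the tails estimate and drag
the jitter/median estimates down; after deconvolving both scaled ACHs the
tails and median estimates land within a few percent of the true 0.04.
The same pipeline in code:

```python
from spikedeconv import compute_cch, compute_ach, deconvolve_cch, estimate_stg

cch = compute_cch(pre, post)            # SpikeTrain inputs, 1-ms bins
dcch = deconvolve_cch(cch, compute_ach(pre), compute_ach(post)).dcch
result = estimate_stg(dcch, "median")   # -> StcResult(estg, b_l, b_r, stc)
```

Other entry points: `minimal_detectable_stg` (analytic detectability
bound; 0.00142 for 1 and 10 spk/s units over 50,000 s at
`alpha = 0.001`), `detect_connection` / `confusion_and_f1` (cohort
screening), `simulate_pair` / `generate_cohort` / `simulate_lif_syn` /
`simulate_network` (ground truth), and the benchmark drivers in
`spikedeconv.protocols`. Each script in `examples/` is a narrative
single-capability walkthrough.

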