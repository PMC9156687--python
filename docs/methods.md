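# Methods

## The estimation problem

Two simultaneously recorded spike trains, a trigger (candidate
presynaptic) unit and a reference (candidate postsynaptic) unit, are
summarized by their cross-correlation histogram (CCH): bin `m` counts
spike pairs whose reference-minus-trigger time difference falls in
`[(m - 1/2)B, (m + 1/2)B)`, with `B = 1` ms and 61 bins (`M = 30`) by
default. A monosynaptic connection appears as a fast causal transient; the
quantity of interest is the **spike transmission gain (STG)** — the
expected number of extra (or, for inhibition, suppressed) postsynaptic
spikes per presynaptic spike.

Under a linear-time-invariant view of spike transmission with small loop
gain, the CCH decomposes into three additive parts: the trigger unit's
autocorrelogram (ACH) convolved with the causal transmission curve, the
reference unit's ACH convolved with the time-reversed reverse-direction
curve, and the cross-correlation of the background ("other inputs")
activity. Two consequences drive the package design:

1. Timescale-separation baselines alone cannot remove the ACH convolution
   terms — bursting or periodicity in either unit leaks fast structure
   into the CCH that mimics or masks transmission.
2. Dividing the CCH's discrete Fourier transform by the transforms of the
   two *scaled* ACHs removes that second-order structure, leaving the
   background term plus the (slightly rescaled) transmission curves: the
   deconvolved CCH (dcCCH).

## Pipeline

`estimate_stg` composes four steps, each available separately:

- **ACH scaling** (`scale_ach`): zero the zero-lag bin, subtract the mean
  over all bins, divide by the total spike count, then set the zero-lag
  bin so the kernel sums to one. A flat count ACH maps to a near-delta
  kernel (exactly delta up to a uniform residue of `c/((2M+1)N)` per bin,
  a consequence of taking the mean over all bins; see Numerical choices),
  so Poisson-like trains leave the CCH essentially untouched.
- **Deconvolution** (`deconvolve_cch`): plain DFT of the 61-bin
  histograms treated as one circular period; divide by one kernel
  spectrum (unidirectional) or both (bidirectional, the default); inverse
  transform. Because the kernels have unit DC gain, the baseline count
  level is preserved.
- **Baseline prediction** (`predictors`): the "other inputs" level is
  estimated by one of three timescale-separation rules — the mean of the
  tail bins (`|lag| >= 11` ms), convolution with a unit-sum Gaussian
  (SD 5 bins, support ±15 bins) whose central weight is multiplied by
  0.6 before renormalization (the variance-reduced analogue of spike-time
  jittering), or a hollow median filter of order 10 (±5 bins, centre
  excluded).
- **Curve extraction** (`extract_stc`): subtract the baseline, scale by
  `1/(N1 B)` to conditional-rate units (spk/s), find the extremum inside
  the causal region of interest `(0, 5]` ms, walk outward to the nearest
  zero crossings to bound the support (left bound clamped to the first
  causal bin; right bound free to leave the ROI), zero the curve
  elsewhere, and integrate: `eSTG = sum(STC) * B`.

Detection (`detect_connection`) tests the extreme ROI bin (or the ROI
sum) against its predicted mean with a one-sided Poisson tail at
`alpha = 0.001`, labelling each pair excitatory, inhibitory, or
unconnected. The default tail is the plain conservative `P(X >= k)`;
with the max-bin statistic over a 5-bin ROI and no multiplicity
correction this keeps the excitatory false-positive rate on independent
Poisson pairs below 0.005 (measured on 1000 null pairs in the test
suite). The mid-p variant (`mid_p=True`) subtracts half the point mass
and is slightly anti-conservative in the same setting.

Two closed-form quantities complete the module: the refractory-corrected
ground-truth gain from paired rates,
`rSTG = (l2_syn - l2_nosyn)/l1 * (1 - l2_nosyn (ARP2 + dt))`, and the
minimal detectable gain `(k* - lambda)/(F1 T)` with
`lambda = F1 F2 T B` and `k*` the inverse Poisson CDF at `1 - alpha`
(the inverse-CDF reading reproduces the worked value 0.00142 for
`F1 = 1`, `F2 = 10`, `T = 50,000` s, `B = 1` ms, `alpha = 0.001`).

## Ground-truth generators

### Point-process pairs (`pointproc`)

Each neuron is sampled per 1-ms step from a Bernoulli process whose
probability is a rate function, then modified in order: gamma-order
decimation (keep every γ-th spike), burst insertion, and removal of
spikes within 2 ms of the previous spike (absolute refractory period,
ARP). The desired rate is pre-compensated,
`lambda_m = lambda_d * gamma / (1 + BR)` with composite burst fraction
`BR = BR1 (1 + BR2)`, so the emitted rate returns to `lambda_d` (verified
within 5% at one hour). Burst timing: a second-in-burst spike lags the
first by 2–6 samples with triangular weights 1:2:3:2:1; a third (with
probability `BR2 = 0.4`) lags the *second* by 3–5 samples with weights
1:2:1. The second-spike construction follows the stated window; the
element count and anchor of the third-spike window are not fully
specified further, and the successive-ISI reading used here is one of
the admissible choices.

Connectivity: for each presynaptic spike, the number of added postsynaptic
spikes is Poisson with mean `STG` (gains above 1 are legal), with latency
drawn from the transmission-curve shape — a 5-element asymmetric triangle
at lags 1–5 samples with weights 5:4:3:2:1, peaked at the shortest
latency as monosynaptic couplings are. Inhibition removes spikes: each
presynaptic spike attempts, with probability `|STG|` divided by the
empirical probability that the 1–5-sample window contains a postsynaptic
spike, to delete one window spike (chosen with probability proportional
to the curve weight at its lag). The expected number of removals per
presynaptic spike then equals `|STG|` exactly, saturating at full window
suppression when `|STG|` exceeds the occupancy — a limit reported by a
warning. ARP is re-imposed after connectivity; the ~2–3% of added spikes
lost to refractory collisions are the same loss the refractory-corrected
gain formula describes.

Co-modulation: both rate functions share
`lambda(t) = lambda_m (1 + lambda_c(t))` where `lambda_c` is Gaussian
white noise filtered with a decaying exponential (`tau_c = 20` ms),
normalized to a stationary SD of `sigma_c` spk/s *on the summed rate of
the pair*, and clipped to [-1, 1]. `sigma_c` is dimensionally a rate
while the modulation it feeds is relative; the summed-rate normalization
was fixed once so that the cohort's `sigma_c ~ U[1, 15]` spk/s spans
weak to full modulation (clipping engages only near the top of the
range). The default cohort (`CohortSpec`) holds the remaining study
conditions: 500/500/250 excitatory/inhibitory/unconnected pairs, 2 and
8 spk/s pre/post, `BR1 ~ U[0, 0.4]`, durations 90 min–5 h, co-modulation
in 60% of pairs, log-normal gains with mean ± SD 0.019 ± 0.01
(excitatory) and −0.014 ± 0.007 (inhibitory).

### LIF-synapse model (`lifsyn`)

A conductance-based leaky integrate-and-fire neuron
(`C = 1 uF/cm^2`, `g_L = 0.5 mS/cm^2`, `E_L = -60 mV`, threshold −50 mV,
reset −70 mV, bias 1 uA/cm^2, peak/hold 50 mV for 1 ms then reset for
1 ms, total refractoriness 2 ms) driven by a Poisson train (5 spk/s,
minimum ISI 4 ms) through a single excitatory conductance with
rise/decay 0.1/3 ms gated by `H(V) = (1 + tanh(V/4))/2`. Integration is
explicit second-order Runge-Kutta (endpoint) at `dt = 0.1` ms.
`calibrate_uepsp` bisects the conductance so that a single spike at rest
deflects the membrane by a requested unitary EPSP; the range
`g_syn in [0, 0.032] mS/cm^2` maps onto 0–2 mV, which the implementation
reproduces (1.98 mV at the upper bound).

**Noise convention.** The noise amplitude `sigma` (mV) is defined as the
stationary SD of the subthreshold membrane potential of the passive
membrane and realized as per-step voltage increments of SD
`sigma * sqrt(2 dt / tau_m)`. A literal per-step current draw without
step-size scaling would make the effective noise vanish at small `dt`
and silence the cell across the entire working `sigma` range, so the
diffusion convention is used instead; a fixed gain of 0.9 on the mapping
was calibrated once so the spontaneous rate-vs-`sigma` curve matches the
target phenotype (no spiking below 2 mV; under 25 spk/s below 4 mV) and
then frozen. Paired synapse-on/off runs share the presynaptic train and
draw one noise value per step in both conditions, so the rate difference
isolates transmitted spikes.

### Conductance-based network (`network`)

80 excitatory cells (quadratic "simple-model" dynamics with a slow
recovery variable; per-cell reset potential — the burst factor BF —
uniform on [−42, −35] mV with the recovery increment mapped linearly
onto the same dial, 1.12 at −42 to 1.225 at −35) and 20 Wang–Buzsáki
interneurons, integrated with endpoint RK2 at `dt = 0.025` ms. Wiring:
each E-cell contacts one random I-cell (0.055 mS/cm^2), each I-cell one
random E-cell and one other I-cell (0.25 mS/cm^2); no E–E connections;
a log-normal variant draws per-edge conductances (means 0.055/0.22/0.22,
SDs 0.02/0.08/0.04). Synaptic gates follow the same `H(V)` kinetics with
AMPA (0.1/3 ms, 0 mV) and GABA_A (0.3/9 ms, −80 mV) parameters.

The same noise convention applies, with per-class gains (2.4 for
E-cells, 2.6 for I-cells) calibrated once so the spontaneous phenotype is
CA1-like: E-cells at a few spk/s with BF-graded short-ISI content,
I-cells tonic at 10–30 spk/s with negative burst index when unconnected.
The nominal `sigma = 2 mV` with an unspecified integrator scaling cannot
drive the E-cells over their ~15 mV threshold barrier under any literal
reading, so the gain dial is a required part of this generator. E-cell
spikes are peak crossings (reset applied); I-cell spikes are upward zero
crossings with a 2-ms double-count guard; the simulation aborts if any
membrane potential leaves ±200 mV.

## What the generators do and do not emulate

The point-process cohort reproduces the statistical features the
estimators are sensitive to — bursting, gamma-order refractoriness,
shared slow co-modulation, wide duration and gain ranges — with exactly
known gains, but transmission there is stationary, history-independent,
and single-lag-shaped; no common-input third neuron, plasticity, or
nonstationarity is modelled. The conductance models add spike-generation
nonlinearity, reciprocal loops, and biophysical transmission curves, at
the cost of gains known only through paired contrasts (two-cell model) or
conductances (network). Passing recovery tests on these generators
therefore shows the pipeline removes second-order spike-train statistics
under the stated model of transmission; it does not certify behaviour
under nonstationary rates or strong loops, where the small-loop-gain
approximation itself fails.

## Numerical choices and degenerate inputs

- Bin membership: differences are divided by `B` and floored after
  adding 1/2, making edge behaviour deterministic (half-open on the
  right); simulator spike times are integer multiples of the step, so no
  difference falls near a bin edge.
- ACH scaling subtracts the mean over **all** `2M + 1` bins (with the
  zero-lag bin already zeroed), matching the worked scaling example;
  subtracting the off-zero-bin mean instead would make flat ACHs map to
  exact deltas, but the two differ only by `O(lambda B)` in the kernel
  and by well under 1% in any downstream gain.
- Deconvolution regularization: kernel Fourier coefficients below 1e-3
  in magnitude are raised to the floor with phase preserved; the event
  is reported on the result object. The division is circular (no
  padding); round-trip reconvolution error is bounded at 1e-6 in tests.
- Zero crossings in `extract_stc`: the first bin, moving outward from
  the extremum, with opposite sign or exactly zero ends the support;
  ties in the extremum go to the smallest lag; an all-zero (or
  wrong-signed) ROI returns an empty curve with zero gain.
- Degenerate inputs: empty trains produce all-zero histograms (not
  errors); an ACH with no spikes cannot be scaled; a predictor that is
  non-positive across the whole ROI makes detection fail loudly.
- Burst index: `(head - tail)/(head + tail)` with head the summed ACH
  counts at lags (2, 10] ms and tail at (35, 50] ms. The windows have 8
  and 15 bins, so a flat (Poisson-like) ACH sits near −0.30, not 0;
  positive values indicate strong short-ISI structure.
- All stochastic components accept explicit seeds; one master seed fans
  out to per-pair/per-cell child streams (`numpy` `SeedSequence`), so
  cohorts are bit-reproducible and partially re-runnable.

## Benchmark problem sizes

The test suite and the acceptance script run the study designs at
reduced scale, chosen as the package's own benchmark sizes: the worked
bursty-pair example at its full 833 min over 10 seeds; the noisy cohort
at 1/10 of the class counts (125 pairs, distributions unchanged); the
LIF grid as 4 noise levels (3–5 mV, the non-degenerate spontaneous
regime at one-hour runs) × 4 uEPSP amplitudes (0.5–2 mV) × 2
repetitions of 60-min paired runs; and the network benchmark as three
20 E + 5 I networks of 20 simulated minutes. At these sizes the
recovered numbers carry Monte-Carlo spread of a few percent
(seed-to-seed SD ≈ 1% on the LIF-grid mean relative error, ≈ 15% on the
cohort MSE); the full-scale designs are reachable by passing the
original sizes to the same functions.

## Known limitations

- The hollow-median and jitter baselines absorb part of a 5-bin-wide
  transmission curve (4–5 of the 10 window values lie inside the peak),
  biasing their gains low by roughly 10–15% at cohort-like signal-to-
  noise; the tails baseline is unbiased on isolated peaks but inherits
  any slow background under its tail window. These are properties of the
  estimators themselves and are visible in the benchmark tables.
- The causal-support convention discards transmitted mass at the zero-lag
  bin (~1–2% for realistic latency spreads) and beyond the first noise
  crossing; on the LIF grid the net effect is a mean gain deficit of
  ~4% at one-hour runs.
- Inhibitory gains are recoverable only up to the window-occupancy limit
  `lambda_post * W`; configurations beyond it saturate (warned).
- The bidirectional deconvolution divides each transmission curve by the
  *other* unit's kernel; for strongly structured partner ACHs this
  redistributes curve mass within its causal side (the documented
  divisive-factor caveat), which is why strong-coupling settings should
  use the unidirectional mode.
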