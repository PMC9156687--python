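"""Point-process spike-train pairs with exactly known transmission gain.

Each pair is generated in three sequential steps: (1) a rate function per
neuron (constant, or co-modulated by shared exponential-filtered noise);
(2) independent Bernoulli sampling per time step, followed by gamma-order
decimation, burst insertion, and absolute-refractory-period (ARP)
decimation; (3) connectivity, adding (excitation) or removing (inhibition)
postsynaptic spikes per presynaptic spike according to a causal spike
transmission curve, followed by a final ARP pass.

The desired mean rate ``lambda_d`` is pre-compensated to
``lambda_m = lambda_d * gamma / (1 + BR)`` (BR the composite burst fraction
``BR1 * (1 + BR2)``) so that decimation and burst insertion return the
emitted rate to approximately ``lambda_d``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numba as nb
import numpy as np
from scipy.signal import lfilter

from .trains import SpikeTrain

__all__ = [
    "NeuronSpec",
    "PairSimConfig",
    "CohortSpec",
    "SimulatedPair",
    "make_rate_function",
    "sample_spike_train",
    "apply_connectivity",
    "simulate_pair",
    "generate_cohort",
]

# second-in-burst lags the first burst spike by 2 samples: offsets 2..6,
# symmetric triangular weights
_BURST2_OFFSETS = np.array([2, 3, 4, 5, 6])
_BURST2_WEIGHTS = np.array([1.0, 2.0, 3.0, 2.0, 1.0]) / 9.0
# third-in-burst lags the second by a 3-sample triangular window
_BURST3_OFFSETS = np.array([3, 4, 5])
_BURST3_WEIGHTS = np.array([1.0, 2.0, 1.0]) / 4.0
# spike transmission curve: asymmetric triangle lagging the presynaptic
# spike by one sample, peaked at the shortest latency
STC_OFFSETS = np.array([1, 2, 3, 4, 5])
STC_WEIGHTS = np.array([5.0, 4.0, 3.0, 2.0, 1.0]) / 15.0

LOOP_GAIN_WARN = 1e-3


@dataclass(frozen=True)
class NeuronSpec:
    """Generative parameters of one point-process neuron.

    rate: desired mean rate lambda_d, spk/s.  gamma: gamma order (1 =
    Poisson).  br1: probability that a spike is first in a burst; br2:
    probability of a third burst spike given a second.  arp: absolute
    refractory period, seconds.
    """

    rate: float
    gamma: int = 1
    br1: float = 0.0
    br2: float = 0.4
    arp: float = 0.002

    @property
    def burst_fraction(self) -> float:
        """Composite burst fraction BR = BR1 * (1 + BR2)."""
        return self.br1 * (1.0 + self.br2)

    @property
    def modified_rate(self) -> float:
        """lambda_m = lambda_d * gamma / (1 + BR)."""
        return self.rate * self.gamma / (1.0 + self.burst_fraction)


@dataclass(frozen=True)
class PairSimConfig:
    """Full generative specification of one simulated pair."""

    neuron1: NeuronSpec
    neuron2: NeuronSpec
    stg12: float = 0.0
    stg21: float = 0.0
    comod_sigma: float = 0.0
    comod_tau: float = 0.02
    duration: float = 3600.0
    dt: float = 0.001
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass(frozen=True)
class SimulatedPair:
    s1: SpikeTrain
    s2: SpikeTrain
    truth: dict
    config: PairSimConfig


def make_rate_function(cfg: PairSimConfig, rng: np.random.Generator):
    """Per-step rate arrays (spk/s) for both neurons.

    Without co-modulation both rates are the constant compensated rates.
    With co-modulation, shared Gaussian white noise is filtered with a
    decaying exponential (time constant ``comod_tau``), normalized to a
    stationary SD of ``comod_sigma`` spk/s on the summed rate of the pair
    (so the relative modulation depth is ``sigma_c / (lm1 + lm2)``, full
    modulation at the top of the cohort's sigma_c range), clipped to
    [-1, 1], and applied as the common relative modulation
    ``lambda(t) = lambda_m * (1 + lambda_c(t))``.
    """
    n = cfg.n_samples
    lm1 = cfg.neuron1.modified_rate
    lm2 = cfg.neuron2.modified_rate
    if cfg.comod_sigma <= 0:
        return np.full(n, lm1), np.full(n, lm2)
    a = np.exp(-cfg.dt / cfg.comod_tau)
    white = rng.normal(0.0, 1.0, size=n)
    filtered = lfilter([1.0], [1.0, -a], white)
    filtered *= np.sqrt(1.0 - a * a)  # unit stationary SD
    lam_c = np.clip(filtered * cfg.comod_sigma / (lm1 + lm2), -1.0, 1.0)
    return lm1 * (1.0 + lam_c), lm2 * (1.0 + lam_c)


@nb.njit(cache=True)
def _arp_keep(idx: np.ndarray, arp_samples: int) -> np.ndarray:
    keep = np.empty(idx.size, dtype=np.bool_)
    last = -10 * arp_samples
    for i in range(idx.size):
        ok = idx[i] - last >= arp_samples
        keep[i] = ok
        if ok:
            last = idx[i]
    return keep


def _enforce_arp(idx: np.ndarray, arp_samples: int) -> np.ndarray:
    """Remove spikes closer than arp_samples after the previous kept spike."""
    if idx.size == 0:
        return idx
    return idx[_arp_keep(np.ascontiguousarray(idx, dtype=np.int64), arp_samples)]


def _bernoulli_indices(p, n: int, rng: np.random.Generator) -> np.ndarray:
    """Indices of successes of a per-step Bernoulli process.

    For a constant success probability the gaps are geometric and are
    sampled directly; a per-step probability array is handled by thinning a
    constant-rate envelope.  Both are draw-for-draw exact equivalents of
    stepping through all n Bernoulli trials.
    """
    p_arr = None
    if isinstance(p, np.ndarray) and p.size > 1:
        p_arr = p
        p_max = float(p.max())
    else:
        p_max = float(p if np.isscalar(p) else p.item())
    if p_max <= 0:
        return np.empty(0, dtype=np.int64)
    chunks, pos = [], -1
    while pos < n:
        m = max(int((n - pos) * p_max * 1.2) + 16, 1024)
        gaps = rng.geometric(p_max, size=m)
        idx = pos + np.cumsum(gaps)
        chunks.append(idx)
        pos = int(idx[-1])
    idx = np.concatenate(chunks) if len(chunks) > 1 else chunks[0]
    idx = idx[idx < n]
    if p_arr is not None and idx.size:
        idx = idx[rng.random(idx.size) < p_arr[idx] / p_max]
    return idx


def sample_spike_train(
    rate, spec: NeuronSpec, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Sample one spike train (sample indices) over ``n = len(rate)`` steps.

    Bernoulli sampling with p = rate * dt per step, then gamma decimation
    (every gamma-th spike kept), burst insertion (only originally sampled
    spikes seed bursts), and ARP decimation.  *rate* may be a per-step
    array or a ``(constant_rate, n_steps)`` tuple.
    """
    if isinstance(rate, tuple):
        lam, n = rate
        p = lam * dt
        p_max = p
    else:
        rate = np.asarray(rate, dtype=float)
        n = rate.size
        p = rate * dt
        p_max = float(p.max())
    if p_max >= 1.0:
        raise ValueError("rate * dt must stay below 1")
    idx = _bernoulli_indices(p, n, rng)
    if spec.gamma > 1:
        idx = idx[spec.gamma - 1 :: spec.gamma]
    if spec.br1 > 0 and idx.size:
        first = idx[rng.random(idx.size) < spec.br1]
        second = first + rng.choice(_BURST2_OFFSETS, size=first.size, p=_BURST2_WEIGHTS)
        third_mask = rng.random(first.size) < spec.br2
        third = second[third_mask] + rng.choice(
            _BURST3_OFFSETS, size=int(third_mask.sum()), p=_BURST3_WEIGHTS
        )
        idx = np.unique(np.concatenate([idx, second, third]))
        idx = idx[idx < n]
    arp_samples = int(round(spec.arp / dt))
    return _enforce_arp(idx, arp_samples)


def apply_connectivity(
    pre_idx: np.ndarray,
    post_idx: np.ndarray,
    stg: float,
    n_samples: int,
    rng: np.random.Generator,
    stc_offsets: np.ndarray = STC_OFFSETS,
    stc_weights: np.ndarray = STC_WEIGHTS,
) -> np.ndarray:
    """Modify the postsynaptic spike train according to one directed STC.

    Excitation: per presynaptic spike the number of added spikes is Poisson
    with mean ``stg`` (the gain is not limited to [0, 1]); each latency is
    drawn from the normalized STC shape.  Inhibition: a decimation attempt
    removes one postsynaptic spike from the STC window following the
    presynaptic spike (chosen with probability proportional to the STC
    weight at its lag); the attempt probability is ``|stg|`` divided by the
    empirical window-occupancy probability, so the expected number of
    removals per presynaptic spike equals ``|stg|`` (saturating at full
    window suppression when ``|stg|`` exceeds the occupancy).  The caller
    re-imposes the ARP afterwards.
    """
    if stg == 0 or pre_idx.size == 0:
        return post_idx
    if stg > 0:
        n_add = rng.poisson(stg, size=pre_idx.size)
        total = int(n_add.sum())
        if total == 0:
            return post_idx
        origins = np.repeat(pre_idx, n_add)
        lags = rng.choice(stc_offsets, size=total, p=stc_weights)
        new = origins + lags
        new = new[new < n_samples]
        return np.unique(np.concatenate([post_idx, new]))
    if stg < -1:
        raise ValueError("inhibitory gain magnitude cannot exceed 1")
    if post_idx.size == 0:
        return post_idx
    lo_off, hi_off = int(stc_offsets[0]), int(stc_offsets[-1])
    j_lo = np.searchsorted(post_idx, pre_idx + lo_off, side="left")
    j_hi = np.searchsorted(post_idx, pre_idx + hi_off, side="right")
    has = j_hi > j_lo
    p_avail = float(has.mean())
    if p_avail == 0.0:
        return post_idx
    q = -stg / p_avail
    if q > 1.0:
        warnings.warn(
            "inhibitory gain exceeds the postsynaptic window occupancy; "
            "decimation saturates below the requested |stg|", stacklevel=2,
        )
        q = 1.0
    acting = np.flatnonzero(has & (rng.random(pre_idx.size) < q))
    weight_at = np.zeros(hi_off + 1)
    weight_at[stc_offsets] = stc_weights
    removed = np.zeros(post_idx.size, dtype=bool)
    for i in acting:
        cand = np.arange(j_lo[i], j_hi[i])
        cand = cand[~removed[cand]]
        if cand.size == 0:
            continue
        w = weight_at[post_idx[cand] - pre_idx[i]]
        if w.sum() <= 0:
            continue
        removed[rng.choice(cand, p=w / w.sum())] = True
    return post_idx[~removed]


def simulate_pair(cfg: PairSimConfig) -> SimulatedPair:
    """Generate one pair with recorded ground truth.

    The three steps (rates, independent sampling, bidirectional
    connectivity) use independent child streams of ``cfg.seed``, and the
    connectivity in each direction acts on the pre-connectivity trains.
    """
    loop = abs(cfg.stg12 * cfg.stg21)
    if loop > LOOP_GAIN_WARN:
        warnings.warn(
            f"loop gain |stg12*stg21| = {loop:.2g} exceeds the small-loop "
            "approximation range", stacklevel=2,
        )
    ss = np.random.SeedSequence(cfg.seed)
    r_rate, r_s1, r_s2, r_c12, r_c21 = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    if cfg.comod_sigma <= 0:  # constant rates: skip materializing the arrays
        n_steps = cfg.n_samples
        rate1 = (cfg.neuron1.modified_rate, n_steps)
        rate2 = (cfg.neuron2.modified_rate, n_steps)
    else:
        rate1, rate2 = make_rate_function(cfg, r_rate)
    idx1 = sample_spike_train(rate1, cfg.neuron1, cfg.dt, r_s1)
    idx2 = sample_spike_train(rate2, cfg.neuron2, cfg.dt, r_s2)
    n = cfg.n_samples
    new2 = apply_connectivity(idx1, idx2, cfg.stg12, n, r_c12)
    new1 = apply_connectivity(idx2, idx1, cfg.stg21, n, r_c21)
    arp1 = int(round(cfg.neuron1.arp / cfg.dt))
    arp2 = int(round(cfg.neuron2.arp / cfg.dt))
    idx1 = _enforce_arp(new1, arp1)
    idx2 = _enforce_arp(new2, arp2)
    if cfg.stg12 > 0:
        label = "excitatory"
    elif cfg.stg12 < 0:
        label = "inhibitory"
    else:
        label = "none"
    truth = {"stg12": cfg.stg12, "stg21": cfg.stg21, "connection_label": label}
    return SimulatedPair(
        s1=SpikeTrain(idx1 * cfg.dt, duration=cfg.duration, label="1"),
        s2=SpikeTrain(idx2 * cfg.dt, duration=cfg.duration, label="2"),
        truth=truth,
        config=cfg,
    )


def _lognormal_params(mean: float, sd: float):
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


@dataclass(frozen=True)
class CohortSpec:
    """Distributional specification of a noisy pair cohort.

    Defaults mirror the benchmark cohort: 500 excitatory / 500 inhibitory /
    250 unconnected pairs, presynaptic 2 spk/s and postsynaptic 8 spk/s,
    presynaptic BR1 uniform on [0, 0.4], durations uniform on 90 min - 5 h,
    co-modulation in 60% of pairs with sigma_c uniform on [1, 15] spk/s,
    log-normal gains with mean +-SD 0.019 +- 0.01 (excitatory) and
    0.014 +- 0.007 (inhibitory, negative sign).
    """

    n_excitatory: int = 500
    n_inhibitory: int = 500
    n_unconnected: int = 250
    rate_pre: float = 2.0
    rate_post: float = 8.0
    br1_range: tuple = (0.0, 0.4)
    duration_range: tuple = (5400.0, 18000.0)
    comod_fraction: float = 0.6
    comod_sigma_range: tuple = (1.0, 15.0)
    exc_gain_mean_sd: tuple = (0.019, 0.01)
    inh_gain_mean_sd: tuple = (0.014, 0.007)

    def scaled(self, factor: float) -> "CohortSpec":
        """Cohort with class counts scaled by *factor* (same distributions)."""
        return replace(
            self,
            n_excitatory=max(1, int(round(self.n_excitatory * factor))),
            n_inhibitory=max(1, int(round(self.n_inhibitory * factor))),
            n_unconnected=max(1, int(round(self.n_unconnected * factor))),
        )


def generate_cohort(spec: CohortSpec, seed: int = 0):
    """Yield ``(pair_id, PairSimConfig)`` for every pair of the cohort.

    Configurations (not the simulations) are generated eagerly so the truth
    table is available up front; call :func:`simulate_pair` on each config.
    Reproducible: one master seed fans out to per-pair child seeds.
    """
    if min(spec.n_excitatory, spec.n_inhibitory, spec.n_unconnected) < 0:
        raise ValueError("class counts must be non-negative")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    n_total = spec.n_excitatory + spec.n_inhibitory + spec.n_unconnected
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_total)]
    labels = (
        ["excitatory"] * spec.n_excitatory
        + ["inhibitory"] * spec.n_inhibitory
        + ["none"] * spec.n_unconnected
    )
    configs = []
    for pair_id, (label, child) in enumerate(zip(labels, child_seeds)):
        if label == "excitatory":
            mu, sg = _lognormal_params(*spec.exc_gain_mean_sd)
            stg = float(rng.lognormal(mu, sg))
        elif label == "inhibitory":
            mu, sg = _lognormal_params(*spec.inh_gain_mean_sd)
            stg = -float(min(rng.lognormal(mu, sg), 1.0))
        else:
            stg = 0.0
        br1 = float(rng.uniform(*spec.br1_range))
        duration = float(rng.uniform(*spec.duration_range))
        comod = (
            float(rng.uniform(*spec.comod_sigma_range))
            if rng.random() < spec.comod_fraction
            else 0.0
        )
        cfg = PairSimConfig(
            neuron1=NeuronSpec(rate=spec.rate_pre, br1=br1),
            neuron2=NeuronSpec(rate=spec.rate_post),
            stg12=stg,
            comod_sigma=comod,
            duration=duration,
            seed=child,
        )
        configs.append((pair_id, cfg))
    return configs
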