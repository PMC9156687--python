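"""Spike-transmission curve extraction and gain quantities.

The spike transmission curve (STC) is the causal impulse response of spike
transmission from a trigger (presynaptic) to a reference (postsynaptic)
neuron, in conditional-rate units.  Its integral is the spike transmission
gain (STG): the expected number of extra postsynaptic spikes per
presynaptic spike (negative for suppression).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import poisson

from .correlograms import Correlogram, ConditionalRateCurve, conditional_rate
from .predictors import make_predictor

__all__ = [
    "StcResult",
    "RateSummary",
    "extract_stc",
    "estimate_stg",
    "real_stg_from_rates",
    "minimal_detectable_stg",
]


@dataclass(frozen=True)
class StcResult:
    """Extracted spike transmission curve and its scalar gain.

    ``stc`` is nonzero only on the support ``[b_l, b_r]`` (lag-bin indices,
    ``b_l >= 1`` so the support is strictly causal); ``estg`` equals the sum
    of the STC over its support times the bin width.  For an empty result
    (flat curve) ``b_l`` and ``b_r`` are None and ``estg`` is 0.
    """

    stc: np.ndarray
    b_l: int | None
    b_r: int | None
    roi_ms: tuple
    sign: str
    estg: float
    bin_width: float


def _roi_bins(half_width: int, bin_width: float, roi_ms) -> np.ndarray:
    lo, hi = roi_ms
    m = np.arange(1, half_width + 1)
    lag_ms = m * bin_width * 1e3
    sel = m[(lag_ms > lo) & (lag_ms <= hi)]
    if sel.size == 0:
        raise ValueError("empty ROI")
    return sel


def extract_stc(
    cr: ConditionalRateCurve,
    roi_ms=(0.0, 5.0),
    sign: str = "auto",
) -> StcResult:
    """Extract the STC from a conditional-rate curve.

    Locates the extremum in the causal ROI (max for excitatory, min for
    inhibitory; under ``"auto"`` the larger magnitude wins, ties toward the
    smaller lag), walks outward to the nearest zero crossings to set the
    support bounds, clamps the left bound to the first positive-lag bin, and
    zeroes the curve outside the support.  The right bound may exceed the
    ROI.
    """
    if sign not in ("auto", "excitatory", "inhibitory"):
        raise ValueError(f"unknown sign {sign!r}")
    center = cr.half_width
    rates = np.asarray(cr.rates, dtype=float)
    roi = _roi_bins(center, cr.bin_width, roi_ms)
    vals = rates[center + roi]

    if sign == "auto":
        sign = "excitatory" if vals.max() >= -vals.min() else "inhibitory"
    if sign == "excitatory":
        peak_bin = int(roi[np.argmax(vals)])
        peak_val = rates[center + peak_bin]
        same_sign = rates > 0
    else:
        peak_bin = int(roi[np.argmin(vals)])
        peak_val = rates[center + peak_bin]
        same_sign = rates < 0

    stc = np.zeros_like(rates)
    if peak_val == 0 or (sign == "excitatory") != (peak_val > 0):
        return StcResult(
            stc=stc, b_l=None, b_r=None, roi_ms=tuple(roi_ms), sign=sign,
            estg=0.0, bin_width=cr.bin_width,
        )

    b_l = peak_bin
    while b_l - 1 >= -center and same_sign[center + b_l - 1]:
        b_l -= 1
    b_r = peak_bin
    while b_r + 1 <= center and same_sign[center + b_r + 1]:
        b_r += 1
    b_l = max(b_l, 1)  # strictly causal support start

    stc[center + b_l : center + b_r + 1] = rates[center + b_l : center + b_r + 1]
    estg = float(stc.sum() * cr.bin_width)
    return StcResult(
        stc=stc, b_l=b_l, b_r=b_r, roi_ms=tuple(roi_ms), sign=sign,
        estg=estg, bin_width=cr.bin_width,
    )


def estimate_stg(
    cch_or_dcch: Correlogram,
    predictor="median",
    roi_ms=(0.0, 5.0),
    sign: str = "auto",
    **predictor_params,
) -> StcResult:
    """Convenience pipeline: predictor -> conditional rate -> STC -> eSTG."""
    pred = make_predictor(cch_or_dcch, predictor, **predictor_params)
    cr = conditional_rate(cch_or_dcch, pred)
    return extract_stc(cr, roi_ms=roi_ms, sign=sign)


@dataclass(frozen=True)
class RateSummary:
    """Firing rates of a paired (synapse on/off) experiment.

    lambda1: presynaptic rate, spk/s.  lambda2_syn / lambda2_nosyn:
    postsynaptic rates with and without the synapse.  arp2: postsynaptic
    absolute refractory period (s).  dt: simulation time step (s).
    """

    lambda1: float
    lambda2_syn: float
    lambda2_nosyn: float
    arp2: float
    dt: float

    def __post_init__(self) -> None:
        if min(self.lambda1, self.lambda2_syn, self.lambda2_nosyn) < 0:
            raise ValueError("rates must be non-negative")
        if self.arp2 <= 0 or self.dt <= 0:
            raise ValueError("arp2 and dt must be positive")


def real_stg_from_rates(r: RateSummary) -> float:
    """Exact ground-truth STG from paired firing rates.

    The naive rate-difference ratio ``(l2_syn - l2_nosyn) / l1`` undercounts
    transmitted spikes that replace spontaneous ones during the postsynaptic
    refractory period; the correction factor ``1 - l2_nosyn * (ARP2 + dt)``
    (fraction of non-occupied bins) restores the exact gain.
    """
    if r.lambda1 <= 0:
        raise ValueError("presynaptic rate must be positive")
    naive = (r.lambda2_syn - r.lambda2_nosyn) / r.lambda1
    return naive * (1.0 - r.lambda2_nosyn * (r.arp2 + r.dt))


def minimal_detectable_stg(
    f1: float, f2: float, duration: float, bin_width: float = 0.001,
    alpha: float = 0.001,
) -> float:
    """Smallest unidirectional STG detectable with the tails predictor.

    For Poisson trains and a single-bin impulse response, the CCH baseline
    count is ``lam = F1 * F2 * T * B``.  The inverse Poisson distribution at
    ``1 - alpha`` gives the minimal significant bin count ``k*``; the excess
    ``k* - lam``, divided by the number of presynaptic spikes ``F1 * T``, is
    the minimal detectable gain.
    """
    if min(f1, f2, duration, bin_width) <= 0:
        raise ValueError("rates, duration, and bin width must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    lam = f1 * f2 * duration * bin_width
    k_star = float(poisson.ppf(1.0 - alpha, lam))
    return (k_star - lam) / (f1 * duration)
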