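"""Baseline ("other inputs") predictors for correlograms.

All three predictors estimate the slow component of a CCH by timescale
separation: a flat tails mean, convolution with a partially hollowed
Gaussian (the surrogate-jitter equivalent), or a hollow median filter.
Each reproduces a flat histogram exactly.

Near the histogram edges the filters operate on the histogram extended by
reflection, so the predictor is defined on all ``2M + 1`` bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correlograms import Correlogram

__all__ = [
    "PredictorCurve",
    "predictor_tails",
    "predictor_jitter",
    "predictor_median",
    "make_predictor",
    "jitter_kernel",
]


@dataclass(frozen=True)
class PredictorCurve:
    """Per-bin expected baseline counts for a correlogram."""

    expected: np.ndarray
    method: str
    params: dict = field(default_factory=dict)


def predictor_tails(cch: Correlogram, m0: int = 11) -> PredictorCurve:
    """Constant baseline: mean of all bins with ``|lag index| >= m0``."""
    m = cch.half_width
    if m0 > m:
        raise ValueError("m0 exceeds the histogram half-width (no tail bins)")
    idx = np.abs(np.arange(-m, m + 1)) >= m0
    level = float(cch.counts[idx].mean())
    return PredictorCurve(
        expected=np.full(cch.counts.size, level), method="tails", params={"m0": m0}
    )


def jitter_kernel(delta: int = 5, hollow: float = 0.6) -> np.ndarray:
    """Unit-sum Gaussian kernel (SD *delta* bins, support ``6*delta + 1`` bins)
    whose central weight is multiplied by the hollow fraction before
    renormalization."""
    if delta < 1:
        raise ValueError("delta must be >= 1")
    k = np.arange(-3 * delta, 3 * delta + 1)
    w = np.exp(-(k.astype(float) ** 2) / (2.0 * delta**2))
    w[3 * delta] *= hollow
    return w / w.sum()


def predictor_jitter(
    cch: Correlogram, delta: int = 5, hollow: float = 0.6
) -> PredictorCurve:
    """Convolution of the CCH with the partially hollowed Gaussian kernel."""
    w = jitter_kernel(delta=delta, hollow=hollow)
    padded = np.pad(cch.counts.astype(float), 3 * delta, mode="reflect")
    expected = np.convolve(padded, w, mode="valid")
    return PredictorCurve(
        expected=expected, method="jitter", params={"delta": delta, "hollow": hollow}
    )


def predictor_median(cch: Correlogram, delta: int = 5) -> PredictorCurve:
    """Hollow median filter of order ``2*delta`` (central bin excluded)."""
    if delta < 1:
        raise ValueError("delta must be >= 1")
    padded = np.pad(cch.counts.astype(float), delta, mode="reflect")
    windows = np.lib.stride_tricks.sliding_window_view(padded, 2 * delta + 1)
    hollow = np.delete(windows, delta, axis=1)
    expected = np.median(hollow, axis=1)
    return PredictorCurve(expected=expected, method="median", params={"delta": delta})


_PREDICTORS = {
    "tails": predictor_tails,
    "jitter": predictor_jitter,
    "median": predictor_median,
}


def make_predictor(cch: Correlogram, method, **params) -> PredictorCurve:
    """Dispatch a predictor by name, or call a user-supplied provider.

    A callable *method* acts as a plug-in slot: it receives the correlogram
    plus *params* and must return a :class:`PredictorCurve` (or a bare array
    of expected counts).
    """
    if callable(method):
        out = method(cch, **params)
        if isinstance(out, PredictorCurve):
            return out
        return PredictorCurve(expected=np.asarray(out, dtype=float), method="custom")
    try:
        fn = _PREDICTORS[method]
    except KeyError:
        raise ValueError(f"unknown predictor {method!r}") from None
    return fn(cch, **params)
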