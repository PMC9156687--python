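"""Auto- and cross-correlation histograms of spike trains.

Lag convention: bin ``m`` of a correlogram collects reference-minus-trigger
spike-time differences in the half-open interval ``[(m - 1/2)B, (m + 1/2)B)``
for ``m`` in ``[-M, M]``, so a positive lag means the reference (postsynaptic)
spike follows the trigger (presynaptic) spike.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .trains import SpikeTrain

__all__ = [
    "Correlogram",
    "AchKernel",
    "ConditionalRateCurve",
    "compute_cch",
    "compute_ach",
    "scale_ach",
    "conditional_rate",
    "read_correlogram",
    "write_correlogram",
]


@dataclass(frozen=True)
class Correlogram:
    """Binned pair-count histogram (ACH, CCH, or deconvolved CCH).

    ``counts`` has odd length ``2M + 1``; the lag of bin ``m`` is ``m * B``
    seconds for ``m`` in ``[-M, M]``.  Raw histograms hold non-negative
    integer counts; deconvolved histograms (``kind="dcCCH"``) are real-valued.
    """

    counts: np.ndarray
    bin_width: float
    n_trigger: int
    n_reference: int
    kind: str = "CCH"

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", c)
        if c.ndim != 1 or c.size % 2 != 1:
            raise ValueError("counts must be a 1-D array of odd length")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.kind not in ("ACH", "CCH", "dcCCH"):
            raise ValueError(f"unknown correlogram kind {self.kind!r}")
        if self.kind in ("ACH", "CCH"):
            if np.any(c < 0) or np.any(c != np.round(c)):
                raise ValueError("raw histogram counts must be non-negative integers")

    @property
    def half_width(self) -> int:
        """M, the number of bins on each side of zero lag."""
        return (self.counts.size - 1) // 2

    @property
    def lags(self) -> np.ndarray:
        """Bin-center lags in seconds."""
        m = self.half_width
        return np.arange(-m, m + 1) * self.bin_width

    @property
    def lags_ms(self) -> np.ndarray:
        return self.lags * 1e3

    def __getitem__(self, m: int) -> float:
        """Count at lag-bin index m (0 is the zero-lag bin)."""
        return float(self.counts[m + self.half_width])


@dataclass(frozen=True)
class AchKernel:
    """Scaled (unit-sum) ACH used as a deconvolution kernel."""

    weights: np.ndarray
    bin_width: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("kernel weights must sum to 1")

    @property
    def half_width(self) -> int:
        return (self.weights.size - 1) // 2


@dataclass(frozen=True)
class ConditionalRateCurve:
    """Baseline-subtracted CCH scaled to spk/s per bin (the crCCH)."""

    rates: np.ndarray
    bin_width: float
    n_trigger: int

    @property
    def half_width(self) -> int:
        return (self.rates.size - 1) // 2


def _pair_differences(t1: np.ndarray, t2: np.ndarray, window: float):
    """All ordered differences t2[j] - t1[i] with magnitude < window."""
    lo = np.searchsorted(t2, t1 - window, side="left")
    hi = np.searchsorted(t2, t1 + window, side="left")
    npairs = hi - lo
    total = int(npairs.sum())
    if total == 0:
        return np.empty(0)
    ii = np.repeat(np.arange(t1.size), npairs)
    starts = np.concatenate(([0], np.cumsum(npairs)[:-1]))
    jj = np.arange(total) - np.repeat(starts, npairs) + np.repeat(lo, npairs)
    return t2[jj] - t1[ii]


def compute_cch(
    s1: SpikeTrain,
    s2: SpikeTrain,
    bin_width: float = 0.001,
    half_width_bins: int = 30,
) -> Correlogram:
    """Cross-correlation histogram between trigger train *s1* and reference *s2*.

    Bin ``m`` counts spike pairs with ``(m - 1/2)B <= t2_j - t1_i < (m + 1/2)B``.
    An empty train yields an all-zero histogram.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if half_width_bins < 1:
        raise ValueError("half_width_bins must be >= 1")
    m = half_width_bins
    window = (m + 0.5) * bin_width
    d = _pair_differences(s1.times, s2.times, window)
    bins = np.floor(d / bin_width + 0.5).astype(np.int64)
    keep = (bins >= -m) & (bins <= m)
    counts = np.bincount(bins[keep] + m, minlength=2 * m + 1)
    kind = "ACH" if s1 is s2 else "CCH"
    return Correlogram(
        counts=counts,
        bin_width=bin_width,
        n_trigger=s1.n_spikes,
        n_reference=s2.n_spikes,
        kind=kind,
    )


def compute_ach(
    s: SpikeTrain, bin_width: float = 0.001, half_width_bins: int = 30
) -> Correlogram:
    """Auto-correlation histogram; the zero-lag bin holds the N self-pairs."""
    return compute_cch(s, s, bin_width=bin_width, half_width_bins=half_width_bins)


def scale_ach(ach: Correlogram) -> AchKernel:
    """Scale a count ACH to the unit-sum deconvolution kernel.

    Four steps: the zero-lag bin is set to zero; the mean (over all bins) is
    subtracted; every bin is divided by the total number of spikes; the
    zero-lag bin is set to complement the sum to one.
    """
    if ach.kind != "ACH":
        raise ValueError("scale_ach expects an ACH")
    n = ach.n_trigger
    if n <= 0:
        raise ValueError("cannot scale the ACH of an empty train")
    w = ach.counts.astype(float).copy()
    center = ach.half_width
    w[center] = 0.0
    w -= w.mean()
    w /= n
    w[center] = 0.0
    w[center] = 1.0 - w.sum()
    return AchKernel(weights=w, bin_width=ach.bin_width)


def conditional_rate(cch: Correlogram, pred) -> ConditionalRateCurve:
    """Conditional-rate curve ``(CCH[m] - pred[m]) / (N1 * B)`` in spk/s."""
    expected = np.asarray(getattr(pred, "expected", pred), dtype=float)
    if expected.shape != cch.counts.shape:
        raise ValueError("predictor and histogram lag axes differ")
    if cch.n_trigger <= 0:
        raise ValueError("n_trigger must be positive")
    rates = (cch.counts - expected) / (cch.n_trigger * cch.bin_width)
    return ConditionalRateCurve(
        rates=rates, bin_width=cch.bin_width, n_trigger=cch.n_trigger
    )


def write_correlogram(path_or_buf, cg: Correlogram) -> None:
    """Write a correlogram as a ``lag_ms, count`` table (bin centers in ms)."""
    lines = ["lag_ms,count\n"]
    for lag, c in zip(cg.lags_ms, cg.counts):
        lines.append(f"{lag:.6g},{c:.10g}\n")
    text = "".join(lines)
    if isinstance(path_or_buf, (str, os.PathLike)):
        with open(path_or_buf, "w") as fh:
            fh.write(text)
    else:
        path_or_buf.write(text)


def read_correlogram(
    path_or_buf, n_trigger: int = 0, n_reference: int = 0, kind: str = "CCH"
) -> Correlogram:
    """Read a correlogram from a ``lag_ms, count`` table."""
    data = np.loadtxt(path_or_buf, delimiter=",", skiprows=1, ndmin=2)
    lags_ms, counts = data[:, 0], data[:, 1]
    if counts.size < 3 or counts.size % 2 != 1:
        raise ValueError("correlogram table must have an odd number of bins >= 3")
    bin_width = float(np.median(np.diff(lags_ms))) * 1e-3
    return Correlogram(
        counts=counts,
        bin_width=bin_width,
        n_trigger=n_trigger,
        n_reference=n_reference,
        kind=kind,
    )
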