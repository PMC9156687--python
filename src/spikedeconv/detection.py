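"""Monosynaptic-connection detection, scoring, and resampling tests.

Detection uses a Poisson test on the causal region of interest of a CCH (or
dcCCH) against a baseline predictor: the default statistic compares the
extreme single bin in the ROI with its predicted mean, with continuity
correction; a summed-ROI variant is available.  Performance is summarized
with pooled false-positive / false-negative rates and the f1 score, and the
bootstrap / permutation tests operate on those summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import poisson, spearmanr

from .correlograms import Correlogram
from .predictors import PredictorCurve

__all__ = [
    "DetectionResult",
    "ConfusionSummary",
    "BurstMetrics",
    "detect_connection",
    "confusion_and_f1",
    "burst_index",
    "bootstrap_f1_compare",
    "bootstrap_slope_compare",
    "permutation_corr_test",
    "normalized_slope",
    "filter_pairs",
]

LABELS = ("excitatory", "inhibitory", "none")


@dataclass(frozen=True)
class DetectionResult:
    label: str
    p_exc: float
    p_inh: float
    alpha: float
    roi_ms: tuple


@dataclass(frozen=True)
class ConfusionSummary:
    """Detection rates (counts / N_conn, the number of tested connections)."""

    tp: float
    fp_exc: float
    fp_inh: float
    fn_exc: float
    fn_inh: float
    f1: float


@dataclass(frozen=True)
class BurstMetrics:
    burst_index: float
    head: float
    tail: float


def _poisson_tail_upper(k: float, mu: float, mid_p: bool) -> float:
    """Upper tail P(X >= k); with ``mid_p`` the half-weight correction
    P(X > k) + 0.5 P(X = k) is used instead."""
    k = int(np.round(k))
    if mid_p:
        return float(poisson.sf(k, mu) + 0.5 * poisson.pmf(k, mu))
    return float(poisson.sf(k - 1, mu))


def _poisson_tail_lower(k: float, mu: float, mid_p: bool) -> float:
    """Lower tail P(X <= k); mirrored mid-p form when requested."""
    k = int(np.round(k))
    if mid_p:
        return float(poisson.cdf(k - 1, mu) + 0.5 * poisson.pmf(k, mu))
    return float(poisson.cdf(k, mu))


def detect_connection(
    cch_or_dcch: Correlogram,
    pred: PredictorCurve,
    roi_ms=(0.0, 5.0),
    alpha: float = 0.001,
    stat: str = "maxbin",
    mid_p: bool = False,
) -> DetectionResult:
    """Classify a pair as excitatory / inhibitory / unconnected.

    ``stat="maxbin"`` tests the maximum (minimum) observed ROI bin against
    its per-bin predicted mean for excitation (inhibition); ``stat="roisum"``
    tests the summed ROI count against the summed prediction.  The label is
    set by the smaller tail probability if it is below *alpha*.  No
    multiplicity correction is applied over ROI bins; the default tail is
    the plain (conservative) Poisson tail, which keeps the family-wise
    false-positive rate of the max-bin statistic well under control, with
    the mid-p continuity-corrected variant available via ``mid_p``.
    """
    if stat not in ("maxbin", "roisum"):
        raise ValueError(f"unknown statistic {stat!r}")
    center = cch_or_dcch.half_width
    lo, hi = roi_ms
    m = np.arange(1, center + 1)
    lag_ms = m * cch_or_dcch.bin_width * 1e3
    roi = m[(lag_ms > lo) & (lag_ms <= hi)]
    if roi.size == 0:
        raise ValueError("empty ROI")
    obs = cch_or_dcch.counts[center + roi]
    mu = np.asarray(pred.expected, dtype=float)[center + roi]
    ok = mu > 0
    if not ok.any():
        raise ValueError("predicted mean non-positive over the whole ROI")
    obs, mu = obs[ok], mu[ok]
    if stat == "maxbin":
        i_max = int(np.argmax(obs))
        i_min = int(np.argmin(obs))
        p_exc = _poisson_tail_upper(obs[i_max], mu[i_max], mid_p)
        p_inh = _poisson_tail_lower(obs[i_min], mu[i_min], mid_p)
    else:
        p_exc = _poisson_tail_upper(obs.sum(), mu.sum(), mid_p)
        p_inh = _poisson_tail_lower(obs.sum(), mu.sum(), mid_p)
    if min(p_exc, p_inh) < alpha:
        label = "excitatory" if p_exc <= p_inh else "inhibitory"
    else:
        label = "none"
    return DetectionResult(
        label=label, p_exc=p_exc, p_inh=p_inh, alpha=alpha, roi_ms=tuple(roi_ms)
    )


def _labels(detections) -> list[str]:
    out = []
    for d in detections:
        lab = d.label if isinstance(d, DetectionResult) else d
        if lab not in LABELS:
            raise ValueError(f"unknown label {lab!r}")
        out.append(lab)
    return out


def confusion_and_f1(detections, truth) -> ConfusionSummary:
    """Pooled detection rates and f1 score.

    A false positive is a detection on an unconnected pair; a false negative
    is a simulated connection not detected as its own class.  All rates are
    divided by the total number of tested connections, and
    ``f1 = TP / (TP + 0.5 (FP + FN))`` with FP, FN pooled over the
    excitatory and inhibitory classes.
    """
    pred = _labels(detections)
    true = _labels(truth)
    if len(pred) != len(true):
        raise ValueError("detections and truth must have equal lengths")
    n = len(pred)
    if n == 0:
        raise ValueError("empty input")
    tp = sum(1 for p, t in zip(pred, true) if t != "none" and p == t) / n
    fp_exc = sum(1 for p, t in zip(pred, true) if t == "none" and p == "excitatory") / n
    fp_inh = sum(1 for p, t in zip(pred, true) if t == "none" and p == "inhibitory") / n
    fn_exc = sum(1 for p, t in zip(pred, true) if t == "excitatory" and p != t) / n
    fn_inh = sum(1 for p, t in zip(pred, true) if t == "inhibitory" and p != t) / n
    fp, fn = fp_exc + fp_inh, fn_exc + fn_inh
    denom = tp + 0.5 * (fp + fn)
    f1 = tp / denom if denom > 0 else 0.0
    return ConfusionSummary(
        tp=tp, fp_exc=fp_exc, fp_inh=fp_inh, fn_exc=fn_exc, fn_inh=fn_inh, f1=f1
    )


def burst_index(ach: Correlogram) -> BurstMetrics:
    """Burstiness of a unit from its ACH.

    ``(head - tail) / (head + tail)`` with head the summed counts at lags
    ``2 < tau <= 10`` ms and tail at ``35 < tau <= 50`` ms (positive lags);
    positive for bursty units.
    """
    lag_ms = ach.lags_ms
    if lag_ms[-1] < 50.0 - 1e-9:
        raise ValueError("ACH must span at least 50 ms of positive lag")
    head = float(ach.counts[(lag_ms > 2.0) & (lag_ms <= 10.0)].sum())
    tail = float(ach.counts[(lag_ms > 35.0) & (lag_ms <= 50.0)].sum())
    if head + tail == 0:
        raise ValueError("burst index undefined: no counts in either window")
    return BurstMetrics(burst_index=(head - tail) / (head + tail), head=head, tail=tail)


def _f1_of(table: pd.DataFrame) -> float:
    return confusion_and_f1(table["label"].tolist(), table["truth"].tolist()).f1


def bootstrap_f1_compare(
    group1: pd.DataFrame,
    group2: pd.DataFrame,
    n_iter: int = 3500,
    rng_seed: int | None = None,
) -> dict:
    """Bootstrap comparison of two detection-outcome tables.

    Each table needs ``truth`` and ``label`` columns, one row per tested
    pair.  Pairs are resampled with replacement within each group; the
    returned ``p`` is the fraction of iterations in which f1(group1) was
    smaller than f1(group2).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if len(group1) == 0 or len(group2) == 0:
        raise ValueError("empty group")
    rng = np.random.default_rng(rng_seed)
    f1s = np.empty((2, n_iter))
    for it in range(n_iter):
        for g, tab in enumerate((group1, group2)):
            idx = rng.integers(0, len(tab), size=len(tab))
            f1s[g, it] = _f1_of(tab.iloc[idx])
    return {
        "p": float(np.mean(f1s[0] < f1s[1])),
        "mean_f1": (float(f1s[0].mean()), float(f1s[1].mean())),
        "sem_f1": (
            float(f1s[0].std(ddof=1) / np.sqrt(n_iter)),
            float(f1s[1].std(ddof=1) / np.sqrt(n_iter)),
        ),
    }


def _bootstrap_slopes(x, y, n_resamples, rng) -> np.ndarray:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    slopes = np.empty(n_resamples)
    for it in range(n_resamples):
        while True:
            idx = rng.integers(0, x.size, size=x.size)
            if np.ptp(x[idx]) > 0:
                break
        slopes[it] = np.polyfit(x[idx], y[idx], 1)[0]
    return slopes


def bootstrap_slope_compare(
    x1, y1, x2, y2, n_resamples: int = 300, rng_seed: int | None = None
) -> dict:
    """Cross-paired bootstrap comparison of two least-squares slopes.

    Each group is resampled *n_resamples* times; every slope of group 1 is
    compared with every slope of group 2 (``n_resamples**2`` pairs, the
    conservative cross-iteration pairing), and ``p`` is the fraction with
    slope1 < slope2.  Resamples with zero x-variance are redrawn.
    """
    if min(len(x1), len(x2)) < 3:
        raise ValueError("each group needs at least 3 points")
    rng = np.random.default_rng(rng_seed)
    s1 = _bootstrap_slopes(x1, y1, n_resamples, rng)
    s2 = _bootstrap_slopes(x2, y2, n_resamples, rng)
    p = float(np.mean(s1[:, None] < s2[None, :]))
    return {"p": p, "slopes": (s1, s2)}


def permutation_corr_test(x, y, n_perm: int = 1000, rng_seed: int | None = None) -> dict:
    """Spearman rank correlation with a permutation test on ``|rho|``."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 paired samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    rng = np.random.default_rng(rng_seed)
    rho = float(spearmanr(x, y).statistic)
    count = 0
    for _ in range(n_perm):
        r = float(spearmanr(x, rng.permutation(y)).statistic)
        if abs(r) >= abs(rho):
            count += 1
    return {"rho": rho, "p": count / n_perm}


def normalized_slope(burst_fractions, estimates) -> float:
    """Slope of estimate vs burst fraction after normalizing by the mean
    estimate at zero burst fraction (puts gain- and PSP-scaled methods on a
    common scale)."""
    br = np.asarray(burst_fractions, float)
    est = np.asarray(estimates, float)
    at_zero = est[br == 0]
    if at_zero.size == 0 or at_zero.mean() == 0:
        raise ValueError("need a non-empty, non-zero-mean zero-burst group")
    return float(np.polyfit(br, est / at_zero.mean(), 1)[0])


def filter_pairs(
    table: pd.DataFrame,
    min_burst_index: float = 0.0,
    estg_ratio_bounds=(0.5, 2.0),
    min_cch_counts: int = 400,
) -> pd.Series:
    """Generic analysis-pair filter for cohort studies.

    Expects columns ``burst_index_pre`` (trigger-unit burst index),
    ``detected_raw`` and ``detected_dc`` (booleans: connection detected
    without / with deconvolution), ``estg_raw`` and ``estg_dc``, and
    ``cch_counts`` (total CCH counts within +-30 ms).  Returns a boolean
    mask of pairs that (1) have a non-negative trigger burst index, (2) are
    detected both with and without deconvolution, (3) have an eSTG ratio
    within *estg_ratio_bounds*, and (4) have at least *min_cch_counts*
    counts.
    """
    ratio = table["estg_raw"] / table["estg_dc"]
    lo, hi = estg_ratio_bounds
    return (
        (table["burst_index_pre"] >= min_burst_index)
        & table["detected_raw"].astype(bool)
        & table["detected_dc"].astype(bool)
        & (ratio >= lo)
        & (ratio <= hi)
        & (table["cch_counts"] >= min_cch_counts)
    )
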