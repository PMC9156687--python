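"""Fourier-domain deconvolution of scaled ACH kernels from a CCH.

The CCH between two coupled trains is, to small loop gain, a sum of the
"other inputs" cross-correlation plus each ACH convolved with the
corresponding spike-transmission curve.  Dividing the CCH's discrete Fourier
transform by the transforms of the unit-sum scaled ACH kernels removes the
second-order single-train statistics (bursting, refractoriness,
periodicity), producing the deconvolved CCH (dcCCH).

The finite ``2M + 1``-bin histograms are treated as one period of a circular
signal (plain DFT, no padding); the scaled kernels have unit DC gain, so the
baseline level of the CCH is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import fft, ifft

from .correlograms import AchKernel, Correlogram, scale_ach

__all__ = ["DeconvolutionResult", "deconvolve_cch"]


@dataclass(frozen=True)
class DeconvolutionResult:
    """Deconvolved CCH plus bookkeeping about the spectral division."""

    dcch: Correlogram
    mode: str
    regularization_floor: float
    guard_fired: bool


def _kernel_spectrum(kernel, cch: Correlogram) -> np.ndarray:
    if isinstance(kernel, Correlogram):
        kernel = scale_ach(kernel)
    if not isinstance(kernel, AchKernel):
        raise TypeError("kernel must be an ACH Correlogram or an AchKernel")
    w = kernel.weights
    if w.size != cch.counts.size:
        raise ValueError("kernel and CCH lag axes differ")
    # zero lag must sit at index 0 for the circular-convolution theorem
    return fft(np.roll(w, -kernel.half_width))


def _guarded(spectrum: np.ndarray, floor: float):
    mag = np.abs(spectrum)
    low = mag < floor
    if not low.any():
        return spectrum, False
    out = spectrum.copy()
    nz = low & (mag > 0)
    out[nz] = floor * spectrum[nz] / mag[nz]
    out[low & (mag == 0)] = floor
    return out, True


def deconvolve_cch(
    cch: Correlogram,
    ach1,
    ach2=None,
    mode: str = "bidirectional",
    regularization_floor: float = 1e-3,
) -> DeconvolutionResult:
    """Deconvolve one or both scaled ACH kernels from a CCH.

    Parameters
    ----------
    cch
        Raw cross-correlation histogram (trigger = presynaptic candidate).
    ach1, ach2
        Count ACHs (scaled internally) or ready :class:`AchKernel` objects.
        ``ach2`` is required for (and only used by) the bidirectional mode.
    mode
        ``"bidirectional"`` divides by both kernel transforms (the default);
        ``"unidirectional"`` divides by the trigger-train kernel only, for
        use when connectivity is strong and presynaptic rates are high.
    regularization_floor
        Kernel Fourier coefficients with magnitude below this are raised to
        the floor (phase preserved) before division; ``guard_fired`` on the
        result records whether this happened.

    Returns
    -------
    DeconvolutionResult
        With ``dcch.counts`` real-valued on the same lag axis as *cch*.
    """
    if mode not in ("bidirectional", "unidirectional"):
        raise ValueError(f"unknown mode {mode!r}")
    denom = _kernel_spectrum(ach1, cch)
    if mode == "bidirectional":
        if ach2 is None:
            raise ValueError("bidirectional deconvolution needs both ACHs")
        denom = denom * _kernel_spectrum(ach2, cch)
    denom, guard = _guarded(denom, regularization_floor)
    spec = fft(cch.counts.astype(float)) / denom
    dc = ifft(spec)
    resid = np.abs(dc.imag).max()
    scale = max(np.abs(dc.real).max(), 1.0)
    if resid > 1e-9 * scale:
        raise FloatingPointError("imaginary residue above tolerance after ifft")
    dcch = Correlogram(
        counts=dc.real,
        bin_width=cch.bin_width,
        n_trigger=cch.n_trigger,
        n_reference=cch.n_reference,
        kind="dcCCH",
    )
    return DeconvolutionResult(
        dcch=dcch, mode=mode, regularization_floor=regularization_floor,
        guard_fired=guard,
    )
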