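"""Windowed spectral measures: relative band power and inter-site phase
clustering (ISPC, a.k.a. the phase-locking value).

Relative band power is the trapezoidal integral of the Welch power spectral
density over a band divided by the integral over the full one-sided PSD
support. ISPC between two phase series is the modulus of the mean unit
phasor of their wrapped differences: 1 for a perfectly consistent phase
relation, ~0 for independent phases.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .bands import Band, DEFAULT_BANDS

__all__ = [
    "welch_band_power",
    "batched_welch_band_power",
    "BandPowerPlan",
    "ispc",
    "batched_ispc",
]


def _welch_psd(x: np.ndarray, sampling_rate: float) -> Tuple[np.ndarray, np.ndarray]:
    nperseg = int(sampling_rate // 2)
    if x.shape[-1] < nperseg:
        raise ValueError(
            f"window of {x.shape[-1]} samples shorter than one Welch segment ({nperseg})"
        )
    return sps.welch(
        x,
        fs=sampling_rate,
        window="hamming",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        axis=-1,
    )


def batched_welch_band_power(
    windows: np.ndarray,
    sampling_rate: float,
    bands: Sequence[Band] = DEFAULT_BANDS,
) -> np.ndarray:
    """Relative band powers for a batch of windows, shape (..., n_bands).

    Welch segments are SR/2 samples with 50% overlap and a Hamming taper;
    band powers are trapezoidal integrals over band frequencies, normalized
    by the integral over the full PSD support (0 to Nyquist), so the five
    band values sum to less than one.
    """
    freqs, psd = _welch_psd(np.asarray(windows, dtype=float), sampling_rate)
    total = np.trapezoid(psd, freqs, axis=-1)
    total = np.where(total > 0, total, 1.0)
    out = np.empty(psd.shape[:-1] + (len(bands),))
    for k, b in enumerate(bands):
        m = (freqs >= b.lo) & (freqs <= b.hi)
        if m.sum() < 2:
            raise ValueError(f"band {b.name!r} spans fewer than two Welch frequencies")
        out[..., k] = np.trapezoid(psd[..., m], freqs[m], axis=-1) / total
    return out


def welch_band_power(
    window_signal: np.ndarray,
    sampling_rate: float,
    bands: Sequence[Band] = DEFAULT_BANDS,
) -> np.ndarray:
    """Relative band powers of a single 1-D window."""
    x = np.asarray(window_signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("window_signal must be one-dimensional")
    return batched_welch_band_power(x[None, :], sampling_rate, bands)[0]


class BandPowerPlan:
    """Precomputed Welch segmentation and trapezoid weights for one window
    length; numerically identical to :func:`batched_welch_band_power` but
    without per-call setup, for the inner tensor loop."""

    def __init__(self, window_len: int, sampling_rate: float, bands: Sequence[Band]):
        nperseg = int(sampling_rate // 2)
        if window_len < nperseg:
            raise ValueError(
                f"window of {window_len} samples shorter than one Welch segment ({nperseg})"
            )
        step = nperseg - nperseg // 2
        starts = np.arange(0, window_len - nperseg + 1, step)
        self.frame_idx = starts[:, None] + np.arange(nperseg)[None, :]
        self.taper = sps.get_window("hamming", nperseg)
        self.scale = 1.0 / (sampling_rate * (self.taper**2).sum())
        self.freqs = np.fft.rfftfreq(nperseg, d=1.0 / sampling_rate)
        nf = self.freqs.size
        # trapezoid quadrature weights on the uniform frequency grid
        df = self.freqs[1] - self.freqs[0]
        full_w = np.full(nf, df)
        full_w[[0, -1]] = df / 2
        self.total_w = full_w
        self.band_w = np.zeros((nf, len(bands)))
        for k, b in enumerate(bands):
            m = (self.freqs >= b.lo) & (self.freqs <= b.hi)
            if m.sum() < 2:
                raise ValueError(f"band {b.name!r} spans fewer than two Welch frequencies")
            w = np.full(m.sum(), df)
            w[[0, -1]] = df / 2
            self.band_w[m, k] = w
        self.nperseg = nperseg

    def __call__(self, windows: np.ndarray) -> np.ndarray:
        frames = windows[..., self.frame_idx]  # (..., F, nperseg)
        frames = frames - frames.mean(axis=-1, keepdims=True)
        taper = self.taper.astype(windows.dtype, copy=False)
        spec = np.fft.rfft(frames * taper, axis=-1)
        psd = (spec.real**2 + spec.imag**2) * self.scale
        if self.nperseg % 2:
            psd[..., 1:] *= 2.0
        else:
            psd[..., 1:-1] *= 2.0
        psd = psd.mean(axis=-2)  # average over Welch segments
        total = psd @ self.total_w
        total = np.where(total > 0, total, 1.0)
        return (psd @ self.band_w) / total[..., None]


def ispc(phase_x: np.ndarray, phase_y: np.ndarray) -> float:
    """Inter-site phase clustering of two equal-length phase series.

    ISPC = |n^-1 sum_t exp(i (phi_x(t) - phi_y(t)))|, in [0, 1]. Adding a
    constant to either series leaves it unchanged.
    """
    px = np.asarray(phase_x, dtype=float)
    py = np.asarray(phase_y, dtype=float)
    if px.shape != py.shape or px.ndim != 1:
        raise ValueError("phase series must be one-dimensional with equal length")
    if px.size < 2:
        raise ValueError("need at least two phase samples")
    return float(np.abs(np.exp(1j * (px - py)).mean()))


def batched_ispc(phase_x: np.ndarray, phase_y: np.ndarray) -> np.ndarray:
    """ISPC along the last axis for batched phase arrays of equal shape."""
    d = np.asarray(phase_x, dtype=float) - np.asarray(phase_y, dtype=float)
    return np.abs(np.exp(1j * d).mean(axis=-1))
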