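"""Signal preparation: epoching, band-pass filtering, instantaneous phase and
zero-lag leakage correction.

Leakage correction addresses the spurious instantaneous correlation that
source reconstruction smears across parcels: it replaces the epoch matrix by
the closest (least-squares) matrix whose rows are mutually uncorrelated at
lag zero, treating all regions symmetrically. Filtering is zero-phase
(forward-backward Butterworth), and phase is the argument of the analytic
signal from the Hilbert transform, wrapped to (-pi, pi].
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .bands import Band
from .containers import ParcellatedRecording

__all__ = [
    "epoch_recording",
    "bandpass",
    "instantaneous_phase",
    "leakage_correct",
]


def epoch_recording(recording: ParcellatedRecording) -> np.ndarray:
    """Split a recording into consecutive fixed-length epochs.

    Returns an (M, N, L) array with M = floor(T / L) epochs of
    L = epoch_length_s * sampling_rate samples each; the trailing remainder
    is discarded. Each epoch is subsequently processed independently.
    """
    L = recording.epoch_samples
    T = recording.n_samples
    if T < L:
        raise ValueError(f"recording ({T} samples) shorter than one epoch ({L} samples)")
    m = T // L
    return recording.data[:, : m * L].reshape(recording.n_regions, m, L).transpose(1, 0, 2).copy()


def _bandpass_sos(band: Band, sampling_rate: float, order: int = 4):
    nyq = sampling_rate / 2.0
    if band.hi >= nyq:
        raise ValueError(
            f"band {band.name!r} upper edge {band.hi} Hz >= Nyquist ({nyq} Hz)"
        )
    return sps.butter(order, [band.lo, band.hi], btype="bandpass", fs=sampling_rate, output="sos")


def bandpass(x: np.ndarray, band: Band, sampling_rate: float, order: int = 4) -> np.ndarray:
    """Zero-phase band-pass filter (forward-backward Butterworth, order
    ``order`` per pass) applied along the last axis."""
    sos = _bandpass_sos(band, sampling_rate, order)
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def instantaneous_phase(band_passed: np.ndarray) -> np.ndarray:
    """Per-sample phase of the analytic signal, in (-pi, pi].

    The input must already be band-limited; no unwrapping is applied because
    downstream phase-clustering statistics operate on wrapped differences.
    """
    return np.angle(sps.hilbert(np.asarray(band_passed, dtype=float), axis=-1))


def _dependent_rows(x_centered: np.ndarray, s: np.ndarray, u: np.ndarray, tol: float) -> list:
    """Rows implicated in a linear dependence, from left-singular vectors of
    near-zero singular values."""
    bad = np.flatnonzero(s < tol)
    rows: set = set()
    for k in bad:
        v = np.abs(u[:, k])
        rows.update(np.flatnonzero(v > 0.1 * v.max()).tolist())
    return sorted(rows)


def leakage_correct(
    epoch_data: np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> np.ndarray:
    """Symmetric zero-lag orthogonalization of an (N, L) epoch matrix.

    Finds the matrix nearest to the (row-demeaned) input, in the Frobenius
    sense, whose rows are exactly uncorrelated at lag zero: rows are written
    as P @ diag(lam) with P an orthonormal column frame and per-row scalings
    lam, alternating an orthogonal-Procrustes update of P with a
    least-squares update of lam until the relative change falls below
    ``tol`` (or ``max_iter`` iterations). No region is privileged.

    Raises ``ValueError`` naming the dependent rows when the input is rank
    deficient (orthogonalization is then ill-posed).
    """
    X = np.asarray(epoch_data, dtype=float)
    if X.ndim != 2:
        raise ValueError("epoch_data must be (n_regions, n_samples)")
    n, L = X.shape
    if n > L:
        raise ValueError("need at least as many samples as regions")
    Xc = X - X.mean(axis=1, keepdims=True)

    # rank check on the demeaned matrix
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    rank_tol = s.max() * max(n, L) * np.finfo(float).eps * 10
    if (s < rank_tol).any():
        rows = _dependent_rows(Xc, s, u, rank_tol)
        raise ValueError(f"rank-deficient epoch: rows {rows} are linearly dependent")

    Y = Xc.T  # (L, n): columns are region time courses
    lam = np.linalg.norm(Y, axis=0)
    prev = None
    for _ in range(max_iter):
        # closest orthonormal frame to Y scaled by current row norms
        U, _, Vt = np.linalg.svd(Y * lam[None, :], full_matrices=False)
        P = U @ Vt
        lam = np.einsum("ij,ij->j", Y, P)
        O = P * lam[None, :]
        if prev is not None:
            num = np.linalg.norm(O - prev)
            den = np.linalg.norm(prev)
            if den > 0 and num / den < tol:
                prev = O
                break
        prev = O
    return prev.T.copy()
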