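"""Event detection, communication-window placement and past-conditioned
partial correlation: the primitives of event-windowed communication (EWC).

EWC anchors fixed-length windows at salient excursions ("events") of a
source region's signal and at delay-shifted positions in each structurally
connected target, then measures the lagged statistical dependence inside the
window pair, conditioning on both regions' immediate past to discount
internal dynamics. Temporal ordering via distance-proportional delays is the
only source of directional asymmetry.
"""

from __future__ import annotations

import warnings
from typing import List, Sequence, Tuple

import numpy as np
from scipy import special

__all__ = [
    "detect_events",
    "place_windows",
    "windowed_partial_correlation",
    "batched_partial_correlation",
    "gate_significance",
    "WindowOutOfBounds",
]


class WindowOutOfBounds(ValueError):
    """A communication window (or its conditioning past) leaves the epoch."""


def detect_events(
    epoch_signal: np.ndarray,
    z_threshold: float = 3.0,
    window_samples: int = 0,
    max_outgoing_delay: int = 0,
) -> np.ndarray:
    """Onsets of supra-threshold excursions within one epoch.

    The signal is z-scored within the epoch; a run of consecutive samples
    with |z| > ``z_threshold`` counts as a single event whose onset is the
    run's first sample. Events are discarded when their window plus the
    largest outgoing delay would cross the epoch end, or when the
    one-window past-conditioning segment would precede the epoch start.

    A zero-variance signal yields an empty catalog with a warning (it is a
    degenerate epoch, not an error).
    """
    x = np.asarray(epoch_signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("epoch_signal must be one-dimensional")
    sd = x.std()
    if sd == 0:
        warnings.warn("zero-variance epoch signal: no events detected", stacklevel=2)
        return np.array([], dtype=int)
    z = (x - x.mean()) / sd
    supra = np.abs(z) > z_threshold
    if not supra.any():
        return np.array([], dtype=int)
    # onsets: first sample of each supra-threshold run
    starts = np.flatnonzero(supra & ~np.r_[False, supra[:-1]])
    lo = window_samples
    hi = x.size - window_samples - max_outgoing_delay
    return starts[(starts >= lo) & (starts < hi)].astype(int)


def place_windows(
    event_onset: int,
    delay_samples: int,
    window_samples: int,
    epoch_length: int,
) -> Tuple[slice, slice, slice, slice]:
    """Index slices for (source window, target window, source past, target past).

    The source window starts at the event; the target window starts
    ``delay_samples`` later; each past segment is the ``window_samples``
    samples immediately preceding its window. Raises
    :class:`WindowOutOfBounds` when any segment leaves the epoch.
    """
    t0, d, w = int(event_onset), int(delay_samples), int(window_samples)
    if d < 0 or w <= 0:
        raise ValueError("delay must be >= 0 and window length positive")
    if t0 - w < 0 or t0 + d + w > epoch_length:
        raise WindowOutOfBounds(
            f"event at {t0} with delay {d} and window {w} leaves epoch of {epoch_length}"
        )
    return (
        slice(t0, t0 + w),
        slice(t0 + d, t0 + d + w),
        slice(t0 - w, t0),
        slice(t0 + d - w, t0 + d),
    )


def batched_partial_correlation(
    source_win: np.ndarray,
    target_win: np.ndarray,
    source_past: np.ndarray,
    target_past: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray]:
    """Past-conditioned partial correlation for a batch of window pairs.

    All inputs share the shape (..., L). Each source/target window is
    linearly regressed (with intercept) on the two sample-aligned past
    segments, and the Pearson correlation of the residuals is returned with
    a t-distribution p-value on L - 4 degrees of freedom. Window pairs with
    degenerate residual variance return r = 0 with p = 1.
    """
    sw = np.asarray(source_win)
    dt = sw.dtype if sw.dtype in (np.dtype(np.float32), np.dtype(np.float64)) else np.dtype(float)
    sw = sw.astype(dt, copy=False)
    tw = np.asarray(target_win).astype(dt, copy=False)
    sp = np.broadcast_to(np.asarray(source_past).astype(dt, copy=False), sw.shape)
    tp = np.broadcast_to(np.asarray(target_past).astype(dt, copy=False), sw.shape)
    if not (sw.shape == tw.shape == sp.shape == tp.shape):
        raise ValueError("all four segments must share a shape")
    L = sw.shape[-1]
    if L < 10:
        raise ValueError("windows must contain at least 10 samples")

    # normal equations of the regression on Z = [1, sp, tp], assembled from
    # moments (equivalent to explicit residualization, but batch-friendly)
    def dot(a, b):
        return (a * b).sum(axis=-1)

    ones_row = np.full(sw.shape[:-1], L, dtype=dt)
    G = np.stack(
        [
            np.stack([ones_row, sp.sum(-1), tp.sum(-1)], axis=-1),
            np.stack([sp.sum(-1), dot(sp, sp), dot(sp, tp)], axis=-1),
            np.stack([tp.sum(-1), dot(sp, tp), dot(tp, tp)], axis=-1),
        ],
        axis=-2,
    )  # (..., 3, 3)
    a_s = np.stack([sw.sum(-1), dot(sp, sw), dot(tp, sw)], axis=-1)
    a_t = np.stack([tw.sum(-1), dot(sp, tw), dot(tp, tw)], axis=-1)
    rhs = np.stack([a_s, a_t], axis=-1)  # (..., 3, 2)
    try:
        beta = np.linalg.solve(G, rhs)
    except np.linalg.LinAlgError:
        beta = np.einsum("...km,...mn->...kn", np.linalg.pinv(G), rhs)
    # residual second moments: r_x' r_y = x'y - a_x' G^-1 a_y
    sww, tww = dot(sw, sw), dot(tw, tw)
    rss = np.maximum(sww - (a_s * beta[..., 0]).sum(-1), 0.0)
    rtt = np.maximum(tww - (a_t * beta[..., 1]).sum(-1), 0.0)
    rst = dot(sw, tw) - (a_s * beta[..., 1]).sum(-1)
    den = np.sqrt(rss * rtt)
    tiny = np.finfo(dt).tiny
    # degenerate when residual variance is numerically zero relative to the
    # window's own scale (constant windows, perfect fits)
    rel = 1e-12 if dt == np.dtype(np.float64) else 1e-5
    good = (rss > rel * np.maximum(sww, tiny)) & (rtt > rel * np.maximum(tww, tiny))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(good, rst / np.where(good, den, 1.0), 0.0)
    r = np.clip(r, -1.0, 1.0)
    df = L - 4
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        t = r.astype(np.float64) * np.sqrt(df / np.maximum(1.0 - r.astype(np.float64) ** 2, tiny))
    p = 2.0 * special.stdtr(df, -np.abs(t))
    p = np.where(good, p, 1.0)
    return r, p


def windowed_partial_correlation(
    source_win: np.ndarray,
    target_win: np.ndarray,
    source_past: np.ndarray,
    target_past: np.ndarray,
) -> Tuple[float, float]:
    """Scalar past-conditioned partial correlation for one window pair."""
    r, p = batched_partial_correlation(
        np.atleast_2d(source_win),
        np.atleast_2d(target_win),
        np.atleast_2d(source_past),
        np.atleast_2d(target_past),
    )
    return float(r[0]), float(p[0])


def gate_significance(
    r_values: np.ndarray,
    p_values: np.ndarray,
    n_events: int,
    alpha_event: float = 0.01,
) -> np.ndarray:
    """Zero out event-wise estimates that fail the Bonferroni gate.

    Values with p >= alpha_event / n_events are set to zero; ``n_events`` is
    the total number of events in the epoch (the number of times the
    correlation is tested within it).
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    r = np.asarray(r_values, dtype=float)
    p = np.asarray(p_values, dtype=float)
    return np.where(p < alpha_event / n_events, r, 0.0)
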