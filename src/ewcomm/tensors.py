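"""The shared window engine: event catalogs, the N x N x M communication
tensor, and the matching spectral tensors.

``compute_tensors`` is the single code path that places windows, evaluates
the past-conditioned partial correlation, gates it by epoch-wise Bonferroni
significance, and (optionally) measures target relative band power and
source-target ISPC inside the very same windows. Both public builders and
the cyclic-surrogate branch call it, so observed and null statistics are
produced by identical code. Cyclic target shifts are supported natively: a
shift k turns every target index t into (t - k) mod L, i.e. windows are read
from the circularly permuted series.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np

from .bands import Band, DEFAULT_BANDS, validate_bands
from .containers import (
    CommunicationTensor,
    Connectome,
    EventCatalog,
    EwcParams,
    SpectralTensors,
)
from .ewc import batched_partial_correlation, detect_events, gate_significance
from .preprocess import bandpass, instantaneous_phase
from .spectral import BandPowerPlan

__all__ = [
    "build_event_catalog",
    "prepare_phases",
    "prepare_phasors",
    "compute_tensors",
    "build_communication_tensor",
    "build_spectral_tensors",
]


def build_event_catalog(
    epochs: np.ndarray,
    connectome: Connectome,
    params: EwcParams,
    sampling_rate: float,
) -> EventCatalog:
    """Detect boundary-filtered events for every (epoch, region).

    Events are filtered so that the source window plus the region's largest
    outgoing structural delay fits in the epoch and a full window of past
    precedes the onset.
    """
    M, N, L = epochs.shape
    w = params.window_samples(sampling_rate)
    if 2 * w > L:
        raise ValueError(
            f"window of {w} samples leaves no room for past conditioning in epochs of {L}"
        )
    delays = connectome.delay_samples(params.conduction_velocity_m_s, sampling_rate)
    max_out = np.where(
        connectome.adjacency.any(axis=1),
        (delays * connectome.adjacency).max(axis=1),
        0,
    )
    events = [
        [
            detect_events(epochs[m, i], params.z_threshold, w, int(max_out[i]))
            for i in range(N)
        ]
        for m in range(M)
    ]
    return EventCatalog(events=events)


def prepare_phases(
    epochs: np.ndarray,
    bands: Sequence[Band],
    sampling_rate: float,
) -> np.ndarray:
    """Instantaneous phase of every epoch in every band: (M, B, N, L).

    Whole epochs are band-passed before the Hilbert transform so the
    communication windows, which are interior to the epoch by construction,
    avoid per-window filter transients.
    """
    M, N, L = epochs.shape
    out = np.empty((M, len(bands), N, L))
    for k, b in enumerate(bands):
        out[:, k] = instantaneous_phase(bandpass(epochs, b, sampling_rate))
    return out


def prepare_phasors(phases: np.ndarray) -> np.ndarray:
    """Unit phasors exp(i*phase); precomputed once so the ISPC inner loop
    (observed and every surrogate) reduces to gather-multiply-mean."""
    return np.exp(1j * phases)


def compute_tensors(
    epochs: np.ndarray,
    catalog: EventCatalog,
    connectome: Connectome,
    params: EwcParams,
    sampling_rate: float,
    bands: Optional[Sequence[Band]] = None,
    phases: Optional[np.ndarray] = None,
    phasors: Optional[np.ndarray] = None,
    compute_spectral: bool = True,
    sources: Optional[Sequence[int]] = None,
    shifts: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, Optional[np.ndarray], Optional[np.ndarray], np.ndarray]:
    """Core engine shared by observed and surrogate passes.

    Parameters
    ----------
    epochs : (M, N, L) leakage-corrected epoch array
    catalog : boundary-filtered events per (epoch, region)
    phases : optional precomputed (M, B, N, L) phase array (required when
        ``compute_spectral`` and bands are given); built on the fly otherwise
    sources : restrict computation to these source regions (default: all)
    shifts : optional (N, M) int array of cyclic target shifts; shifts[i, m]
        is applied to every target of source i in epoch m (the source itself
        is never shifted). Target windows then wrap circularly.

    Returns
    -------
    (comm, power, ispc, counts): comm and counts are (N, N, M); power/ispc
    are (N, N, M, B) or None when ``compute_spectral`` is false.
    """
    M, N, L = epochs.shape
    w = params.window_samples(sampling_rate)
    delays = connectome.delay_samples(params.conduction_velocity_m_s, sampling_rate)
    if compute_spectral:
        bands = validate_bands(bands if bands is not None else DEFAULT_BANDS)
        if phasors is None:
            if phases is None:
                phases = prepare_phases(epochs, bands, sampling_rate)
            phasors = prepare_phasors(phases)
        B = len(bands)
        plan = BandPowerPlan(w, sampling_rate, bands)
    comm = np.zeros((N, N, M))
    counts = np.zeros((N, N, M), dtype=int)
    power = np.zeros((N, N, M, B)) if compute_spectral else None
    ispc_t = np.zeros((N, N, M, B)) if compute_spectral else None

    src_list = range(N) if sources is None else sources
    win = np.arange(w)

    for m in range(M):
        n_ev = catalog.n_events(m)
        if n_ev == 0:
            continue
        x = epochs[m]
        # flatten all (source, target, event) triplets of this epoch so the
        # window statistics run as one batch; triplets stay grouped by pair
        src_l, tgt_l, ons_l, dly_l = [], [], [], []
        for i in src_list:
            onsets = catalog.events[m][i]
            jarr = connectome.neighbors(i)
            if onsets.size == 0 or jarr.size == 0:
                continue
            for j in jarr:
                src_l.append(np.full(onsets.size, i))
                tgt_l.append(np.full(onsets.size, j))
                ons_l.append(onsets)
                dly_l.append(np.full(onsets.size, delays[i, j]))
        if not src_l:
            continue
        src = np.concatenate(src_l)
        tgt = np.concatenate(tgt_l)
        ons = np.concatenate(ons_l)
        dly = np.concatenate(dly_l)
        if shifts is None:
            # observed pass: skip events whose target window leaves the epoch
            fits = ons + dly + w <= L
            if not fits.all():
                src, tgt, ons, dly = src[fits], tgt[fits], ons[fits], dly[fits]
            if src.size == 0:
                continue
        idx = ons[:, None] + win[None, :]  # (P, w)
        tofs = idx + dly[:, None]
        tpofs = tofs - w
        if shifts is not None:
            # surrogate pass: targets are circularly shifted, windows wrap
            k = shifts[src, m][:, None]
            tofs = (tofs - k) % L
            tpofs = (tpofs - k) % L
        sw = x[src[:, None], idx]
        sp = x[src[:, None], idx - w]
        tw = x[tgt[:, None], tofs]
        tp = x[tgt[:, None], tpofs]

        r, p = batched_partial_correlation(sw, tw, sp, tp)
        gated = gate_significance(r, p, n_ev, params.alpha_event)

        # segment boundaries of the contiguous (source, target) groups
        pair_code = src * N + tgt
        seg = np.r_[0, np.flatnonzero(np.diff(pair_code)) + 1]
        si, ti = src[seg], tgt[seg]
        cnt = np.diff(np.r_[seg, pair_code.size])
        comm[si, ti, m] = np.add.reduceat(gated, seg) / cnt
        counts[si, ti, m] = cnt

        if compute_spectral:
            bp = plan(tw)  # (P, B)
            ps = phasors[m][:, src[:, None], idx]  # (B, P, w)
            pt = phasors[m][:, tgt[:, None], tofs]
            iv = np.abs((ps * pt.conj()).mean(axis=-1))  # (B, P)
            power[si, ti, m, :] = np.add.reduceat(bp, seg, axis=0) / cnt[:, None]
            ispc_t[si, ti, m, :] = (np.add.reduceat(iv, seg, axis=1) / cnt[None, :]).T
    return comm, power, ispc_t, counts


def build_communication_tensor(
    epochs: np.ndarray,
    catalog: EventCatalog,
    connectome: Connectome,
    params: EwcParams,
    sampling_rate: float,
) -> CommunicationTensor:
    """N x N x M tensor of epoch-wise mean gated partial correlations.

    Entry (i, j, m) is the arithmetic mean over source i's usable events in
    epoch m of the Bonferroni-gated event-wise values (zeros from
    non-significant events included); structurally disconnected pairs, the
    diagonal and zero-event epochs remain exactly zero.
    """
    comm, _, _, counts = compute_tensors(
        epochs, catalog, connectome, params, sampling_rate, compute_spectral=False
    )
    return CommunicationTensor(values=comm, n_events_used=counts)


def build_spectral_tensors(
    epochs: np.ndarray,
    catalog: EventCatalog,
    connectome: Connectome,
    params: EwcParams,
    sampling_rate: float,
    bands: Sequence[Band] = DEFAULT_BANDS,
    phases: Optional[np.ndarray] = None,
) -> SpectralTensors:
    """Target relative band power and source-target ISPC in the EWC windows.

    Uses the identical window placement as the communication tensor; the
    target window sits at the delay-shifted position. Values are means over
    the source's usable events; the zero pattern matches the communication
    tensor's structural zeros.
    """
    _, power, ispc_t, _ = compute_tensors(
        epochs,
        catalog,
        connectome,
        params,
        sampling_rate,
        bands=bands,
        phases=phases,
        compute_spectral=True,
    )
    return SpectralTensors(
        target_power=power, ispc=ispc_t, band_names=tuple(b.name for b in bands)
    )
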