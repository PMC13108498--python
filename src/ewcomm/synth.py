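"""Synthetic parcellated recordings with known directed coupling.

The generator builds each region's baseline as a sum of damped stochastic
harmonic oscillators (one per frequency band, a second-order autoregressive
resonator driven by white noise) on top of a 1/f background, injects sparse
transient high-amplitude events (smooth multiplicative bursts, ~100 ms) at
Poisson times, and adds, for every directed coupled pair, a scaled copy of
the source signal delayed in proportion to centroid Euclidean distance.
Coupling gain can optionally be gated per sample by the target's band-limited
envelope (power routing) or by the instantaneous source-target phase
alignment (coherence routing), normalized to mean gain one so gated and
ungated runs carry comparable power.

Everything is driven by a single seed; identical seeds give bit-identical
outputs.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .bands import Band, DEFAULT_BANDS, band_index
from .containers import (
    Connectome,
    GroundTruth,
    GATING_MODES,
    ParcellatedRecording,
    SimulationConfig,
)
from .preprocess import bandpass, instantaneous_phase

__all__ = [
    "generate_connectome",
    "simulate_recording",
    "make_gradient_fixture",
    "motif_fixture",
    "DEFAULT_BAND_PROFILE",
]

#: Relative oscillator weights emulating a resting posterior-dominant
#: spectrum: strong alpha, moderate beta/theta, weak gamma, on a 1/f floor.
DEFAULT_BAND_PROFILE: Dict[str, float] = {
    "theta": 0.4,
    "alpha": 1.0,
    "beta": 0.5,
    "gamma_lo": 0.25,
    "gamma_hi": 0.2,
}
PINK_WEIGHT = 1.0


def generate_connectome(
    n_regions: int,
    density: float,
    seed: int,
    radius_mm: float = 70.0,
) -> Connectome:
    """Random binary symmetric connectome with centroids on a sphere.

    Exactly ``round(density * n_regions * (n_regions - 1) / 2)`` undirected
    edges are placed uniformly at random; centroids are drawn uniformly on a
    sphere of the given radius (approximating a head).
    """
    if n_regions < 2:
        raise ValueError("need at least two regions")
    if not (0 < density <= 1):
        raise ValueError("density must lie in (0, 1]")
    n_pairs = n_regions * (n_regions - 1) // 2
    n_edges = int(round(density * n_pairs))
    if n_edges < 1:
        raise ValueError(f"density {density} yields no edges for {n_regions} regions")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n_regions, k=1)
    chosen = rng.choice(n_pairs, size=n_edges, replace=False)
    adj = np.zeros((n_regions, n_regions), dtype=np.int8)
    adj[iu[0][chosen], iu[1][chosen]] = 1
    adj |= adj.T
    vecs = rng.standard_normal((n_regions, 3))
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    centroids = radius_mm * vecs
    return Connectome(adjacency=adj, centroids=centroids)


def _resonator(band: Band, sampling_rate: float, drive: np.ndarray) -> np.ndarray:
    """Damped second-order resonator at the band's center frequency.

    Pole radius r = exp(-pi * bandwidth / SR) sets the -3 dB width; r must be
    strictly inside the unit circle for stability.
    """
    r = float(np.exp(-np.pi * band.width / sampling_rate))
    if not (0 < r < 1):
        raise ValueError(
            f"unstable resonator for band {band.name!r}: pole radius {r} not in (0, 1)"
        )
    w0 = 2 * np.pi * band.center / sampling_rate
    a = [1.0, -2.0 * r * np.cos(w0), r * r]
    y = sps.lfilter([1.0], a, drive)
    sd = y.std()
    return y / sd if sd > 0 else y


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """1/f-power background via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    y = np.fft.irfft(spec * scale, n=n)
    sd = y.std()
    return y / sd if sd > 0 else y


def _event_envelope(
    rng: np.random.Generator,
    n_samples: int,
    rate_hz: float,
    sampling_rate: float,
    amplitude: float,
    duration_s: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """Multiplicative burst envelope and the burst onset samples.

    Bursts last ``duration_s`` with cosine on/off ramps (Tukey window) so the
    z-score detector sees them without discontinuity artifacts.
    """
    env = np.ones(n_samples)
    if rate_hz <= 0:
        return env, np.array([], dtype=int)
    dur = max(int(round(duration_s * sampling_rate)), 4)
    bump = sps.windows.tukey(dur, alpha=0.5)
    onsets: List[int] = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / rate_hz)
        onset = int(round(t * sampling_rate))
        if onset + dur >= n_samples:
            break
        if onsets and onset <= onsets[-1]:
            onset = onsets[-1] + 1
            if onset + dur >= n_samples:
                break
        onsets.append(onset)
        env[onset : onset + dur] = np.maximum(
            env[onset : onset + dur], 1.0 + (amplitude - 1.0) * bump
        )
    return env, np.asarray(onsets, dtype=int)


def _slow_envelope(
    rng: np.random.Generator, n: int, cv: float, tau_samples: float
) -> np.ndarray:
    """Slow positive amplitude modulation of one band rhythm.

    Log-normal envelope from Gaussian-smoothed white noise with correlation
    time ``tau_samples``; emulates the waxing and waning of band power seen
    in resting recordings over seconds-to-minutes, which is what gives band
    power meaningful epoch-to-epoch variation.
    """
    if cv <= 0:
        return np.ones(n)
    # Gaussian smoothing in the Fourier domain: O(n log n) regardless of the
    # correlation time (a direct kernel would span tens of thousands of taps)
    white = rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, d=1.0)
    kernel = np.exp(-0.5 * (2 * np.pi * freqs * tau_samples) ** 2)
    g = np.fft.irfft(np.fft.rfft(white) * kernel, n=n)
    g = g - g.mean()
    sd = g.std()
    if sd < 1e-12:
        return np.ones(n)
    g = g / sd
    return np.exp(cv * g - 0.5 * cv * cv)


def _delayed(x: np.ndarray, delay: int) -> np.ndarray:
    """Causal shift: output[t] = x[t - delay], zero-padded at the start."""
    if delay == 0:
        return x
    out = np.zeros_like(x)
    out[delay:] = x[:-delay]
    return out


def simulate_recording(
    connectome: Connectome,
    config: SimulationConfig,
    gating: str = "none",
    gated_band: str = "alpha",
    band_profile: Optional[Sequence[Dict[str, float]]] = None,
    coupling: Optional[np.ndarray] = None,
    gating_exponent: float = 1.0,
) -> Tuple[ParcellatedRecording, GroundTruth]:
    """Simulate a parcellated recording over a structural connectome.

    Parameters
    ----------
    gating : "none", "target_power" or "phase_coherence"
        Under ``target_power`` the per-sample coupling gain scales with the
        target's gated-band envelope; under ``phase_coherence`` it scales
        with the short-time (one-second) phase-locking magnitude of the
        source-target phase difference in the gated band, i.e. transfer is
        strong while the two rhythms hold a consistent phase relation. Both
        gates are normalized to mean gain one so gated and ungated runs
        carry comparable power.
    coupling : optional explicit (N, N) directed gain matrix; when omitted,
        each structural edge is assigned one random direction with gain
        ``config.coupling_gain``.
    gating_exponent : exponent applied to the gate before normalization;
        values > 1 deepen the modulation (a larger planted effect) without
        changing its timing.
    """
    if gating not in GATING_MODES:
        raise ValueError(f"gating must be one of {GATING_MODES}")
    bands = config.bands
    if gating != "none":
        band_index(bands, gated_band)  # raises for unknown band
    n = connectome.n_regions
    if n != config.n_regions:
        raise ValueError("connectome size does not match config.n_regions")
    sr = config.sampling_rate_hz
    T = config.n_samples
    rng = np.random.default_rng(config.seed)

    if band_profile is None:
        band_profile = [dict(DEFAULT_BAND_PROFILE) for _ in range(n)]
    else:
        band_profile = [dict(p) for p in band_profile]
        if len(band_profile) != n:
            raise ValueError("need one band profile per region")

    # --- directed coupling over the structural graph -----------------------
    if coupling is None:
        coupling = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        for i, j in zip(*iu):
            if connectome.adjacency[i, j]:
                if rng.random() < 0.5:
                    coupling[i, j] = config.coupling_gain
                else:
                    coupling[j, i] = config.coupling_gain
    else:
        coupling = np.asarray(coupling, dtype=float)
        if coupling.shape != (n, n):
            raise ValueError("coupling must be (N, N)")
        if ((coupling != 0) & (connectome.adjacency == 0)).any():
            raise ValueError("coupling only allowed along structural edges")

    delay_s = connectome.delay_seconds(config.conduction_velocity_m_s)
    delay_smp = connectome.delay_samples(config.conduction_velocity_m_s, sr)

    # --- per-region baselines ----------------------------------------------
    baselines = np.empty((n, T))
    event_times: List[np.ndarray] = []
    tau = config.slow_mod_tau_s * sr
    for i in range(n):
        prof = band_profile[i]
        sig = PINK_WEIGHT * _pink_noise(rng, T)
        for b in bands:
            w = prof.get(b.name, 0.0)
            if w > 0:
                osc = _resonator(b, sr, rng.standard_normal(T))
                osc *= _slow_envelope(rng, T, config.slow_mod_cv, tau)
                sig = sig + w * osc
        sig /= sig.std()
        env, onsets = _event_envelope(
            rng, T, config.event_rate_hz, sr, config.event_amplitude, config.event_duration_s
        )
        baselines[i] = sig * env
        event_times.append(onsets)

    # --- gating series (from baselines, normalized to mean gain 1) ---------
    # Under gating the channel routes the gated band: the transmitted copy is
    # the source's band-limited component (unit SD), so the planted mechanism
    # is band-specific; ungated coupling transmits the broadband signal.
    if gating != "none":
        if gating_exponent <= 0:
            raise ValueError("gating_exponent must be positive")
        gb = bands[band_index(bands, gated_band)]
        narrow = bandpass(baselines, gb, sr)
        transmitted = narrow / narrow.std(axis=-1, keepdims=True)
        if gating == "target_power":
            # smooth the envelope over one second so the gate acts at the
            # timescale the windowed power estimates resolve
            envelope = uniform_filter1d(
                np.abs(sps.hilbert(narrow, axis=-1)), int(round(sr)), mode="nearest"
            )
        else:
            phases = instantaneous_phase(narrow)
            plv_win = int(round(sr))  # one-second sliding phase-locking window

    # --- assemble outputs: baseline + delayed, gated source copies ---------
    data = baselines.copy()
    for i in range(n):
        for j in range(n):
            g = coupling[i, j]
            if g == 0:
                continue
            d = int(delay_smp[i, j])
            src = _delayed(baselines[i] if gating == "none" else transmitted[i], d)
            if gating == "none":
                gain = g
            elif gating == "target_power":
                gate = envelope[j] ** gating_exponent
                gain = g * gate / gate.mean()
            else:  # phase_coherence: sliding phase-locking of the pair
                phasor = np.exp(1j * (_delayed(phases[i], d) - phases[j]))
                plv = np.abs(uniform_filter1d(phasor.real, plv_win, mode="nearest")
                             + 1j * uniform_filter1d(phasor.imag, plv_win, mode="nearest"))
                gate = plv**gating_exponent
                gain = g * gate / gate.mean()
            data[j] = data[j] + gain * src

    if config.noise_sd > 0:
        data = data + config.noise_sd * rng.standard_normal((n, T))

    recording = ParcellatedRecording(
        data=data,
        sampling_rate=sr,
        region_labels=list(connectome.region_labels),
    )
    truth = GroundTruth(
        coupling=coupling,
        delay_s=delay_s,
        event_times=event_times,
        band_profile=band_profile,
        gating=gating,
        gated_band=gated_band if gating != "none" else None,
    )
    return recording, truth


def motif_fixture(
    coupling_gain: float = 0.5,
    delays_ms: Tuple[float, float] = (4.0, 20.0),
    velocity_m_s: float = 10.0,
) -> Tuple[Connectome, np.ndarray]:
    """Four-node common-drive motif: true couplings A->B and A->C only.

    The structural graph carries A-B, A-C and B-C edges (B-C is anatomically
    present but causally silent, so spurious common-drive communication is
    analyzable); node D is isolated. Centroids are placed so the A->B and
    A->C delays equal ``delays_ms``.
    """
    d_ab = delays_ms[0] * 1e-3 * velocity_m_s * 1000.0  # mm
    d_ac = delays_ms[1] * 1e-3 * velocity_m_s * 1000.0
    centroids = np.array(
        [
            [0.0, 0.0, 0.0],  # A
            [d_ab, 0.0, 0.0],  # B
            [0.0, d_ac, 0.0],  # C
            [-60.0, -60.0, 30.0],  # D (isolated)
        ]
    )
    adj = np.zeros((4, 4), dtype=int)
    for i, j in [(0, 1), (0, 2), (1, 2)]:
        adj[i, j] = adj[j, i] = 1
    conn = Connectome(adjacency=adj, centroids=centroids, region_labels=list("ABCD"))
    coupling = np.zeros((4, 4))
    coupling[0, 1] = coupling[0, 2] = coupling_gain
    return conn, coupling


def make_gradient_fixture(
    n_regions: int,
    n_modules: int = 2,
    seed: int = 0,
    within: float = 0.6,
    between: float = 0.1,
    noise: float = 0.02,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Modular FC matrix with spatially clustered sphere coordinates.

    Regions are laid out along a smooth one-dimensional functional axis split
    into ``n_modules`` contiguous modules; FC decays smoothly with distance
    along the axis from ``within`` (typical same-module correlation) to
    ``between`` (typical cross-module correlation), plus small symmetric
    noise. The smooth falloff keeps the row-sparsified cosine affinity graph
    connected (hard block structure would disconnect it) while preserving
    within-module correlation >> between-module. Returns
    ``(fc, sphere_coords, module_labels)`` with unit-norm coordinates
    clustered by module along an arc.
    """
    if n_modules < 2:
        raise ValueError("need at least two modules")
    if n_modules > n_regions:
        raise ValueError("more modules than regions")
    if not (0 <= between < within <= 1):
        raise ValueError("need 0 <= between < within <= 1")
    rng = np.random.default_rng(seed)
    # evenly spaced functional axis with jitter; contiguous module labels
    u = (np.arange(n_regions) + 0.5) / n_regions
    u = u + rng.uniform(-0.2, 0.2, n_regions) / n_regions
    labels = np.minimum((u * n_modules).astype(int), n_modules - 1)
    du = np.abs(u[:, None] - u[None, :]) * n_modules  # in module widths
    fc = between + (within - between) * np.exp(-((du / 0.75) ** 2))
    jitter = rng.standard_normal((n_regions, n_regions)) * noise
    fc = fc + (jitter + jitter.T) / 2
    fc = (fc + fc.T) / 2
    np.fill_diagonal(fc, 1.0)
    fc = np.clip(fc, -0.999, 1.0)

    # arc on the unit sphere, jittered, so coordinates cluster by module
    theta = u * np.pi
    coords = np.column_stack([np.sin(theta), np.zeros(n_regions), np.cos(theta)])
    coords = coords + 0.08 * rng.standard_normal((n_regions, 3))
    coords /= np.linalg.norm(coords, axis=1, keepdims=True)
    return fc, coords, labels
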