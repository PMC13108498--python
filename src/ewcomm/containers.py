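"""Data containers shared across the pipeline stages.

All containers are thin dataclasses around numpy arrays with validation in
``__post_init__``; they carry no behaviour beyond derived quantities (e.g.
inter-centroid distances and sample delays on :class:`Connectome`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .bands import DEFAULT_BANDS, Band, validate_bands

GATING_MODES = ("none", "target_power", "phase_coherence")


@dataclass
class ParcellatedRecording:
    """Region-by-time source-amplitude matrix with sampling metadata.

    data : (n_regions, n_samples) float array, arbitrary units
    sampling_rate : Hz
    region_labels : unique ordered identifiers, one per row
    epoch_length_s : epoch duration used downstream (default 10 s)
    """

    data: np.ndarray
    sampling_rate: float
    region_labels: Sequence[str]
    epoch_length_s: float = 10.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError("data must be (n_regions >= 2, n_samples)")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite values")
        if self.sampling_rate <= 0 or self.epoch_length_s <= 0:
            raise ValueError("sampling_rate and epoch_length_s must be positive")
        self.region_labels = list(self.region_labels)
        if len(self.region_labels) != self.data.shape[0]:
            raise ValueError("one label per region required")
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValueError("region labels must be unique")
        if self.data.shape[1] < self.epoch_samples:
            raise ValueError("recording shorter than one epoch")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def epoch_samples(self) -> int:
        return int(round(self.epoch_length_s * self.sampling_rate))


@dataclass
class Connectome:
    """Binary structural adjacency plus region centroids (mm).

    Sample delays between regions are derived from centroid Euclidean
    distance at a fixed conduction velocity: delay_ij = round((ED_ij / v) * SR).
    """

    adjacency: np.ndarray
    centroids: np.ndarray
    region_labels: Optional[List[str]] = None

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        self.centroids = np.asarray(self.centroids, dtype=float)
        n = self.adjacency.shape[0]
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be square")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if not np.isin(self.adjacency, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        if np.trace(self.adjacency) != 0:
            raise ValueError("adjacency diagonal must be zero")
        if self.centroids.shape != (n, 3):
            raise ValueError("centroids must be (n_regions, 3)")
        self.adjacency = self.adjacency.astype(np.int8)
        if self.region_labels is None:
            self.region_labels = [f"R{i:03d}" for i in range(n)]

    @property
    def n_regions(self) -> int:
        return self.adjacency.shape[0]

    @property
    def distances_mm(self) -> np.ndarray:
        diff = self.centroids[:, None, :] - self.centroids[None, :, :]
        return np.sqrt((diff**2).sum(-1))

    def delay_seconds(self, velocity_m_s: float) -> np.ndarray:
        """delta_ij = ED_ij / v with distances in mm and v in m/s."""
        return (self.distances_mm / 1000.0) / velocity_m_s

    def delay_samples(self, velocity_m_s: float, sampling_rate: float) -> np.ndarray:
        d = np.rint(self.delay_seconds(velocity_m_s) * sampling_rate).astype(int)
        np.fill_diagonal(d, 0)
        return d

    def neighbors(self, region: int) -> np.ndarray:
        return np.flatnonzero(self.adjacency[region])


@dataclass
class GroundTruth:
    """What the synthetic generator actually planted.

    coupling : (N, N) directed gain, coupling[i, j] is the i -> j gain
    delay_s : (N, N) propagation delay in seconds
    event_times : per-region arrays of event-onset sample indices (global time)
    band_profile : per-region mapping band name -> relative spectral weight
    gating : one of GATING_MODES
    gated_band : band name the gating acts on (None when gating == "none")
    """

    coupling: np.ndarray
    delay_s: np.ndarray
    event_times: List[np.ndarray]
    band_profile: List[Dict[str, float]]
    gating: str = "none"
    gated_band: Optional[str] = None

    def __post_init__(self) -> None:
        self.coupling = np.asarray(self.coupling, dtype=float)
        self.delay_s = np.asarray(self.delay_s, dtype=float)
        if np.any(np.diag(self.coupling) != 0):
            raise ValueError("coupling diagonal must be zero")
        if np.any(self.delay_s < 0):
            raise ValueError("delays must be non-negative")
        if self.gating not in GATING_MODES:
            raise ValueError(f"gating must be one of {GATING_MODES}")
        for i, t in enumerate(self.event_times):
            t = np.asarray(t, dtype=int)
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise ValueError(f"event times of region {i} not strictly increasing")
            self.event_times[i] = t

    @property
    def driven_sources(self) -> np.ndarray:
        """Regions with at least one outgoing true coupling."""
        return np.flatnonzero((self.coupling != 0).any(axis=1))


@dataclass
class SimulationConfig:
    """Knobs of the stochastic oscillator-network generator.

    Defaults are the bundled demo conditions: 12 regions, 300 s at 250 Hz,
    structural density 0.3, directed coupling gain 0.5, events at 0.5 Hz with
    amplitude 6x the baseline SD and ~100 ms duration.
    """

    n_regions: int = 12
    duration_s: float = 300.0
    sampling_rate_hz: float = 250.0
    connection_density: float = 0.3
    coupling_gain: float = 0.5
    event_rate_hz: float = 0.5
    event_amplitude: float = 6.0
    event_duration_s: float = 0.1
    noise_sd: float = 0.2
    conduction_velocity_m_s: float = 10.0
    slow_mod_cv: float = 0.5
    slow_mod_tau_s: float = 10.0
    seed: int = 0
    bands: Tuple[Band, ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        self.bands = validate_bands(self.bands)
        if self.n_regions < 2:
            raise ValueError("need at least two regions")
        if min(self.duration_s, self.sampling_rate_hz, self.event_duration_s) <= 0:
            raise ValueError("rates and durations must be positive")
        if self.event_rate_hz < 0 or self.coupling_gain < 0 or self.noise_sd < 0:
            raise ValueError("rates, gains and noise SD must be non-negative")
        if self.slow_mod_cv < 0 or self.slow_mod_tau_s <= 0:
            raise ValueError("slow modulation CV must be >= 0 and timescale positive")
        if self.event_amplitude < 1:
            raise ValueError("event_amplitude is a multiple of baseline SD, >= 1")
        nyq_need = 2.0 * max(b.hi for b in self.bands)
        if self.sampling_rate_hz < nyq_need:
            raise ValueError(
                f"sampling rate {self.sampling_rate_hz} Hz below 2x highest band edge ({nyq_need} Hz)"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))


@dataclass
class EwcParams:
    """Operating parameters of event-windowed communication inference."""

    z_threshold: float = 3.0
    window_s: float = 1.0
    conduction_velocity_m_s: float = 10.0
    alpha_event: float = 0.01
    dependence_measure: str = "partial_correlation"

    def __post_init__(self) -> None:
        if min(self.z_threshold, self.window_s, self.conduction_velocity_m_s, self.alpha_event) <= 0:
            raise ValueError("all EWC parameters must be positive")
        if self.dependence_measure != "partial_correlation":
            raise NotImplementedError(
                "only 'partial_correlation' is implemented as the dependence measure"
            )

    def window_samples(self, sampling_rate: float) -> int:
        return int(round(self.window_s * sampling_rate))


@dataclass
class EventCatalog:
    """Boundary-filtered event onsets per (epoch, region).

    events[m][i] is a strictly increasing int array of onset samples within
    epoch m for region i. ``n_events(m)`` is the Bonferroni denominator: the
    total number of events in the epoch across all regions.
    """

    events: List[List[np.ndarray]]

    def n_events(self, epoch: int) -> int:
        return int(sum(len(e) for e in self.events[epoch]))

    @property
    def n_epochs(self) -> int:
        return len(self.events)

    def total_events(self) -> int:
        return int(sum(self.n_events(m) for m in range(self.n_epochs)))


@dataclass
class CommunicationTensor:
    """N x N x M directed communication estimates (source, target, epoch)."""

    values: np.ndarray
    n_events_used: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("values must be (N, N, M)")
        if not np.isfinite(self.values).all():
            raise ValueError("communication tensor contains non-finite values")


@dataclass
class SpectralTensors:
    """Per-window target relative band power and source-target ISPC.

    Both arrays are (N, N, M, n_bands) with the band axis ordered as the
    analysis bands; zeros where no event/window existed (same structural-zero
    pattern as the communication tensor).
    """

    target_power: np.ndarray
    ispc: np.ndarray
    band_names: Tuple[str, ...]

    def __post_init__(self) -> None:
        self.target_power = np.asarray(self.target_power, dtype=float)
        self.ispc = np.asarray(self.ispc, dtype=float)
        if self.target_power.shape != self.ispc.shape:
            raise ValueError("power and ispc tensors must share a shape")
        if self.target_power.min() < 0 or self.target_power.max() > 1 + 1e-9:
            raise ValueError("relative power must lie in [0, 1]")
        if self.ispc.min() < -1e-12 or self.ispc.max() > 1 + 1e-9:
            raise ValueError("ISPC must lie in [0, 1]")


@dataclass
class PrincipleMatrix:
    """Per-source Pearson alignment to the 10 candidate routing measures.

    values : (N, 10), columns are the 5 power bands then the 5 ISPC bands;
    NaN marks flagged-missing entries (fewer than ``min_valid`` paired
    samples, or degenerate variance).
    """

    values: np.ndarray
    n_valid: np.ndarray
    column_names: Tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (np.abs(finite) > 1 + 1e-9).any():
            raise ValueError("Pearson coefficients must lie in [-1, 1]")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def principle_column_names(bands: Sequence[Band] = DEFAULT_BANDS) -> Tuple[str, ...]:
    return tuple(f"power_{b.name}" for b in bands) + tuple(f"ispc_{b.name}" for b in bands)


@dataclass
class SurrogateResult:
    """Cyclic-surrogate ensemble with empirical p-values and FDR mask."""

    surrogate_values: np.ndarray  # (S, N, 10)
    p_values: np.ndarray  # (N, 10)
    fdr_mask: np.ndarray  # binary (N, 10)
    n_surrogates: int
    seed: int

    def __post_init__(self) -> None:
        p = self.p_values[np.isfinite(self.p_values)]
        if p.size and (p.min() < 0 or p.max() > 1):
            raise ValueError("p-values must lie in [0, 1]")


@dataclass
class GradientMap:
    """Principal diffusion-embedding gradient of an FC matrix."""

    values: np.ndarray
    eigenvalues: np.ndarray
    sign_convention: str = "positive_skew"


@dataclass
class GradientAlignment:
    """Spearman alignment of one map column against the gradient."""

    measure: str
    spearman_r: float
    p_spin: float
    n_spins: int
    n_valid: int
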