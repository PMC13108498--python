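"""End-to-end orchestration: prep -> EWC -> spectra -> principles ->
surrogates -> gradient, from one config object.

``analyze_recording`` is the in-memory driver used throughout the tests and
examples; ``run_analysis`` wraps it with file I/O, a run log and an output
manifest; ``make_fixtures`` writes the bundled synthetic demo inputs. All
randomness flows from named seeds in the config — there is no ambient RNG.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import h5py
import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .bands import Band, DEFAULT_BANDS, validate_bands
from .containers import (
    CommunicationTensor,
    Connectome,
    EwcParams,
    ParcellatedRecording,
    PrincipleMatrix,
    SimulationConfig,
    SpectralTensors,
    SurrogateResult,
)
from .gradients import GradientAlignment, diffusion_gradient, gradient_alignment
from .preprocess import epoch_recording, leakage_correct
from .principles import build_principle_matrix, top_band_report
from .surrogate import mask_principles, run_surrogate_analysis
from .synth import generate_connectome, make_gradient_fixture, simulate_recording
from .tensors import build_event_catalog, compute_tensors, prepare_phases, prepare_phasors

__all__ = ["AnalysisConfig", "AnalysisResult", "analyze_recording", "run_analysis", "make_fixtures"]


@dataclass
class AnalysisConfig:
    """Serializable description of one full analysis run."""

    recording_paths: List[str]
    adjacency_path: str
    centroids_path: str
    output_dir: str
    fc_path: Optional[str] = None
    sphere_coords_path: Optional[str] = None
    z_threshold: float = 3.0
    window_s: float = 1.0
    conduction_velocity_m_s: float = 10.0
    alpha_event: float = 0.01
    n_surrogates: int = 1000
    n_spins: int = 10_000
    surrogate_seed: int = 0
    spin_seed: int = 0
    fdr_q: float = 0.05
    leakage_correction: bool = True
    bands: List[List] = field(
        default_factory=lambda: [[b.name, b.lo, b.hi] for b in DEFAULT_BANDS]
    )

    def band_objects(self) -> Tuple[Band, ...]:
        return validate_bands([Band(str(n), float(lo), float(hi)) for n, lo, hi in self.bands])

    def ewc_params(self) -> EwcParams:
        return EwcParams(
            z_threshold=self.z_threshold,
            window_s=self.window_s,
            conduction_velocity_m_s=self.conduction_velocity_m_s,
            alpha_event=self.alpha_event,
        )

    def validate_paths(self) -> None:
        paths = list(self.recording_paths) + [self.adjacency_path, self.centroids_path]
        for p in (self.fc_path, self.sphere_coords_path):
            if p is not None:
                paths.append(p)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class AnalysisResult:
    """In-memory output bundle of one recording's analysis."""

    comm: CommunicationTensor
    spectral: SpectralTensors
    principles: PrincipleMatrix
    surrogates: Optional[SurrogateResult]
    masked_principles: Optional[np.ndarray]
    log: Dict


def analyze_recording(
    recording: ParcellatedRecording,
    connectome: Connectome,
    params: Optional[EwcParams] = None,
    bands: Sequence[Band] = DEFAULT_BANDS,
    n_surrogates: int = 1000,
    surrogate_seed: int = 0,
    fdr_q: float = 0.05,
    leakage_correction: bool = True,
) -> AnalysisResult:
    """Full single-recording analysis, in memory.

    With ``n_surrogates = 0`` the surrogate stage is skipped and the masked
    matrix is absent (None).
    """
    params = params or EwcParams()
    bands = validate_bands(bands)
    sr = recording.sampling_rate
    log: Dict = {"timings_s": {}, "params": asdict(params) if hasattr(params, "__dataclass_fields__") else {}}

    t0 = time.perf_counter()
    epochs = epoch_recording(recording)
    if leakage_correction:
        epochs = np.stack([leakage_correct(e) for e in epochs])
    log["timings_s"]["prep"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    catalog = build_event_catalog(epochs, connectome, params, sr)
    log["n_events_per_epoch"] = [catalog.n_events(m) for m in range(catalog.n_epochs)]
    phasors = prepare_phasors(prepare_phases(epochs, bands, sr))
    comm_v, power, ispc_t, counts = compute_tensors(
        epochs, catalog, connectome, params, sr, bands=bands, phasors=phasors
    )
    comm = CommunicationTensor(values=comm_v, n_events_used=counts)
    spectral = SpectralTensors(
        target_power=power, ispc=ispc_t, band_names=tuple(b.name for b in bands)
    )
    log["timings_s"]["tensors"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    pm = build_principle_matrix(comm, spectral, connectome)
    log["timings_s"]["principles"] = time.perf_counter() - t0

    surrogates = None
    masked = None
    if n_surrogates > 0:
        t0 = time.perf_counter()
        surrogates = run_surrogate_analysis(
            pm.values, epochs, catalog, connectome, params, sr,
            bands=bands, phasors=phasors, n_surrogates=n_surrogates,
            seed=surrogate_seed, q=fdr_q,
        )
        masked = mask_principles(pm.values, surrogates.fdr_mask)
        log["timings_s"]["surrogates"] = time.perf_counter() - t0
    else:
        log["surrogate_stage"] = "skipped (n_surrogates = 0); masked outputs absent"
    return AnalysisResult(
        comm=comm, spectral=spectral, principles=pm,
        surrogates=surrogates, masked_principles=masked, log=log,
    )


def _save_principle_table(path, values: np.ndarray, columns, labels) -> None:
    pd.DataFrame(values, index=list(labels), columns=list(columns)).to_csv(
        path, sep="\t", index_label="region"
    )


def run_analysis(config: AnalysisConfig) -> Dict:
    """Run the configured analysis and write the output bundle.

    Writes, per recording r: ``tensors_r.h5``, ``principles_r.tsv``,
    ``pvalues_r.tsv`` / ``fdr_mask_r.tsv`` / ``masked_principles_r.tsv``
    (when surrogates are enabled); plus, when >= 3 recordings are given, a
    ``top_bands.tsv`` report; when FC and sphere coordinates are given, the
    diffusion gradient and per-measure spin-test alignment; and always a
    ``log.json`` and a ``manifest.json`` of output hashes.
    """
    config.validate_paths()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    conn = eio.load_connectome(config.adjacency_path, config.centroids_path)
    bands = config.band_objects()
    params = config.ewc_params()

    numeric_outputs: List[Path] = []
    log: Dict = {
        "config": asdict(config),
        "versions": _versions(),
        "recordings": [],
    }
    results: List[AnalysisResult] = []
    masked_stack: List[np.ndarray] = []
    for r, rec_path in enumerate(config.recording_paths):
        rec = eio.load_recording(rec_path)
        if rec.n_regions != conn.n_regions:
            raise ValueError(
                f"stage 'load': recording {rec_path} has {rec.n_regions} regions, "
                f"connectome has {conn.n_regions}"
            )
        res = analyze_recording(
            rec, conn, params=params, bands=bands,
            n_surrogates=config.n_surrogates,
            surrogate_seed=config.surrogate_seed + r,
            fdr_q=config.fdr_q,
            leakage_correction=config.leakage_correction,
        )
        results.append(res)
        labels = rec.region_labels
        tpath = out / f"tensors_{r}.h5"
        eio.save_tensors(tpath, res.comm, res.spectral)
        numeric_outputs.append(tpath)
        cpath = out / f"communication_{r}.tsv"
        eio.save_comm_table(cpath, res.comm, labels)
        numeric_outputs.append(cpath)
        ppath = out / f"principles_{r}.tsv"
        _save_principle_table(ppath, res.principles.values, res.principles.column_names, labels)
        numeric_outputs.append(ppath)
        if res.surrogates is not None:
            for name, arr in (
                ("pvalues", res.surrogates.p_values),
                ("fdr_mask", res.surrogates.fdr_mask),
                ("masked_principles", res.masked_principles),
            ):
                fp = out / f"{name}_{r}.tsv"
                _save_principle_table(fp, arr, res.principles.column_names, labels)
                numeric_outputs.append(fp)
            spath = out / f"surrogates_{r}.h5"
            with h5py.File(spath, "w") as f:
                f.create_dataset("surrogates", data=res.surrogates.surrogate_values)
                f.create_dataset("p", data=res.surrogates.p_values)
                f.create_dataset("mask", data=res.surrogates.fdr_mask)
                f.attrs["seed"] = res.surrogates.seed
            numeric_outputs.append(spath)
            masked_stack.append(res.masked_principles)
        log["recordings"].append(res.log)

    if len(results) >= 3:
        report = top_band_report([res.principles for res in results])
        rpath = out / "top_bands.tsv"
        report.to_csv(rpath, sep="\t", index=False)
        numeric_outputs.append(rpath)

    if config.fc_path and config.sphere_coords_path and masked_stack:
        fc = eio.load_matrix(config.fc_path)
        coords = np.loadtxt(config.sphere_coords_path, delimiter="\t")
        grad = diffusion_gradient(fc)
        # group map: mean of the surrogate-masked per-recording matrices
        stack = np.stack(masked_stack)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells stay NaN
            group = np.nanmean(stack, axis=0)
        aligns = gradient_alignment(
            group, grad, coords, results[0].principles.column_names,
            n_spins=config.n_spins, seed=config.spin_seed,
        )
        adf = pd.DataFrame(
            [
                {"measure": a.measure, "spearman_r": a.spearman_r,
                 "p_spin": a.p_spin, "n_valid": a.n_valid}
                for a in aligns
            ]
        )
        apath = out / "gradient_alignment.tsv"
        adf.to_csv(apath, sep="\t", index=False)
        numeric_outputs.append(apath)
        gpath = out / "gradient.tsv"
        eio.save_matrix(gpath, grad.values[:, None])
        numeric_outputs.append(gpath)

    (out / "log.json").write_text(json.dumps(log, indent=2, default=str) + "\n")
    eio.write_manifest(out / "manifest.json", numeric_outputs)
    return log


def _versions() -> Dict[str, str]:
    import scipy
    import statsmodels

    from . import __version__

    return {
        "ewcomm": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }


def make_fixtures(
    out_dir,
    n_regions: int = 12,
    duration_s: float = 300.0,
    sampling_rate_hz: float = 250.0,
    density: float = 0.3,
    seed: int = 7,
    gating: str = "none",
    gated_band: str = "alpha",
) -> Dict[str, str]:
    """Write the bundled synthetic demo inputs and return their paths.

    Produces the recording (HDF5), binary adjacency and centroid tables, the
    ground-truth directed edge list, and a two-module FC matrix with matching
    unit-sphere coordinates for the gradient stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    conn = generate_connectome(n_regions, density, seed)
    cfg = SimulationConfig(
        n_regions=n_regions, duration_s=duration_s,
        sampling_rate_hz=sampling_rate_hz, connection_density=density, seed=seed,
    )
    rec, truth = simulate_recording(conn, cfg, gating=gating, gated_band=gated_band)
    fc, coords, labels = make_gradient_fixture(n_regions, n_modules=2, seed=seed)

    paths = {
        "recording": out / "recording.h5",
        "adjacency": out / "adjacency.tsv",
        "centroids": out / "centroids.tsv",
        "ground_truth": out / "ground_truth.tsv",
        "fc": out / "fc.tsv",
        "sphere_coords": out / "sphere_coords.tsv",
        "module_labels": out / "module_labels.tsv",
    }
    eio.save_recording(paths["recording"], rec)
    eio.save_connectome(paths["adjacency"], paths["centroids"], conn)
    eio.save_ground_truth(paths["ground_truth"], truth, rec.region_labels)
    eio.save_matrix(paths["fc"], fc)
    np.savetxt(paths["sphere_coords"], coords, delimiter="\t")
    np.savetxt(paths["module_labels"], labels, fmt="%d", delimiter="\t")
    return {k: str(v) for k, v in paths.items()}
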