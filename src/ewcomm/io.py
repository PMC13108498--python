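"""Disk formats: HDF5 recordings/tensors and delimited tables.

Recordings live in HDF5 (datasets ``data`` [N x T], scalar attributes
``sampling_rate`` and ``epoch_length_s``, dataset ``labels``); connectomes,
centroids, FC matrices and result tables are plain delimited text so they
stay inspectable and joinable to parcellation lookup tables.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import h5py
import numpy as np
import pandas as pd

from .containers import (
    CommunicationTensor,
    Connectome,
    GroundTruth,
    ParcellatedRecording,
    SpectralTensors,
)

__all__ = [
    "save_recording",
    "load_recording",
    "save_connectome",
    "load_connectome",
    "save_matrix",
    "load_matrix",
    "save_tensors",
    "load_tensors",
    "save_ground_truth",
    "file_sha256",
    "write_manifest",
]


def save_recording(path, recording: ParcellatedRecording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data)
        f.attrs["sampling_rate"] = recording.sampling_rate
        f.attrs["epoch_length_s"] = recording.epoch_length_s
        f.create_dataset(
            "labels", data=np.array(recording.region_labels, dtype=h5py.string_dtype())
        )


def load_recording(path) -> ParcellatedRecording:
    with h5py.File(path, "r") as f:
        return ParcellatedRecording(
            data=f["data"][...],
            sampling_rate=float(f.attrs["sampling_rate"]),
            region_labels=[s.decode() if isinstance(s, bytes) else str(s) for s in f["labels"][...]],
            epoch_length_s=float(f.attrs["epoch_length_s"]),
        )


def save_connectome(adjacency_path, centroids_path, connectome: Connectome) -> None:
    np.savetxt(adjacency_path, connectome.adjacency, fmt="%d", delimiter="\t")
    pd.DataFrame(
        connectome.centroids, columns=["x_mm", "y_mm", "z_mm"], index=connectome.region_labels
    ).to_csv(centroids_path, sep="\t", index_label="region")


def load_connectome(adjacency_path, centroids_path) -> Connectome:
    adj = np.loadtxt(adjacency_path, delimiter="\t")
    cent = pd.read_csv(centroids_path, sep="\t", index_col="region")
    return Connectome(
        adjacency=adj.astype(int),
        centroids=cent[["x_mm", "y_mm", "z_mm"]].to_numpy(),
        region_labels=[str(r) for r in cent.index],
    )


def save_matrix(path, matrix: np.ndarray, labels: Optional[Sequence[str]] = None) -> None:
    if labels is None:
        np.savetxt(path, matrix, delimiter="\t")
    else:
        pd.DataFrame(matrix, index=list(labels)).to_csv(path, sep="\t", header=False)


def load_matrix(path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t")


def save_tensors(
    path,
    comm: CommunicationTensor,
    spectral: Optional[SpectralTensors] = None,
) -> None:
    """Communication (and optionally spectral) tensors in one HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("ewc", data=comm.values)
        f.create_dataset("n_events_used", data=comm.n_events_used)
        if spectral is not None:
            f.create_dataset("power", data=spectral.target_power)
            f.create_dataset("ispc", data=spectral.ispc)
            f.attrs["band_names"] = list(spectral.band_names)


def load_tensors(path) -> Tuple[CommunicationTensor, Optional[SpectralTensors]]:
    with h5py.File(path, "r") as f:
        comm = CommunicationTensor(
            values=f["ewc"][...], n_events_used=f["n_events_used"][...]
        )
        spectral = None
        if "power" in f:
            spectral = SpectralTensors(
                target_power=f["power"][...],
                ispc=f["ispc"][...],
                band_names=tuple(str(b) for b in f.attrs["band_names"]),
            )
    return comm, spectral


def save_comm_table(path, comm: CommunicationTensor, labels: Sequence[str]) -> None:
    """Long-format communication table: source, target, epoch, value.

    Only structurally possible (nonzero-capable) pairs are written: rows
    where the event count is zero and the value is zero are kept, so the
    table reproduces the tensor's analyzed support exactly.
    """
    # analyzed support: pairs with at least one usable event in some epoch
    mask = comm.n_events_used.sum(axis=2) > 0
    rows = []
    for i, j in zip(*np.nonzero(mask)):
        for m in range(comm.values.shape[2]):
            rows.append(
                {
                    "source": labels[i],
                    "target": labels[j],
                    "epoch": m,
                    "value": comm.values[i, j, m],
                    "n_events": int(comm.n_events_used[i, j, m]),
                }
            )
    pd.DataFrame(rows, columns=["source", "target", "epoch", "value", "n_events"]).to_csv(
        path, sep="\t", index=False
    )


def save_ground_truth(path, truth: GroundTruth, labels: Sequence[str]) -> None:
    """Directed coupling edge list with delays, one row per true edge."""
    rows: List[Dict] = []
    n = truth.coupling.shape[0]
    for i in range(n):
        for j in range(n):
            if truth.coupling[i, j] != 0:
                rows.append(
                    {
                        "source": labels[i],
                        "target": labels[j],
                        "gain": truth.coupling[i, j],
                        "delay_s": truth.delay_s[i, j],
                    }
                )
    pd.DataFrame(rows, columns=["source", "target", "gain", "delay_s"]).to_csv(
        path, sep="\t", index=False
    )


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path, files: Sequence[Path]) -> None:
    manifest = {Path(f).name: file_sha256(f) for f in sorted(files, key=str)}
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
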