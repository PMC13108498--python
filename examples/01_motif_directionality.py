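"""Directionality recovery on a four-node common-drive motif.

Builds the bundled motif (true couplings A->B and A->C at distinct delays,
structural edge B-C present but causally silent), simulates 300 s of
recording, runs event-windowed communication inference, and prints the mean
communication estimates. Forward (true) edges should clearly exceed their
reversals, and the spurious B-C communication induced by the common drive A
should stay well below both true edges.
"""

import numpy as np

import ewcomm as e
from ewcomm.preprocess import epoch_recording, leakage_correct
from ewcomm.tensors import build_communication_tensor, build_event_catalog

conn, coupling = e.motif_fixture(coupling_gain=0.5)
cfg = e.SimulationConfig(n_regions=4, duration_s=300.0, sampling_rate_hz=250.0, seed=7)
rec, truth = e.simulate_recording(conn, cfg, coupling=coupling)

params = e.EwcParams()
epochs = np.stack([leakage_correct(x) for x in epoch_recording(rec)])
catalog = build_event_catalog(epochs, conn, params, rec.sampling_rate)
tensor = build_communication_tensor(epochs, catalog, conn, params, rec.sampling_rate)
m = tensor.values.mean(axis=2)

print("mean EWC over 30 epochs (row = source, col = target):")
for i, row in enumerate(m):
    print("  " + conn.region_labels[i], np.round(row, 4))
print()
print(f"true A->B = {m[0,1]:.3f}   vs reversed B->A = {m[1,0]:.3f}")
print(f"true A->C = {m[0,2]:.3f}   vs reversed C->A = {m[2,0]:.3f}")
print(f"common-drive B->C = {m[1,2]:.3f}, C->B = {m[2,1]:.3f} (should be smallest)")
print()
print("Positive, larger values along the true directed edges mean the")
print("delay-ordered, past-conditioned windows correctly resolved who drives whom.")
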