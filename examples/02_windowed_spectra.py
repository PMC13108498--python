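"""Band power and phase clustering inside communication windows.

Simulates a small coupled network, detects events, and prints the target
relative band power and source-target ISPC measured in the exact windows the
communication estimates come from. With the default alpha-dominant spectral
profile, the alpha band should carry the largest relative power, and ISPC of
coupled pairs should exceed that of the surrogate-like uncoupled pairs.
"""

import numpy as np

import ewcomm as e

conn = e.generate_connectome(n_regions=8, density=0.4, seed=3)
cfg = e.SimulationConfig(n_regions=8, duration_s=60.0, connection_density=0.4, seed=3)
rec, truth = e.simulate_recording(conn, cfg)

res = e.analyze_recording(rec, conn, n_surrogates=0)

band_names = res.spectral.band_names
connected = (conn.adjacency > 0)[:, :, None]
pow_by_band = [
    res.spectral.target_power[..., b][conn.adjacency > 0].mean() for b in range(5)
]
ispc_by_band = [res.spectral.ispc[..., b][conn.adjacency > 0].mean() for b in range(5)]

print("mean in-window target relative power / ISPC over connected pairs:")
for b, name in enumerate(band_names):
    print(f"  {name:9s} power {pow_by_band[b]:.3f}   ispc {ispc_by_band[b]:.3f}")

coupled = truth.coupling > 0
uncoupled = (conn.adjacency > 0) & ~coupled
alpha_ispc = res.spectral.ispc[..., 1].mean(axis=2)
print()
print(f"alpha ISPC, truly coupled pairs:   {alpha_ispc[coupled].mean():.3f}")
print(f"alpha ISPC, silent structural pairs: {alpha_ispc[uncoupled].mean():.3f}")
print()
print("Relative powers are unitless fractions of total window power; ISPC is")
print("the phase-locking value in [0, 1] between source and delayed target.")
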