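"""Routing-principle statistics: the N x 10 principle matrix and per-region
top-band reports.

Each source region's alignment to a candidate routing principle is the
Pearson correlation between its epoch-concatenated communication values and
the matching windowed oscillatory measure (five relative power bands, five
ISPC bands), restricted to anatomically connected targets. Across
recordings, a one-way ANOVA over the five bands of a measure family followed
by Tukey-Kramer pairwise comparisons identifies regions whose communication
is tracked by a single dominant band.
"""

from __future__ import annotations

from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .bands import BAND_NAMES
from .containers import (
    CommunicationTensor,
    Connectome,
    PrincipleMatrix,
    SpectralTensors,
    principle_column_names,
)

__all__ = ["build_principle_matrix", "principle_rows", "top_band_report"]

MIN_VALID = 10  # fewer paired samples than this flags the entry as missing


def _pearson_columns(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r between vector x (n,) and every column of Y (n, k)."""
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0, keepdims=True)
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((Yc**2).sum(axis=0))
    out = np.full(Y.shape[1], np.nan)
    if sx == 0:
        return out
    ok = sy > 0
    out[ok] = (xc @ Yc[:, ok]) / (sx * sy[ok])
    return np.clip(out, -1.0, 1.0)


def principle_rows(
    comm_values: np.ndarray,
    target_power: np.ndarray,
    ispc: np.ndarray,
    adjacency: np.ndarray,
    sources: Optional[Sequence[int]] = None,
    min_valid: int = MIN_VALID,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-source Pearson correlations between communication and measures.

    For source i the communication row comm[i, j, m] is concatenated over
    its structural neighbours j and epochs m (a 1 x n_neighbours*M vector)
    and correlated with the identically concatenated power and ISPC rows.
    Returns (rows, n_valid): rows is (len(sources), 10) with NaN where fewer
    than ``min_valid`` paired samples exist or variance is degenerate.
    """
    N = comm_values.shape[0]
    B = target_power.shape[-1]
    src = np.arange(N) if sources is None else np.asarray(list(sources))
    rows = np.full((len(src), 2 * B), np.nan)
    nval = np.zeros(len(src), dtype=int)
    for k, i in enumerate(src):
        jarr = np.flatnonzero(adjacency[i])
        if jarr.size == 0:
            continue
        x = comm_values[i, jarr, :].ravel()
        nval[k] = x.size
        if x.size < min_valid:
            continue
        Y = np.concatenate(
            [
                target_power[i, jarr, :, :].reshape(x.size, B),
                ispc[i, jarr, :, :].reshape(x.size, B),
            ],
            axis=1,
        )
        rows[k] = _pearson_columns(x, Y)
    return rows, nval


def build_principle_matrix(
    comm: CommunicationTensor,
    spectral: SpectralTensors,
    connectome: Connectome,
    min_valid: int = MIN_VALID,
) -> PrincipleMatrix:
    """Observed N x 10 principle matrix (5 power columns, then 5 ISPC)."""
    if comm.values.shape != spectral.target_power.shape[:3]:
        raise ValueError("communication and spectral tensors must share (N, N, M)")
    rows, nval = principle_rows(
        comm.values,
        spectral.target_power,
        spectral.ispc,
        connectome.adjacency,
        min_valid=min_valid,
    )
    names = tuple(f"power_{b}" for b in spectral.band_names) + tuple(
        f"ispc_{b}" for b in spectral.band_names
    )
    return PrincipleMatrix(values=rows, n_valid=nval, column_names=names)


def _family_report(
    data: np.ndarray, band_names: Sequence[str], alpha: float
) -> Optional[dict]:
    """ANOVA + Tukey-Kramer for one (region, measure family).

    ``data`` is (n_recordings, n_bands); NaN observations are dropped per
    band. Returns None when fewer than two bands have >= 2 observations.
    """
    groups = [data[:, b][np.isfinite(data[:, b])] for b in range(data.shape[1])]
    keep = [b for b, g in enumerate(groups) if g.size >= 2]
    if len(keep) < 2:
        return None
    groups = [groups[b] for b in keep]
    names = [band_names[b] for b in keep]
    means = np.array([g.mean() for g in groups])
    order = np.argsort(means)[::-1]
    top, second = names[order[0]], names[order[1]]
    pooled = np.concatenate(groups)
    if np.allclose(pooled, pooled[0]):
        return {
            "anova_p": 1.0, "f_stat": 0.0, "top_band": None, "second_band": None,
            "tukey_p_top2": np.nan, "single_dominant": False,
        }
    f, p = sst.f_oneway(*groups)
    rec: dict = {"anova_p": float(p), "f_stat": float(f)}
    if not np.isfinite(p) or p >= alpha:
        rec.update(top_band=None, second_band=None, tukey_p_top2=np.nan, single_dominant=False)
        return rec
    labels = np.concatenate([[nm] * g.size for nm, g in zip(names, groups)])
    tk = pairwise_tukeyhsd(pooled, labels, alpha=alpha)
    uniq = [str(g) for g in tk.groupsunique]
    p_top2 = np.nan
    for (a, b), pv in zip(combinations(uniq, 2), np.atleast_1d(tk.pvalues)):
        if {a, b} == {top, second}:
            p_top2 = float(pv)
            break
    rec.update(
        top_band=top,
        second_band=second,
        tukey_p_top2=p_top2,
        single_dominant=bool(p_top2 < alpha),
    )
    return rec


def top_band_report(
    matrices: Sequence[PrincipleMatrix | np.ndarray],
    band_names: Sequence[str] = BAND_NAMES,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-region dominant-band classification across recordings.

    For each region and each measure family (power, ISPC) separately, the
    five band columns across recordings are compared with a one-way ANOVA;
    where it is significant at ``alpha``, a Tukey-Kramer HSD comparison of
    the top two bands decides whether a single band dominates. Regions whose
    ANOVA is not significant carry no top band ("no top mechanism").
    """
    stack = np.stack(
        [m.values if isinstance(m, PrincipleMatrix) else np.asarray(m) for m in matrices]
    )
    if stack.shape[0] < 3:
        raise ValueError("need at least three recordings for the ANOVA")
    R, N, C = stack.shape
    B = C // 2
    records: List[dict] = []
    for i in range(N):
        for fam, sl in (("power", slice(0, B)), ("ispc", slice(B, 2 * B))):
            rec = _family_report(stack[:, i, sl], list(band_names), alpha)
            if rec is None:
                continue
            rec.update(region=i, family=fam)
            records.append(rec)
    cols = [
        "region", "family", "anova_p", "f_stat",
        "top_band", "second_band", "tukey_p_top2", "single_dominant",
    ]
    return pd.DataFrame.from_records(records, columns=cols)
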