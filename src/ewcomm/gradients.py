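"""Diffusion-map functional gradients and spin-permutation alignment tests.

The principal gradient is the first non-trivial eigenvector of a diffusion
operator built from a functional-connectivity matrix (row-wise top-10%
sparsification, cosine-similarity affinity, anisotropic normalization with
alpha = 0.5). Spatial alignment between two parcel maps is the Spearman
correlation, with significance from a spin test: random 3-D rotations of the
parcel positions on the sphere (mirrored across hemispheres when labels are
given) with nearest-neighbour reassignment, which preserves each map's value
multiset and spatial autocorrelation.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sst
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .containers import GradientAlignment, GradientMap

__all__ = ["diffusion_gradient", "spin_test", "spin_nulls", "gradient_alignment"]


def _cosine_affinity(rows: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(rows, axis=1)
    if (norms == 0).any():
        bad = np.flatnonzero(norms == 0).tolist()
        raise ValueError(f"regions {bad} have empty sparsified FC rows")
    aff = (rows @ rows.T) / np.outer(norms, norms)
    return np.clip(aff, 0.0, 1.0)


def diffusion_gradient(
    fc_matrix: np.ndarray,
    sparsity: float = 0.9,
    alpha: float = 0.5,
    degeneracy_tol: float = 1e-8,
) -> GradientMap:
    """Principal diffusion-embedding gradient of a symmetric FC matrix.

    Per row, only the top ``1 - sparsity`` fraction of connections is kept;
    rows are compared by cosine similarity to form a non-negative affinity;
    the diffusion operator uses anisotropic normalization with ``alpha``;
    the gradient is the first non-trivial eigenvector, sign-fixed so the
    gradient is positively skewed (a documented, arbitrary convention that
    makes runs comparable).

    Raises on non-symmetric input, a disconnected affinity graph (naming the
    components) and a degenerate leading eigengap (no stable gradient).
    """
    fc = np.asarray(fc_matrix, dtype=float)
    n = fc.shape[0]
    if fc.ndim != 2 or fc.shape != (n, n):
        raise ValueError("fc_matrix must be square")
    if not np.isfinite(fc).all():
        raise ValueError("fc_matrix contains non-finite values")
    if not np.allclose(fc, fc.T, atol=1e-10):
        raise ValueError("fc_matrix must be symmetric")

    A = fc.copy()
    np.fill_diagonal(A, 0.0)
    # keep the top (1 - sparsity) fraction per row, but never fewer than
    # three neighbours (tiny matrices would otherwise shred to singletons)
    k = int(np.clip(np.ceil((1 - sparsity) * (n - 1)), 3, n - 1))
    thresh = np.sort(A, axis=1)[:, -k][:, None]
    A = np.where(A >= thresh, A, 0.0)
    W = _cosine_affinity(A)

    n_comp, labels = connected_components((W > 0).astype(int), directed=False)
    if n_comp > 1:
        groups = [np.flatnonzero(labels == c).tolist() for c in range(n_comp)]
        raise ValueError(f"affinity graph disconnected; components: {groups}")

    d = W.sum(axis=1)
    L = W / np.outer(d**alpha, d**alpha)
    d2 = L.sum(axis=1)
    S = L / np.sqrt(np.outer(d2, d2))
    S = (S + S.T) / 2
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    if evals[1] - evals[2] < degeneracy_tol * max(abs(evals[1]), 1.0):
        raise ValueError(
            "degenerate non-trivial eigenvalues: no stable principal gradient "
            f"(lambda_1 = {evals[1]:.6g}, lambda_2 = {evals[2]:.6g})"
        )

    # right eigenvectors of the Markov operator, normalized by the trivial one
    phi = evecs / np.sqrt(d2)[:, None]
    grad = phi[:, 1] / np.abs(phi[:, 0]).mean()
    grad = grad * evals[1]
    skew = np.mean((grad - grad.mean()) ** 3)
    if skew < 0 or (skew == 0 and grad[0] < 0):
        grad = -grad
    return GradientMap(values=grad, eigenvalues=evals[:10])


def _rotations(rng: np.random.Generator, n_spins: int) -> np.ndarray:
    return sst.special_ortho_group.rvs(3, size=n_spins, random_state=rng).reshape(
        n_spins, 3, 3
    )


def _spin_assignment(
    coords: np.ndarray, rotation: np.ndarray, hemi: Optional[np.ndarray]
) -> np.ndarray:
    """Index map: region i takes the value of assignment[i] after rotation.

    With hemisphere labels, the right hemisphere uses the left rotation
    mirrored across the sagittal plane, and reassignment is within
    hemisphere; duplicated assignments are permitted.
    """
    n = coords.shape[0]
    out = np.empty(n, dtype=int)
    mirror = np.diag([-1.0, 1.0, 1.0])
    if hemi is None:
        rotated = coords @ rotation.T
        out[:] = np.argmin(cdist(coords, rotated), axis=1)
        return out
    for h in np.unique(hemi):
        sel = np.flatnonzero(hemi == h)
        rot_h = rotation if h == np.unique(hemi)[0] else mirror @ rotation @ mirror
        rotated = coords[sel] @ rot_h.T
        out[sel] = sel[np.argmin(cdist(coords[sel], rotated), axis=1)]
    return out


def spin_nulls(
    values: np.ndarray,
    sphere_coords: np.ndarray,
    n_spins: int,
    seed: int = 0,
    hemi: Optional[np.ndarray] = None,
    mirrored: bool = False,
) -> np.ndarray:
    """Spun versions of a parcel map, shape (n_spins, N).

    Each spin applies one random 3-D rotation to the unit-sphere parcel
    coordinates and reassigns every parcel the value of its nearest rotated
    neighbour; the value multiset of each spun map is a sub-multiset drawn
    from the original values (ties/duplicates permitted).
    """
    if mirrored and hemi is None:
        raise ValueError("mirrored rotation requested but hemisphere labels are missing")
    coords = np.asarray(sphere_coords, dtype=float)
    if coords.shape != (len(values), 3):
        raise ValueError("sphere_coords must be (n_regions, 3)")
    norms = np.linalg.norm(coords, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("sphere coordinates must be unit-norm")
    rng = np.random.default_rng(seed)
    rots = _rotations(rng, n_spins)
    vals = np.asarray(values, dtype=float)
    out = np.empty((n_spins, len(vals)))
    for s in range(n_spins):
        out[s] = vals[_spin_assignment(coords, rots[s], hemi)]
    return out


def spin_test(
    map_a: np.ndarray,
    map_b: np.ndarray,
    sphere_coords: np.ndarray,
    n_spins: int = 10_000,
    seed: int = 0,
    hemi: Optional[np.ndarray] = None,
    measure: str = "map",
) -> GradientAlignment:
    """Spearman alignment of two parcel maps with a spin-permutation p-value.

    ``map_b`` is spun; p_spin = (1 + #(|null r| >= |observed r|)) / (1 + s),
    the +1 correction keeping p strictly positive at finite spins.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need at least three valid paired regions")
    obs = sst.spearmanr(a[ok], b[ok]).statistic
    nulls = spin_nulls(b, sphere_coords, n_spins, seed=seed, hemi=hemi)
    null_r = np.array(
        [sst.spearmanr(a[ok], nb[ok]).statistic for nb in nulls]
    )
    p = (1.0 + np.sum(np.abs(null_r) >= np.abs(obs))) / (1.0 + n_spins)
    return GradientAlignment(
        measure=measure,
        spearman_r=float(obs),
        p_spin=float(p),
        n_spins=n_spins,
        n_valid=int(ok.sum()),
    )


def gradient_alignment(
    masked_principles: np.ndarray,
    gradient: GradientMap | np.ndarray,
    sphere_coords: np.ndarray,
    column_names: Sequence[str],
    n_spins: int = 10_000,
    seed: int = 0,
    hemi: Optional[np.ndarray] = None,
    min_valid: int = 10,
) -> List[GradientAlignment]:
    """Spearman + spin-test alignment of every principle column to the gradient.

    Columns with fewer than ``min_valid`` non-missing regions are flagged
    missing (NaN statistics).
    """
    g = gradient.values if isinstance(gradient, GradientMap) else np.asarray(gradient)
    pm = np.asarray(masked_principles, dtype=float)
    out: List[GradientAlignment] = []
    for c, name in enumerate(column_names):
        col = pm[:, c]
        ok = np.isfinite(col) & np.isfinite(g)
        if ok.sum() < min_valid:
            out.append(GradientAlignment(name, np.nan, np.nan, n_spins, int(ok.sum())))
            continue
        out.append(
            spin_test(
                col, g, sphere_coords, n_spins=n_spins, seed=seed, hemi=hemi, measure=name
            )
        )
    return out
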