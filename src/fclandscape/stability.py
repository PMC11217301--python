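"""Temporal-stability landscapes of dynamic functional connectivity.

At each timepoint the dominant subspace of the phase-coherence matrix is
extracted (its leading eigenvectors; phase-coherence slices have exact
rank <= 2, so the default subspace dimension is 2).  Dissimilarity
between timepoints is the principal angle between their dominant
subspaces, giving a T x T "temporal landscape" with entries in
[0, pi/2].  Two summaries are computed:

* entropy ``E`` of the histogram of landscape values (256 bins by
  default, mirroring 8-bit image-histogram practice), with temporal
  stability ``TS = 1/E``;
* the global temporal distance, the mean principal angle between
  *successive* timepoints (the superdiagonal of the landscape), with
  global temporal stability ``TS_global`` its inverse.

Lower distances / entropies mean a more stable, slowly reconfiguring
connectome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .connectivity import DFCStack
from .io import ParcellatedTimeseries

__all__ = [
    "DominantSubspace",
    "TemporalStabilityMatrix",
    "StabilitySummary",
    "dominant_subspace",
    "angular_distance",
    "stability_matrix",
    "entropy_ts",
    "global_temporal_distance",
    "stability_summary",
    "network_stability",
]

_RANK_RTOL = 1e-8
_ORTHO_TOL = 1e-8
_ANGLE_MODES = ("largest", "smallest", "mean")


@dataclass
class DominantSubspace:
    """Orthonormal basis of the leading eigenspace of one dFC slice."""

    basis: np.ndarray  # N x k, orthonormal columns
    explained_variance: np.ndarray  # k eigenvalues, descending

    def __post_init__(self) -> None:
        b = np.asarray(self.basis, dtype=float)
        if b.ndim != 2:
            raise ValueError("basis must be N x k")
        gram = b.T @ b
        if np.abs(gram - np.eye(b.shape[1])).max() > 1e-10:
            raise ValueError("basis columns are not orthonormal")
        self.basis = b
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)

    @property
    def k(self) -> int:
        return self.basis.shape[1]


@dataclass
class TemporalStabilityMatrix:
    """T x T symmetric matrix of principal angles phi(t_x, t_y)."""

    phi: np.ndarray
    subspace_dim: int

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi, dtype=float)
        if phi.ndim != 2 or phi.shape[0] != phi.shape[1]:
            raise ValueError("phi must be square")
        if not np.allclose(phi, phi.T, atol=1e-9):
            raise ValueError("phi must be symmetric")
        if phi.min() < -1e-12 or phi.max() > math.pi / 2 + 1e-12:
            raise ValueError("phi entries must lie in [0, pi/2]")
        if np.abs(np.diag(phi)).max(initial=0.0) > 1e-12:
            raise ValueError("phi diagonal must be zero")
        self.phi = np.clip(phi, 0.0, math.pi / 2)
        np.fill_diagonal(self.phi, 0.0)

    @property
    def n_timepoints(self) -> int:
        return self.phi.shape[0]


@dataclass
class StabilitySummary:
    """Scalar summaries of one temporal landscape.

    ``ts`` and ``ts_global`` are ``inf`` when their denominators are
    exactly zero (a legitimate outcome for degenerate inputs, e.g. a
    perfectly static connectome).
    """

    entropy: float
    ts: float
    global_temporal_distance: float
    ts_global: float
    scope: str = "whole-brain"

    def to_summary_dict(self) -> dict:
        return {
            "entropy": self.entropy,
            "ts": self.ts,
            "global_temporal_distance": self.global_temporal_distance,
            "ts_global": self.ts_global,
            "scope": self.scope,
        }


def _sign_fix(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: first nonzero component positive."""
    v = vectors.copy()
    for j in range(v.shape[1]):
        col = v[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            v[:, j] = -col
    return v


def dominant_subspace(slice_: np.ndarray, k: int = 2) -> DominantSubspace:
    """Eigenvectors of the ``k`` largest (signed) eigenvalues of a slice.

    Raises if ``k`` exceeds the numerical rank of the matrix (relative
    tolerance 1e-8 on eigenvalue magnitude), so callers cannot silently
    pad a degenerate subspace.
    """
    a = np.asarray(slice_, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("slice must be square")
    if not np.allclose(a, a.T, atol=1e-9):
        raise ValueError("slice must be symmetric")
    n = a.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    evals, evecs = np.linalg.eigh(a)  # ascending
    evals, evecs = evals[::-1], evecs[:, ::-1]  # descending signed value
    rank = int(np.sum(np.abs(evals) > _RANK_RTOL * max(np.abs(evals).max(), 1e-300)))
    if a.any() and k > rank:
        raise ValueError(f"requested k={k} exceeds numerical rank {rank}")
    basis = _sign_fix(evecs[:, :k])
    return DominantSubspace(basis=basis, explained_variance=evals[:k].copy())


def _principal_angles(b1: np.ndarray, b2: np.ndarray) -> np.ndarray:
    sigma = np.linalg.svd(b1.T @ b2, compute_uv=False)
    return np.arccos(np.clip(sigma, 0.0, 1.0))


def _check_orthonormal(b: np.ndarray, name: str) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    if b.ndim == 1:
        b = b[:, None]
    dev = np.abs(b.T @ b - np.eye(b.shape[1])).max()
    if dev > _ORTHO_TOL:
        raise ValueError(f"{name} is not orthonormal (deviation {dev:.2e})")
    return b


def angular_distance(
    b1: np.ndarray, b2: np.ndarray, mode: str = "largest"
) -> float:
    """Principal angle between the subspaces spanned by two bases.

    Angles are ``arccos`` of the singular values of ``b1.T @ b2``
    (clipped to [0, 1]); ``mode`` selects the largest angle (default,
    the most conservative measure of subspace discrepancy), the
    smallest, or their mean.  Result is in [0, pi/2]: 0 for identical
    subspaces, pi/2 for orthogonal ones.
    """
    if mode not in _ANGLE_MODES:
        raise ValueError(f"mode must be one of {_ANGLE_MODES}")
    b1 = _check_orthonormal(b1, "b1")
    b2 = _check_orthonormal(b2, "b2")
    if b1.shape[0] != b2.shape[0]:
        raise ValueError("bases live in different ambient dimensions")
    angles = _principal_angles(b1, b2)  # descending sigma -> ascending angle
    if mode == "largest":
        return float(angles[-1])
    if mode == "smallest":
        return float(angles[0])
    return float(angles.mean())


def stability_matrix(
    dfc: DFCStack, k: int = 2, mode: str = "largest"
) -> TemporalStabilityMatrix:
    """Temporal landscape: principal angle between every pair of timepoints."""
    if mode not in _ANGLE_MODES:
        raise ValueError(f"mode must be one of {_ANGLE_MODES}")
    T = dfc.n_timepoints
    bases = np.empty((T, dfc.n_regions, k))
    for t in range(T):
        bases[t] = dominant_subspace(dfc.slice_at(t), k).basis
    # all pairwise k x k cross-Gram matrices, batched SVD
    cross = np.einsum("tnk,snl->tskl", bases, bases)
    sigma = np.linalg.svd(cross, compute_uv=False)  # T x T x k, descending
    angles = np.arccos(np.clip(sigma, 0.0, 1.0))
    if mode == "largest":
        phi = angles[:, :, -1]
    elif mode == "smallest":
        phi = angles[:, :, 0]
    else:
        phi = angles.mean(axis=2)
    phi = (phi + phi.T) / 2.0
    np.fill_diagonal(phi, 0.0)
    return TemporalStabilityMatrix(phi=phi, subspace_dim=k)


def entropy_ts(
    m: TemporalStabilityMatrix | np.ndarray,
    n_bins: int = 256,
    include_diagonal: bool = True,
) -> tuple[float, float]:
    """Histogram entropy of the landscape and its inverse, TS = 1/E.

    Entries are mapped linearly from [0, pi/2] onto [0, 1] (fixed range,
    so the measure is comparable across subjects) and binned into
    ``n_bins`` uniform bins over all T^2 entries; ``E = -sum p log2 p``
    over occupied bins, in bits.  ``TS`` is ``inf`` when E is zero
    (all mass in one bin).
    """
    phi = m.phi if isinstance(m, TemporalStabilityMatrix) else np.asarray(m, float)
    vals = phi / (math.pi / 2)
    if include_diagonal:
        flat = vals.ravel()
    else:
        t = vals.shape[0]
        flat = vals[~np.eye(t, dtype=bool)]
    counts, _ = np.histogram(flat, bins=n_bins, range=(0.0, 1.0))
    p = counts / flat.size
    p = p[p > 0]
    e = float(-(p * np.log2(p)).sum())
    ts = 1.0 / e if e > 0 else math.inf
    return e, ts


def global_temporal_distance(
    m: TemporalStabilityMatrix | np.ndarray,
    all_offdiagonal: bool = False,
) -> tuple[float, float]:
    """Mean principal angle between successive timepoints, and its inverse.

    The default follows the successive-timepoint definition: the mean of
    the landscape's superdiagonal, ``(1/(T-1)) sum_i phi[i, i+1]``.
    ``all_offdiagonal=True`` instead averages every off-diagonal entry
    (a sensitivity variant).  Returns ``(gtd, ts_global)`` with
    ``ts_global = inf`` when the distance is exactly zero.
    """
    phi = m.phi if isinstance(m, TemporalStabilityMatrix) else np.asarray(m, float)
    t = phi.shape[0]
    if t < 2:
        raise ValueError("need at least 2 timepoints")
    if all_offdiagonal:
        gtd = float(phi[~np.eye(t, dtype=bool)].mean())
    else:
        gtd = float(np.diagonal(phi, offset=1).mean())
    ts_global = 1.0 / gtd if gtd > 0 else math.inf
    return gtd, ts_global


def stability_summary(
    dfc: DFCStack,
    k: int = 2,
    mode: str = "largest",
    n_bins: int = 256,
    scope: str = "whole-brain",
) -> StabilitySummary:
    """Landscape construction plus both summaries, in one call."""
    m = stability_matrix(dfc, k=k, mode=mode)
    e, ts = entropy_ts(m, n_bins=n_bins)
    gtd, tsg = global_temporal_distance(m)
    return StabilitySummary(
        entropy=e, ts=ts, global_temporal_distance=gtd, ts_global=tsg, scope=scope
    )


def network_stability(
    ts: ParcellatedTimeseries,
    dfc: DFCStack,
    network: str,
    k: int = 2,
    mode: str = "largest",
    n_bins: int = 256,
) -> StabilitySummary:
    """Temporal stability of one resting-state network.

    The dFC tensor is restricted to the network's member regions and the
    whole landscape pipeline re-run on the restriction (submatrices of a
    rank-<=2 slice are still rank <= 2, so the same subspace dimension
    applies).
    """
    idx = ts.network_members(network)
    if idx.size < 2:
        raise ValueError(f"network {network!r} has fewer than 2 regions")
    sub = dfc.restrict(idx)
    return stability_summary(sub, k=k, mode=mode, n_bins=n_bins, scope=network)
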