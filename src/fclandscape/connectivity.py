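"""Static and dynamic functional connectivity.

Static FC is the Pearson correlation between region timeseries, Fisher
r-to-z transformed, with the diagonal fixed at zero so the matrix can be
used directly as a signed weighted adjacency for community detection.

Dynamic FC is BOLD phase coherence: the instantaneous phase of each
region's signal is obtained from the analytic signal (Hilbert
transform), and the coherence between regions ``n`` and ``p`` at
timepoint ``t`` is

    dFC(n, p, t) = cos(theta(n, t) - theta(p, t)).

Because cos(a - b) = cos(a)cos(b) + sin(a)sin(b), every timepoint slice
is the sum of two outer products and therefore has rank at most 2 -- the
structural fact the temporal-stability machinery relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .io import ParcellatedTimeseries

__all__ = [
    "StaticFC",
    "DFCStack",
    "static_fc",
    "instantaneous_phase",
    "phase_coherence_dfc",
]

# Fisher clip: keeps atanh finite for duplicated rows while leaving any
# realistically attainable correlation untouched.
_R_CLIP = 1.0 - 1e-12


@dataclass
class StaticFC:
    """Fisher-z transformed Pearson correlation matrix, zero diagonal."""

    z_matrix: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z_matrix, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("z_matrix must be square")
        if not np.isfinite(z).all():
            raise ValueError("z_matrix contains non-finite entries")
        if not np.allclose(z, z.T, atol=1e-10):
            raise ValueError("z_matrix must be symmetric")
        if np.abs(np.diag(z)).max(initial=0.0) > 0:
            raise ValueError("z_matrix diagonal must be zero")
        self.z_matrix = z

    @property
    def n_regions(self) -> int:
        return self.z_matrix.shape[0]


@dataclass
class DFCStack:
    """Phase-coherence tensor (N x N x T) plus the phases that built it."""

    tensor: np.ndarray
    phases: np.ndarray  # N x T, radians in (-pi, pi]

    @property
    def n_regions(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.tensor.shape[2]

    def slice_at(self, t: int) -> np.ndarray:
        return self.tensor[:, :, t]

    def restrict(self, region_idx: np.ndarray) -> "DFCStack":
        """Sub-stack over a subset of regions (used for per-network analyses)."""
        idx = np.asarray(region_idx, dtype=int)
        if idx.size < 2:
            raise ValueError("need at least 2 regions to restrict a dFC stack")
        return DFCStack(
            tensor=self.tensor[np.ix_(idx, idx)], phases=self.phases[idx]
        )


def _check_variance(data: np.ndarray, names: list[str]) -> None:
    sd = data.std(axis=1)
    scale = np.maximum(np.abs(data).max(axis=1), 1.0)
    flat = np.flatnonzero(sd <= 100 * np.finfo(float).eps * scale)
    if flat.size:
        raise ValueError(
            f"region {names[flat[0]]!r} has zero variance (constant signal)"
        )


def static_fc(ts: ParcellatedTimeseries) -> StaticFC:
    """Pearson correlation of region timeseries, r-to-z transformed.

    Correlations are clipped to ``1 - 1e-12`` in magnitude before
    ``atanh`` so duplicated rows produce a large finite weight rather
    than infinity.  Diagonal is set to zero.
    """
    if ts.n_timepoints < 3:
        raise ValueError("static FC needs at least 3 timepoints")
    _check_variance(ts.data, ts.region_names)
    r = np.corrcoef(ts.data)
    r = np.clip(r, -_R_CLIP, _R_CLIP)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return StaticFC(z_matrix=z)


def _bandpass(data: np.ndarray, tr_seconds: float, band: tuple[float, float], order: int) -> np.ndarray:
    fs = 1.0 / tr_seconds
    nyq = fs / 2.0
    low, high = band
    if not 0 < low < high < nyq:
        raise ValueError(f"band {band} outside (0, Nyquist={nyq:g}) Hz")
    sos = sp_signal.butter(order, [low / nyq, high / nyq], btype="bandpass", output="sos")
    return sp_signal.sosfiltfilt(sos, data, axis=1)


def instantaneous_phase(
    ts: ParcellatedTimeseries,
    band: tuple[float, float] | None = None,
    filter_order: int = 2,
) -> np.ndarray:
    """Instantaneous phase of each region's signal, radians in (-pi, pi].

    Each row is mean-centered (mandatory: the phase of a signal with a
    DC offset is ill-defined), optionally Butterworth band-pass filtered
    when ``band=(low_hz, high_hz)`` is given, then converted to its
    analytic signal by the Hilbert transform; the phase is the argument
    of the analytic signal.
    """
    data = ts.data - ts.data.mean(axis=1, keepdims=True)
    _check_variance(data, ts.region_names)  # zero after centering = constant
    if band is not None:
        data = _bandpass(data, ts.tr_seconds, band, filter_order)
    analytic = sp_signal.hilbert(data, axis=1)
    return np.angle(analytic)


def phase_coherence_dfc(
    ts: ParcellatedTimeseries,
    band: tuple[float, float] | None = None,
    filter_order: int = 2,
) -> DFCStack:
    """Time-resolved phase-coherence dFC: cos of pairwise phase differences.

    Symmetry and the unit diagonal hold by construction; each slice has
    rank <= 2 (cosine difference identity).
    """
    theta = instantaneous_phase(ts, band=band, filter_order=filter_order)
    c, s = np.cos(theta), np.sin(theta)
    # cos(a-b) = cos a cos b + sin a sin b, per timepoint
    tensor = np.einsum("nt,pt->npt", c, c) + np.einsum("nt,pt->npt", s, s)
    np.clip(tensor, -1.0, 1.0, out=tensor)
    return DFCStack(tensor=tensor, phases=theta)
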