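"""Synthetic inputs with the statistical structure the pipeline assumes.

Two generators:

* ``gen_weighted_sbm`` draws a dense signed weighted graph with planted
  block structure (independent normal edge weights per block pair) --
  the generative counterpart of the weighted stochastic block model.
* ``gen_oscillator_timeseries`` builds phase-coupled oscillatory
  timeseries: every region oscillates at a common frequency around a
  community-shared random phase offset, with per-region phase jitter
  whose spread interpolates from zero (perfect coupling) to about
  uniform (no coupling).  An optional switching regime re-draws the
  community offsets every ``switch_period`` samples, emulating
  large-scale dynamic reconfiguration of the connectome; switching
  lowers temporal stability in a controllable way.

``gen_cohort`` assembles two groups of subjects (with sampled age/sex
covariates) from per-group oscillator templates; it is a pure function
of its spec, with per-subject seeds derived deterministically from the
master seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

from .io import CovariateTable, ParcellatedTimeseries
from .wsbm import Partition

# lag-one autocorrelation of the phase-jitter AR(1) process (~10 s
# correlation time at TR = 2 s)
_JITTER_RHO = 0.8

__all__ = [
    "BlockGraphSpec",
    "OscillatorSpec",
    "CohortSpec",
    "gen_weighted_sbm",
    "gen_oscillator_timeseries",
    "gen_cohort",
]


@dataclass
class BlockGraphSpec:
    """Planted-partition weighted graph: normal edge weights per block."""

    n_nodes: int
    community_sizes: list[int]
    block_means: np.ndarray  # K x K signed means
    block_sds: np.ndarray  # K x K nonnegative sds
    seed: int = 0

    def __post_init__(self) -> None:
        self.block_means = np.asarray(self.block_means, dtype=float)
        self.block_sds = np.asarray(self.block_sds, dtype=float)
        k = len(self.community_sizes)
        if k < 2:
            raise ValueError("need at least 2 communities")
        if sum(self.community_sizes) != self.n_nodes:
            raise ValueError(
                f"community sizes sum to {sum(self.community_sizes)}, "
                f"not n_nodes={self.n_nodes}"
            )
        for name, m in (("block_means", self.block_means), ("block_sds", self.block_sds)):
            if m.shape != (k, k):
                raise ValueError(f"{name} must be {k}x{k}")
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
        if (self.block_sds < 0).any():
            raise ValueError("block_sds must be nonnegative")


def gen_weighted_sbm(spec: BlockGraphSpec) -> tuple[np.ndarray, Partition]:
    """Draw a symmetric zero-diagonal signed weight matrix with planted blocks.

    Each edge (i, j), i < j, is an independent normal draw with mean and
    sd given by the block pair of the endpoints; the matrix is
    symmetrized and the ground-truth partition returned alongside.
    """
    rng = np.random.default_rng(spec.seed)
    z = np.repeat(np.arange(len(spec.community_sizes)), spec.community_sizes)
    mean = spec.block_means[np.ix_(z, z)]
    sd = spec.block_sds[np.ix_(z, z)]
    n = spec.n_nodes
    draw = rng.normal(mean, sd)
    iu = np.triu_indices(n, k=1)
    A = np.zeros((n, n))
    A[iu] = draw[iu]
    A = A + A.T
    return A, Partition(labels=z + 1, K=len(spec.community_sizes))


@dataclass
class OscillatorSpec:
    """Phase-coupled oscillator cohort member.

    Defaults emulate a resting-state acquisition at desk scale: 48
    regions in 4 equal communities, 150 samples at TR = 2 s, a 0.05 Hz
    carrier (the slow resting-state band), strong but imperfect
    within-community coupling, and mild measurement noise.
    """

    n_regions: int = 48
    n_timepoints: int = 150
    tr_seconds: float = 2.0
    community_assignment: list[int] | None = None  # default: 4 equal blocks
    coupling_strength: float = 0.9
    noise_sd: float = 0.1
    switch_period: int | None = None
    oscillation_freq_hz: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2 or self.n_timepoints < 4:
            raise ValueError("need n_regions >= 2 and n_timepoints >= 4")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.tr_seconds <= 0 or self.oscillation_freq_hz <= 0:
            raise ValueError("tr_seconds and oscillation_freq_hz must be positive")
        if self.switch_period is not None and not (
            2 <= self.switch_period <= self.n_timepoints
        ):
            raise ValueError("switch_period must lie in [2, n_timepoints]")
        if self.community_assignment is None:
            k = 4 if self.n_regions >= 8 else 2
            self.community_assignment = list(
                np.arange(self.n_regions) * k // self.n_regions
            )
        if len(self.community_assignment) != self.n_regions:
            raise ValueError("community_assignment length must equal n_regions")


def gen_oscillator_timeseries(
    spec: OscillatorSpec,
) -> tuple[ParcellatedTimeseries, dict[str, Any]]:
    """Simulate one subject's parcellated oscillatory timeseries.

    Region i in community c produces

        x_i(t) = cos(2 pi f t TR + theta_c(t) + eps_i(t)) + noise

    where ``theta_c`` is a community-shared uniform random offset
    (re-drawn every ``switch_period`` samples when switching is on) and
    ``eps_i(t)`` is per-region phase jitter: a stationary AR(1) process
    with marginal sd ``(1 - coupling_strength) * pi`` and lag-one
    correlation 0.8, so phase wander is smooth on the timescale of a
    few samples (BOLD-like) rather than white in time -- temporal
    reconfiguration is controlled by ``switch_period``, not by the
    jitter.  With coupling 1 and zero noise all regions of a community
    carry identical signals.

    Returns the timeseries and a provenance dict recording the spec and
    the number of regime changes.
    """
    rng = np.random.default_rng(spec.seed)
    n, T = spec.n_regions, spec.n_timepoints
    comm = np.asarray(spec.community_assignment)
    communities = np.unique(comm)
    t_sec = np.arange(T) * spec.tr_seconds
    base = 2.0 * math.pi * spec.oscillation_freq_hz * t_sec  # shape (T,)

    sp = spec.switch_period
    if sp is None:
        boundaries = [0, T]
    else:
        boundaries = list(range(0, T, sp))
        if boundaries[-1] != T:
            boundaries.append(T)
        # drop a zero-length trailing segment when sp divides T
        boundaries = sorted(set(boundaries))
    n_regime_changes = len(boundaries) - 2 if len(boundaries) > 2 else 0

    theta_c = np.empty((communities.size, T))
    for seg_start, seg_end in zip(boundaries[:-1], boundaries[1:]):
        offs = rng.uniform(-math.pi, math.pi, size=communities.size)
        theta_c[:, seg_start:seg_end] = offs[:, None]

    jitter_sd = (1.0 - spec.coupling_strength) * math.pi
    if jitter_sd > 0:
        # stationary AR(1): eps_t = rho * eps_{t-1} + sqrt(1-rho^2) * sd * eta
        rho = _JITTER_RHO
        innov = rng.normal(0.0, jitter_sd, size=(n, T))
        eps = np.empty((n, T))
        eps[:, 0] = innov[:, 0]
        scale = math.sqrt(1.0 - rho**2)
        for t in range(1, T):
            eps[:, t] = rho * eps[:, t - 1] + scale * innov[:, t]
    else:
        eps = np.zeros((n, T))
    comm_idx = np.searchsorted(communities, comm)
    phase = base[None, :] + theta_c[comm_idx] + eps
    data = np.cos(phase)
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=(n, T))

    width = len(str(n - 1))
    ts = ParcellatedTimeseries(
        subject_id=f"sim{spec.seed}",
        data=data,
        region_names=[f"R{i:0{width}d}" for i in range(n)],
        network_labels=[f"NET{c}" for c in comm],
        tr_seconds=spec.tr_seconds,
    )
    provenance = {
        "n_regions": n,
        "n_timepoints": T,
        "tr_seconds": spec.tr_seconds,
        "coupling_strength": spec.coupling_strength,
        "noise_sd": spec.noise_sd,
        "switch_period": sp,
        "n_regime_changes": n_regime_changes,
        "oscillation_freq_hz": spec.oscillation_freq_hz,
        "seed": spec.seed,
    }
    return ts, provenance


@dataclass
class CohortSpec:
    """Two-group cohort assembled from oscillator templates.

    Group sizes may differ (clinical cohorts usually do).  Ages are
    sampled uniformly over ``age_range`` and sex as Bernoulli
    ``p_female``; per-subject seeds derive from ``master_seed`` so the
    cohort is a pure function of the spec.
    """

    group_a_spec: OscillatorSpec
    group_b_spec: OscillatorSpec
    n_per_group: int = 20
    n_group_b: int | None = None  # defaults to n_per_group
    group_names: tuple[str, str] = ("A", "B")
    age_range: tuple[float, float] = (20.0, 50.0)
    p_female: float = 0.5
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_group_b is not None and self.n_group_b < 2:
            raise ValueError("n_group_b must be >= 2")
        if not 0.0 <= self.p_female <= 1.0:
            raise ValueError("p_female must lie in [0, 1]")


def _subject_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def gen_cohort(
    spec: CohortSpec,
) -> tuple[list[ParcellatedTimeseries], CovariateTable]:
    """Generate both groups plus a covariate table (group, age, sex)."""
    n_a = spec.n_per_group
    n_b = spec.n_group_b if spec.n_group_b is not None else spec.n_per_group
    cov_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.master_seed, spawn_key=(10**6,))
    )
    subjects: list[ParcellatedTimeseries] = []
    rows = []
    idx = 0
    for gname, gspec, gn in (
        (spec.group_names[0], spec.group_a_spec, n_a),
        (spec.group_names[1], spec.group_b_spec, n_b),
    ):
        for j in range(gn):
            sid = f"{gname}{j:03d}"
            sub_spec = replace(gspec, seed=_subject_seed(spec.master_seed, idx))
            ts, _ = gen_oscillator_timeseries(sub_spec)
            ts.subject_id = sid
            subjects.append(ts)
            rows.append(
                {
                    "subject_id": sid,
                    "group": gname,
                    "age": float(cov_rng.uniform(*spec.age_range)),
                    "sex": "F" if cov_rng.random() < spec.p_female else "M",
                }
            )
            idx += 1
    covariates = CovariateTable(pd.DataFrame(rows), group_levels=spec.group_names)
    return subjects, covariates
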