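"""Community interaction motifs, diversity, and regional assortativity.

Given a signed weighted adjacency ``A`` (zero diagonal) and a hard
partition into K communities, every unordered community pair (r, s) is
characterized by three densities

    w_rr = sum_{i in r, j in r} A_ij / (N_r * N_r)
    w_ss = sum_{i in s, j in s} A_ij / (N_s * N_s)
    w_rs = sum_{i in r, j in s} A_ij / (N_r * N_s)

(the within-community denominator is N_r^2; with a zero diagonal this
is a uniform rescaling relative to counting only off-diagonal pairs,
which is available as a flag) and classified as

* assortative       if min(w_rr, w_ss) > w_rs
* core-periphery    if w_rr > w_rs > w_ss (core = r) or the mirror image
* disassortative    if w_rs > max(w_rr, w_ss)

Ties (any equality) fall through the rules in that order and, if no
strict rule fires, the pair is labelled degenerate and excluded from
frequency profiles.  Singleton communities are excluded throughout.

Per community, the frequencies P_a / P_c / P_p / P_d of the classes it
participates in (a core-periphery pair contributes "core" to its denser
side, "periphery" to the other) give the diversity index

    H_r = -(P_a log P_a + P_c log P_c + P_p log P_p)

(natural log; the disassortative frequency is tallied but excluded by
default).  H_r is 0 when the community participates in one class only
and maximal, log 3, when it splits equally across all three.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .wsbm import Partition

__all__ = [
    "CommunityDensityMatrix",
    "MotifClassification",
    "CommunityMotifProfile",
    "RegionalScores",
    "MorphospacePoints",
    "community_densities",
    "classify_motif",
    "community_motif_profile",
    "subject_motif_summary",
    "regional_assortativity",
    "morphospace",
]

ASSORTATIVE = "assortative"
CORE_PERIPHERY = "core-periphery"
DISASSORTATIVE = "disassortative"
DEGENERATE = "degenerate"


@dataclass
class CommunityDensityMatrix:
    """K x K matrix of within/between community densities."""

    omega: np.ndarray
    community_sizes: np.ndarray

    @property
    def K(self) -> int:
        return self.omega.shape[0]

    def retained(self) -> np.ndarray:
        """1-based indices of non-singleton, non-empty communities."""
        return np.flatnonzero(self.community_sizes >= 2) + 1


@dataclass
class MotifClassification:
    """Class of one unordered community pair (1-based community ids)."""

    r: int
    s: int
    motif_class: str
    core_side: int | None = None  # r or s, defined iff core-periphery

    def __post_init__(self) -> None:
        if (self.motif_class == CORE_PERIPHERY) != (self.core_side is not None):
            raise ValueError("core_side is defined iff class is core-periphery")


@dataclass
class CommunityMotifProfile:
    """Motif-class participation frequencies of one community."""

    community: int
    p_assortative: float
    p_core: float
    p_periphery: float
    p_disassortative: float
    diversity: float
    n_pairs: int


@dataclass
class RegionalScores:
    """Per-region densities to each community plus the assortativity score.

    ``assr_reg[i] = a[i, z_i] - max_{r != z_i} a[i, r]`` over retained
    communities; NaN for regions whose own community is a singleton.
    """

    densities: np.ndarray  # N x K, a_ir; NaN for excluded communities
    assr_reg: np.ndarray  # N
    labels: np.ndarray  # 1-based community per region


@dataclass
class MorphospacePoints:
    """One (w_rr, w_rs, w_ss) triple per retained community pair.

    Coordinates are ordered so the first within-density is the larger
    one; ``classes`` carries each pair's motif label for coloring.
    """

    coords: np.ndarray  # P x 3 as (w_rr, w_rs, w_ss), w_rr >= w_ss
    pairs: list[tuple[int, int]]
    classes: list[str]


def _validate(A: np.ndarray, part: Partition) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if A.shape[0] != part.n_nodes:
        raise ValueError("adjacency size does not match partition")
    if np.abs(np.diag(A)).max(initial=0.0) > 0:
        raise ValueError("adjacency diagonal must be zero")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    return A


def community_densities(
    A: np.ndarray, part: Partition, offdiag_denominator: bool = False
) -> CommunityDensityMatrix:
    """Within- and between-community mean edge weights.

    ``offdiag_denominator=True`` divides within-densities by
    N_r (N_r - 1) instead of N_r^2 (sensitivity variant).
    """
    A = _validate(A, part)
    K = part.K
    sizes = part.community_sizes()
    if sizes.sum() == 0:
        raise ValueError("empty partition")
    # indicator matrix M (N x K); block sums = M^T A M
    M = np.zeros((part.n_nodes, K))
    M[np.arange(part.n_nodes), part.indices] = 1.0
    block_sum = M.T @ A @ M
    denom = np.outer(sizes, sizes).astype(float)
    if offdiag_denominator:
        d = np.diag_indices(K)
        denom[d] = sizes * np.maximum(sizes - 1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        omega = np.where(denom > 0, block_sum / denom, 0.0)
    return CommunityDensityMatrix(omega=omega, community_sizes=sizes)


def classify_motif(
    w_rr: float, w_ss: float, w_rs: float
) -> tuple[str, str | None]:
    """Classify one community pair from its density triple.

    Returns ``(class, core_side)`` where ``core_side`` is ``"r"`` or
    ``"s"`` for core-periphery pairs and None otherwise.  Rules are
    strict inequalities tried in the order assortative, core-periphery,
    disassortative; a triple that satisfies none (only possible with
    equalities) is degenerate.
    """
    for v in (w_rr, w_ss, w_rs):
        if not math.isfinite(v):
            raise ValueError("densities must be finite")
    if min(w_rr, w_ss) > w_rs:
        return ASSORTATIVE, None
    if w_rr > w_rs > w_ss:
        return CORE_PERIPHERY, "r"
    if w_ss > w_rs > w_rr:
        return CORE_PERIPHERY, "s"
    if w_rs > max(w_rr, w_ss):
        return DISASSORTATIVE, None
    return DEGENERATE, None


def classify_pairs(
    dens: CommunityDensityMatrix,
) -> list[MotifClassification]:
    """Classify every unordered pair of retained communities."""
    out: list[MotifClassification] = []
    retained = dens.retained()
    for a_idx in range(len(retained)):
        for b_idx in range(a_idx + 1, len(retained)):
            r, s = int(retained[a_idx]), int(retained[b_idx])
            w_rr = dens.omega[r - 1, r - 1]
            w_ss = dens.omega[s - 1, s - 1]
            w_rs = dens.omega[r - 1, s - 1]
            cls, side = classify_motif(w_rr, w_ss, w_rs)
            core = {"r": r, "s": s}.get(side)
            out.append(MotifClassification(r=r, s=s, motif_class=cls, core_side=core))
    return out


def _entropy(freqs: list[float], log_base: float = math.e) -> float:
    h = -sum(p * math.log(p) for p in freqs if p > 0)
    return h / math.log(log_base) + 0.0  # normalize -0.0


def community_motif_profile(
    A: np.ndarray,
    part: Partition,
    log_base: float = math.e,
    include_disassortative: bool = False,
    offdiag_denominator: bool = False,
) -> tuple[list[CommunityMotifProfile], float]:
    """Motif-class frequencies and diversity index per retained community.

    Returns the per-community profiles and the mean diversity across
    retained communities.  ``include_disassortative=True`` adds the P_d
    term to the entropy (the default follows the three-term definition).
    """
    dens = community_densities(A, part, offdiag_denominator=offdiag_denominator)
    retained = dens.retained()
    if len(retained) < 2:
        raise ValueError("need at least 2 non-singleton communities")
    pairs = classify_pairs(dens)
    profiles: list[CommunityMotifProfile] = []
    any_classified = False
    for r in retained:
        counts = {ASSORTATIVE: 0, "core": 0, "periphery": 0, DISASSORTATIVE: 0}
        n_pairs = 0
        for pc in pairs:
            if r not in (pc.r, pc.s) or pc.motif_class == DEGENERATE:
                continue
            n_pairs += 1
            if pc.motif_class == ASSORTATIVE:
                counts[ASSORTATIVE] += 1
            elif pc.motif_class == DISASSORTATIVE:
                counts[DISASSORTATIVE] += 1
            else:
                counts["core" if pc.core_side == r else "periphery"] += 1
        if n_pairs == 0:
            continue
        any_classified = True
        p_a = counts[ASSORTATIVE] / n_pairs
        p_c = counts["core"] / n_pairs
        p_p = counts["periphery"] / n_pairs
        p_d = counts[DISASSORTATIVE] / n_pairs
        terms = [p_a, p_c, p_p] + ([p_d] if include_disassortative else [])
        profiles.append(
            CommunityMotifProfile(
                community=int(r),
                p_assortative=p_a,
                p_core=p_c,
                p_periphery=p_p,
                p_disassortative=p_d,
                diversity=_entropy(terms, log_base=log_base),
                n_pairs=n_pairs,
            )
        )
    if not any_classified:
        raise ValueError("all community pairs are degenerate")
    mean_div = float(np.mean([p.diversity for p in profiles]))
    return profiles, mean_div


def subject_motif_summary(
    A: np.ndarray, part: Partition, **kwargs
) -> dict[str, float]:
    """Subject-level assortativity / coreness / peripheryness.

    Each is the mean, across retained communities, of that community's
    class-participation frequency.
    """
    profiles, mean_div = community_motif_profile(A, part, **kwargs)
    return {
        "assortativity": float(np.mean([p.p_assortative for p in profiles])),
        "coreness": float(np.mean([p.p_core for p in profiles])),
        "peripheryness": float(np.mean([p.p_periphery for p in profiles])),
        "mean_diversity": mean_div,
    }


def regional_assortativity(A: np.ndarray, part: Partition) -> RegionalScores:
    """Per-region community densities a_ir and assortativity score.

    ``a_ir`` is the mean weight from region i to the members of
    community r (``(1/n_r) sum_{j in r} A_ij``; the self term
    contributes 0 via the zero diagonal).  Scores are computed over
    retained (non-singleton) communities only; a region whose own
    community is a singleton gets NaN.
    """
    A = _validate(A, part)
    sizes = part.community_sizes()
    retained_mask = sizes >= 2
    if retained_mask.sum() < 2:
        raise ValueError("need at least 2 non-singleton communities")
    N, K = part.n_nodes, part.K
    M = np.zeros((N, K))
    M[np.arange(N), part.indices] = 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = (A @ M) / np.where(sizes > 0, sizes, 1)
    dens[:, ~retained_mask] = np.nan
    z = part.indices
    own = dens[np.arange(N), z]
    other = dens.copy()
    other[np.arange(N), z] = -np.inf
    other[:, ~retained_mask] = -np.inf
    best_other = np.nanmax(np.where(np.isneginf(other), -np.inf, other), axis=1)
    assr = own - best_other
    assr[~retained_mask[z]] = np.nan
    return RegionalScores(densities=dens, assr_reg=assr, labels=part.labels.copy())


def morphospace(A: np.ndarray, part: Partition, **kwargs) -> MorphospacePoints:
    """Density triples for every retained community pair.

    Coordinates (w_rr, w_rs, w_ss) are ordered so that w_rr >= w_ss;
    each point keeps its motif class for plotting.
    """
    dens = community_densities(A, part, **kwargs)
    pairs = classify_pairs(dens)
    coords = []
    pair_ids = []
    classes = []
    for pc in pairs:
        w_rr = dens.omega[pc.r - 1, pc.r - 1]
        w_ss = dens.omega[pc.s - 1, pc.s - 1]
        w_rs = dens.omega[pc.r - 1, pc.s - 1]
        if w_rr >= w_ss:
            coords.append((w_rr, w_rs, w_ss))
            pair_ids.append((pc.r, pc.s))
        else:
            coords.append((w_ss, w_rs, w_rr))
            pair_ids.append((pc.s, pc.r))
        classes.append(pc.motif_class)
    return MorphospacePoints(
        coords=np.array(coords).reshape(-1, 3), pairs=pair_ids, classes=classes
    )
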