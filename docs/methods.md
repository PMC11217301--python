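# Methods

`fclandscape` characterizes a parcellated functional connectome along two
complementary branches: the **temporal stability** of dynamic functional
connectivity (dFC), and the **mesoscale community architecture** of static
functional connectivity (sFC). This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish.

## Dynamic branch: phase coherence and the temporal landscape

**Phase-coherence dFC.** Each region's signal is mean-centered (mandatory —
the phase of a signal with a DC offset is ill-defined) and converted to its
analytic signal with the Hilbert transform; θ(n, t) is the argument of the
analytic signal, reported in (−π, π]. The dFC at time t is
`dFC(n, p, t) = cos(θ(n,t) − θ(p,t))`. By the cosine difference identity
each N×N slice is `c cᵀ + s sᵀ` with `c = cos θ(·,t)`, `s = sin θ(·,t)`:
symmetric, unit diagonal, entries in [−1, 1], and **rank ≤ 2 exactly**.
This rank bound is the load-bearing structural fact of the branch and is
asserted throughout the test suite.

No band-pass filter is applied before the Hilbert transform by default; an
optional Butterworth band-pass (`band=(low, high)` Hz, order configurable,
0.01–0.1 Hz suggested) is available because much of the phase-coherence
literature filters into the slow resting-state band. The default is to not
silently add a preprocessing step.

**Dominant subspaces and principal angles.** At each timepoint the dominant
subspace D_t is spanned by the leading eigenvectors of the slice. The
default subspace dimension is k = 2, which captures the slice exactly
(rank ≤ 2); k = 1 (leading eigenvector only) is available. Requesting k
beyond the numerical rank (relative tolerance 1e-8) is an error rather than
silently padding. Eigenvector sign is fixed deterministically (first
nonzero component positive).

Dissimilarity between timepoints is the principal angle between D_tx and
D_ty: arccos of the singular values of the cross-Gram matrix, clipped to
[0, 1]. For k > 1 there are k angles; the default reports the **largest**
(the most conservative subspace discrepancy, and the convention that
preserves the full [0, π/2] range), with "smallest" and "mean" selectable.
The T×T matrix of these angles is the temporal landscape: symmetric, zero
diagonal, entries in [0, π/2].

**Summaries.**

- *Entropy E* (bits): landscape entries are mapped linearly from the fixed
  range [0, π/2] to [0, 1] (fixed rather than per-subject min–max, so
  values are comparable across subjects), binned into 256 uniform bins —
  mirroring 8-bit image-histogram practice — over all T² entries including
  the zero diagonal; `E = −Σ p log₂ p` over occupied bins. Temporal
  stability is `TS = 1/E`. Bin count and diagonal inclusion are exposed as
  parameters for sensitivity analyses.
- *Global temporal distance* (radians): the mean of the landscape's
  superdiagonal, `(1/(T−1)) Σ φ(t_i, t_{i+1})` — the successive-timepoint
  reading; averaging every off-diagonal entry is available as a variant
  flag. Its inverse is global temporal stability `TS_global`.
- Degenerate inputs (a perfectly static connectome) legitimately give
  E = 0 or distance 0; the inverses are then reported as an `"inf"`
  sentinel in JSON rather than raising.

Per-network summaries restrict the dFC tensor to a network's member
regions and re-run the same machinery (a principal submatrix of a rank-≤2
slice is still rank ≤ 2). Network labels are opaque strings from the
metadata sidecar; the package imposes no naming scheme.

## Static branch: WSBM communities and interaction motifs

**sFC.** Pearson correlation between region timeseries, Fisher r-to-z
transformed, correlations clipped to 1 − 1e-12 in magnitude so duplicated
rows give a large finite weight; diagonal fixed at 0. The result is the
signed weighted adjacency A used for community detection.

**Weighted stochastic block model.** Nodes carry latent labels
z_i ∈ {1..K} with Dirichlet(1) mixing prior; each unordered pair
contributes `A_ij ~ Normal(μ_{z_i z_j}, 1/τ_{z_i z_j})` with conjugate
Normal–Gamma priors (mean 0, pseudo-count 1, shape 1, rate 1 — weakly
informative for Fisher-z weights; all configurable). The likelihood is
weight-only: an FC graph is complete, so an edge-presence component would
carry no information. The normal family matches signed real-valued
weights.

Inference is mean-field coordinate-ascent variational Bayes: node
responsibilities updated sequentially, then the Dirichlet and Normal–Gamma
posteriors in closed form. Every update is an exact coordinate
maximization, so the ELBO is non-decreasing within a restart; the fitter
raises if it ever observes a decrease beyond 1e-9 relative slack (this is
an internal consistency check, not a tolerance to tune). A restart stops
when the relative ELBO improvement drops below 1e-6 (configurable) or at
500 iterations. Defaults are K = 7 and 30 restarts — the convention for
whole-cortex functional parcellations — with the best-ELBO restart
returned.

*Initialization.* From near-uniform responsibilities the symmetric fixed
point collapses all nodes into one community: the Normal–Gamma
parameter-uncertainty penalty (−1/(2κ) per pair) favours populated blocks,
making the one-block solution a strong attractor that plain annealing does
not escape. Each restart therefore seeds hard labels with k-means++ on the
rows of A — rows are exactly the weight profiles whose stochastic
equivalence the model captures — with an independent random seed per
restart. Uniform-random responsibility initialization is retained as
`init="random"` for comparison. MAP labels are the row-wise argmax of the
responsibilities (ties to the smallest index). Empty communities after
fitting are tracked, not forbidden.

**Community densities and motifs.** For communities r, s the densities are
block mean weights; the within-community denominator is N_r² (including
diagonal positions — with a zero diagonal this rescales within-densities
uniformly by (N_r−1)/N_r relative to counting only off-diagonal pairs,
which is available behind a flag). Each unordered pair is classified by
strict inequalities, tried in order:

- assortative: min(ω_rr, ω_ss) > ω_rs
- core–periphery: ω_rr > ω_rs > ω_ss (core = r) or the mirror image
- disassortative: ω_rs > max(ω_rr, ω_ss)

Ties fall through to the next rule; a triple satisfying none (possible only
with exact equalities, measure-zero for real FC data but required to be
deterministic) is labelled degenerate and excluded from frequency
profiles. The core side of a core–periphery pair is the community with the
larger within-density.

**Diversity and summaries.** Per retained (non-singleton) community the
class-participation frequencies P_a, P_c, P_p, P_d are tallied over its
non-degenerate pairs; the diversity index is the natural-log entropy over
the {a, c, p} terms (P_d recorded but excluded by default; a flag includes
it, and the log base is configurable). H_r ∈ [0, ln 3]: zero for a
single-class community, maximal for an equal three-way split. Subject-level
assortativity / coreness / peripheryness are the means of P_a / P_c / P_p
across retained communities. Regional assortativity is
`a_{i,z_i} − max_{r≠z_i} a_{ir}` with `a_{ir}` the mean weight from region
i to community r (denominator n_r, self term contributing 0); regions in
singleton communities get NaN. Singleton means size exactly 1. The
morphospace records one (ω_rr, ω_rs, ω_ss) triple per retained pair,
ordered so the first within-density is the larger.

## Group statistics

Both samples are screened with the Jarque–Bera and D'Agostino–Pearson
omnibus tests; the parametric path (pooled-variance unpaired t-test) is
taken only if **both** tests pass on **both** samples at α = 0.05 (the
combination rule is configurable to "either"). Otherwise the Wilcoxon
rank-sum test is used, computed as the Mann–Whitney U with tie-corrected
normal approximation and no continuity correction (so identical samples
give p = 1 exactly). Samples below n = 8 cannot be screened and take the
nonparametric path with a warning; data with zero pooled variance return
p = 1 directly. Calibration of the full gate+test protocol is verified in
the test suite: type-I error within [0.03, 0.07] at nominal 0.05 over
2000 null simulations.

Region-wise comparisons residualize the pooled sample on intercept + age +
sex indicators by OLS (collinear or constant columns dropped with a
warning), apply the t-test per region, and append Benjamini–Hochberg
q-values across regions. Matched-control designs are approximated by this
covariate residualization; an explicit matching algorithm is out of scope.

## Synthetic data: what it emulates, and what it does not

`gen_weighted_sbm` draws independent normal edge weights per block pair —
the exact generative inverse of the fitted model, used for recovery and
parameter-recovery loops.

`gen_oscillator_timeseries` emulates slow coupled oscillations:
region i in community c produces
`cos(2π f t·TR + θ_c(t) + ε_i(t)) + measurement noise`, with a
community-shared offset θ_c ~ U(−π, π] re-drawn every `switch_period`
samples (piecewise-constant regimes; `floor((T−1)/switch_period)` regime
changes), and per-region phase jitter ε_i. The jitter has marginal sd
`(1 − coupling_strength)·π`, so coupling interpolates linearly between
identical phases (1) and near-uniform phases (0), and is a stationary
AR(1) process with lag-one correlation 0.8 (≈10 s correlation time at
TR = 2 s): phase wander is smooth like the signals it stands in for, and
the rate of large-scale reconfiguration is controlled by `switch_period`
alone rather than leaking in through white-in-time jitter.

Defaults (chosen once as the package's study conditions): 48 regions in 4
equal communities, T = 150 samples at TR = 2 s, carrier 0.05 Hz (the slow
resting-state band), coupling 0.9, measurement noise sd 0.1, cohorts of 20
subjects per group with ages uniform on [20, 50] and balanced sex. These
sizes keep every end-to-end check tractable on one CPU; the dimensions of
a full cortical parcellation (N = 400) change nothing structural, only
runtime.

Deliberately *not* modelled: hemodynamic convolution, physiological and
motion noise, scanner drift, spatial autocorrelation of parcels, or any
relationship between the oscillator communities and the block structure of
sFC beyond shared phase. Consequently, passing the regime-discrimination
tests shows the pipeline detects controlled reconfiguration differences in
clean oscillatory data — it does not certify sensitivity at clinical
effect sizes in real fMRI.

Cohort generation is a pure function of its spec: per-subject seeds derive
from the master seed via `SeedSequence(master_seed, spawn_key=(index,))`.

## Known limitations

- The WSBM's K is fixed by the user; model-evidence selection of K and
  degree-corrected variants are out of scope.
- Motif profiles are undefined when every pair is degenerate (raised as an
  error) and exclude singleton communities entirely; partitions with fewer
  than two retained communities cannot be scored.
- The entropy summary depends on bin count (default 256); comparisons are
  only meaningful at a fixed binning.
- The rank-sum path reports the Mann–Whitney U statistic (an equivalent
  reparameterization of the rank-sum W).
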