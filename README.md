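# fclandscape

Temporal-stability landscapes and community interaction motifs for
functional connectomes.

Resting-state functional connectivity is usually summarized as one static
correlation matrix, but the connectome reconfigures continuously during a
scan, and both *how its communities are organized* and *how stable its
dynamics are* carry information that a static summary discards. This
package implements both characterizations as a tested, reusable pipeline
for parcellated BOLD-like timeseries (regions × timepoints matrices with a
region/network metadata sidecar), aimed at researchers studying
mesoscale network organization and its dynamics in health and disease.

## What it computes

**Dynamic branch — temporal stability.** Instantaneous phases θ(n, t) come
from the Hilbert transform of each region's mean-centered signal, and the
time-resolved connectivity is phase coherence

    dFC(n, p, t) = cos(θ(n, t) − θ(p, t)),

an exactly rank-≤2 symmetric matrix at every timepoint. The dominant
subspace D_t (top-k eigenvectors, k = 2 by default) summarizes each
timepoint, and the principal angle φ(t_x, t_y) ∈ [0, π/2] between
subspaces fills a T×T *temporal landscape*. Two summaries follow:

- entropy E = −Σ p log₂ p of the landscape's 256-bin histogram, with
  temporal stability TS = 1/E;
- global temporal distance = (1/(T−1)) Σᵢ φ(tᵢ, tᵢ₊₁), the mean angle
  between successive timepoints, with TS_global its inverse.

**Static branch — community architecture.** Static FC (Fisher-z Pearson
correlations, zero diagonal) is fitted with a weighted stochastic block
model — normal edge weights per community pair, conjugate Normal–Gamma
priors, mean-field variational Bayes with multi-restart selection
(K = 7, 30 restarts by default). Community pairs (r, s) are classified
from their densities ω_rr, ω_ss, ω_rs into assortative, core–periphery,
or disassortative motifs; per-community class frequencies give the
diversity index H_r = −(P_a ln P_a + P_c ln P_c + P_p ln P_p), and
per-region scores give the regional assortativity
Assr_reg = a_{i,z_i} − max_{r≠z_i} a_{ir}. A density morphospace
(one (ω_rr, ω_rs, ω_ss) point per pair) visualizes the motif repertoire.

**Group analysis.** Normality-gated comparisons (Jarque–Bera +
D'Agostino–Pearson screens choosing between pooled t-test and Wilcoxon
rank-sum), OLS residualization of age and sex, and Benjamini–Hochberg
q-values for region-wise reports.

**Synthetic cohorts.** A first-class generator produces planted-block
weighted graphs and phase-coupled oscillator timeseries whose
within-community coupling and state-switching rate are controllable, so
the entire pipeline — including group statistics — runs end to end
without any scanner data. See `docs/methods.md` for the generative model
and its limits.

## Worked example

```python
import numpy as np
import fclandscape as fl

# --- temporal branch: does state switching lower temporal stability? ---
static, _ = fl.gen_oscillator_timeseries(fl.OscillatorSpec(seed=7))
switching, _ = fl.gen_oscillator_timeseries(
    fl.OscillatorSpec(seed=7, switch_period=20))
for name, ts in [("static coupling ", static), ("switching (20 TR)", switching)]:
    s = fl.stability_summary(fl.phase_coherence_dfc(ts))
    print(f"{name}: entropy={s.entropy:.3f} bits  "
          f"gtd={s.global_temporal_distance:.3f} rad  TS_global={s.ts_global:.3f}")

# --- static branch: recover a planted 3-community structure ---
spec = fl.BlockGraphSpec(n_nodes=60, community_sizes=[20, 20, 20],
                         block_means=np.where(np.eye(3), 1.0, 0.0),
                         block_sds=np.full((3, 3), 0.3), seed=5)
A, truth = fl.gen_weighted_sbm(spec)
model = fl.fit_wsbm(A, K=3, restarts=10, seed=1)
part = fl.map_partition(model)
print("ELBO:", round(model.elbo, 1), "sizes:", list(part.community_sizes()))
print(fl.subject_motif_summary(A, part))
```

prints

```
static coupling : entropy=5.718 bits  gtd=0.229 rad  TS_global=4.366
switching (20 TR): entropy=7.358 bits  gtd=0.373 rad  TS_global=2.680
ELBO: -534.0 sizes: [20, 20, 20]
{'assortativity': 1.0, 'coreness': 0.0, 'peripheryness': 0.0, 'mean_diversity': 0.0}
```

The subject whose community coupling re-randomizes every 20 samples has a
visibly rougher temporal landscape — higher entropy, larger mean angle
between successive timepoints, lower global temporal stability — while
the block-model fit recovers the planted communities exactly and
classifies every community pair as assortative (diversity 0).

The same stages are available from the shell:

```bash
fclandscape simulate --out data --n-regions 48 --seed 3
fclandscape stability --in data/sim3_timeseries.tsv --meta data/sim3_regions.tsv \
    --subspace-dim 2 --out results
fclandscape wsbm --adjacency adj.tsv --k 7 --restarts 30 --seed 11 --out results
fclandscape pipeline --out demo --n-per-group 10 --seed 1
```

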