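# Methods

This note documents the models, conventions and design choices behind
`longconn`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Connectome representation

A connectome is a square symmetric nonnegative matrix of streamline counts
over an ordered parcel list at one parcellation scale (1–5). The diagonal
is stored as zero: self-connections carry no information for any
implemented metric, and discarding them is the standard convention for
streamline connectomes. On read, relative Frobenius asymmetry up to 1e-6 is
repaired by averaging (floating-point artifacts from upstream tooling);
anything larger is rejected as wrong data rather than silently symmetrized.

The parcellation contract fixes the subcortical anatomy of the Lausanne
2018 scheme — seven thalamic subregions and three hippocampal parcels per
hemisphere, four brainstem parcels — and maps every cortical parcel to one
of ten (hemisphere, lobe) combinations. The five-lobe taxonomy per
hemisphere (frontal, temporal, parietal, occipital, insular-cingulate) is a
configurable default: atlases disagree on whether insula and cingulate are
separate lobes, so the taxonomy is data, not code.

## Graph metrics

All metrics are weighted; a config switch to binary variants exists but is
not the default, because "degree" here means total streamline weight.

* **Strength / mean degree** — row sums of `W` and their mean.
* **Transitivity** — Onnela's geometric-mean formulation: weights are
  scaled by the network maximum, triangle intensity is
  `(w_ij w_jk w_ki)^{1/3}` summed over ordered triplets, divided by
  `Σ_i k_i(k_i − 1)` with `k_i` the binary degree. The max-scaling keeps
  the value in [0, 1] and makes it invariant to uniform weight scaling.
* **Modularity** — Louvain at resolution γ (default 1) with an explicit
  seed; communities are relabelled by smallest member so the partition is a
  pure function of (matrix, γ, seed). Q is Newman's weighted modularity of
  that partition, evaluated by the package's own formula (networkx supplies
  only the Louvain search). The participation coefficient uses this same
  partition — the measure is only interpretable relative to a stated
  community structure.
* **Efficiency** — shortest paths on edge lengths `1/w` (the standard
  mapping for streamline counts, where more streamlines mean a "shorter"
  connection), averaged as `1/d` over ordered pairs `n(n−1)`; unreachable
  pairs contribute 0. Local efficiency of node *i* is the global efficiency
  of the subgraph induced by its neighbours, 0 for fewer than two
  neighbours.
* **Eigenvector centrality** — principal eigenvector of `W` (dense
  symmetric eigensolver), oriented nonnegative, unit Euclidean norm. For
  disconnected graphs this is the Perron vector of the dominant component;
  an all-zero graph is an error.

## Network controllability

Dynamics are discrete-time linear, `x(t+1) = A x(t) + B u(t)`, with
`A = W / (1 + λ_max(W))` — the dominant normalization in the
structural-connectome control literature, giving spectral radius < 1 with
no additional stabilization offset. Inputs are single nodes, `B = e_i`.

* **Average controllability** is `trace(W_i)` of the infinite-horizon
  Gramian `W_i = Σ_t A^t e_i e_i' (A')^t`, the solution of the discrete
  Lyapunov equation `W_i = A W_i A' + e_i e_i'`. For symmetric `A` the
  trace reduces exactly to `[(I − A²)⁻¹]_ii`, computed here with one dense
  solve; tests verify agreement with `scipy`'s general Lyapunov solver and
  with 500-term series summation. Every value is ≥ 1 (the t = 0 identity
  term), with equality only for isolated nodes.
* **Modal controllability** is `φ_i = Σ_j (1 − λ_j²) v_ij²` over the
  eigenpairs of `A` — the discrete-time (eigenvalue-squared) form,
  consistent with the normalization above. Values lie in (0, 1]; weakly
  connected nodes approach 1.

The continuous- vs discrete-time choice and the exact normalization are
convention, not consequence; both are recorded here and in the run
manifest so results are attributable to a stated scheme.

## Normative modelling

One Gaussian identity-link GLM (ordinary least squares) per feature, design
`[1, age, sex]`, fitted on controls only. No age² term by default (a
config flag adds it) and no age × sex interaction: with cohorts of a few
dozen controls, the minimal model is the defensible one. Nodal and
thalamic models are fitted independently per (parcel, metric) with no
spatial shrinkage, mirroring per-node Z-score designs in the epilepsy
normative-mapping literature.

Z-scores standardize the residual by the control residual mean and SD
(n−1 denominator), so re-scoring the training controls gives sample mean 0
and SD 1 exactly. The abnormal-node burden counts Z strictly outside ±2;
ties at exactly ±2.0 are measure-zero and excluded for determinism.
Patients younger than the youngest control are extrapolated with a logged
warning rather than refused — exclusion is handled explicitly by the
sensitivity analysis (`exclude_age_below`), not implicitly by the model.

Global metrics are compared between scans as raw residuals; nodal and
thalamic features as Z-scores. Both carry the same information per feature
(Z is an affine transform of the residual); the split follows the
different downstream uses — distribution comparison for globals, threshold
counting for nodes.

## Thalamocortical profiling

For each hemisphere, the streamline weights between that hemisphere's
seven thalamic parcels and its own cortical parcels of each lobe are
summed — ten (hemisphere, lobe) sums per scan. Contralateral
thalamocortical edges never contribute. The per-lobe sums are Z-scored
against control normative models; the per-patient change is
`Δz = z_late − z_early`.

The affected-lobe statistic standardizes the ten Δz values within the
patient (subtract their mean, divide by their n−1 SD, affected lobe
included in both) and takes the affected lobe's standardized value; the
cohort of these "z-of-z" values is tested against 0 with a two-sided
one-sample t-test. One value per patient enters, from the clinically
recorded affected hemisphere and lobe.

## Longitudinal statistics

* **Paired Wilcoxon signed-rank**, two-sided; zero differences dropped
  before ranking (Wilcoxon's original treatment); exact null distribution
  for ≤ 25 nonzero differences without ties in |difference|, otherwise the
  normal approximation with continuity correction. At least 5 nonzero
  differences are required; comparisons that fall below this (common for
  integer burden counts) are reported with P = NaN rather than a fabricated
  value.
* **Cohen's d** for paired data: mean difference over the n−1 SD of the
  differences. The average-of-timepoint-SDs denominator is available as a
  flag, since the literature is inconsistent about paired-d denominators.
* **Multiple comparisons**: a fixed threshold P < 0.01 (no FDR), emitted
  alongside raw p-values so readers can apply their own policy.
* **Subgroups**: Kruskal–Wallis on the per-patient changes grouped by
  histopathology and by seizure freedom; groups with fewer than two
  members are dropped with a warning.
* **Sensitivity sweep**: the full analysis repeated across parcellation
  scales, reported as −log₁₀ P per (scale, metric), with optional exclusion
  of patients whose early-scan age falls below a threshold (for cohorts
  whose youngest patients have no age-matched controls).

Burden comparisons run on all three counts per nodal metric — total,
Z > +2 and Z < −2 — because a null total can hide opposite-signed tail
shifts.

## Synthetic cohort generator

The generator exists so every stage is testable end to end without
clinical data. It emulates the statistical structure the analysis assumes,
not the biology of tractography.

**Template.** One deterministic weighted stochastic-block template per
scale: cortical parcels cluster by (hemisphere, lobe); thalamic,
hippocampal/deep and brainstem blocks are separate communities; weights
are inflated within communities, elevated between homologous lobes and on
ipsilateral thalamocortical edges, and carry fixed lognormal edge
heterogeneity plus a block-dependent sparsity mask. This makes modularity,
participation and eigenvector centrality non-degenerate.

**Subject scans.** Scans modulate the template multiplicatively on the log
scale: a linear age effect (β_age = 0.015/yr around age 12), a sex offset
(β_sex = 0.05), a stable subject trait (σ_subject = 0.08) shared by a
patient's two scans, per-scan test–retest variability (σ_scan = 0.04), and
symmetric edge noise (σ_edge = 0.5). Lognormal factors keep weights
nonnegative while inducing approximately linear metric–age relations that
the Gaussian GLM recovers; the trait/scan split makes repeat scans of one
subject much more similar than scans of different subjects, which is what
gives the paired design its power. Test–retest variability of a few
percent against a between-subject spread of ~9% on the log-weight scale is
in the range reported for repeat streamline-count connectomes.

**Study conditions.** Defaults mirror the emulated study: 57 controls
(ages 6–18), 23 patient pairs (early-scan ages 3–16, so a handful of
patients fall below the control age range), inter-scan interval lognormal
with median 1.15 years and log-SD 0.671 (matching an IQR of roughly
0.78–1.93 years). Cortical parcel counts per lobe (2/3/5/8/12 per
hemisphere for scales 1–5) are deliberately smaller than real atlas
scales; the subcortical counts (7 thalamic, 3 hippocampal per hemisphere,
4 brainstem) are exact. Subject attributes are drawn from subject-keyed
random substreams so the same subject is identical across scales and a
single integer seed fully determines the cohort.

**Injected effects.** Effects are specified in units of the
between-subject control SD on the log-weight scale
(σ_ref = √(σ_subject² + σ_scan²) ≈ 0.089): `global_strength` multiplies
the late-scan matrix by exp(m·σ_ref); `nodal_strength_subset` and
`thalamocortical_lobe` apply the factor to the selected edges;
`thalamic_modal` divides the selected hemisphere's thalamic edges by it
(weaker connectivity raises modal controllability);
`participation_structure` shrinks within-community edges of the selected
parcels (raising their participation coefficient). The SD-unit calibration
is exact for scale-dependent features and approximate for ratio-type
features; directional recovery is what the tests assert for the latter.

**What passing tests do not show.** The generator has no distance-
dependent connectivity, no tractography biases (gyral bias, bottleneck
counting), no scanner or motion effects, and its age effect is a smooth
multiplicative trend. Calibration and power results on synthetic cohorts
therefore validate the machinery — estimators, Z-scoring, test logic,
determinism — not the biological effect sizes one would see in real data.

## Numerical and reproducibility choices

* Louvain seed, analysis seed and generator seed are explicit everywhere;
  two runs with the same seed and config produce byte-identical TSVs
  (checked in the acceptance suite).
* Eigen-decompositions use dense symmetric solvers; spectral radius ≥ 1 in
  the controllability routines raises rather than returning divergent
  sums.
* Degenerate inputs fail loudly with named subjects/features: all-zero
  networks, constant features in controls, single-sex designs, zero-spread
  z-of-z vectors, fewer than five usable pairs.
* Verification problem sizes: oracle agreement uses ≥ 100 random graphs of
  ≤ 8 nodes (where exhaustive enumeration is exact); calibration uses 200
  controls + 100 pseudo-patients; power and false-positive simulations use
  100 replicates of the 57 + 23 design at scale 1, the package's chosen
  balance between replicate count and per-replicate cost.
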