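# Methods

## The model

The pipeline integrates two imaging modalities on a shared voxel grid:

* **Resting-state fMRI** gives, per participant, a whole-cortex functional
  connectivity matrix — the Fisher z-transform `z = arctanh(r)` of the
  Pearson correlation between every pair of atlas node time series — and a
  striatal-voxel × cortical-node connectivity matrix computed the same way.
* **¹⁸F-DOPA PET** gives a voxelwise parametric map of K<sub>i</sub><sup>cer</sup>
  (1/min), the influx rate constant from reference-region Patlak analysis
  with the cerebellum as reference, an index of dopamine synthesis capacity.

Cortical nodes are grouped into resting-state networks by Louvain modularity
maximization on the connectivity matrix (negative z edges zeroed first — the
standard convention for signed matrices, which keeps the configuration null
model of modularity valid). Detected communities are named by
maximum-overlap Hungarian matching to reference network labels (DMN, SMN,
CON, DAT, AUD, VIS), and the visual network is excluded downstream because
of its sparse direct striatal projections.

For each network *k*, each striatal voxel *v* receives a weight

    w_vk = max(z̄_vk, 0) / Σ_k' max(z̄_vk', 0)

where z̄ is the voxel's mean Fisher-z connectivity to the network's nodes.
This clip-then-normalize construction yields per-voxel weights in [0, 1]
summing to 1 wherever any positive connectivity exists — a probabilistic
(soft) parcellation rather than winner-takes-all, reflecting the heavy
overlap of parallel corticostriatal projections. Network-specific
K<sub>i</sub><sup>cer</sup> is the weight-weighted mean of the voxelwise map:

    Ki_k = Σ_v w_vk · Ki_v / Σ_v w_vk

a convex combination, hence always bounded by the in-mask extremes.

## Inference machinery

**Participant-level permutation.** Ki rows are shuffled against symptom rows
(Marder five-factor scores) jointly across all subdivisions — one subject
permutation per iteration — so each null iteration preserves the
subdivision × subdivision Ki correlation structure exactly. P-values use
the add-one rule `p = (1 + #{|r_null| ≥ |r_obs|}) / (1 + P)`, which is
valid under exchangeability and never zero; two-sided by default (sidedness
configurable, since the direction of dopamine-symptom associations is an
empirical question). FDR (Benjamini–Hochberg) is applied across the full
subdivision × factor family (25 tests in the standard 5 × 5 configuration),
separately per permutation scheme.

**Cortical-node permutation.** Node-to-network labels are permuted
(preserving the observed network sizes, identically across subjects within
an iteration) and the entire weight-map → network-Ki pipeline is recomputed
per iteration by re-grouping cached voxel × node connectivity columns — no
time series are touched. Because every null parcellation still tiles the
same striatum with per-voxel-normalized weights, the weight-sum-weighted
mean Ki over all networks equals the plain striatal mean in every
iteration: the null retains any global whole-striatum Ki-symptom
relationship, so small p-values indicate *topographic specificity*.

A caveat the simulations make explicit: exact uniformity of the
node-permutation p-value under a purely global association is an
exchangeability property. It holds when the data carry no corticostriatal
topography (the observed grouping is then statistically equivalent to a
random regrouping). When genuine topography exists, the observed,
data-aligned grouping produces more concentrated weight maps than random
regroupings, and the null distribution of the statistic is mildly
mis-calibrated in the tails. The specificity experiment therefore plants the
global effect in a structureless-coupling world, and the topographic power
experiment covers the structured alternative.

**Pairwise correlation-difference tests** use |r_a − r_b| with the null
taken from the same joint participant permutations (preserving the a–b
dependence) and a one-sided add-one p.

**Group spatial-topography tests** compare patients and controls per network
on (a) the mean of the clipped (pre-normalization) connectivity values —
normalized weights would make the contrast vacuous since every voxel's
weights sum to 1 by construction — and (b) a gradient score Σ_v w_v·ramp(v)
with a linear 0→1 ramp across the mask bounding box along each voxel axis
(x, y, z), constant along the others; a one-voxel-thick axis gets a
constant 0.5 ramp with a warning. Note that the gradient score scales with
total weight, so a group difference in overall weighting shows up on every
axis; a pure spatial shift at matched mass is what the x-axis contrast
isolates. Both quantities feed pooled-variance independent-samples t tests
(df = n₁ + n₂ − 2).

**Reliability** is the single-measure consistency intraclass correlation
ICC(3,1) = (BMS − EMS)/(BMS + (k−1)·EMS) from the two-way ANOVA of a
complete subject × session matrix (random subjects, fixed sessions), with
parcel values taken as voxel averages. Consistency means a constant session
offset does not lower the ICC.

**Orthogonality comparison** between parcellation methods uses a
Dunn–Clark-type z for two dependent correlations sharing no variable (the
same subjects underlie both correlations but the four Ki variables are
distinct), with the covariance term evaluated at the back-transformed mean
of the two correlations (Silver/Hittner modification) and a two-sided
normal p. Monte-Carlo calibration under equal-correlation multivariate
normal nulls shows type-I error ≈ 0.05 at n = 50.

**Patlak estimation** regresses target(T)/ref(T) on ∫₀ᵀref/ref(T) by OLS
over frames with T ≥ t\* (trapezoidal integration assuming zero activity at
t = 0); the slope is K<sub>i</sub> (1/min). Default t\* = 20 min, the
conventional choice for DOPA tracers, exposed in configuration. Wavelet
denoising and motion correction are out of scope; inputs are assumed
preprocessed and PET/MRI pre-aligned on one grid (checked by shape and
affine agreement within 1e-4 mm).

## The synthetic cohort generator

Because no real scans ship with the package, `striaparc.synth` generates
coupled cohorts with planted ground truth:

* **Cortex**: block-factor BOLD. Node i in network k follows
  √a·f_k + √(1−a)·ε with unit-variance factors, giving within-network
  correlation `a` (default 0.6) and between-network correlation `b`
  (default 0) via a global component shared by the factors (requires
  b ≤ a; positive semidefiniteness is guaranteed by construction, no
  Cholesky needed, and the scheme scales to hundreds of nodes trivially).
* **Striatum**: voxels are mixtures of the network factors plus noise
  (sd 0.5 in factor units), with loadings one-hot (disjoint topographies,
  laid out as slabs along the x axis of the striatal box), soft (overlap
  κ to a neighbouring network), or uniform (no topography — the
  exchangeable null world). Cortex and striatum share one 4-D grid with a
  separate striatal mask, mirroring a single functional run covering both.
* **Ki maps**: Ki_sv = baseline + global_s + Σ_k loading_vk(effect_k + u_sk)
  + ε_v. Defaults: baseline 1.28e-2 1/min (a typical whole-striatum value),
  between-subject network-specific sd 1.5e-3, global sd 1e-3, voxel noise sd
  2e-3, between-session variability 8e-4. With these variances the emergent
  test-retest ICC sits near 0.75–0.85 and connectivity-subdivision Ki
  correlations near 0.3–0.6 — the ranges reported for real cohorts.
* **Symptoms**: five Marder factors (positive, negative, disorganization,
  excitement, depression/anxiety); one designated factor carries a planted
  correlation (default 0.49 between DMN Ki and the negative factor, the
  headline association) via ρ·z(target) + √(1−ρ²)·noise; the rest are
  independent standard normals.
* **Dynamic PET**: target TACs built as Ki·∫ref + V·ref so the Patlak slope
  equals the planted Ki exactly, with optional Gaussian noise.

Default cohort size is 29 patients and 21 controls with 255 timepoints
(an 8.5-minute run at TR 2 s) and 333 cortical nodes in 5 networks.

What the generator does **not** emulate: hemodynamic response shapes,
physiological noise spectra, scanner artefacts, motion, spatial
autocorrelation of BOLD or Ki noise, and registration error. Passing tests
therefore demonstrate the correctness and calibration of the computational
machinery under the stated generative model, not robustness to real-data
artefacts.

## Numerical choices

* Correlations are clipped at |r| ≤ 1 − 1e-12 before arctanh; zero-variance
  series give r = 0 with a logged warning rather than an error, so masked-out
  regions cannot abort a cohort run.
* Louvain runs `n_runs` restarts (default 100; simulation studies use 3–10,
  ample for the block structures tested) with per-run seeds derived from one
  seed; the best-Q partition wins, ties broken by lexicographically smallest
  canonical membership vector, so results are fully deterministic.
* Thresholded display maps keep ⌈f·n⌉ voxels (default f = 0.35), ties at the
  cut broken by voxel index.
* The top-level seed drives every random stream (cohort generation, Louvain
  restarts, both permutation schemes); two runs with the same config produce
  byte-identical output tables.
* BH-FDR adjusted p-values dominate the input and preserve ranks; the
  step-up adjustment is not idempotent as a map on arbitrary vectors (only
  flat vectors are exact fixpoints), which the tests encode precisely.

## Problem sizes in the validation studies

Community recovery uses the full 333-node configuration over 10 seeds.
Permutation-calibration studies use reduced cohorts (50 nodes, 60 voxels,
150 timepoints, n = 29, 500–1,000 permutations, 100–1,000 replicate
datasets) — chosen so each study completes in well under a minute on one
core while keeping Monte-Carlo error far below the decision margins. The
end-to-end headline run uses 60 nodes, 90 voxels, 255 timepoints and the
full 29 + 21 cohort.

## Known limitations

* Results depend on upstream fMRI denoising, which is assumed done; no
  temporal filtering, global-signal regression or scrubbing is applied.
* The community partition depends on the algorithm and resolution γ
  (default 1.0, exposed); the package reproduces the procedure, not any
  specific empirical partition.
* Node permutations preserve observed community sizes (a relabelling);
  whether to redraw sizes instead is a design choice the literature leaves
  open.
* The node-permutation null is exactly calibrated only in the exchangeable
  (no-topography) regime; see above.
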