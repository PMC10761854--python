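# Methods

`rovnet` re-implements, as a tested pipeline, an individual-variability
analysis of a task-fMRI network: where does a cohort vary most — in task
activity and in grey-matter anatomy — and do the functional couplings
among those highly variable regions predict behavior? This note records
the models, the numerical choices, and what the synthetic validation does
and does not establish.

## Variance mapping

For each voxel, the between-individuals variance of a task contrast and
the within-individuals variance implied by the first-level residuals are

S_B² = [ (1/(NSubj−1)) Σᵢ (conᵢ − mean(con))² ] / 2 × NScan
S_W² = meanᵢ(ResMSᵢ) / (NScan − 1)
F    = S_B² / S_W²

with `conᵢ` the subject's contrast image, `ResMSᵢ` the residual
mean-square image and NScan the first-level scan count. The `/2 × NScan`
scaling is applied literally as the source analysis prints it; it has no
stated derivation, so `between_subject_variance(..., halve_scale=False)`
drops it for sensitivity analyses. Voxels with S_W² = 0 have no defined
ratio and are set to NaN, never +∞, so downstream thresholding stays
well-behaved. The grey-matter analogue is the voxelwise across-subject
sample SD (ddof = 1 throughout the package).

The subject stack is centred by the first subject's map before computing
the variance — algebraically exact, and it guarantees that an identical
cohort yields exactly zero rather than float dust, which matters because
the change-point thresholding treats "all values equal" as "no threshold
exists".

Group masking uses a second-level one-sample t-test with voxelwise
Bonferroni FWE over in-analysis voxels and a ≥ 10-voxel cluster-extent
filter under 26-connectivity. Bonferroni replaces random-field theory
deliberately: it is deterministic, assumption-free and conservative; masks
are therefore somewhat smaller than an RFT-based implementation would
give.

## Change-point thresholding and ROV extraction

Map values are sorted ascending and split at the single index minimising
the summed within-segment squared error (piecewise-constant mean, one
change point, exhaustive O(n) search via prefix sums; ties take the first
index). The threshold is the first value of the upper segment and
survival is `value ≥ threshold`, so the detected segment survives its own
threshold. Clusters of survivors (26-connected, ≥ 10 voxels) are ranked
by peak value; each peak seeds a 10-mm spherical region of variance (ROV)
containing every voxel whose centre lies within the radius. A packaged
coordinate table (`rovnet.atlas`) carries the 13 published ROV peaks — 6
functional, 7 structural, with the left angular gyrus appearing in both
sets at distinct peaks — so networks can be built on the published
geometry without rerunning extraction.

The single-change-point least-squares reading is the closest
deterministic interpretation of the named change-point procedure; the
source names the algorithm but not its statistic or penalty.

## Series cleaning

Resting series are cleaned before network construction; task beta-series
are only z-scored, since nuisance regression properly belongs to the
first-level model that produced the betas (`clean_task=True` overrides).
The chain, recorded as `CLEANING_ORDER`, is:

1. zero-phase Butterworth bandpass (0.009–0.08 Hz at the acquisition TR;
   0.009–0.25 Hz for task when requested; order 4, `sosfiltfilt`),
2. regression of the band-filtered confound design (24 motion parameters
   = 6 walks + lags + squares, CSF, WM, global signal, plus intercept),
3. truncation to a common length when requested,
4. per-voxel z-normalisation (sample SD).

Filtering precedes regression, and the confounds are filtered with the
same filter, so the residuals are exactly orthogonal to the filtered
confounds. The naive sequential order (regress, then filter) measurably
reintroduces confound correlation at the band edges — on synthetic leaky
series the residual–global correlation comes back at 0.1–0.5, versus
< 1e−8 with the harmonised order — which is why modular-preprocessing
practice filters signals and regressors jointly. Rank-deficient designs
are repaired by dropping dependent columns with a warning.

## Distance-correlation networks

An edge between two ROVs is the multivariate distance correlation of
their full voxel patterns: observations (trials or time points) are
points in voxel space, pairwise Euclidean distance matrices are
U-centred, and the unbiased (Székely–Rizzo) estimator gives dCov², dVar
and dCor = √(max(dCov², 0) / √(dVar_X · dVar_Y)), clipped to [0, 1], with
0 returned when a distance variance is non-positive. U-centring requires
at least 4 observations. Distances are computed through the Gram-matrix
identity (BLAS) and all K(K−1)/2 edges of a subject come from one product
of the stacked U-centred matrices; a brute-force four-loop transcription
of the estimator is kept in the test suite as the oracle (agreement to
1e−10 for T ≤ 12).

Multiple rest runs are cleaned and estimated separately and the edge
estimates averaged (`n_runs_rest`, default 2), mirroring per-run
truncation to 316 volumes in the source workflow. Averaging matters
quantitatively: one band-limited 316-volume run at TR 0.72 s has roughly
2·B·T ≈ 32 independent samples, giving a per-edge estimation SD of
≈ 0.12 — as large as the true across-subject variation — and this noise
is correlated between edges sharing a node because each node's U-centred
matrix enters all of its edges.

Edge variability compares the per-edge across-subject SD between states
with a paired t-test over the K(K−1)/2 edges (df = 77 for 13 nodes). With
the desk-scale defaults the *task* SD exceeds the rest SD — the reverse
of the empirical finding — because a 40-trial beta-series carries far
more estimation noise than two averaged 316-volume rest runs; the sign of
that comparison is a property of the simulation scale, not of the code.

## Connectome-based prediction (CPM)

Leave-one-out over subjects: per fold, every unique edge is Pearson-
correlated with the behavioral score over the training subjects, edges
with two-sided p ≤ 0.05 are split by sign into positive/negative masks,
an ordinary least-squares line is fitted to the masked edge sum (each
unordered pair counted once), and the held-out subject is predicted from
their own masked sum. Folds with an empty mask (or constant sums) predict
the training mean; a model fails outright only if every fold lacked edges
of its sign. Model validity is Pearson r between observed and predicted
scores; significance comes from re-running the *entire* LOOCV — selection
included — on permuted scores, with the add-one estimator
p = (1 + #{r_perm ≥ r_obs})/(1 + n_perm) applied to each model's own r
and failed permutations entering at −∞. Both models use the same upper
tail on their own statistic (significance of prediction performance, not
sign). The contributing network is the set of edges present in the
positive mask of every fold.

Leakage is structurally impossible — each fold's training set is built by
explicit exclusion — and the suite verifies bit-identical fold masks and
coefficients when the held-out score is perturbed.

## Behavior statistics

ROV markers are mean contrast betas (functional) or mean GM volume
(structural) over member voxels. Scores are screened with a Shapiro–Wilk
statistic (reported, not enforced) and values with |z| > 3 replaced by the
mean of the remaining values (> 20 % outliers aborts). Marker–score
association is Pearson correlation, or first-order partial correlation
given a brain-size covariate (delegated to `pingouin`), Bonferroni-
corrected over the marker × score family (the family size is explicit
because the original analysis leaves it unstated).

## The synthetic cohort

The generator emulates the study conditions at desk scale: 97 subjects,
13 ROVs, 316-volume rest runs at TR 0.72 s, a 24³ grid of 3-mm voxels
(large enough for non-overlapping 10-mm spheres on a 24-mm lattice). All
randomness descends from one integer seed through keyed sub-streams, so
cohorts are byte-identical per config and stable under cohort extension.

* **Contrast maps**: conᵢ = μ + bᵢ, bᵢ ~ N(0, σ_B(v)²). σ_B is a smooth
  field (base 0.08) times a region multiplier that is a Gaussian bump
  (scale r/2, peak ×6) at each designated high-variance sphere — peaked,
  not flat, so cluster-peak recovery is well-posed. ResMSᵢ is scaled
  chi-square with NScan−1 df and expectation σ_W², so the
  residual-averaging formula is genuinely exercised.
* **GM maps**: smooth template + N(0, σ_GM(v)²), clipped at 0, with the
  same bump geometry (base SD 0.04). The resulting SD-map change-point
  thresholds land around 0.07–0.10.
* **ROV series**: one latent series per ROV; voxel series = loading ×
  latent + noise. A subject's K×K latent correlation matrix is a trait
  shared across states and runs, drawn as a normalised Wishart sample
  centred on the population target with df chosen to give the requested
  across-subject edge SD. (Independent Gaussian jitter of SD ≈ 0.2 on a
  13-node correlation matrix is almost never positive definite, and
  repairing it by eigenvalue projection leaks a global factor into every
  edge; the Wishart construction is valid by construction.) Rest latents
  are temporally smoothed to mimic BOLD autocorrelation, and rest voxel
  series receive additive confound leakage so the cleaning stage has real
  work. Population targets are heterogeneous (U[0.1, 0.35]) with a
  strongly coupled triangle module at 0.55 over the first three nodes —
  uniform targets would concentrate all across-subject variation on a
  single global factor, which both is unrealistic and swamps edge
  selection. Behavior couples to that triangle's measured edges.
* **Behavior**: score = intercept + slope × Σ(designated edges) + noise,
  noise SD defaulting to the signal SD (SNR 1); a second uncoupled score
  and a brain-size covariate (total GM volume) are emitted alongside.
* **Edge-level networks** (`gen_edge_networks` / `cpm_power_conditions`):
  for power and calibration analyses of the prediction machinery, edges
  are drawn independently per subject around heterogeneous targets, with
  the designated edges carrying the large across-subject SD (0.19, the
  observed rest-state mean for variability-selected networks) over a
  quieter background (0.08). This isolates the CPM algorithm from the
  correlated dCor estimation noise of the full voxel pipeline.

## What the validation shows — and does not

Synthetic recovery demonstrates that the implementation is correct and
well-calibrated under the generative model: hand-checkable formula values;
exact agreement with brute-force oracles; null rejection of the
permutation test at the nominal rate; recovery of configured variance
hotspots and behavior-coupled edges. It does not establish that the
method's empirical findings generalise: the generator has no anatomy, no
hemodynamics, Gaussian noise everywhere, and its confounds are stylised
random walks and low-frequency processes. Full-pipeline CPM at SNR 1
typically attains LOOCV r ≈ 0.5 — the intrinsic cost of per-fold edge
selection under estimation noise — so prediction effect sizes on real
data should be expected well below the naive √(SNR/(1+SNR)) ceiling.

## Problem sizes and numerical conventions

Default test and acceptance runs use 97 subjects, 13 nodes, 40-trial task
series, two 316-volume rest runs; calibration/power runs use 50/20
replicates with 99 permutations. Sample statistics use ddof = 1; peak and
change-point ties break to the lowest index; all thresholds are inclusive
(≥). Degenerate inputs (all-equal maps, zero-variance voxels or edges,
empty masks) are handled by sentinel (+∞ threshold, NaN ratio, dropped
columns, training-mean folds) and logged, never silently altered.
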