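# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limitations of `axonet`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Study design the package emulates

Two groups (AN, acutely underweight; HC, healthy controls) of equal size
(default 77 per group). Per participant: serum NF-L (pg/ml), plasma leptin
(ng/ml, left-censored at the assay LOD of 0.20 ng/ml), age, BMI and a
BMI-SDS z-like score, clinical scores (drive for thinness, body
dissatisfaction, depression), a motion scalar, eTIV, 73 WM ROI volumes,
and two symmetric connectivity matrices (FA- and NOS-weighted) on a
parcellation of 233 nodes (219 cortical subdivisions of the
Desikan-Killiany scheme + 14 subcortical nuclei). The package's fixture
parcellation reproduces the node counts and label style programmatically;
it is synthetic and does not ship atlas files.

## Synthetic cohort generator

**Biomarkers.** NF-L and leptin are log-normal per group, parameterized by
the group median and IQR typical of acute-AN studies (AN NF-L median
10.80 pg/ml, IQR [7.83, 15.50]; HC 5.98 [4.73, 7.79]; AN leptin 0.58
[0.165, 1.635] ng/ml; HC 10.4 [5.895, 15.035]); σ is recovered from the
IQR via σ = (log q75 − log q25)/1.349. Log-normality is a modeling choice
consistent with the field's routine log-transformation of these markers.
Under the default AN leptin parameters the implied censoring probability
at LOD 0.20 is 0.27, close to the ≈23% censoring rate typical of acute AN
samples; censoring is applied by truncation-and-flag (the stored value is
the LOD), and imputation is an explicit downstream step, never applied at
generation or read time.

**Planted mediation.** In AN only, three standardized latents form a
linear-Gaussian chain: z_leptin → z_conn (path a, default −0.5),
z_conn → z_NFL (path b, default +0.45), plus a direct z_leptin → z_NFL
path (c′, default −0.45). The residual SD of z_NFL is chosen so its
marginal variance is exactly 1, so the planted standardized indirect
effect is a·b = −0.225 and the total is c′ + a·b = −0.675. `z_conn` is
carried on the cohort table and consumed by the connectome generator, so
the chain is realized through actual edge weights.

**Volumes.** Regional volume = baseline + slope·log NF-L (affected ROIs,
AN only by default; slope −800 mm³ per log unit) + 40·age + 0.004·eTIV +
Gaussian noise (SD 400 mm³). Hemispheric totals are sums of their 35
regional parts and the global column is the sum of the two hemispheres,
so the 73-column table satisfies the aggregation identity exactly and
planted effects propagate into the aggregates. The affected-ROI default
list matches the regions that volume studies of acute AN most often
report.

**Connectomes.** A shared support mask (density 0.30) and shared per-edge
FA baselines in [0.30, 0.60] are drawn once; participants add Gaussian
noise (SD 0.03). Planted NF-L components add `edge_effect` per
within-group SD of log NF-L (so the expected per-edge t is approximately
edge_effect/0.03·√n); mediation components add `mediation_edge_effect`
(default 0.03) per unit z_conn. FA is clipped to [0, 1] with a logged
warning if clipping touches more than 10% of draws; NOS are gamma-Poisson
(over-dispersed) counts on the same support. The default network size for
tests is 30-60 nodes; 233 is exercised in the conformance check — the
choice keeps permutation loops at desk scale while leaving the code
dimension-agnostic.

**Motion** is half-normal with a slightly larger scale in AN (0.35 vs
0.30); no published motion metric is being imitated, only a plausible
positive nuisance correlated with group.

**Randomness.** Everything flows from one seed through
`numpy.random.SeedSequence` spawning (cohort: one child per group;
pipeline: cohort/volumes/connectomes/NBS/mediation in documented order).
Identical configuration and seed give byte-identical outputs.

**What the generator does not emulate:** spatial autocorrelation of edge
weights, distance-dependent connection probability, hub structure,
site/scanner effects, non-Gaussian edge noise, missing data patterns
beyond leptin censoring, and any coupling between volumes and
connectomes. Passing recovery tests therefore demonstrates correctness of
the inference machinery under the planted model, not performance on real
connectomes.

## Edge models and the NBS

Edge-wise OLS uses the Frisch-Waugh-Lovell identity: outcome and
predictor are residualized on the covariate block (QR-based) once, after
which the t statistic for the predictor is exact OLS at a fraction of the
cost; permutations of the predictor reuse the residualized outcomes, so a
full null distribution is a handful of matrix products. The identity is
verified against statsmodels OLS to 1e-10 in the tests.

Choices that matter:

- **Component size** is edge count (extent); intensity statistics are out
  of scope.
- **Permutation scheme** is simple permutation of the predictor with
  covariates fixed (default); a Freedman-Lane option (permuting
  covariate-residualized outcomes) is available for stronger
  exchangeability under influential covariates.
- **One-sided contrasts** run separately per direction; per-direction
  nulls are used rather than a pooled two-sided null.
- **Add-one p-values** (1 + exceedances)/(1 + n_perm) avoid zero
  p-values; the smallest achievable p is 1/(n_perm + 1).
- **Degenerate edges** (constant across participants, detected by zero
  range) are dropped from the analyzed mask with a log entry; a
  zero-variance predictor yields t = 0 everywhere with a warning rather
  than an error, so permutation-degenerate inputs fail soft.
- **NOS weights** are log(1 + NOS) upstream of the edge model; the +1
  admits zero counts.
- **Ordering** of reported components is size-descending with
  lexicographic tie-break, for reproducible reports.

At the default threshold t = 3.2 the largest-component null is strongly
discrete (most null permutations have no supra-threshold edge at all), so
the empirical family-wise error rate under a global null sits well below
the nominal 5% — the permutation construction guarantees validity, not
exactness. The acceptance script measures this rate directly; at lower
thresholds (t = 2) the test suite observes near-nominal behavior.

## Volume and group-comparison models

Per-ROI OLS (volume ~ log NF-L + age + eTIV, within group) is computed by
QR — with eTIV in mm³ next to an intercept the normal equations lose
about half the available precision, and QR does not. Standardized β is
β·SD(x)/SD(y) with within-group sample SDs. FDR is Benjamini-Hochberg
step-up over exactly the 73 ROI tests (delegated to statsmodels).
Two-sided Wald p-values are the default; NF-L enters on the log scale
(raw scale available via a flag).

Group comparisons use Wilcoxon rank-sum tests with continuity correction
(the reported W is the first group's U, the R convention; effect size
r = |z|/√n with z recovered from the asymptotic p) for demographics and
clinical scores, and a Welch t-test for log NF-L (effect size
r = √(t²/(t² + df))). Default sidedness is one-sided per prior hypothesis
except age; medians/IQRs are reported on the raw scale.

## Quality control

The group edge mask keeps edges with non-zero weight in ≥ 60% of a
group. Missing fractions are computed per participant against that mask
(fail above 10%). Outlier edges are flagged against **leave-one-out**
group mean/SD at 3 SD: with include-self statistics the z-score of one
participant among n is bounded by (n−1)/√n, which would make single-edge
outliers undetectable in small groups. All three thresholds are explicit
parameters and are declared in every run manifest. (The cohort-level
biomarker outlier exclusion, by contrast, is deliberately single-pass
include-self at 3 group SDs, matching standard practice for participant
exclusion.)

## Component-level clinical models

Robust regressions use Huber M-estimation (tuning constant 1.345, MAD
scale, max 200 iterations, tolerance 1e-8; statsmodels RLM) of z-scored
mean component connectivity on the z-scored clinical predictor plus age,
WM volume and motion as nuisances; Wald p-values come from the robust
covariance, and FDR is applied across the components tested in the run —
the q-values change if the component count changes, which the tests
assert explicitly.

Sub-LOD leptin imputation defaults to the deterministic LOD/√2
substitution; a stochastic alternative draws from a log-normal fitted to
the uncensored values and truncated above at the LOD (inverse-CDF,
seeded). Missing values are never imputed.

## Mediation

Paths are fitted as a: m ~ x and (b, c′): y ~ m + x, by OLS (default) or
Huber RLM; indirect = a·b, direct = c′, total = direct + indirect by
construction (the separately refitted total from y ~ x is retained in
`total_refit` for comparison). Variables are z-scored by default so all
effects are standardized. Inference is a nonparametric case-resampling
bootstrap (default 5,000 resamples): percentile CIs for all three
effects, z-values (estimate / bootstrap SE) for direct and total, and a
two-sided sign-tail bootstrap p for the indirect effect. Mediation runs
without nuisance covariates by default (adjustment available via the
regression module).

On the full synthetic chain the *numerical* standardized path estimates
differ from the planted latent values: the mediator is the mean FA of a
component that is both NF-L-associated and leptin-driven, so measurement
noise and the selection step shift the decomposition. The tested
properties there are the sign pattern (direct, indirect, total all
negative) and HC specificity; exact path recovery (a·b = 0.20 within
±0.05) is verified on a clean linear-Gaussian generator whose variables
have unit population variance, making standardized and raw coefficients
coincide.

## Phantom tractography

Phantoms specify bundles (straight tubes with optional per-voxel FA
profiles, constant-turn arc chains, orthogonal crossings) on an integer
grid; each bundle's end caps are parcellation nodes. The FACT tracker
advances a ray to the current voxel's boundary and continues with the
next voxel's direction (no sub-voxel interpolation); 8 seeds per voxel at
the octant centers (±¼ offsets), tracked in both directions and merged.
Eigenvector sign is resolved per step by flipping the next direction to
non-negative dot product with the incoming one; the turn angle is
computed after flipping. The voxel that triggers a stop (low FA, sharp
turn, mask exit) is not added to the visited list; both half-track stop
reasons are recorded. Seeding happens in every masked voxel: a seed voxel
below the FA threshold yields a single-voxel streamline with reason
`low_fa`, which makes "FA below threshold everywhere" a well-defined
degenerate case.

Edge membership uses the pass-through rule (a streamline serves edge
(A, B) if it visits at least one voxel of each label), so a streamline
crossing more than two labels serves every pair — total NOS can exceed
the streamline count only in that case. Edge FA is the traversal-weighted
mean of voxel FA over all voxels crossed by contributing streamlines,
each crossing counted once.

In the crossing primitive the shared voxels take the first (x-axis)
bundle's direction — a deterministic stand-in for the fiber-crossing
ambiguity a single-tensor model cannot resolve; the orthogonal bundle is
interrupted there, which is the expected FACT behavior.

## Problem sizes in the checks

The calibration checks run at sizes chosen to keep a laptop-scale run
comfortable while preserving the tested property: null FWER over 200
datasets (n = 77, 30 nodes, 1,000 permutations), planted recovery over 50
seeds, mediation recovery over 100 seeds at n = 500 with 1,000-resample
bootstraps, coverage under b = 0 over 200 seeds at n = 200, HC
specificity over 20 seeds. The production defaults (10,000 permutations,
5,000 bootstrap resamples) remain the reference settings for real
analyses.

## Known limitations

- The edge-count component statistic is conservative at high primary
  thresholds (discreteness); users scanning several thresholds should use
  the sweep rather than a single point.
- Huber M-estimation protects against outlying responses, not outlying
  design points (no leverage downweighting).
- The bootstrap treats participants as exchangeable; no stratified or
  wild bootstrap is provided.
- The tracker is single-tensor and deterministic: crossing fibers,
  fanning and curvature below voxel scale are out of scope by design.
- The synthetic generator's independence assumptions (see above) make
  power estimates optimistic relative to real connectomes.
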