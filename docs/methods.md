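# Methods

## Scientific setting

Postmortem cohort studies of cognitive ageing relate dendritic-spine
morphology in cortical tissue to antemortem cognition.  The analysis this
package implements asks whether any per-case spine trait — density, length,
head diameter, volume — adds predictive value for an episodic-memory
composite beyond the standard covariates (amyloid neuritic-plaque score NP,
neurofibrillary-tangle burden NFT, sex, age), and whether the effect is
specific to the temporal cortex (a BA37-like region) as opposed to the
premotor cortex (a BA6-like region).  No human data ship with the package;
a synthetic-cohort generator reproduces the statistical structure of such a
study so every stage is testable end to end.

## Spine morphometry

A spine is a backbone polyline (µm) from the dendritic insertion point to
the distal tip, a per-point diameter profile, and a voxel count.

* Length: sum of consecutive point-to-point Euclidean distances.
* Head/neck: the neck diameter is the profile minimum strictly between
  insertion and tip; the head diameter is the profile maximum from that
  minimum outward.  How a reconstruction package internally splits head
  from neck is not published, so this minimum-split rule is our own;
  pipelines with pre-measured head/neck columns can bypass it.  Monotone
  profiles (no interior neck) fall back to the global max/min and are
  flagged `degenerate`.
* Volume: voxel count × single-voxel volume.
* Density: spines per 10 µm of dendrite, per segment.

Classification thresholds: head-to-neck ratio (HNR) 1.1, length-to-head
ratio (LHR) 2.5, mushroom head 0.35 µm, filopodium length 3.0 µm.
Rules, in order: (1) HNR > 1.1 and head > 0.35 µm → mushroom; (2) HNR < 1.1
and (LHR > 2.5 or head < 0.35 µm) → filopodia if length > 3.0 µm else thin;
(3) otherwise stubby.  The strict inequalities on both sides of 1.1 leave
boundary spines (HNR exactly 1.1; HNR > 1.1 with head ≤ 0.35 µm) unmatched:
they are routed to stubby — the only class never defined by an explicit
rule — and flagged `residual` rather than silently absorbed.  The LHR uses
the total curvilinear length, the only length the measurement set defines.

## Synthetic cohorts

Defaults mirror the study conditions: 128 cases; ages normal with mean
90.53 and SD 6.06 years; sex coded 0 = female, 1 = male with P(male) = 0.35
(brain-bank cohorts of this age skew female); 8–12 neurons per case per
region (uniform over the range — the within-range distribution is not
published), one 20–40 µm segment per neuron; Poisson spine counts at ~5
spines/10 µm; class mix 45/30/20/5% thin/stubby/mushroom/filopodia; two
regions (`BA37`, `BA6`); exactly 3 cases receive missing NP/NFT/memory
values (missing at random over those three columns).

Per-class geometry distributions are truncated normals on head diameter
and length plus a uniform head/neck ratio, chosen to sit inside each
class's rule region (e.g. mushroom head 0.55 ± 0.08 µm truncated to
(0.36, 1.20); filopodium length 3.9 ± 0.6 µm truncated above 3.05 µm).
Only the thresholds are published; the distributions are package defaults,
exposed in `DEFAULT_CLASS_PRIORS` and overridable.  Every sampled spine is
rebuilt as an explicit geometry (two-segment backbone of the exact target
length; three-point diameter profile base–neck–head) and re-measured
through the morphometry module; rejection sampling guarantees the measured
class equals the requested one.  Voxel counts follow a cylinder-plus-cap
volume approximation at 0.1 µm isotropic voxels with log-normal noise.

Between-case heterogeneity is region-specific: each (case, region) draws
its own head-diameter shift (SD 0.03 µm), length shift (SD 0.12 µm),
Dirichlet class-mix tilt (concentration 60) and log-normal density
multiplier (SD 0.15).  Region specificity is essential — a shared latent
would leak the temporal-cortex signal into premotor traits and destroy the
regional contrast the analysis is about.

Pathology: NP and NFT are truncated normals (mean 1.0, SD 0.5, floored at
0) with male means shifted down by 0.35 units, so males carry less
pathology, as in the emulated cohort.  Episodic memory is generated as

    memory = β_hd·meanHD(BA37) + β_np·NP + β_nft·NFT + β_sex·sex + ε

with defaults β_hd = 10 memory-units/µm, β_np = −0.4, β_nft = −0.3,
β_sex = +0.2, ε ~ N(0, 0.25²); meanHD is the case's *measured* pooled mean
head diameter, so the generative effect flows through the same morphometry
the analysis later applies.  A premotor-like cohort sets β_hd = 0.  The
additional scores (global cognition, perceptual speed, amyloid load) are
derived with their own noise for the correlation screen.  β_hd = 10 with a
between-case meanHD SD of ≈0.025–0.03 µm yields a marginal Spearman ρ of
≈0.5 with memory at n = 125 — a strong but realistic single-trait effect.

Randomness: one seed per cohort; each case and each (case, neuron) gets a
child `SeedSequence` keyed by stable integers, so enlarging a cohort never
perturbs earlier cases.

What the generator does **not** emulate: staining/imaging artifacts, axial
smear, within-neuron spine clustering, spatial correlation along dendrites,
item-level cognitive tests, or realistic semiquantitative (ordinal)
pathology scales.  Passing tests therefore demonstrate that the *pipeline*
recovers known generative structure, not that the biological findings
replicate on new human data.

## Feature aggregation and design

Density is computed per segment (per 10 µm) and averaged over segments —
each dendritic segment counts equally regardless of length.  Morphology
means are pooled over all spines of a (case, region) by default; a
per-neuron two-stage mean is available (`aggregation="per_neuron"`) since
the original aggregation convention is not published.  Class-specific
variants restrict to one class; a case with no spines of a class gets a
missing mean (pairwise-deleted downstream) and a zero density.

Complete-case filtering requires NP, NFT and episodic memory; at the
default size it drops exactly 3 of 128 cases.  The discovery/validation
split permutes the 125 complete cases with a seeded generator and assigns
⌈n/2⌉ = 63 to discovery, 62 to validation.  The original analysis' R
permutation stream is language-specific; membership determinism under this
package's own seed is the reproducibility contract here.

## LASSO discovery

Objective: (1/2n)·Σ(yᵢ − β₀ − xᵢβ)² + λ·‖β‖₁ with unpenalised intercept
and internally standardised predictors (coefficients reported on both
scales).  Only the four spine traits enter; covariates are reserved for
the validation stage.  The λ grid is 100 log-spaced values from
λ_max = maxⱼ|xⱼᵀ(y−ȳ)|/n down to 10⁻⁴·λ_max.  10-fold CV picks the
MSE-minimising grid value; the CV is repeated 1000 times with reshuffled
folds and the final λ is the lower median of the 1000 minimisers (lower
median documented for even counts).  A 1-SE rule is available behind
`one_se_rule=True`, off by default, since the emulated analysis minimised
CV-MSE.

The solver is cyclic coordinate descent on Gram matrices (tolerance 1e-7
on the maximum coefficient change for CV fits, 1e-11 for final fits; warm
starts from λ_max down), vectorised across all fold × repeat systems at
once; held-out MSE comes from validation cross-moments in
training-standardised coordinates.  Fold assignment happens after rows are
put in a canonical lexicographic order, which makes the selected λ exactly
invariant to input row order.  KKT conditions and ℓ1-path monotonicity are
asserted in the test suite, with sklearn's `Lasso` as an independent
cross-check oracle.

## Nested-model validation

Candidate models combine NP+NFT (always both, as the pathology block),
sex, age and spine traits; the default ladder is full, full−age,
pathology+sex+trait, pathology+sex, pathology+trait.  Each model is scored
by leave-one-out CV mean squared error, computed with the hat-matrix
identity e⁽⁻ⁱ⁾ = eᵢ/(1 − hᵢᵢ) (equality with n explicit refits is asserted
to 1e-10).  R² is 1 − SSE_pred/SST on the pooled LOOCV predictions, and
the Pearson correlation of observed vs predicted is reported alongside —
the R² convention for CV predictions is not standardised, so both are
emitted.  Singular designs are reported and skipped, not fatal.

Bootstrap MSE intervals resample whole cases with replacement (B = 1000,
level 90% by default; neither is pinned by the emulated analysis) and
rerun the complete LOOCV per replicate; percentile endpoints are returned
and singular resamples are redrawn with a logged count.  Case resampling
(rather than residual resampling) was chosen because the quantity of
interest is prediction error over the case population.

## Correlation screen

All feature × score cells on the full complete-case cohort, per region:
Spearman rho as the Pearson correlation of mid-ranks (average ranks on
ties), pairwise deletion, p from the t approximation on n−2 df, switching
to the exact permutation null below n = 10.  Storey q-values over each
region's grid: π̂₀(λ) = #{p>λ}/(m(1−λ)) on λ ∈ {0.05,…,0.95}, smoothed by a
cubic polynomial and read at λ = 0.95; lists shorter than 20 use the fixed
λ = 0.5 estimate and shorter than 4 use π₀ = 1; π̂₀ is clipped to
[1/m, 1].  With π₀ pinned to 1 the q-values equal Benjamini–Hochberg
adjusted p-values exactly (asserted against statsmodels).  Cells are
flagged at q < 0.1 and q < 0.05; the heatmap annotation convention is `*`
for q < 0.1 with p < 0.05 and `**` for q < 0.05.

## Replicate experiments and problem sizes

`recovery_experiment` reruns generation → morphometry → aggregation →
filter → split → LASSO → nested LOOCV on 100 fresh single-region cohorts
(n = 128 each).  Within the replicate loop λ selection uses 100 CV repeats
rather than 1000 — the median-λ is stable well below 1000 repeats and this
keeps the 100-replicate experiment at a few minutes on one core; the
library default remains 1000.  On temporal-like cohorts, head diameter is
the top-ranked trait in ≳90% of replicates and pathology+sex+head-diameter
beats pathology+sex in essentially all; on β_hd = 0 cohorts the LASSO
returns the all-zero model in the majority and the head-diameter model
beats pathology+sex only at chance rates.  `null_fdr_experiment` runs 200
all-null cohorts (60 cases, one region — FDR behaviour does not depend on
the cohort size, and the smaller cohorts keep the simulation near two
minutes) and records the flagged-cell fractions.

## Numerical choices and degenerate inputs

* Coordinate-descent tolerances as above; max 10⁵ sweeps.
* Constant predictor columns are dropped from the penalty path with a
  warning; their coefficients report as 0.
* Leverage-1 LOOCV folds (a row that determines its own fit) raise a
  singular-model error rather than returning infinite errors.
* Zero-length segments, non-positive diameters/voxel dimensions, invalid
  class-mix vectors and out-of-range p-values raise `ValueError`s.
* Lower median on even counts wherever a median of an even-length list is
  taken.

## Known limitations

The generator's effect sizes are point choices, not estimates from the
emulated study's (restricted) data; absolute R² and MSE values printed by
the analysis scripts characterise the synthetic conditions only.  The
morphometric head/neck split is a stand-in for an unpublished proprietary
algorithm.  Semiquantitative pathology scores are modelled as continuous.
The bootstrap interval is percentile (no BCa correction), which can
undercover slightly for skewed MSE distributions at small n.
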