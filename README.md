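# spinemem

Does the *size* of dendritic spines — rather than their number — predict
episodic memory in very old adults?  `spinemem` implements, end to end and
on fully synthetic cohorts, the analysis pipeline behind that question:
per-spine morphometry and classification, per-case trait aggregation,
LASSO discovery of memory-associated spine traits, nested linear-model
validation by leave-one-out cross-validation, and an FDR-controlled
Spearman correlation screen.  It is aimed at quantitative neuropathology
and biostatistics readers who want a tested, reproducible reference
implementation of this multistage design.

## The model

Each case contributes reconstructed dendritic spines from two cortical
regions (temporal-like `BA37`, premotor-like `BA6`).  Spines are measured
(curvilinear length, head diameter, neck diameter, voxel volume) and
classified into thin / stubby / mushroom / filopodia with the standard
thresholds (head-to-neck ratio 1.1, length-to-head ratio 2.5, mushroom
head 0.35 µm, filopodium length 3.0 µm), then aggregated per case into
density, mean length, mean head diameter and mean volume.

The statistical core, per region:

1. **Discovery** (n = 63 of the 125 complete cases): LASSO,

       min_β (1/2n)·Σᵢ(yᵢ − β₀ − xᵢβ)² + λ·Σⱼ|βⱼ|,

   on the four spine traits, λ chosen as the median CV-minimiser over
   1000 reshuffled 10-fold cross-validations of a 100-value grid.
2. **Validation** (n = 62): nested linear models for episodic memory
   (pathology NP+NFT, sex, age, spine traits) compared by LOOCV MSE via
   the hat-matrix identity e⁽⁻ⁱ⁾ = eᵢ/(1−hᵢᵢ), with percentile bootstrap
   MSE intervals from case resampling.
3. **Screen** (n = 125): Spearman correlations of every spine feature
   with cognition/pathology scores, Storey q-value FDR at 10% and 5%.

A synthetic-cohort generator (128 cases, 8–12 neurons/case/region, one
20–40 µm segment per neuron, per-spine geometries that classify back to
their intended class) provides data with known ground truth: episodic
memory is generated from pathology, sex and the temporal-region mean spine
head diameter, with no premotor effect.  See `docs/methods.md` for every
modelling choice.

## Worked example

```bash
python analysis/01_simulate_cohort.py   # generate the cohort (seed 11)
python analysis/02_aggregate_features.py
python analysis/03_lasso_discovery.py
python analysis/04_validate_models.py
python analysis/05_correlation_screen.py
```

which prints (abridged):

```
cohort: 128 cases, 3 with missing scores
  BA37: 19335 spines over 38101 um of dendrite; class mix {'thin': 0.459, ...}
128 cases -> 125 complete -> 63 discovery / 62 validation
BA37: lambda = 0.0312; head_diameter (+0.234) > density (+0.021)
BA6: lambda = 0.0667; null model (all coefficients zero)
BA37: best model = pathology_sex_head_diameter (MSE-CV 0.0699, R2 0.717, r 0.847)
    pathology_sex_head_diameter      MSE 0.0699 [0.0419, 0.0904]  R2 0.717
    ...
    pathology_sex                    MSE 0.1798 [0.1193, 0.2159]  R2 0.273
BA6: best model = pathology_sex (MSE-CV 0.1798, R2 0.273, r 0.529)
BA37: 120 cells, 45 at q<0.1, 22 at q<0.05
    head diameter vs episodic memory: rho +0.522, p 4.36e-10, q 1.83e-08 **
BA6: 120 cells, 0 at q<0.1, 0 at q<0.05
```

Reading: of 128 simulated cases, 3 are dropped for missing scores and the
125 remaining split 63/62.  In the temporal-like region the LASSO shrinks
density, length and volume (nearly) away but keeps head diameter; the
nested-model comparison confirms on held-out cases that adding head
diameter to pathology+sex cuts the LOOCV MSE by more than half, while the
premotor-like region shows a null model and no correlated cells — exactly
the generative truth (β_hd = 10 memory-units/µm in BA37, 0 in BA6).

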