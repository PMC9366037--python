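# Methods

## Scope and model

`petstrat` implements a baseline ¹⁸F-FDG PET/CT quantification and
prognostic-stratification pipeline for follicular lymphoma (FL):

1. **Quantification.** Standardized uptake value SUV = activity
   concentration / (injected dose / body weight), assuming body-weight
   normalization and tissue density 1 g/mL (Bq/mL ≡ Bq/g); decay correction
   is assumed upstream. Candidate lesions are 26-connected components of
   voxels with SUV ≥ a detection threshold (default 2.5). Each candidate is
   delineated at 41% of its *own* SUVmax (closed comparison, ≥), restricted
   to the connected piece containing the peak voxel. Per lesion:
   MTV = voxel count × voxel volume (cm³), SUVmean over the mask,
   TLG = MTV × SUVmean. Per patient: SUVmax = max over lesions,
   TMTV = Σ MTV, TLG = Σ TLG, and Dmax = the largest pairwise Euclidean
   distance between lesion SUVmax-voxel positions (cm; 0 for ≤ 1 lesion).
   Spleen involvement: focal uptake inside the spleen, or diffuse spleen
   uptake above 150% of the mean liver SUV. Bone-marrow uptake contributes
   volume only when focal.
2. **Cutpoints.** Continuous features are dichotomized by maximally
   selected log-rank statistics: scan midpoints between consecutive sorted
   unique values, keep splits leaving both groups ≥ floor(min_frac·n)
   (default min_frac 0.1), return the chi-square maximizer. The corrected
   p-value uses the Miller–Siegmund approximation for the supremum of the
   standardized log-rank process over the admissible quantile band, clamped
   to [p_uncorrected, 1].
3. **Survival analysis.** PFS in months (days/30.44, configurable) from
   diagnosis to progression/relapse/death, censored at last follow-up.
   Kaplan–Meier with Greenwood-based confidence bands (lifelines); k-group
   log-rank from counting-process sums (own implementation, needed in
   vectorized form by the cutpoint scan; cross-checked against lifelines);
   Cox partial likelihood via statsmodels PHReg with Efron tie handling by
   default and Breslow optional, Newton iterations to tolerance 1e-8, Wald
   95% CIs. Univariate screening keeps covariates with p < 0.05; the three
   metabolic burden measures (SUVmax, TMTV, TLG) enter *separate*
   multivariate models because they are near-collinear measures of the same
   burden.
4. **Stratification.** The three-factor score counts TLG > cutoff,
   Dmax > cutoff and elevated LDH (strict inequalities at cutoffs) and maps
   0–1 → low, 2 → intermediate, 3 → high risk. Comparators: FLIPI
   (age ≥ 60, stage III–IV, Hb < 12 g/dl, > 4 nodal sites, elevated LDH;
   0–1/2/≥3), FLIPI2 (age > 60, elevated β2-MG, Hb < 12, LodLIN > 6 cm,
   marrow involvement; 0/1–2/3–5), PRIMA-PI (elevated β2-MG → high, else
   marrow involvement → intermediate, else low). β2-MG is accepted either
   as a lab reference flag or as a value against a 3 mg/L threshold,
   because cohorts often record only normal/elevated.
5. **Evaluation.** Harrell's C (pairs usable when the shorter observed time
   has the event; risk ties count ½; the vectorized code reproduces the
   O(n²) definition exactly and matches scikit-survival). Model comparison
   by paired bootstrap over patients (default 2000 replicates, percentile
   CI, two-sided bootstrap p) — the comparison method is a package choice
   and is documented as such. Time-dependent AUC is the cumulative/dynamic
   IPCW estimator (cases weighted by 1/G(t⁻) with G the censoring KM);
   it agrees with scikit-survival's Uno estimator to numerical precision.
   Decision curves: net benefit = TP/n − FP/n · pt/(1−pt) with TP/FP of the
   treated subgroup estimated from its KM event probability at the horizon;
   thresholds default to 0.01…0.99 step 0.01. Calibration bins by predicted
   survival (or by the risk categories) and compares the bin-mean
   prediction with the KM-observed survival and its Greenwood band. Ordinal
   category scores are mapped 0/1/2 for C-index and ROC; for DCA and
   calibration the per-category KM event probabilities serve as predicted
   probabilities.
6. **Grade analysis.** Pearson chi-square *without* continuity correction
   when all expected counts ≥ 5, else Fisher's exact (the routing can be
   forced — the B-symptoms comparison, minimum expected count ≈ 4.3,
   reproduces its published p-value only under forced Pearson). Mann-Whitney
   U two-sided: exhaustive permutation when both samples ≤ 8 (tie safe),
   else normal approximation with tie correction. ROC: trapezoid AUC
   (= normalized rank-sum), cutoff maximizing Youden's J with ties broken
   toward higher specificity, predictive values from the confusion matrix
   at that cutoff, AUC p-value against 0.5 from the rank-sum normal
   approximation. Logistic regression by Newton ML with Wald inference;
   |β| > 15 is treated as separation.

## Synthetic data: what it emulates

**Phantoms** are uniform-uptake ellipsoids on a Gaussian-noise background
(noise truncated at zero — SUV cannot be negative), with optional liver and
spleen regions and an optional Gaussian blur for partial-volume stress
tests (off by default). Uniform uptake makes the 41% isocontour recover the
full lesion exactly, so recovery tests can demand bit-exact equality.
Ground-truth volumes are obtained by *voxel counting* of the noiseless
lesion masks, not from the analytic ellipsoid volume, for the same reason.
Ground-truth lesion positions use the same SUVmax-voxel tie-break as the
quantifier (lexicographic (z, y, x) scan order), since every voxel of a
uniform lesion ties at SUVmax; analytic centers are stored separately.
Overlapping lesions are rejected because their per-lesion truth would be
ambiguous. Phantoms deliberately omit realistic anatomy, scanner
point-spread functions and motion: exact-recovery tests validate the
measurement arithmetic, not robustness to scanner physics.

**Cohorts** draw binary adverse factors independently (optionally with a
Gaussian copula) at the marginal prevalences reported for a 126-patient FL
population (e.g. stage III–IV 0.825, elevated LDH 0.214, marrow involvement
0.484). Continuous covariates (age, Hb, platelets, nodal count, LodLIN) are
drawn conditionally on their flags so both representations agree. PET
features are log-normal with medians and log-SDs matched to published
medians and interquartile ranges (SUVmax 11.45/σ 0.31, TMTV 231.5/σ 1.26,
TLG 1112.5/σ 1.25, Dmax 67.0 cm/σ 0.48; σ from IQR = exp(2·0.6745σ)).
Event times follow a proportional-hazards model with cumulative baseline
hazard H₀(t) = (λ₀t)^k (default exponential, k = 1, λ₀ = 0.0025/month,
giving ≈ 86% 5-year PFS for a factor-free patient, consistent with the
reported low-risk stratum); the default true log hazard ratios place the
published multivariate effect sizes on the three score factors
(TLG HR 3.612, Dmax HR 2.877, LDH HR 2.287) and zero elsewhere.
Administrative censoring is uniform over (1, 102) months, matching the
reported follow-up range. The generator reproduces marginal prevalences and
a proportional-hazards structure, not real inter-feature correlation (the
source cohort reports none), so passing tests demonstrate calibration of
the estimators under the stated model, not transportability to real
cohorts.

## Numerical choices

- Axis order (x, y, z) per NIfTI; physical coordinates are voxel centers,
  0-based indices; anisotropic spacing throughout; distances in mm
  internally, Dmax reported in cm.
- Threshold comparisons closed (≥) at detection and delineation; strict (>)
  at prognostic cutoffs, mirroring the ">x vs ≤x" convention of the score.
- SUVmax ties broken by lexicographic (z, y, x) scan order; candidate
  ordering by SUVmax descending with the same tie-break.
- Connectivity fixed at 26-neighborhood.
- "Focal" organ uptake has no canonical quantitative definition; a
  component covering more than half the organ compartment (configurable)
  is treated as diffuse.
- Dmax between SUVmax voxels by default; centroid mode available (which of
  the two the original workstation used is not documented).
- Cutpoint ties in chi-square resolve to the smaller cutoff; log-rank
  variance uses the hypergeometric form with the (n−1) denominator.
- Bootstrap resamples that lose all usable pairs are redrawn.
- Published cohort cutoffs (SUVmax 17.60, TMTV 408.72 cm³, TLG 1446.98,
  Dmax 56.73 cm) are configuration presets, not re-derived: they cannot be
  recomputed without the per-patient data.

## Problem sizes used in the shipped checks

Phantom recovery runs on 60³ grids with three lesions. Statistical
calibration uses 100 simulated cohorts of n = 2000 for Cox CI coverage and
500 null cohorts of n = 126 for the cutpoint type-I rate; the
stratification comparison uses one cohort of n = 400 with 1000 paired
bootstrap replicates. These sizes give stable Monte-Carlo estimates while
keeping the whole suite fast.

## Known limitations

- Lesion detection is threshold-based; the original measurements were made
  by physicians on a clinical workstation. The manual escape hatch is an
  exclusion mask plus configurable thresholds, not a GUI.
- The X-tile software's internal algorithm is not public; maximally
  selected log-rank with the Miller–Siegmund correction is a principled
  stand-in and will not reproduce X-tile's exact numerics.
- DCA under censoring relies on KM within the treated subgroup, which is
  noisy at extreme thresholds.
- No DICOM ingestion, automatic organ segmentation, response scoring or
  overall-survival endpoints.
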