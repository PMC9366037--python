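# petstrat

Baseline ¹⁸F-FDG PET/CT quantification and prognostic stratification for
follicular lymphoma (FL).

Whole-body FDG-PET captures two complementary aspects of lymphoma: total
metabolic burden and how widely the disease is disseminated. `petstrat`
implements the full analysis chain that turns a baseline PET volume into a
risk category for progression-free survival (PFS), and the statistical
machinery to validate such a score against the established clinical indices
(FLIPI, FLIPI2, PRIMA-PI) — all exercisable on synthetic phantoms and
simulated cohorts with known ground truth.

**Imaging metrics.** Lesions are delineated at 41% of each lesion's own
SUVmax (the EANM-recommended fixed-threshold isocontour). Per patient:

- SUVmax — highest uptake over all lesions;
- TMTV = Σᵢ MTVᵢ (cm³) — total metabolic tumor volume;
- TLG = Σᵢ MTVᵢ · SUVmeanᵢ — total lesion glycolysis;
- Dmax (cm) — the largest distance between any two lesions (positions =
  lesion SUVmax voxels; 0 for a single lesion), a dissemination measure.

**Prognostic model.** Continuous features are dichotomized by maximally
selected log-rank cutpoints (Miller–Siegmund corrected); Cox
proportional-hazards models screen and adjust covariates; the three-factor
score counts TLG > cutoff, Dmax > cutoff and elevated LDH and maps 0–1 / 2 /
3 factors to low / intermediate / high risk. Model comparison uses
Harrell's C with paired-bootstrap deltas, IPCW time-dependent ROC, decision
curves and calibration against Kaplan–Meier observations.

## Worked example

```python
import petstrat as ps

# A noiseless phantom with two ellipsoidal lesions of known uptake
spec = ps.PhantomSpec(
    grid_shape=(60, 60, 60), spacing_mm=(3.0, 3.0, 2.0), background_suv=0.8,
    lesions=[ps.LesionSpec((45, 45, 30), (12, 9, 9), 9.0),
             ps.LesionSpec((120, 120, 80), (8, 8, 8), 6.0)],
    seed=0)
vol, truth = ps.gen_phantom(spec)
patient = ps.quantify(vol, detect_suv=2.5)
print(patient.suv_max_patient, patient.tmtv_cm3, patient.tlg_total,
      patient.d_max_cm)
# 9.0 6.192 48.978 12.111
```

SUVmax 9.0 is the hotter lesion's uptake; TMTV 6.192 cm³ is the sum of the
two recovered volumes (3.942 + 2.250, each exactly the ground-truth voxel
count × voxel volume); TLG 48.98 = Σ MTV·SUVmean; Dmax 12.11 cm is the
distance between the two lesions' peak voxels.

```python
# A simulated cohort with hazard carried by TLG, Dmax and LDH
cohort, _ = ps.gen_cohort(ps.CohortSpec(n=400, seed=20))
scored = ps.add_scores(cohort)          # adds score + FLIPI/FLIPI2/PRIMA-PI
print(scored["risk_category"].value_counts().to_dict())
# {'low': 245, 'intermediate': 134, 'high': 21}

t, e = scored["time_months"], scored["event"]
res = ps.compare_c(scored["risk_category_ord"], scored["prima_pi_ord"],
                   t, e, n_boot=1000, seed=5)
print(f"{res.c_a:.3f} vs {res.c_b:.3f}, delta {res.delta:.3f}, CI {res.ci}")
# 0.673 vs 0.532, delta 0.141, CI (0.076, 0.204)
```

The three-factor score concordance (0.673) exceeds PRIMA-PI's (0.532) on
this cohort — expected, since only the score's factors carry hazard in the
default generator — and the paired-bootstrap CI for the difference excludes
zero.

A thin CLI exposes the same pipeline
(`petstrat simulate|quantify|cutpoint|score|survival|evaluate|grade`), e.g.

```bash
petstrat simulate --kind cohort --n 400 --seed 20 --out cohort
petstrat score --cohort cohort.csv --out scored.csv
petstrat cutpoint --cohort cohort.csv --feature tlg
```

## Layout

| module | contents |
| --- | --- |
| `petstrat.synth` | phantoms + cohorts with ground truth |
| `petstrat.petquant` | SUV, detection, 41% delineation, organ rules, Dmax |
| `petstrat.cutpoint` | maximally selected log-rank cutoffs |
| `petstrat.survival` | PFS, Kaplan–Meier, log-rank, Cox |
| `petstrat.stratify` | three-factor score, FLIPI, FLIPI2, PRIMA-PI |
| `petstrat.evaluate` | C-index, paired bootstrap, IPCW AUC, DCA, calibration |
| `petstrat.grade` | 2×2 tests, Mann-Whitney, ROC, logistic regression |
| `petstrat.io` / `petstrat.cli` | NIfTI/CSV/JSON formats, config, CLI |

See `docs/methods.md` for the model assumptions, parameter defaults and
the design rationale.
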