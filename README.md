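# lesionkinetics

Model-based analysis of individual RECIST target-lesion time series:
quantify, lesion by lesion, how fast tumours shrink under treatment and how
fast they re-grow as resistance emerges, and decompose the variability of
those rates into between-patient and within-patient components.

Standard trial reporting collapses a patient's target lesions into the sum
of longest diameters (SLD) and then into CR/PR/SD/PD categories, discarding
the per-lesion dynamics. `lesionkinetics` keeps them. It is written for
pharmacometricians and biostatisticians who work with longitudinal imaging
data from oncology trials — or who need a faithful simulated stand-in for
such data, since the real arms are generally not redistributable.

## The model

A tumour whose proliferation is confined to a thin outer rim grows linearly
in radius (`dr/dt = a·d`, with `a = ln2/t_d` the rim growth rate and `d`
its thickness), so the imaged longest diameter of lesion *j* in patient *i*
is modelled piecewise linearly with a population switch point `sp` from
decay to re-growth:

    L_ijk = BSL_ij + d_ij·t_k + e_ijk                      t_k <  sp
    L_ijk = BSL_ij + d_ij·sp + g_ij·(t_k − sp) + e_ijk     t_k >= sp

with log-normal baselines `BSL`, normally distributed decay (`d`) and
re-growth (`g`) rates decomposed into independent patient-level and
lesion-level random effects, and Gaussian residual error `e`. The switch
point is profiled over the midpoints of consecutive on-treatment imaging
visits (days 63, 116, 179 for the standard 0/42/84/147/210-day schedule)
and chosen by marginal log-likelihood; the marginal likelihood integrates
the slope random effects exactly and the log-normal baseline effects by a
Laplace approximation, validated against adaptive Gauss–Hermite
quadrature. Variability is summarised by coefficients of variation
(SD/|mean|) per rate and level, and the association between shrinkage and
re-growth by the r² of per-lesion estimates. See `docs/methods.md` for
assumptions, defaults and limitations.

## Worked example

```python
import lesionkinetics as lk

cfg = lk.SyntheticConfig(n_patients=200, seed=1)   # vemurafenib-like arm
cohort, truth = lk.generate(cfg)
cohort = lk.filter_responders(cohort)              # keep SD/PR/CR at week 6

best_sp, profile, fits = lk.select_sp(
    cohort, lk.ModelSpec(hierarchy="patient_lesion", sp=63.0))
best = fits[best_sp]
print(f"selected switch point: day {best_sp}")
print(profile.to_string(index=False))

cv = lk.cv_table(best)
print(cv[["parameter", "level", "cv"]].to_string(index=False))

corr = lk.decay_regrowth_correlation(best)
print(f"decay-regrowth r^2 = {corr.r_squared:.3f} over {corr.n_lesions} lesions")
```

prints

```
selected switch point: day 63
 sp  log_likelihood          aic  converged
 63    -7149.532781 14317.065562       True
116    -8122.867392 16263.734785       True
179    -8771.601784 17561.203568       True
parameter           level       cv
    decay between_patient 0.227847
    decay  within_patient 0.244492
 regrowth between_patient 0.250376
 regrowth  within_patient 0.305592
decay-regrowth r^2 = 0.062 over 561 lesions
```

Read: the log-likelihood profile peaks at the true generating switch point
(day 63, between the week-6 and week-12 visits); the fitted CVs recover
the generating values (decay ≈ 0.23 at both levels, re-growth ≈ 0.30 at
the lesion level); and the decay and re-growth rates — independent by
construction in the generator — show essentially no association
(r² ≪ 0.1). A lesion's shrinkage rate tells you nothing about how fast it
will re-grow.

The same pipeline is scriptable from the shell:

```sh
lesionkinetics simulate  --out cohort.csv --truth truth.csv --seed 1
lesionkinetics summarize --input cohort.csv --day 42
lesionkinetics fit       --input cohort.csv --sp-grid auto --out fit.json
lesionkinetics report    --input cohort.csv --fit fit.json --out report/
```

To analyse real data, supply a long-format CSV with columns
`patient_id, lesion_id, day, diameter_mm` (other column names via a schema
mapping in `read_cohort`).

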