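# Methods

## The problem

In solid-tumour trials, response is imaged on a fixed schedule and reduced,
via RECIST, to per-patient categories (CR/PR/SD/PD) built from the sum of
longest diameters (SLD) of the target lesions. That reduction discards the
individual lesion time courses, which carry information about two distinct
kinetic processes: how fast a lesion shrinks under treatment, and how fast
it re-grows once a resistant phenotype takes over. `lesionkinetics`
models each target lesion's longest-diameter series directly, and asks
three questions: (1) are lesion dynamics correlated within a patient,
(2) how does between-patient variability of the kinetic rates compare with
within-patient variability, and (3) does the shrinkage rate of a lesion
predict its re-growth rate.

## Structural model

Why linear? If proliferation is confined to an outer rim of thickness
`d` (small relative to the radius `r`) whose cell population doubles every
`t_d` hours (rate `a = ln 2 / t_d`), the rim volume is `V_p = 4πr²d`, all
volume growth comes from the rim (`dV_c/dt = 0` for the necrotic core), and

    dr/dt = (dr/dV)(dV/dt) = (1/4πr²) · a·4πr²d = a·d,

i.e. the radius — and hence the imaged longest diameter — grows *linearly*
while the volume grows cubically. The same linear form is assumed for
shrinkage (clearance of dead cells, linear to first order). The regime of
validity is intermediate-size tumours: very small lesions grow nearly
exponentially and very large ones saturate; neither regime is modelled.
The `growth_law` module implements exactly this chain and the tests assert
its internal identities (cubic volume, `dV/dt = a·V_p`).

Treatment and resistance are superimposed in the simplest possible way: a
piecewise-linear course with one population switch point `sp`,

    L(t) = bsl + d·t,                    t <  sp
    L(t) = bsl + d·sp + g·(t − sp),      t >= sp

with baseline diameter `bsl` (mm), decay rate `d` (mm/day, typically
negative) and re-growth rate `g` (mm/day, typically positive). Neither
slope is sign-constrained: a minority of lesions genuinely grow under
treatment or shrink after the switch, and the model must be able to say
so. The parameterisation is continuous at `sp` (the re-growth slope acts
on time since the switch). Taken literally, the second displayed branch of
this model family can also be read with the re-growth term multiplying
absolute time, which jumps by `g·sp` at the switch; that discontinuous
variant has no biological reading here and breaks observed-vs-fitted
diagnostics, so the continuous form is the implementation and the literal
variant is kept behind `predict(..., literal_form=True)` for comparison
only. The boundary point `t = sp` belongs to the re-growth branch.

Structural predictions may go negative under strong shrinkage. Clipping at
0 mm happens only in the observation model (`observe`), never inside the
trajectory algebra, so the likelihood machinery stays linear-Gaussian in
`(bsl, d, g)` at fixed `sp`.

## Hierarchical statistical model

Two random-effect structures are fitted and compared:

* **lesion_only** — every lesion independent: `bsl_j = exp(β0 + b_j)` with
  `b_j ~ N(0, σ_b²)` (log-normal, keeping diameters positive), and
  `d_j = d̄ + δ_j`, `g_j = ḡ + γ_j` with independent normal deviations.
* **patient_lesion** — lesions nested in patients: additionally
  `d_ij = d̄ + d_i + δ_ij`, `g_ij = ḡ + g_i + γ_ij`, where the patient-level
  deviations `d_i, g_i` are shared by all lesions of patient `i`.

All random effects are mutually independent (diagonal covariance), and a
single residual SD `σ_e` is shared by all observations of one fit. The
baseline random effect is lesion-level only by default (a patient-level
baseline component is not part of the default model).

`sp` cannot be estimated freely — with 4–5 imaging visits per lesion it is
not identifiable per lesion — so it is profiled over the midpoints of
consecutive on-treatment visit days (days 63, 116, 179 for the standard
schedule 0/42/84/147/210), refitting at each candidate and keeping the
highest log-likelihood; ties break toward the earlier candidate (the
conservative clinical reading: resistance detected sooner). The two
hierarchies are compared at a common `sp` by raw maximised log-likelihood
(the richer model contains the simpler one); AIC is reported alongside but
not used for selection.

### Marginal likelihood

Conditional on the baseline effects `b`, the model is linear-Gaussian in
every slope random effect, so those integrate exactly:

    y | b ~ N( X(d̄, ḡ) + S·exp(β0 + b),  σ_e² I + Z D Z' ),

with `S` the lesion-membership indicator and `Z D Z'` the slope
random-effect covariance. The remaining integral over `b` (one dimension
per lesion) is non-Gaussian because `b` enters through an exponential; it
is evaluated by

* **Laplace approximation** (default): batched damped-Newton search for
  the per-unit posterior mode of `b`, then the usual Gaussian curvature
  correction. Because the slope-block curvature does not depend on `b`,
  this coincides exactly with the Laplace approximation at the joint mode
  of *all* random effects — the reduction changes the computation, not
  the approximation.
* **adaptive Gauss–Hermite quadrature** (oracle): tensor-product grid
  centred and scaled at the Laplace mode, for units with at most 3
  lesions. It exists to validate the Laplace backend by brute force, not
  for production fits.

Laplace accuracy degrades with the baseline SD: on 5-visit units the
discrepancy against converged quadrature is ~1e-4 at `σ_b = 0.02`, ~5e-4
at `σ_b = 0.05` and a few 1e-3 at the default generating value 0.25. That
bias is shared smoothly across candidate switch points and hierarchies, so
selection and comparison are unaffected; the recovery experiments bound
its effect on the estimates themselves.

### Estimation

Maximum likelihood (not REML — the log-likelihood comparisons change fixed
structures) via L-BFGS-B over the fixed effects and the log-parameterised
SDs (positivity by construction; bounds `exp(−12)`…`exp(3)`).
Initialisation is deterministic: per-lesion OLS on the piecewise design,
then moment estimates (between-patient SD = SD of patient means of lesion
slopes; within = SD around patient means). Convergence: relative
log-likelihood change below 1e-10, at most 500 outer iterations; the inner
Newton stops on a scale-aware Newton-decrement criterion so the Laplace
value is accurate to roughly the likelihood's own numerical precision.
Per-unit empirical-Bayes estimates are the posterior modes of `b` with
BLUPs of the slope effects at the fitted population parameters.

Two boundary situations are handled explicitly. A variance component that
collapses below `exp(−10)` is reported as "no variability required" — on
real vemurafenib-like data the re-growth rate can need no distribution at
all, and this is how the package expresses that. And when the data are
reproduced exactly by a single piecewise line (zero-variance, noise-free
input), the likelihood increases without bound as the SDs shrink, so the
optimum lies on the variance lower bound with the OLS fixed effects; this
case is detected at initialisation and returned directly instead of being
ground through the optimiser.

## Post-fit reports

* **CV table**: for decay and re-growth, between-patient CV =
  patient-level SD / |population mean| and within-patient CV =
  lesion-level SD / |population mean|. The absolute value matters because
  decay means are negative; a zero mean leaves the CV undefined and the
  entry is flagged rather than returned as infinity.
* **Decay-vs-re-growth correlation**: r² of OLS of per-lesion re-growth on
  per-lesion decay, over empirical-Bayes estimates by default. EB
  shrinkage attenuates extreme lesions and hence can deflate r²; raw
  per-lesion least-squares slopes (`estimator="ols"`) avoid the shrinkage
  at the cost of much noisier points. Sign-anomaly fractions (decay > 0,
  re-growth < 0) are reported from the same table.
* **Observed vs fitted**: per-observation EB fitted values, R² about the
  line of unity and MAE.
* **Arm summary**: baseline SLD and ILD quartiles, week-6 ORR, week-6
  %SLD-change quartiles. Percentiles use linear interpolation between
  order statistics (NumPy default, type 7) — pinned because quartile
  comparisons depend on the convention.

RECIST categorisation uses the standard target-lesion thresholds
(PR ≤ −30 %, PD ≥ +20 %, CR = disappearance of all target lesions),
overridable via `RecistThresholds`. PD is referenced to baseline, not
nadir; the inclusion filter (keep patients SD/PR/CR at the first
on-treatment visit — the analysis is about response *followed by*
resistance) only ever classifies the first on-treatment visit, where
baseline and nadir coincide.

## Synthetic cohort generator

Real arms of this kind are not redistributable, so the generator is a
first-class module producing arms with exactly the statistical structure
the model assumes: log-normal baselines; additive, independent normal
patient- and lesion-level slope deviations; one common switch point;
additive Gaussian measurement error truncated at 0 mm; the standard
imaging schedule (days 0, 42, 84, 147, 210); a 1–7 lesions-per-patient
distribution with ~80 % of patients multi-lesion; and truncation of a
patient's series after their first PD visit (imaging stops at progression;
death is not modelled).

Default parameters (all overridable via YAML config):

| parameter | default | rationale |
|---|---|---|
| `bsl_log_mean`, `bsl_log_sd` | 3.30, 0.25 | median baseline ILD ≈ 27 mm |
| `decay_mean` | −0.22 mm/day | week-6 median SLD change ≈ −33 % |
| `decay_sd_between/within` | 0.05 / 0.05 | equal levels; CV ≈ 0.23 each |
| `regrowth_mean` | 0.04 mm/day | slow resistant re-growth |
| `regrowth_sd_between/within` | 0.012 / 0.012 | CV ≈ 0.30 each |
| `sp_true` | 63 d | between week-6 and week-12 visits |
| `residual_sd` | 1.5 mm | typical CT longest-diameter reading error |

These defaults emulate a responding (vemurafenib-like) arm — week-6 median
SLD change near −33 % with an IQR inside (−47, −21) — while keeping the
fraction of measurements clipped at 0 mm below 1 % (clipping is the one
place the generator departs from the fitted model's assumptions, so the
default keeps it rare and `GroundTruth.clipped_fraction` reports it).
They are illustrative study conditions, not estimates of any published
arm's parameters: with the clipping constraint binding, the defaults
produce ~1 % sign-anomalous lesions rather than the ~4 % seen in real
arms, and the CV magnitudes are round numbers of the right order. Decay
and re-growth are independent by construction, which is precisely what the
correlation analysis is validated against.

What passing tests on this generator do **not** show about real data:
robustness to non-Gaussian reading error, reader/scanner effects,
unscheduled or missed visits, per-lesion switch points, new-lesion
appearance, or informative dropout beyond PD truncation.

## Problem sizes used in the shipped experiments

Parameter recovery and switch-point selection run 20 replicate arms of 200
patients; hierarchy detection runs 10 seeds per scenario at 200 patients;
the correlation analysis uses one 1000-patient arm; quadrature
cross-checks use 1–3-lesion units. These sizes give Monte-Carlo error
comfortably inside the asserted tolerances while keeping the full suite
fast enough to run routinely.

## Known limitations

* The Laplace bias at large `σ_b` (see above) is unquantified beyond the
  shipped cross-checks; a quadrature production path for many-lesion
  patients would need sparse grids.
* One shared residual SD per fit; no per-arm heteroscedasticity within a
  fit (fit arms separately instead).
* Standard errors are not reported; inference is by log-likelihood
  comparison and simulation, as in the analysis the package reproduces.
* The switch point is a population constant; per-lesion switch points are
  deliberately out of scope (unidentifiable at these visit densities).
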