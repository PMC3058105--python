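# Methods

## Natural history

A person's lung-cancer history is generated in continuous age (years):

1. **Pathway.** One of three histological pathways — squamous,
   adeno/large cell, small cell — drawn from a configurable mix
   (defaults 0.30 / 0.45 / 0.25).
2. **Onset.** With a per-pathway lifetime probability, a preclinical
   lesion arises at an age drawn from a Weibull distribution
   parameterized by shape and mean (scale = mean / Γ(1 + 1/shape)).
   The between-arm *risk factor* multiplies the lifetime probability
   in the intervention arm only; values that would push any effective
   probability above 1 are rejected.
3. **Progression.** Stages are strictly ordered PRE_I → PRE_II →
   CLIN_III → CLIN_IV with exponential dwell times drawn at stage
   entry. PRE_I is undetectable; PRE_II is detectable by screening
   only; CLIN_III/IV are screen-detectable until clinical surfacing.
   A tumor entering CLIN_III surfaces clinically at the end of its
   stage-III dwell with probability `p_clinical_dx_at_III`, otherwise
   it progresses and surfaces at the end of its stage-IV dwell.
   Clinical surfacing is impossible before CLIN_III.
4. **Indolence.** On entering PRE_II a tumor is indolent with
   probability `indolent_fraction` (one shared scalar — the fitted
   over-diagnosis parameter is a single quantity, so a per-pathway
   version would not be identifiable from an 8-cell count table).
   An indolent tumor stays in PRE_II forever: screen-detectable for
   life, never symptomatic.
5. **Competing mortality.** Other-cause death is drawn by sequential
   annual Bernoulli trials against a life table, with uniform
   placement inside the death year and a hard cap at the end of the
   table (default age 101), which acts as administrative censoring.
   Death is what gives over-diagnosis its meaning: an indolent,
   screen-detected lesion in a person who dies of something else is a
   diagnosis the unscreened arm never records.

One tumor per person (first onset only): the calibration currency is
person-level diagnosis counts, so multiplicity is not identifiable.

## Screening

The screened arm receives exams every 4 months for 6 years — 19 exams
including the prevalence screen at entry, `floor(duration/interval)+1`
in general. Attendance is i.i.d. per exam (default 0.75). At an
attended exam the tumor is detectable iff it occupies PRE_II (tested
with `sens_II`) or CLIN_III/IV before surfacing (`sens_III`).

**Systematic negative error.** After a tumor's first false negative,
the miss probability at later exams in the same stage group is
`min(1, (1 - sens) + syserr_group)`; the increment is persistent
(lesion-level) and by default does not compound with repeated misses
(`compound_syserr` turns compounding on). An attended exam taken while
the lesion exists but is still undetectable (PRE_I) also counts toward
the false-negative history (`pre_detectable_misses`, default on): the
screen did fail to find a cancer that was present. This choice is
load-bearing — with miss histories starting only at detectable exams,
a model that fixes sensitivity at 1 while fitting the systematic error
could never leave its null fit, because no first false negative could
ever occur; yet that configuration is exactly the one in which the
systematic-error hypothesis is calibrated. With the flag off, the
mechanism reduces to the strictly-detectable-window reading.

The control arm's usual-care advice is modeled as no effective
screening (attendance 0) by default, so every between-arm contrast is
attributable to a modeled mechanism.

Censoring: diagnoses are recorded if they occur within
`followup_years` of entry (default 12 — the trial-end horizon of the
earliest enrollees; a zero-length window records nothing, including
the prevalence screen). A tumor that had already surfaced clinically
before entry is excluded (such a person would not have been enrolled).

## Count tables and deviance

Counts live on a fixed layout: arm × detection mode × stage group
(8 cells; the clinical/II- cells are structural zeros), optionally
stratified by pathway. Observed and expected tables are scored as
independent Poisson cells, making the saturated model the observed
table itself and the deviance

    D = 2 Σ [O ln(O/E) − (O − E)],   O = 0 term ≡ E.

A cell with E = 0 but O > 0 yields an infinite deviance, reported with
a warning rather than raised. A multinomial-per-arm family is
available behind `family="multinomial"`: each arm's expected total is
conditioned to the observed total before scoring, so only the
allocation of diagnoses across cells within an arm is penalized. Nested extensions are compared by the
χ² upper tail of the deviance reduction, with df = number of newly
freed parameters; the comparison table also carries a fixed-df = 1
column because some published comparisons of this design report df = 1
even for two-parameter extensions.

## Common random numbers and fitting

The engine pre-draws every parameter-independent variate once per
seed — onset gate uniforms, onset ages, dwell times, indolence gates,
entry/death ages, attendance indicators, per-exam detection
uniforms — and evaluates any candidate parameter vector as a
deterministic transform of those arrays. Consequences: the deviance
objective is deterministic given the seed; raising a sensitivity can
only add detections (monotonicity by construction); and all six models
in a suite share every random number, so their deviances are directly
comparable. When only the risk factor and/or indolent fraction vary,
the screening pass is resolved once for both indolence branches and
each objective evaluation reduces to boolean algebra.

Fitting is bounded and derivative-free: zero-parameter models are a
single evaluation; one-parameter models use a three-stage deterministic
grid refinement (21 points per stage — robust to the small plateaus a
finite-sample objective has); multi-parameter models use Nelder–Mead
with clipped bounds and jittered restarts (default 3, budgeted
`maxfev`). Under-converged multi-parameter fits can leave a nested
model's deviance slightly above its parent's; suite invariants are
therefore asserted up to an optimizer tolerance of 0.5.

Expected tables rescale an `oversample`-times larger simulated cohort
to the nominal arm sizes (default oversample 20; the ground-truth
recovery checks use 50). The synthetic-data generator runs the same
engine at 1× and returns the realized integer counts — one stochastic
trial replicate under a fully known truth.

## Default parameter choices

The emulated trial's raw data and its registry-calibrated onset/dwell
parameters were never published, so all natural-history defaults are
documented fixtures, not estimates:

| quantity | default | why |
|---|---|---|
| Weibull shape | 9 | smoker incidence rises steeply with age; a flat onset curve cannot produce the predominance of post-screening clinical diagnoses |
| Weibull mean | 72 / 74 / 70 y | onset centred in the seventh decade |
| lifetime onset probability | 0.26 per pathway | heavy-smoker scale; yields ~200 diagnoses per ~4600-person arm |
| dwell means (PRE_I, PRE_II, III, IV) | 1.2/0.85/0.6/0.4 (squamous), 1.2/0.7/0.6/0.4 (adeno/large), 0.6/0.3/0.3/0.25 (small) | short x-ray-era detectable window; small cell fastest |
| p(clinical dx in III) | 0.45/0.40/0.35 | roughly even III/IV split at clinical surfacing |
| attendance | 0.75 | the historical trial's reported adherence scale |
| follow-up | 12 y | trial-end horizon of the earliest enrollees |
| life table | Gompertz a=1.8e-4, b=0.08, ages 40–100 | ~1% annual mortality at 50, ~5% at 70 — elevated, smoker-like |
| arm sizes | 4618 / 4593 | conventional split of the published 9211 |

Under these defaults the null model expects ~88 screen-detected and
~100 otherwise-diagnosed cancers in the screened arm and ~185 in the
control arm. The pseudo-observed fixture table keeps the two published
intervention-arm marginals (90 screen-detected / 116 otherwise) and
fills every unpublished cell near those null expectations (62/28 stage
split of the 90; control 185), each labeled `fixture` in its source
column. The only deliberate signal in the fixture is therefore the
published intervention-arm excess over its null prediction, which is
why the risk-difference model is the one that improves the fit on it.

## What the synthetic data do and do not show

The generator emulates diagnosis *count tables* under a known truth;
it does not emulate person-level screening records, smoking histories,
radiographs, or lung-cancer mortality (survival endpoints are out of
scope). Passing recovery tests show the calibration machinery is
consistent — parameters injected into the generator are recovered by
the fitter — under the model's own assumptions (exponential dwells,
i.i.d. attendance, one tumor per person, Poisson cells). They say
nothing about whether those assumptions hold for any real trial, and a
fitted risk factor on the fixture table inherits every fixture choice
listed above.

## Numerical notes and known limitations

- χ² arithmetic on published deviance reductions: upper tails of
  (2.14, 1), (0.07, 1), (5.04, 1) round to 0.14, 0.79, 0.02. The
  remaining published pair (1.27, 1) has upper tail 0.26, not the 0.23
  that accompanies it in print; the package reproduces the arithmetic,
  not that printed value. Similarly the published null-model deviance
  appears as both 23.45 and 23.54 in different places; its absolute
  value depends on an unpublished cell layout and is not a package
  output.
- The exact binomial excess test is defined as the upper tail of
  Bin(n_at_risk, expected/n_at_risk) at the observed total; the
  published p = 0.016 for the analogous comparison is not reproducible
  because its n and sidedness were not stated.
- Deviance comparisons need E > 0 wherever O > 0; at very low
  oversampling a sparse expected table can make the objective
  infinite. The default oversample of 20 makes this unlikely at trial
  scale.
- The one-parameter grid fitter resolves parameters to ~0.4% of their
  bound range; treat fitted values below that resolution as ties.
- Attendance is independent across exams: no habitual-attender
  correlation. Systematic error is tumor-level, not person-level.
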