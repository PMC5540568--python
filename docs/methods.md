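# Methods

## Natural-history model

The disease process follows the adenoma–carcinoma sequence with two
adenoma size classes (<10 mm, ≥10 mm) and four preclinical cancer stages.

**Onset.** Adenomas arise in person *i* by a non-homogeneous Poisson
process with intensity `z_i · λ(a)`, where `λ(a)` is a piecewise-constant
age-band rate (events per person-year; zero below the first band edge)
and `z_i` a gamma frailty with mean 1 and variance `v` (default 1;
`v = 0` gives a homogeneous population). Onset times are drawn by
inverse-transform of the piecewise-linear cumulative rate, truncated at
the other-cause death age. The adenoma count per person is therefore
Poisson-distributed and emerges from the process, not modelled jointly.

**Progression.** All dwell times are exponential, one rate per
transition (piecewise-exponential over the path): small→large
(`rate_small_to_large`), large→preclinical I (`rate_large_to_preclinical`,
progressive lesions only; the progressive fraction is `p_progressive`),
and stage progression rates λ₁..λ₃ for I→II→III→IV. In each preclinical
stage, clinical presentation competes with progression at the sojourn
rate μ_s; stage IV exits only by presentation. Non-progressive adenomas
may still grow from small to large but never leave the adenoma states.
Transition draws are made for every lesion regardless of whether earlier
transitions are reached, so parameter changes with a common seed perturb
the draw sequence minimally (used by the monotone-severity check).

**Death.** Other-cause death is drawn once per person by
inverse-transform from the sex-specific lifetable survival curve
(linearly interpolated between integer ages; mass below the last grid
value is assigned to the last grid age). Post-diagnosis survival at stage
s is a mixture-cure model: cured with probability π_s, else an
exponential excess-death time with rate ρ_s attached at the diagnosis
age. All-cause death is the minimum of the two. The two survival
uniforms (cure, time) are person-level quantities drawn once and stored.

## Screening overlay and common random numbers

The no-screening history — demographics, frailty, all lesion
trajectories, the survival uniforms — is sampled once and frozen. The
overlay walks these frozen trajectories with its own random stream, so
the two arms of a comparison are identical except for the consequences
of screening. This realises common random numbers structurally, without
per-person named sub-streams.

Programme mechanics: invitations at programme-wide biennial rounds
(mid-year convention; all intervals half-open `[start, end)`), ages
50–69, with exclusions for prior CRC diagnosis, colonoscopy within the
past 5 years, and pending surveillance. Attendance follows a two-state
behaviour model (first-round probability by sex, optionally by age band;
then retention for previous attenders and conversion for previous
non-attenders). FIT positivity is driven by the single most advanced
lesion present (per-state sensitivity; 1 − specificity if none): the
simplest model consistent with a per-state sensitivity table. A positive
test leads to diagnostic colonoscopy with a per-person adherence draw;
each lesion is detected independently with per-state sensitivity; an
incomplete examination (probability 1 − completeness) is repeated once in
the same year, after which it is treated as complete. Detected adenomas
are removed — the lesion trajectory is truncated and any later clinical
presentation voided. Detected preclinical cancers become screen-detected
CRC at the current stage.

Follow-up after a colonoscopy uses a size-only risk classification (the
model carries no dysplasia grade): 1–2 small adenomas → retest in 5
years; any large adenoma or 3–4 adenomas → surveillance colonoscopy in 3
years; ≥3 large or ≥5 adenomas → surveillance in 1 year; nothing found →
return to screening in 10 years. Thresholds are configurable. People
under surveillance are not re-invited to FIT until discharged (a
normal/low-risk surveillance result returns them to the 10 y/5 y
pathway); surveillance stops at age 74. Cancers presenting clinically
after a negative screen and before the person's next invitation are
tagged interval cancers; a negative screen here is a negative FIT or a
cancer-free colonoscopy.

**Lead-time rule.** Survival of a screen-detected cancer is re-evaluated
at the detection age and stage with the person's stored survival
uniforms, so stage shift alone drives the benefit. Because the same
uniforms at an unchanged stage would place death *earlier* by exactly
the lead time, the screened death age for a lesion is floored at that
lesion's no-screening CRC death age: detecting a cancer earlier never
hastens death. Interval and clinical cancers in the screened arm use the
same survival evaluation and therefore reproduce the no-screening course
bit-for-bit when the same lesion presents at the same age.

## Population and scenarios

The baseline population is an age-structured snapshot (single-year
strata per sex, default baseline 2008, ages 30–89). A person of stratum
age `a` is `a + 0.5` years old at the baseline mid-year; other-cause
death is drawn conditional on being alive at that age, while lesion
histories are sampled unconditionally from birth — persons whose
clinical diagnosis falls before the baseline are simply never eligible
for invitation and fall outside the projection window, in both arms
alike. The default is a closed cohort; an optional renewal mode adds one
entering cohort (the youngest stratum age) per projection year so that
programme activity does not vanish at long horizons. Renewal entrants
are approximated as present from birth, which slightly overstates early
person-years; the mode is intended for qualitative steady-state activity
projections only.

Counts are aggregated per calendar year over a horizon of `H` years
starting the year after baseline, scaled by the weight real persons /
simulated persons (per sex). Incidence counts diagnoses of any mode
(screen, surveillance, interval, clinical), mortality counts CRC deaths,
and life-years lost attaches `other-cause age − CRC death age` to the
death year. Reductions are `100 × (no-screening − screening) /
no-screening`, annual and cumulative, with zero-denominator years
flagged as missing rather than raised.

## Default parameters (illustrative, not calibrated)

The defaults describe a plausible southern-European population of 2008
and are **not calibrated to any cancer registry**; adenoma prevalence in
the population this package emulates was reported higher than in earlier
studies but without printed values, so the onset level is a plausibility
choice.

| Parameter | Default (male / female) | Why |
|---|---|---|
| Onset rates, /person-yr by band (20,40,50,60,70+) | 0.0026–0.031 / 0.0010–0.038 | lifetime clinical CRC risk by 80 lands at ≈6.7% / 4.3%, inside a 4–7% envelope |
| Frailty variance | 1.0 | individual risk heterogeneity of MISCAN-family models |
| Progressive fraction | 0.22 | with the dwell rates, yields the above risk |
| Dwell rates small→large, large→preI | 0.12, 0.11 /yr | decade-scale adenoma dwell times |
| Stage progression λ₁..λ₃ | 0.55, 0.60, 0.70 /yr | mean preclinical sojourn ≈3.2 y (2–6 y envelope) |
| Sojourn rates μ₁..μ₄ | 0.12, 0.25, 0.55, 1.00 /yr | later stages present faster |
| Cure fractions π₁..π₄ | 0.90, 0.75, 0.45, 0.05 | registry-style stage gradient |
| Excess death rates ρ₁..ρ₄ | 0.15, 0.25, 0.45, 1.00 /yr | stage-IV median survival under a year if not cured |
| FIT sensitivity (small, large, preI–IV) | 0.04, 0.22, 0.60–0.88 | quantitative FIT at a 20 µg Hb/g cut-off |
| FIT specificity | 0.965 | first-round positivity ≈6–7% |
| Colonoscopy sensitivity / completeness | 0.77–0.98 / 0.95 | per-lesion miss rates; caecal intubation |
| Participation (first round) | 0.640 / 0.694 | observed first-round programme attendance |
| Retention / conversion | 0.918; 0.25 / 0.30 | observed regular participation; conversion implied by round-2 totals |
| Colonoscopy adherence | 0.929 | observed programme adherence |
| Lifetable (Gompertz–Makeham) | e₀ ≈ 80 / 86 | sex gap in other-cause mortality |

The sex differential deserves a note. Percentage reductions are
invariant to a pure scaling of onset rates, so "male rates above female"
cannot by itself reproduce a larger male benefit. The defaults therefore
shift the female onset-age profile later: female rates are below male in
every band under 70 and exceed them only in the 70+ band, placing a
larger share of female cancers beyond the screened ages. This is a
stylisation — in registries male age-specific incidence exceeds female
at all ages, and the real sex gap works partly through mechanisms this
reduced model omits (lesion site, sex-specific test performance).

## What the synthetic data do and do not show

The generator emulates: a Basque-like 2008 age pyramid (~586,700 persons
aged 50–69), sex-differential CRC risk, programme behaviour matching the
published participation/retention/adherence levels, and count tables
whose first-round positivity and detection rates exceed later rounds.
It does not emulate registry-calibrated incidence, lesion site, the
serrated pathway, secular participation trends, colonoscopy
complications, or haemoglobin-concentration test dynamics (the cut-off
enters only through the sensitivity/specificity table). Passing tests
therefore demonstrate internal consistency and the qualitative behaviour
of organised FIT screening — stage shift, incidence reversal after an
initial detection surge, male-over-female benefit — not quantitative
agreement with any registry's projections.

## Numerical choices

- Continuous ages; calendar time = birth year + age; invitations at
  mid-year; events binned to calendar years by `floor`.
- Inverse-transform sampling throughout; flat (zero-rate) segments are
  dropped before inverting piecewise-linear cumulative rates, and an
  all-zero onset rate raises a configuration error (the batch sampler
  short-circuits on a zero expected count first).
- Indicator rounding is half-up to one decimal and applied only in the
  display layer; internal values keep full precision. Zero denominators
  yield missing values, never exceptions.
- The onset-scale calibration bisects the log multiplier on the signed
  target-weighted relative error, with one shared seed across candidate
  evaluations (common random numbers make the objective smooth and
  monotone); the bracket is [0.25, 4] and the log tolerance 0.01. An
  all-zero target returns the lower bracket edge, flagged.
- Ties in the earliest-presentation scan are broken by lesion order;
  they occur with probability zero under continuous dwell times.
- Problem sizes: the test suite runs its paired-dominance check at
  10⁵ persons, the sex-ordering sign test at 10 seeds × 10⁵, the
  occupancy oracle at 10⁵ and parameter recovery at 2×10⁵ per fit;
  the acceptance script simulates 5×10⁴ persons per sex. These sizes
  put Monte-Carlo errors well below the assertion tolerances while
  keeping a full run at desk scale.

## Known limitations

- Lesion-level independence: FIT positivity ignores simultaneous
  bleeding of multiple lesions; colonoscopy detections are independent
  across lesions.
- After a person's first CRC diagnosis the model stops tracking further
  primaries in that arm; in the screened arm, removal of the index
  adenoma lets a later lesion surface, which can (rarely) produce an
  earlier death from a different cancer than in the no-screening arm.
- The follow-up coding list collapses to six categories (the model has
  no hyperplastic-polyp state, so its 10-year category is never
  assigned).
- Interval cancers retain their no-screening survival; whether they
  should receive distinct survival is an open question in the source
  material and the neutral default was chosen.
- Only the onset scale is calibratable; dwell times and stage
  distributions are inputs, as joint calibration is under-determined at
  desk scale. Relative errors are reported; no goodness-of-fit criterion
  is invented.
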