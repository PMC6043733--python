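# badiary

Analytics for hourly **behavioral-activation (BA) activity diaries** from
patients treated for (bipolar) depression.  In BA therapy the patient logs
one activity per hour between 7 am and 10 pm (16 slots/day) and rates each
with a *pleasure score* (PS, 1–10).  `badiary` turns a stack of such
diaries into the data-driven summaries a therapist (or a BA app) would
want:

- **Ingestion & taxonomy** — parse diary CSVs, map free-text activities to
  the 7-class activity-category (AC) taxonomy (Movement, Work & education,
  Spare time, Daily living, Practical, Social, Other) via a keyword
  lexicon, quantify rater agreement (Cohen κ) and hourly compliance.
- **Descriptives** — daily average PS (dPS), per-patient and pooled
  category-hour distributions, mean PS per category.
- **Good/worse days** — split each patient's days at the median dPS,
  weight category hours by |dPS − median|, and contrast good vs worse days
  per category with a Wilcoxon signed-rank test (exact enumeration for
  small n, continuity-corrected normal z otherwise; uncorrected for
  multiple comparisons).
- **Diurnal rhythm** — the patient's *template* is the modal category per
  hour slot over weekdays; a day's adherence is the Jaccard coefficient
  JAC = (matching slots)/16.  A within-subject ANCOVA regresses the
  next-day PS change `dPS(x+1) − dPS(x)` on JAC(x) with dummy-coded
  subject intercepts; the fitted zero crossing is the adherence level
  above which tomorrow is predicted to be better than today.
- **Dose–response** — cross-sectional least squares
  `dPS = β₀ + β₁X + β₂X²` of daily pleasure on daily hours `X` of one
  category, refit linear when the quadratic term is insignificant; a
  concave fit has an interior optimum at `−β₁/(2β₂)` hours.
- **Synthetic cohorts** — a generator that plants all of the above
  (templates, Beta-distributed daily adherence, slot-level missingness,
  category PS effects, a lagged JAC effect with a configurable zero
  crossing, a concave social-hours curve) with full ground truth, so every
  estimator is verified by parameter recovery.

Real diaries of this kind are not publicly available; the package is
therefore built around the simulator plus the published per-patient
summary tables of a seven-patient cohort (transcribed in
`badiary.reference`), against which the cohort-level arithmetic is checked.

## Worked example

```sh
ba-diary simulate --seed 1 --out results/cohort     # or: python analysis/01_simulate_cohort.py
python analysis/02_descriptives.py
python analysis/03_good_worse_days.py
python analysis/04_diurnal_rhythm.py
python analysis/05_dose_response.py
```

On the default simulated cohort (7 patients × 4 weeks, ~90% compliance,
seed 1) this prints:

```
compliance range: 89-92%
highest-pleasure category: Movement (mean 6.90, n=301)
3 of 49 patient-category contrasts significant at alpha=.05 (uncorrected):
  S3 Movement: z=2.306, p=0.021 (more weighted hours on good days)
  S6 SpareTime: z=-2.574, p=0.010 (more weighted hours on worse days)
  S6 DailyLiving: z=-2.009, p=0.045 (more weighted hours on worse days)
112 weekday pairs across 7 patients
within-subject correlation=0.237, p=0.0146, slope=0.81 PS/JAC
predicted next-day change crosses zero at JAC=0.37: days more similar to
the routine than that predict a better next day
Social: concave fit (beta2=-0.147, p=0.0000), optimum at 2.1 h/day over 196 days
```

Reading: movement hours carry the highest pleasure; a patient who follows
more than ~0.4 of their usual hourly routine tends to report a *better*
day tomorrow; and pleasure peaks at about two hours of daily social
activity — each of these is a planted property of the simulated cohort
that the pipeline recovered.  Tables land in `results/` (demographics,
category distributions, PS by category, per-category contrasts, diurnal
templates, adherence pairs, ANCOVA report, dose–response fits).

The same pipeline runs on real diary CSVs
(`patient_id, date, slot|hour, raw_text, category?, pleasure?`):

```sh
ba-diary analyze my_diaries.csv --out my_report
```

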