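# sigreach

Colorectal-cancer anatomic subsite reachability by flexible sigmoidoscopy
versus colonoscopy, as a tested, reusable analysis pipeline for
SEER-style registry case listings.

## The scientific question

Flexible sigmoidoscopy examines the rectum, sigmoid and descending colon;
colonoscopy examines the whole colon but demands deeper sedation, fuller
bowel preparation and shows lower real-world adherence.  A policy-relevant
question is therefore: *what fraction of colorectal adenocarcinomas arise
in subsites a sigmoidoscope can actually see, and do tumors in those
distal locations carry a different prognosis than proximal ones?*

`sigreach` answers this for registry data by

1. partitioning ICD-O-3 topography into **visualizable** subsites
   {C186 descending colon, C187 sigmoid, C199 rectosigmoid junction,
   C209 rectum} and **colonoscopy-required** subsites
   {C180 cecum, C182 ascending, C183 hepatic flexure, C184 transverse,
   C185 splenic flexure};
2. applying registry exclusion rules (unknown stage, non-specific
   subsites C18.8/C18.9/C26.0, autopsy-only, incomplete or zero survival)
   with exact per-rule bookkeeping;
3. estimating per-factor visualizable proportions, univariable 2×2 odds
   ratios with Wald CIs, and a main-effects multivariable logistic
   regression (IRLS) of location on age group, sex, stage,
   race/ethnicity and diagnosis-year group; and
4. contrasting overall survival between location groups within age ×
   stage strata using IPW-adjusted Kaplan–Meier curves and the restricted
   mean survival time: for horizon τ ∈ {24, 60, 120} months,

   RMST(τ) = ∫₀^τ Ŝ(t) dt,  ΔRMST = RMST_vis − RMST_colo,

   ΔΔRMST = (RMST_vis,loc − RMST_vis,dist) − (RMST_colo,loc − RMST_colo,dist),

   with patient-bootstrap standard errors (weights re-estimated per
   replicate), two-sided Z-tests, percentile 99% CIs, and Bonferroni
   control over the declared test families (α = 0.05/27 for ΔRMST,
   0.05/18 for ΔΔRMST).

Registry microdata are not redistributable, so the package ships a
synthetic cohort generator that emulates the published cohort's marginal
structure (subsite-by-age mixture, demographics, stage mixture per
location, exponential stage × location survival with administrative
censoring) with fully known ground truth for validation.

## Worked example

```bash
python examples/02_published_tables.py
```

recomputes the published cohort tables from their raw counts and prints,
among others,

```
quantity  percent_visualizable
 overall             58.160186
 under45             72.703995
  45to49             73.637999
  50plus             55.960291
 under50             73.149855

      age_group 45to49       OR 2.20 (95% CI 2.13-2.27)
      age_group under45      OR 2.10 (95% CI 2.03-2.16)
            sex male         OR 1.54 (95% CI 1.51-1.56)
```

i.e. 58.2% of the 309,466-patient cohort had tumors a sigmoidoscope could
see, rising to 73.1% under age 50, and patients aged 45–49 had ~2.2-fold
odds of a visualizable tumor relative to patients 50+.  The other
examples classify subsites, inject a known odds ratio into a synthetic
cohort and recover it, and run the IPW bootstrap DRMST contrast against
its closed-form truth:

```bash
python examples/01_subsite_classification.py
python examples/03_simulate_and_recover.py
python examples/04_survival_contrasts.py
```

A thin CLI wraps the same pipeline:

```bash
sigreach simulate --n 10000 --seed 1 --out cohort.tsv --truth-out truth.json
sigreach analyze --input cohort.tsv --out bundle/ --seed 1 --n-reps 2000
sigreach replicate-tables --out tables/
```

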