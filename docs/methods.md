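# Methods

This note documents the models and conventions behind `carepath-qi`: what
the synthetic EHR emulates, how the extraction engine and the concordance
statistics are defined, which design choices were genuinely open, and what
the package's tests do and do not demonstrate about real hospital data.

## The care-pathway model

Each patient's journey is generated as a sequence of dated events:

1. **Scheduling order** (day `t0`, a weekday): the administrative action
   that opens the pathway and the first recorded event.
2. **Scanned referral letter**: scanned on `t0`. The referral date *written
   in the letter* is stored in the event's attribute bag; with probability
   `p_ref` it precedes `t0` by 1–3 days (weights 0.6/0.25/0.15). Only a
   human abstractor can read the attribute — structured extraction sees the
   scan, not its content. This single modelling device reproduces both the
   letter-before-order chronology and the constraint that no *event*
   precedes the scheduling order.
3. **Initial consultation**: `t0` plus a waiting time (median 5 days),
   snapped to a weekday.
4. **MDT**: the next weekly tumor-board day (Wednesday by default) after
   the consult plus a short wait (median 0 days). Under this schedule the
   median consult→MDT interval comes out at ≈ 2 days. With probability
   `extra_mdt_prob` a second MDT occurs 7 days later, still before
   treatment — the re-discussion a chart reviewer tends to miss.
5. **Treatment**: surgery with probability 0.50; surgical patients get a
   neck dissection (0.50), complications (0.20, an attribute on the surgery
   event), an unplanned reoperation (0.07) and adjuvant radiotherapy (0.55,
   starting a median of 35 days post-surgery, sometimes with concurrent
   systemic therapy). Non-surgical patients receive primary radiotherapy
   (0.92, 28–35 daily weekday fractions), possibly with concurrent
   systemic therapy (0.25), or primary systemic therapy. Systemic therapy
   is 3 cycles 21 days apart; with probability
   `second_systemic_round_prob` a second round starts 120–250 days after
   the first round ends (tagged `round=2` in the attribute bag — the tag is
   readable by the abstractor, never by the engine).
6. **Supportive care**: dental screening before radiotherapy (0.90);
   physiotherapy after neck dissection (0.60; 0.03 otherwise), delivered
   either through the inpatient form or — with probability
   `physio_outpatient_prob` — only as an outpatient/external contact that
   files no form.

Waiting times are negative-binomial day counts (dispersion 10, mean set to
the configured median, truncated at 6×median+10); the negative binomial was
chosen over a plain geometric because its lighter right tail keeps the
30-day and 7-day indicator proportions in a clinically plausible range
while preserving the configured medians. All knobs live in
`PathwayConfig`; the treatment-mix and supportive-care probabilities above
are calibrated to a published annual cohort's marginal counts (≈ 50%
surgical, ≈ 76% irradiated, ≈ 19% systemic, ≈ 26% neck dissections), not to
any particular hospital's true distributions, which are not public.

## Two observers of one log

* `derive_manual_abstract` plays the registry abstractor: referral date
  from the letter's written date, the *first* MDT on/after the consult,
  every physiotherapy setting visible, systemic end restricted to the
  primary episode. Conditional recording mirrors registry practice:
  neck-dissection/complication/reoperation fields only for surgical
  patients, the physiotherapy flag only when a contact was found, plus
  per-variable missingness rates.
* `extraction_engine` plays the dashboard: referral date proxied by the
  earliest scheduling order, the *last* MDT strictly before treatment
  start, physiotherapy only via the inpatient form, systemic end bounded by
  the round cutoff. `apply_extraction_faults` optionally corrupts the raw
  extract with the systematic +1-day initial-visit error before the engine
  runs; the engine itself always implements the corrected logic.

Under the identity `DiscrepancyProfile` the two observers coincide exactly,
which is the pipeline's null test: 100% agreement on every variable and a
zero manual-vs-automatic difference on all ten indicators.

## Extraction rules worth naming

* **Treatment start** is the earliest of first surgery / first RT fraction
  / first systemic administration, with same-day ties resolved
  surgery > radiotherapy > systemic.
* **Systemic round cutoff** (default 6 weeks, configurable, can be
  disabled): the end date is the last administration reachable from the
  first through gaps of at most the cutoff. Disabling it reproduces the
  naive last-administration logic that picks up a later treatment round.
  The 6-week default mirrors the conventional adjuvant-window timeframe;
  no published value exists for this parameter.
* **"Prior to" comparisons are strict** (a same-day MDT or dental consult
  does not qualify), configurable via `same_day_strict` / per-definition
  `strict_before`. "Within N days" windows are inclusive (≤ N),
  configurable via `boundary`.
* **ICD-10 inclusion** matches code prefixes C00–C14, C30–C32 and C77.0
  through a fixed mapping table to the eight localization categories.

## Cohort criteria

Inclusion: initial consultation in the study year (the dataset's own visit
date decides; the registry year is the fallback when the date is missing),
an eligible head-and-neck localization, curative intent. Exclusion, in
order: carcinoma in situ, second primary, residual/recurrent disease,
non-SCC histology. Each patient gets the first failing criterion as a
disposition label. By default each dataset is filtered on its own fields; a
strict-intersection mode keeps only patients included in both.

## Statistics

Agreement percentages are `100 · n_agree / n_compared` over linked pairs
with the variable present in both sources, rounded half-away-from-zero to
one decimal (two for coverage). Cohen's kappa is computed for categorical
and boolean variables; its null standard error uses the standard
large-sample expression

    SE₀ = sqrt(p_e + p_e² − Σ_i r_i c_i (r_i + c_i) / N³) / ((1 − p_e) √N)

and the p-value is the two-tailed normal tail of κ/SE₀. Degenerate
marginals (p_e = 1) raise rather than return a value. Indicator
differences are `automatic − manual` on the rounded reported values, so a
positive difference always means the automatic result is higher/longer.

## Problem sizes used by the test suite and acceptance script

The null run uses one cohort of n = 262 (a typical filtered annual
cohort). Rate recovery uses 20 replicates of n = 1000 and checks each
replicate against 3 binomial standard deviations. Fault-mode checks use
n = 400 per seed: 20 seeds for the physiotherapy direction and a smaller
set for the systemic-cutoff repair, which is nearly deterministic. These
sizes give stable statistics while keeping a full run in the tens of
seconds on one core.

## Known limitations

* The generator emulates marginal frequencies and the documented error
  modes, not real clinical correlation structure (stage, age, comorbidity,
  modality interactions). Passing tests show the *machinery* is correct
  and the documented fault modes behave directionally as described; they
  do not certify agreement levels on any real hospital's data.
* Localization and intent are copied from the registry into both datasets,
  so their simulated agreement is perfect unless missingness is injected;
  coding disagreement between two human/machine coders is not modelled.
* The waiting-time sign interplay between an earlier manual referral date
  and the extraction's scheduling-order proxy means simulated
  referral-based median waits can differ between datasets in either
  direction depending on which fault modes are active; published tables
  are ambiguous on this sign and the package simply reports what it
  computes.
* Coverage below 100% (patients present in only one source) is expressed
  at validation time; the generator itself emits one registry row per
  patient and does not simulate patients lost by either source.
* No probabilistic record linkage, no case-mix adjustment, no TNM staging
  variables, no free-text documents, no HL7/FHIR exchange.
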