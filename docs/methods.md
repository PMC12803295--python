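# Methods

## Data model and ingest

The study schema describes recruiting sites tagged with one of two multisite
clinical centers (MCC1, MCC2), two surgical cohorts (total knee arthroplasty,
thoracic surgery), an ordered visit schedule with nominal day offsets from
baseline (baseline 0, post-op 14, 3-month 90, 6-month 180 in the example
study), and forms. Each form is a CRF or a PRO, belongs to a data domain, and
carries typed fields (numeric with a range, categorical with choices, date,
time, text), a required flag, an applicability predicate over visit × cohort,
and a REDCap-style completion status field coded 0 = incomplete,
1 = unverified, 2 = complete. Unverified is treated as incomplete throughout.

Flat exports are wide CSVs, one row per subject × event. Besides `record_id`
and `redcap_event_name`, three reserved metadata columns carry what a live
capture system would supply out of band: `site_id`, `cohort` and
`event_date` (ISO-8601; all date arithmetic is in whole days). Ingest melts
every declared field column into a tidy record — exactly one record per
(subject, visit, form, field) — coercing values to their declared type.
Uncoercible cells are retained as text and surfaced as schema violations;
unknown columns are warning-level violations and skipped; duplicate
subject × event rows abort ingest. Cells of forms a subject's cohort/visit
does not collect remain in the tidy table as missing values, preserving the
cells-in = records-out conservation identity; downstream classification marks
them "not collected by design" from the predicate, never from blankness.

The per-field data dictionary round-trips forms but cannot carry sites,
cohorts or the visit schedule; the full schema round-trips through a YAML
config instead. PRO delivery instrument is derived, not stored: PROs at MCC1
sites go through REDCap, at MCC2 sites through MyDataHelps; CRFs are
in-person.

## Edit checks

Checks are declarative definitions — an id, a form, a kind, parameters and a
message — validated against the schema before any evaluation. Six kinds:
missingness (a listed field blank), pair mismatch (|a − b| > tolerance,
default tolerance 0 since duplicate-entry fields should agree exactly;
inequality for categoricals), conditional missingness (trigger field equals a
value and a dependent is blank), chronology (listed time fields strictly
decreasing anywhere), location mismatch (performed-at ≠ entered-for site),
and reason-unspecified (test marked not done, reason blank). Pair, location
and chronology checks defer to missingness when their inputs are absent.

Two deliberate conventions:

- **Checks run only on form instances whose status field says complete.**
  Blanks on an incomplete form are incompleteness, not errors; this keeps the
  "completed with errors" and "incomplete" statuses disjoint and makes the
  simulator's injection log provably equivalent to the flag table.
- **Within a form, checks reference disjoint field sets.** Each check polices
  its own fields, so one data defect raises exactly one flag and flags can be
  attributed unambiguously. Consequently the shipped registry's per-form
  missingness checks list required fields no other check references
  (e.g. vaccination status on the blood form), and fields that are only
  conditionally required (surgical-site pain after a resting-state scan, the
  reason a test was skipped) are not in any blanket missingness list.

A flag carries subject, site, center, cohort, domain, form, visit, check id,
the implicated fields and observed values, a message, the delivery
instrument, and a flag date equal to the entry timestamp of the implicated
row — the date the flagged data were entered, which the windowed reports and
monthly trends consume. `run_checks` is a pure function; output is sorted by
(site, subject, visit order, check id), so identical inputs give
byte-identical CSVs. At most one flag per (subject, visit, check) can arise
by construction.

## Status classification, streaks, combination counts

Every (subject, visit) present in the records crossed with every form gets
one status: not collected by design (predicate), unknown (status field
blank), incomplete (0/1), complete with/without error (2, by flag presence).
A status value outside {0, 1, 2, blank} is classified unknown with a warning
rather than failing, since ingest has already recorded the violation.
Quadrant percentages are taken over applicable instances only and are rounded
to one decimal, ties away from zero (the package-wide reporting convention);
the four statuses sum to 100 before rounding.

Streaks summarize a subject's primary biomarker forms (configurable; default
imaging, QST, functional testing, blood collection) over *due* visits — those
whose nominal offset has elapsed by the as-of date, so on-schedule subjects
are never penalized for the future. Any due applicable instance incomplete or
unknown (including a missing row) ⇒ incomplete streak; otherwise any flagged
instance ⇒ streak with errors; otherwise complete streak without errors.
Subjects lacking a baseline date are excluded.

Combination counts stratify subjects by time since baseline — early
(< 35 days) and late (> 7 calendar months, month arithmetic clamping to
month end) — and tally the exact subset of tracked forms each subject has
complete without errors (membership: at least one due applicable instance,
all such instances complete without errors). Exclusive subset counts
partition the stratum; per-form marginals equal subset sums; both identities
are tested against a brute-force enumeration over all subsets. The
per-subject boolean membership matrix is the export consumed by standard
UpSet plotting tools.

## Scores and outliers

Score definitions map item fields to a sum/mean/single-field score with a
valid range (GAD-7: 7 items, 0–21; PHQ-9: 9 items, 0–27). Only complete
forms are scored and missing items are never imputed — any missing item
leaves the instance unscored. Summaries (n, mean, median, quartiles) are
grouped by form × visit × cohort over the full cross product of observed
visits and cohorts, so empty groups appear with n = 0. Quantiles use linear
interpolation between order statistics (the numpy default), fixed and
documented because quantile conventions change fence positions. Outliers are
Tukey fences, Q1 − 1.5·IQR to Q3 + 1.5·IQR, within groups of at least four;
values exactly on a fence (e.g. an all-equal group with IQR 0) are not
outliers.

## Windowed reports and instrument breakdown

Flag age in whole days before the as-of date maps to recent [0, 90),
mid [90, 180], archive (180, ∞). The printed "90–180" range is read as
inclusive of both endpoints, with day 90 removed from "recent" so the three
windows partition all ages; the boundary convention is stated rather than
inferred because the underlying convention is undocumented. Reports filter to
a center × cohort × domain × window, sort stably, and export to CSV (byte
stable), Excel (one sheet per domain) and standalone printable HTML built
from the same frame, so all formats are content-equal. The instrument
breakdown tabulates PRO flags per form × site with each error type's
percentage (summing to 100 where errors exist); comparing REDCap against
MyDataHelps rates is the reader's act — the operation only tabulates.

## Trend models

Flags bucket into calendar-month series per domain, zero-filled between each
domain's first and last flagged months. Observed percent change is
100·(last − first)/first over the endpoint months, undefined when the first
count is zero. The trend model regresses counts on the month index with a
log link: Poisson by default, switching to negative binomial (alpha from the
auxiliary moment regression, clamped to [0.01, 10]) when the Pearson
dispersion statistic exceeds 2 — the standard count-trend recipe. Fits
require at least three observation months and refuse all-zero series. The
model percent change is 100·(exp(β·Δt) − 1) over the domain's span Δt; an
exact exponential series reproduces its observed change exactly because it
solves the Poisson score equations. The pooled model stacks domains with
domain-level intercepts and a shared slope on a common calendar month index;
its span runs from the earliest to the latest observation across domains.

The summary table's Total row sums the domain first counts and last counts —
the aggregate initial and latest monthly error burden — because domains
begin and end in different calendar months, so no single month is "first"
for all of them.

## The simulator

The generator emulates the study conditions end to end: 4 sites (2 per
center) each enrolling 4 subjects per month for 12 months starting
2024-09-01, observed as of 2025-09-01; 60/40 knee/thoracic cohort mix;
follow-up visits slip 0–4 days past nominal; 8 % of applicable forms
incomplete, 3 % with unknown status. Clean values are drawn within declared
ranges and then every check's constraint is enforced (pairs equal, times
sorted, locations matched, reasons present), so a zero-injection study
yields zero flags. Violations are then injected per check with probability
p·(1 − r)^m, baseline p = 0.08 and monthly decay r = 0.10 (mirroring a study
whose error rate falls under active feedback), where m is the calendar month
of the entry date; PRO missingness is instead driven by a per-instrument
probability (default 0.06 for both REDCap and MyDataHelps, matched because
no instrument difference is being emulated). Each perturbation establishes
its own check's precondition and breaks only that rule; with field-disjoint
checks, perturbations compose, making the injection log exactly the set of
violations present — the ground truth the soundness tests compare against.

Three independent random streams (enrollment, values, injection) spawn from
the master seed, so extending one concern cannot shift the others and
identical configs are byte-identical across runs.

What the generator does **not** emulate: clinical correlation between
instruments or over time, site-level heterogeneity in error rates, dropout
beyond i.i.d. incompleteness, partial-form entry patterns, or free-text
idiosyncrasies. Passing tests therefore demonstrate the correctness of the
pipeline's logic under controlled conditions, not robustness to the full
messiness of production capture systems.

The `table2` replay fixture is a synthetic flag table whose per-domain
monthly series are pinned at both endpoints (first/last month dates and
counts) with geometrically interpolated interior months; it exists to
exercise the monthly bucketing and percent-change path on a known answer.
Model estimates fitted to it depend on the arbitrary interior interpolation
and are illustrative only.

## Problem sizes and runtime

The shipped tests simulate studies of roughly 50–500 subjects (the
rate-fidelity check uses ~500 for tight binomial tolerances; soundness runs
ten ~40-subject studies), and the trend-recovery check uses 200 replicates
of 12-month Poisson series — sizes at which every property under test is
already well resolved. The full suite runs in well under a minute; the
acceptance script in a few seconds.

## Known limitations

- The example schema and check registry are illustrative of a two-center
  pain study; the full production check inventory (~20 per CRF per site) is
  not public, so the registry is representative, not a reconstruction.
- Branching logic from real REDCap dictionaries is out of scope; the
  applicability mini-grammar covers visit × cohort predicates only.
- The negative-binomial switch uses a moment alpha rather than joint ML —
  adequate for a diagnostic-grade trend, not for inference-critical work.
- Percent-change rounding (one decimal, half away from zero) can differ at
  exact ties from bankers'-rounding pipelines.
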