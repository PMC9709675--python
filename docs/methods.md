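# Methods

## The problem

Electronic prescription and dispensation records are a noisy proxy for
what a patient actually takes.  Overlapping refills, duplicate rows,
short spurious prescriptions and gaps between pick-ups turn the daily
treatment history — especially under polypharmacy, where therapy moves
between mono- and combination regimens — into a fragmented sequence of
short-lived states that is hard to analyse for switches,
discontinuations and adherence.  `rxsmooth` estimates the *most likely
therapy per day* from such records.

Every method here operates on the day-level **exposure series**: for each
day between a patient's first and last covered day, the exact set of
drugs with an active prescription (the *treatment combination*).
Combinations are compared by exact set equality; the empty set (`NONE`)
marks untreated days and is a category like any other, so treatment gaps
are visible to — and can be closed or preserved by — the smoothing.
Intervals are inclusive on both ends at one-day resolution; drug codes
are opaque ATC-style strings, with truncation to a coarser ATC level
available only as an explicit pre-processing step.  Dispensation records
(invoice month + package count) are converted to intervals assuming a
configurable `days_per_package` (default 30 days, the usual one-month
package); the data carry no end date, so any such rule is an assumption,
and per-drug overrides are supported.

## The smoothing algorithm

Two deterministic passes over the series of length `N`, governed by a
single parameter, the window length `wt` (days):

1. **Window mode.**  Full-length windows start at days `0 .. N - wt`
   (when `N < wt`, a single window of length `N`).  Each window is
   assigned the combination occupying the most days in it.  A tie
   carries the previous window's assignment forward, even when that
   combination no longer occurs in the current window; the first window
   breaks ties toward the tied combination occurring earliest.  Each
   day thus collects one *candidate* from every window covering it —
   between 1 (at the follow-up edges) and `wt` (interior).
2. **Candidate vote.**  Each day's final value is its most frequent
   candidate.  Ties prefer the previous day's final choice when it is
   among the tied candidates, otherwise the tied candidate produced by
   the earliest window.

Both tie-break chains favour temporal continuity (keep what was already
happening) and are fully deterministic; candidates are always counted in
increasing window order, so "earliest window" is well defined.

Limiting behaviour: `wt = 1` is the exact identity; `wt = N` with a
unique strictly most frequent combination yields that combination on
every day.  Constant series are fixed points for every `wt`.  Output
length, origin and patient are preserved, and every output combination
occurs somewhere in the input.

A useful guarantee, verified exhaustively in the tests: a single deviant
run of length `L` inside an otherwise constant series is always removed
when `L <= floor((wt-1)/2)` — such a run is a strict minority in every
window that sees it.  Longer runs may survive depending on position.

**Boundary behaviour at even `wt`.**  At a transition between two long
regimens, the window centred on the boundary sees both sides equally
when `wt` is even; the tie is carried forward, which shifts the detected
transition by one day per boundary.  Odd windows have no such tie and
preserve clean boundaries exactly.  This is inherent to mode filtering
with carry-forward ties, is at most one day per true transition, and is
frozen as a measured regression property in the test suite.

Choosing `wt`: 30–60 days is a sensible default range for chronic
medication; short-course drugs (e.g. systemic antibiotics) warrant
smaller windows.  Larger windows simplify more aggressively and
eventually erase clinically real short exposures.

## The persistence-threshold comparator ("traditional method")

The common literature alternative: start from the first observed
treatment and accept a change only when the new combination persists at
least `min_duration` days (inclusive; conventional values 60 days, or
15 days for antibiotics); shorter runs are rewritten to the incumbent.
Runs are of exact combinations — a run interrupted by one different day
counts as two runs, judged independently.  A terminal run shorter than
the threshold cannot have its persistence judged; rewriting it would
fabricate exposure beyond the observed data, so it is accepted and
flagged `tail_censored`.  The method is idempotent, and `min_duration=1`
is the identity.

## Impact statistics and the Wt-grid simulation

For one patient, the impact of a transform is summarised as
`percent_smoothed = 100 × days_changed / active_days`, where
`days_changed` counts every day whose combination differs between the
original and transformed series (including changes to untreated gap
days) and `active_days` counts the original's non-empty days.  The
percentage can therefore exceed 100 for patients with long gaps.  The
simulation harness smooths a cohort at each window length of a grid
(default `10, 20, 30, 45, 60, 90` days) and reports, per `wt`, the
number and proportion of patients with at least one changed day and the
median/IQR of `percent_smoothed` among changed patients (linear-
interpolation, type-7 quantiles).

## Chi-square power

Sample sizing for a validation-type comparison uses the noncentral
chi-square distribution: at Cohen effect size `w`, sample size `n`,
the test statistic is noncentral chi-square with noncentrality
`λ = n·w²`, and power is `P[χ²_nc(df, λ) > χ²_crit(df, 1-α)]`.  At
`w = 0.3062`, `df = 2`, `α = 0.05`, 400 patients give power ≈ 0.9999,
and the smallest `n` reaching 80% power is 103 (frozen regression
value, found by bracketed bisection — power is strictly increasing in
`n`).

## Synthetic cohorts

Real primary-care dispensation databases are not redistributable, so the
generator produces cohorts with known ground truth.  Each patient
follows a regimen plan — by default a chronic cardiovascular course of
mono → dual → triple therapy over ATC codes B01AC06 / C10AA05 / C07AB07,
with per-segment durations drawn uniformly from 120–240, 180–300 and
120–240 days inside a 900-day follow-up — realised as 30-day refill
prescriptions.  Independent noise mechanisms then corrupt the records:

* refill gaps (Poisson, mean 4 per patient; 1–7 days shaved off a
  refill's start),
* overlap jitter (each refill's end extended by 0–5 days),
* duplicates (each record re-emitted with probability 0.10),
* spurious prescriptions (Poisson, mean 2 per patient; 1–7 days of a
  random alphabet drug).

Rates and sizes were fixed once to represent a plausibly messy
primary-care extraction: a handful of imperfect refills per patient per
year, noise episodes no longer than a week.  One random stream per
cohort is keyed by the seed, with per-patient substreams keyed by
(seed, patient index), so a patient's data are invariant to cohort size
and everything is exactly reproducible.

What the generator does *not* emulate: dose/posology, diagnosis linkage,
demographic structure, stockpiling behaviour, seasonal prescribing, or
the empirical noise distributions of any particular database (which are
not published).  Tests passing on these cohorts show the algorithms are
correct and beneficial under this noise model, not that the specific
impact percentages transfer to any real cohort.

`recovery_score` is the fraction of days on which an estimate matches
the ground truth; estimates are first projected onto the truth's date
window (`ExposureSeries.reindex`, padding with `NONE`) because noise can
extend or trim a patient's observed span.

## Numerical and design choices

* All algorithms are deterministic; randomness exists only in the
  synthetic generator, always behind an explicit seed.
* Episode output is sorted by patient then start date, and patients are
  processed independently, so execution order never affects results;
  identical inputs give byte-identical output files.
* Day indices are 0-based offsets from each patient's origin date;
  dates serialise as ISO-8601.
* Degenerate inputs: empty record sets yield an empty-series sentinel;
  smoothing an empty series is an error; `wt` above the series length
  degrades to one full-series window; dispensation records must be
  resolved before expansion.
* The problem sizes used by the test suite and the acceptance script
  (cohorts of 200 patients, ~900-day follow-up, 1,000-series oracle
  sweeps) were chosen as the smallest sizes at which the properties are
  stable and clearly exercised.

## Known limitations

* Mode filtering erases real short exposures below the suppression
  threshold — by design; it is the wrong tool when week-scale exposures
  (e.g. antibiotic courses under a large `wt`) are the outcome of
  interest.
* The even-`wt` one-day boundary shift described above.
* The `days_per_package` rule is a stand-in for unknown dispensation
  coverage; results for dispensation-heavy data inherit its bias.
* No stockpiling: overlapping refills of one drug merge into plain
  coverage rather than extending it.
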