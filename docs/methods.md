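# Methods

## The fragility measure

A two-arm randomized trial with a time-to-event endpoint is summarized by
the two-sided unstratified log-rank test at a threshold α (default .05).
The survival-inferred fragility index (SIFI) asks: how many extreme
subjects must be moved between the arms before the test's conclusion
flips?

For a comparison that starts significant (p < α), the default procedure
repeatedly reassigns the *best survivor* of the experimental arm — the
subject with the longest observed follow-up, whether that record ends in
an event or in censoring — to the control arm, recomputing the log-rank
test after each move. The SIFI is +k, where k is the first iteration at
which p ≥ α. For a comparison that starts non-significant, the mirror
procedure (best control survivor moved to the experimental arm) runs
until p < α, and the SIFI is −k. The value is a count of actual patients,
which makes it a direct, linear-scale statement of how thinly a trial's
statistical conclusion is supported.

Selection is recomputed on the already-modified data at every step, and
every tie is broken deterministically: at equal follow-up time a censored
record is preferred over an event (a censored subject at t is at least as
good a survivor as one who died at t), and remaining ties fall back to
the original record order. The algorithm therefore has no random element;
identical input gives identical output.

### Variants

Four move rules are implemented (`Variant`):

| variant      | subject selected            | move                              |
|--------------|-----------------------------|-----------------------------------|
| `flip_best`  | longest follow-up, donor arm| reassigned to the other arm       |
| `flip_worst` | earliest *event*, donor arm | reassigned to the other arm       |
| `clone_best` | longest follow-up, donor arm| copy appended to the other arm    |
| `clone_worst`| earliest event, donor arm   | copy appended to the other arm    |

For a positive (initially significant) comparison the donor arm is the
one whose degradation erodes the experimental arm's apparent advantage:
best-survivor variants draw from the experimental arm, worst-survivor
variants from the control arm. For negative comparisons the donor and
recipient are swapped so every variant moves the test toward
significance. A config switch (`literal_directions=True`) instead applies
the worst-survivor flip from the experimental arm for positive
comparisons; that direction strengthens rather than weakens a positive
result and typically exhausts, and is provided for completeness because
both conventions appear in informal descriptions of the method.

Clone variants retain the original record in the donor arm and append a
copy to the recipient; each subject may be cloned at most once (tracked
by provenance), otherwise a flat curve would let the same extreme subject
be cloned forever without termination.

### Termination and edge cases

The iteration cap defaults to the total subject count. If the donor arm
runs out of eligible subjects (flip variants stop one short of emptying
the arm, which would make the test undefined; worst-survivor variants
need an event to select; clone variants run out of un-cloned subjects) or
the cap is reached before the threshold is crossed, the result carries
`exhausted=True` and the signed iteration count reached, so batch runs
can proceed and report the condition. Only an exhausted result may carry
the value 0 (no move was possible at all). The p-value trajectory is
returned in full: entry 0 is the unmodified data's p value, entry i the p
value after i moves.

A practically important exhaustion case: when a comparison is significant
*against* the experimental arm (hazard ratio above 1), degrading the
experimental arm further can never lose significance, so the positive
search exhausts. This is inherent to the directional definition of the
measure, not an implementation artifact; it occurs in the simulation grid
at the effect sizes that favor the control arm.

## The log-rank engine

The unstratified two-sample log-rank (Mantel–Haenszel) test is
implemented directly on arrays because it runs once per fragility
iteration. At each distinct event time the observed-minus-expected event
count in the experimental arm and the hypergeometric variance are
accumulated; tied events are handled in a single risk-set step and
subjects censored at t remain at risk for events at exactly t. The
statistic (O−E)²/V is referred to chi-square with 1 df (no continuity
correction). The implementation agrees with lifelines' unstratified
log-rank to 1e-8 on simulated trials (asserted in the test suite); the
variance term uses (n−d)/(n−1) with 0/0 → 0 for singleton risk sets.

## The comparator (artificial average patients)

The alternative fragility measure appends artificial patients — event at
the arithmetic mean of all original subjects' observed times, assigned to
the experimental arm — one at a time until p ≥ α. The mean exposure is
computed once from the original data and not updated as patients
accumulate. The measure is undefined (reported as missing, not an error)
when the comparison starts non-significant, which is precisely the
asymmetry the signed SIFI removes. On simulated panels its median is
several-fold larger than the flip_best SIFI median, mirroring the
published contrast between the two measures on real trials.

## The trial simulator

Trials are drawn from an accelerated-failure-time Weibull model:

    T = exp(−(β₀ᵉ + β·x)) · E^(1/aᵉ),  E ~ Exp(1)      (event)
    C = exp(−β₀ᶜ) · E′^(1/aᶜ)                          (censoring)

with x the arm indicator, observed time min(T, C) and an event iff
T ≤ C. Defaults: aᵉ = 1.5, β₀ᵉ = 2.0, β₀ᶜ = 2.01, aᶜ ∈ {2,…,10}, β from
−1 to 0.2. Under this form the model is proportional-hazards with
log HR = aᵉ·β, so the design's β range spans theoretical hazard ratios
≈0.22–1.35 and estimated ones roughly 0.11–1.98 under sampling noise.
Among the parameterizations compatible with a (shape, location) Weibull
description this is the one whose implied hazard-ratio span matches the
reference ranges; it is the single most consequential interpretation in
the package and is isolated in `simulate_dataset` should a different
convention be needed.

The reference factorial design is 12 cohort sizes (100–1200) × 5
censoring shapes × 25 effect sizes × 10 replicates = 15 000 trials.
Per-trial seeds are derived by hashing (base seed, cell coordinates,
replicate), so any sub-grid reproduces the corresponding rows of the full
grid bit-identically. Hazard ratios per trial are estimated by a Cox
proportional-hazards fit (lifelines, Efron ties); degenerate or
non-converging fits yield NaN and are retained. Acceptance-level checks
run a reduced grid (3 × 2 × 4 × 5 = 120 trials) plus a 400-replicate null
calibration at n = 100; these sizes keep the whole suite under a minute
of simulation time while still spanning the design's envelope.

What the generator does *not* emulate: staggered accrual, covariates
beyond the arm indicator, non-proportional hazards (the crossing curves
seen in some immunotherapy trials), informative censoring, or
administrative cutoff tied to calendar time (a fixed `max_followup` is
available but off by default). Passing tests therefore show correctness
of the algorithms under a clean proportional-hazards world, not that any
particular published trial's value would be reproduced.

## KM-curve inversion (IPD reconstruction)

Published figures give a step curve per arm and number-at-risk counts at
a few checkpoint times. The reconstructor inverts the KM estimator
interval by interval (the Guyot-class scheme): censoring within an
interval is assumed uniform, the censor count is adjusted iteratively
until the subjects remaining at the next checkpoint match the published
count, and events at each digitized drop are recovered by rounding
n·(1 − S/S_last-event) at the running risk set — the running KM product
self-corrects rounding residuals at subsequent steps. The last interval
has no at-risk anchor; censoring there is extrapolated at the average
prior censoring rate unless a per-arm total-event count is supplied, in
which case the censor count is adjusted to match it. Subjects still at
risk after the final digitized point are censored there.

Numerical conventions: at most 60 adjustment passes per interval (the
best allocation is kept and a warning recorded if the target is never
met); inconsistent inputs (rising survival, rising at-risk counts,
mismatched arm labels) are rejected up front; a curve not starting at
(0, 1) has the origin prepended when its first survival value is 1.

Fidelity, measured by round-trips on simulated trials digitized at their
native step corners: at-risk counts are reproduced with discrepancies of
0–1 subjects (median 1 among nonzero), and the log-rank p of the
reconstruction agrees with the original to ~10⁻⁴ for significant trials
and within 0.01 anywhere near the decision threshold. Two limits are
worth knowing. In the deep tail, where fewer than ~25 subjects remain at
risk, a single subject moves the KM step by more than 0.02 and the
uniform-censoring assumption cannot recover the within-interval ordering
of events and censorings, so pointwise curve agreement degrades there.
And in the middle of the p scale (p ≈ 0.2–0.9) the chi-square tail is so
flat that the same small wobble in the statistic becomes a visible (but
decision-irrelevant) p shift of up to a few hundredths.

## Trial-table summaries

The packaged `table1.csv` transcribes the published per-comparison table:
49 comparisons from 45 trials (four trials contribute two comparisons).
Quantiles use linear interpolation between order statistics — the
convention that reproduces the printed medians and IQRs exactly on the
sample-size, SIFI and |SIFI| columns. P values printed as bounds
("<.0001") count as significant and are excluded from the SIFI/log₁₀(p)
Pearson correlation rather than imputed. Drug-class counts are over
distinct trial names, not rows. The "censored in the first ventile"
diagnostic counts an arm's censorings in [0, T_max/20] with T_max the
maximum observed time over both arms; the reverse-KM follow-up
distribution would be an alternative ventile base, but the maximum
observed time is the definition used here because it is computable from
the IPD alone.

## Panel conditions in tests

Property panels ("across N seeded significant datasets…") simulate
cohorts of 300 with β = −0.4 (HR ≈ 0.55), inside the range of the
published significant trials (n 180–1274, HR 0.46–0.85). At much smaller
cohorts (n ≈ 100) the worst-survivor flip sometimes crosses faster than
the best-survivor flip — with tiny risk sets an early control event is a
large perturbation — so the "flip_best is minimal" property is a
statement about trial-scale data, and is asserted as a ≥90% frequency,
not a universal.

## Known limitations

- The measure is directional by definition; significant-harm comparisons
  exhaust rather than yield a finite positive value (see above).
- No confidence interval or sampling distribution for the SIFI is
  provided; the value is a deterministic function of the dataset.
- Only two-arm comparisons are supported; multi-arm trials are analyzed
  pairwise.
- Stratified and weighted log-rank variants are out of scope; all p
  values are from the plain unstratified test, which can differ from a
  trial's own prespecified analysis.
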