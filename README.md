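# sifi — survival-inferred fragility index

How robust is a "positive" survival comparison? A phase-3 trial reports a
two-sided log-rank p value below .05 and the drug is judged effective —
but how many individual patients stand between that conclusion and its
reversal? The **survival-inferred fragility index (SIFI)** answers this
in patient units: it is the minimum number of *best survivors* (longest
follow-up, event or censored) that must be reassigned from the
experimental arm to the control arm before the two-sided unstratified
log-rank test loses significance at α. Comparisons that start
non-significant get a negative value: the number of mirror-image moves
needed to *gain* significance. A SIFI of +2 on a 600-patient trial says
the statistical conclusion hangs on two patients.

The package is aimed at trial methodologists and meta-researchers. It
provides:

- `sifi.sifi_core` — the SIFI algorithm with four variants
  (flip/clone × best/worst survivor) and full p-value trajectories;
- `sifi.johnson` — the comparator fragility measure that appends
  artificial mean-exposure event patients to the experimental arm;
- `sifi.logrank` — the unstratified log-rank engine
  (O−E = Σ d₁ₜ − dₜ·n₁ₜ/nₜ, hypergeometric variance, χ²₁ tail);
- `sifi.simulator` — a Weibull accelerated-failure-time trial generator
  (log HR = shape·β) and the 15 000-trial factorial reference grid;
- `sifi.km_reconstruct` — Guyot-class inversion of digitized
  Kaplan-Meier curves plus number-at-risk tables into individual patient
  data, with an at-risk discrepancy report;
- `sifi.trial_summary` — aggregate statistics over the packaged table of
  49 published immune-checkpoint-inhibitor comparisons (45 trials).

## Worked example

Simulate a 300-patient trial with hazard ratio exp(1.5·−0.4) ≈ 0.55,
then ask how fragile its (significant) result is:

```sh
$ sifi simulate --n 300 --beta -0.4 --seed 11 --out example.csv
wrote 300 subjects to example.csv
$ sifi compute --input example.csv --all-variants
SIFI=+5 p0=0.000455473 variant=flip_best
SIFI=+10 p0=0.000455473 variant=flip_worst
SIFI=+13 p0=0.000455473 variant=clone_best
SIFI=+19 p0=0.000455473 variant=clone_worst
$ sifi johnson --input example.csv
johnson=51 mean_exposure=0.0824755 p0=0.000455473
```

The trial starts at p ≈ 0.0005. Moving its five best experimental
survivors to the control arm is enough to push p above .05 — despite the
impressive initial p value, five patients carry the conclusion. The
alternative variants read higher, as they do on published trials
(flip_best is the most sensitive rule), and the artificial-patient
comparator is an order of magnitude larger (51), illustrating why
average "virtual" patients understate fragility at the extremes of the
curves.

The same analysis is available as a library:

```python
from sifi import read_ipd, compute_sifi, SIFIConfig

ds = read_ipd("example.csv")
res = compute_sifi(ds, SIFIConfig(alpha=0.05))
print(res.value, res.p_trajectory)
```

Reconstructing patient-level data from a published figure (digitized
curve coordinates plus the number-at-risk table) and summarizing the
packaged trial table:

```sh
sifi reconstruct --curve curve.csv --at-risk risk.csv \
    --out ipd.csv --report report.json
sifi summarize --table src/sifi/data/table1.csv
```

`summarize` prints, among other aggregates, a median SIFI of 5
(IQR −4 to 12) and a median sample size of 559 over the 49 packaged
comparisons — i.e. the conclusions of half of these phase-3 trials would
flip with a reassignment of about five patients or fewer.

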