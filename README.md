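# hrvrel

Analysis pipeline for **at-home heart rate variability (HRV) studies in
children**: ingest plain-text R-R interval exports, correct beat
artifacts, compute time- and frequency-domain HRV over the protocol's
windows, and quantify **test-retest reliability** of every parameter.

The protocol it models is a two-visit (day 1 / day 7) home measurement in
4–9-year-olds: a 5 min seated resting recording, then a sub-maximal step
test (30 s stabilisation, 3 min stepping at 88 steps/min, 2 min standing
recovery). The resting phase is analysed in the time domain (SDNN, RMSSD
and its natural log, NN50, pNN50) and the frequency domain (autoregressive
Burg spectrum; VLF/LF/HF band powers, normalized units, LF:HF); the
recovery phase is split into four 30 s windows analysed in the time domain
only. Step-test intensity is reported against the Tanaka age-predicted
maximal heart rate, MHR = 208 − 0.7 × age.

Reliability follows the Hopkins difference-score approach. For a
parameter measured twice on *n* subjects, with difference scores *d*:

- **TEM** (typical error of measurement) = SD(*d*) / √2, with a 90 %
  chi-square confidence interval on *n* − 1 degrees of freedom;
- **TEM% / CV** = 100 · TEM / grand mean, classified <5 % low, 5–10 %
  moderate, >10 % high;
- **Pearson r** with a 90 % Fisher-z interval,
  tanh(atanh r ∓ 1.645/√(n−3)), classified <0.5 poor, 0.5–0.75 moderate,
  0.75–0.9 good, ≥0.9 excellent.

Because no public recordings exist for this protocol, the package ships a
first-class synthetic-data module: sinusoidally modulated resting R-R
series (LF + HF tones plus noise), mono-exponential recovery kinetics,
artifact injection with ground truth, and paired test-retest cohorts with
known TEM or CV — so every stage is testable by parameter recovery.

## Worked example

`examples/04_reliability_study.py` simulates a complete 14-child two-day
study (four protocol phases per day, 2 % injected artifacts), runs the
whole pipeline and prints the resting reliability table:

```
parameter        TEM (90% CI)           TEM% (90% CI)          r (90% CI)           CV class / r class
mean_rr_ms       11.50 (8.77–17.09)     1.68 (1.28–2.50)       0.94 (0.84–0.98)     low / excellent
rmssd_ms         0.77 (0.59–1.14)       2.38 (1.82–3.54)       0.86 (0.67–0.95)     low / good
rmssd_ln         0.02 (0.02–0.03)       0.68 (0.51–1.00)       0.87 (0.69–0.95)     low / good
```

Mean resting R-R shows low absolute error (CV 1.7 %) and excellent
day-to-day correlation because the generator gives each child a stable
individual heart rate with only small day-to-day drift; RMSSD correlates
well across days while its between-child spread is small here, so reading
both TEM% and r together is the point of the table. The other examples
cover resting metrics (`01`), artifact correction with recall against
injected ground truth (`02`), and step-test recovery windows (`03`).

A command line wraps the same pipeline:

```sh
hrvrel simulate -o study/ -n 14 --seed 7
hrvrel analyze study/manifest.csv -o study/out
hrvrel metrics study/S000_day1_rest.txt --freq
```

`analyze` writes per-session metrics, reliability tables (CSV and
Markdown), beat-correction logs and a `run_metadata.yaml` recording every
parameter the run used.

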