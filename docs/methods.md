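# Methods

This note documents the models, parameter choices and numerical
conventions behind `afibvote`, and what the synthetic benchmark does and
does not demonstrate.

## The task and the evaluation model

Each record is a 30-s single-lead (Lead I) ECG at 300 Hz carrying one of
three labels: AFib, non-AFib, or noise (unreadable). Deployment is
binary — AFib positive, non-AFib ∪ noise negative — so per-cohort
performance is summarised by sensitivity `tp/(tp+fn)`, specificity
`tn/(tn+fp)`, PPV `tp/(tp+fp)`, NPV `tn/(tn+fn)`, the positive-class F1
(harmonic mean of PPV and sensitivity), the negative-class F1 (harmonic
mean of NPV and specificity), and their arithmetic mean (average F1).
Any metric with a zero denominator is *undefined* and carried as such,
never coerced to 0; composite aggregation refuses series containing
undefined entries.

Across N test cohorts with per-cohort values `P_i`:

* efficacy index `E_P = (1/N) Σ P_i`;
* variability index `V_P = sqrt( (1/(N-1)) Σ (P_i - E_P)^2 )` — the
  sample standard deviation;
* composite error–variability index, either the convex combination
  `C_P = α(1-E_P) + (1-α)V_P` with `α ∈ [0,1]` (default 0.5) or the
  unit-weights linear form `C_P = (1-E_P) + V_P`.

Both composite modes are implemented because the published comparison
tables are only consistent with the unit-weights form computed on
*unrounded* per-cohort values (the convex form at α = 0.5 is exactly
half of it); `unit_weights` is therefore the default, and `convex` is
available for the bounded-combination semantics. Table values are
rounded half-away-from-zero at 3 decimals after aggregation.

Two cells of the published tables are internally inconsistent with
their own confusion counts and are flagged rather than patched: one
proprietary-algorithm row's counts fall 208 records short of its cohort
total and its printed NPV (0.992) recomputes to 0.993; and the voting
PPV composite prints 0.119, which only matches combining the already
rounded E and V (unrounded values give 0.120), while the specificity
composite requires the unrounded convention. The reproduction table
(`afibvote reproduce-tables`) reports these honestly as known
discrepancies; all other 44 cells reproduce exactly.

A dataset-size-weighted E/V variant is provided
(`weighted_composite_indices`) but is not the default.

## Synthetic cohorts

The generator emulates the structure of proprietary wearable-ECG
cohorts; it makes no claim of physiological fidelity beyond the features
the base detectors and fusion stage actually consume.

**Beat timing.** RR sequences per rhythm class:

* *AFib*: i.i.d. log-normal intervals matched to a target coefficient of
  variation (per-record CV drawn from 0.16–0.30, mean rate 70–140 bpm),
  randomly permuted — an exchangeable, "irregularly irregular" sequence
  with lag-1 autocorrelation centred at 0.
* *Sinus / tachycardia / bradycardia*: AR(1) Gaussian modulation
  (lag-1 correlation 0.3–0.5) with optional respiratory sinus
  arrhythmia; per-record CV 0.02–0.08. An `ectopic_rate` parameter
  inserts isolated premature beats (interval ×0.6) with compensatory
  pauses (×1.4), the classic isolated-PAC/PVC false-positive source for
  RR-irregularity detectors.
* *Bigeminy*: deterministic alternation of short/long coupled intervals
  (±20–40% of the mean) — "regularly irregular".
* *Flutter-like*: fast (125–160 bpm) but regular ventricular response.

Intervals are clipped to 250–3000 ms. Durations and sampling rate
default to 30 s and 300 Hz, both configurable.

**Waveforms.** Each beat is a sum of Gaussian P/Q/R/S/T deflections
(R = 1.0 mV, 16 ms width; P = 0.15 mV at −180 ms). AFib records omit the
P deflection and add a fibrillatory oscillation of three seeded
sinusoids in 4–9 Hz with total amplitude ≤ 0.1 mV; flutter-like records
replace P waves with a continuous 5 Hz 0.15 mV wave. All records carry
mild (< 0.03 mV) baseline wander plus white noise at the cohort's
`noise_level`. Noise-class records are white noise + strong sub-0.5 Hz
wander + motion bursts, with no QRS structure.

**Cohort presets.** Four presets mirror the published cohort roles with
their AFib prevalences (train-like 5.4%, watch-like 9.5%, hand-held
16.6% and 9.5%). Distribution shift is carried by a per-cohort
`DifficultyProfile`: broadband-noise amplitude (0.05–0.12 mV), the share
of hard non-AFib subtypes (bigeminy/flutter, 10–30%), and the share of
easy non-AFib records given ectopy (10–30%). These difficulty values
were chosen so that the individual base detectors land in the published
mid-0.8-to-mid-0.9 average-F1 regime — hard enough that no single
irregularity statistic separates the classes perfectly, with
cohort-to-cohort differences large enough to expose robustness gaps.
Class counts realise the requested mix exactly via largest-remainder
rounding; all generation is bit-reproducible from (seed, parameters).

**What the generator does not model** (hence what passing tests do not
show about real data): P-wave morphology subtleties, wide-QRS ectopy,
pacemaker artifacts, multi-lead information, electrode-specific transfer
functions, or the demographic case-mix drift of real cohorts. The shift
between synthetic cohorts is purely the difficulty-profile mechanism
above, so the benchmark demonstrates the *relative* robustness ordering
of fusion vs base detectors under controlled shift, not absolute
performance on any real device.

**Simulated detector matrices.** For fusion/ranking tests that need no
signal processing, detector outputs are simulated directly: each record
has a latent difficulty `u ~ N(0,1)`; detector d observes
`z = sqrt(ρ)u + sqrt(1-ρ)e_d` and calls positive when `z` is below the
Gaussian quantile matching its marginal sensitivity (AFib rows) or
false-positive rate (other rows); the emitted score `Φ(cut − z)` crosses
0.5 exactly at the decision boundary, so a perfect detector emits the
truth indicator exactly and `ρ` controls shared errors.

## Base detectors

R-peak detection is energy-based: 5–18 Hz band-pass (2nd-order
Butterworth, zero-phase), derivative, squaring, 150 ms moving-window
integration, peak acceptance above 35% of the 98th-percentile energy
with a 200 ms refractory period, followed by refinement to the local
band-passed maximum. All thresholds are relative to the signal's own
scale, so detection is amplitude-invariant.

RR statistics (requiring ≥ 5 beats; fewer raises an explicit
insufficient-data error and maps the record's posterior to (0, 0, 1)):
normalised RMSSD `sqrt(mean ΔRR²)/mean RR`; ΔRR Shannon entropy over 16
fixed bins spanning ±600 ms (values outside are clipped into the edge
bins); sample entropy with m = 1 and absolute tolerance r = 30 ms on the
millisecond series (N−m templates at both lengths; no matches at length
m+1 returns the standard upper bound log B, none at length m returns 0);
turning-point ratio (strict local extrema among interior intervals);
CV and normalised MAD. Signal quality is the fraction of mean-removed
Welch power inside 1–40 Hz — broadband noise spreads power toward the
150 Hz Nyquist and wander concentrates it below 1 Hz, so the score
decreases with either contamination.

Each detector's raw statistic is mapped to an AFib probability by a
logistic fit (AFib vs non-AFib, noise records excluded) on the training
cohort; the noise posterior comes from a shared quality gate — a
logistic soft edge of width 0.05 at the threshold that maximises
balanced accuracy separating noise from readable records. The
quality-gate detector itself uses the quality score as its statistic: it
is by construction a noise detector with only incidental rhythm
information, and serves as the deliberately weak member of the pool.

## Forest, ranking, fusion

The voting classifier is a bagged ensemble of 500 CART trees (Gini,
sqrt(p) candidate features per split, grown to purity, min leaf 1), each
trained on an n-of-n bootstrap with explicit per-tree out-of-bag
bookkeeping. The continuous output is the per-class fraction of hard
tree votes; majority ties break toward non-AFib, then noise, then AFib
(fewest false AFib alarms). OOB error predicts each training row by
majority vote among only the trees for which it is out-of-bag, excluding
rows in-bag everywhere.

Permutation importance shuffles one feature within each tree's OOB rows
(seeded per feature × tree × repeat, 5 repeats by default) and averages
the per-tree OOB-error increase; the reported SE is the across-tree
standard error. The *ranking-stage* forest uses min leaf 5: with fully
grown trees, permutation importance gives label-independent features a
small positive bias (deep splits fit in-bag noise), and the mild
regularisation removes it while leaving the ranking of informative
features unchanged. Top-k selection breaks importance ties toward the
smaller original column index.

Thresholding the fused AFib score supports two strategies: a uniform
0.5, or a per-cohort operating point from a seeded stratified subsample
(default 20%) maximising Youden's J on that subsample's ROC. Youden's J
was chosen as the operating-point criterion because it is standard and
parameter-free; the score == threshold boundary counts as positive, fixed
for bit-exact reproducibility. The benchmark applies the same strategy
to every base detector for a fair comparison.

## Benchmark protocol and problem sizes

The default benchmark trains on a 900-record train-like cohort and
evaluates on three 600-record shifted cohorts; ranking uses 5
permutation repeats, and the full run takes tens of seconds on one CPU.
These sizes give class counts large enough for stable per-cohort metrics
(≥ 57 AFib records per test cohort) while keeping the whole suite quick
to re-run; the acceptance-grade properties (fusion's composite average-F1
index minimal across all seven algorithms) hold across independent
benchmark seeds. Cross-validation of the fusion on its training cohort
(10-fold stratified) is available via `kfold_cv`; stratification uses
the 3-class labels when every class supports k folds, else the binary
reduction, and leave-one-out falls back to unstratified folds.

## Known limitations

* The six base detectors are RR-interval statistics only; no morphology
  (P-wave delineation, QRS width) information enters the pool, so the
  synthetic flutter-like confounder is hard for every member.
* Serialisation of a fitted ensemble uses JSON metadata plus a joblib
  blob for the tree objects; re-fitting from (config, seed) is the
  canonical reproduction path.
* Composite indices carry no confidence intervals; they are descriptive
  summaries over a small number of cohorts.
* The screening-scenario PPV is a closed-form expectation
  `100·n·prev·sen / (n·prev·sen + n(1-prev)(1-spe))`, not a simulation.
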