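# Methods

This note records the models, parameter choices and numerical conventions
behind `mmnstudy`, and what the simulation-based validation does and does
not establish.

## Oddball paradigm

The stimulus set follows the multifeature oddball design: a standard
complex tone built from three summed sinusoids (7,500, 8,000, 8,500 Hz,
equal weight), 75 ms long with 5 ms rise/fall ramps, and four deviant
classes — all three components shifted +10 % (8,250/8,800/9,350 Hz) or
−10 % (6,750/7,200/7,650 Hz), a shortened 25 ms version (15 ms plateau,
5 ms ramps), and a 7 ms silent gap centred in the standard with 1 ms edge
ramps (≥5 ms of exact zeros). Ramps are raised-cosine by default
(configurable to linear); the half-window shape avoids spectral splatter
where the design itself names no ramp shape. Audio is rendered at
44.1 kHz, sample counts rounded from durations.

Blocks hold 91 trials: 10 warm-up standards, then strict
deviant/standard alternation starting and ending with a deviant, so no two
standards are ever adjacent after the warm-up and every deviant follows a
standard. That yields 41 deviants and 50 standards per block (45 % deviants
overall). A nominal "50 % deviants" is arithmetically incompatible with 91
trials, a 10-standard warm-up and the alternation constraint; the generator
enforces the structural constraints, which are checkable, and reports the
realized proportions. The four deviant classes are mixed within each
block in as-equal-as-possible counts (the remainder assigned at random),
which also realises the half-higher/half-lower split of frequency-deviant
trials up to rounding.

The inter-stimulus interval of 900 ms is read offset-to-onset (SOA 975 ms
for a 75 ms stimulus); only this reading makes the 4 × 91 schedule span
~352 s ≈ 6 min. The schedule span is measured from first onset to last
stimulus offset. All sequencing randomness flows from a single integer
seed through one `numpy` generator.

## Synthetic EEG

Recordings are 31 channels (29 scalp sites including the mastoids M1/M2,
nose reference, plus infra-orbital and outer-canthus EOG) at 1,024 Hz, in
μV. The forward model is a linear instantaneous mixture:

* every stimulus evokes N1 (−4 μV at 100 ms, 15 ms SD) and P2 (+3 μV at
  180 ms, 25 ms SD) Gaussian kernels; deviants additionally evoke an MMN
  Gaussian (25 ms SD) with the subject's class-specific amplitude and
  latency. Gaussians give closed-form checks of every downstream
  measurement; the obligatory components cancel exactly in the difference
  wave, as they must.
* the cortical topography assigns gain 1.0 to the frontocentral ROI, 0.5
  to its immediate neighbours, 0.1 to far sites and −0.4 to the mastoids,
  reproducing the polarity-reversal validity criterion under a nose
  reference; EOG channels carry no cortical signal.
* noise comprises per-channel 1/f background (default 8 μV RMS; exponent
  configurable, 0 gives white noise), posterior-dominant 10 Hz alpha with
  slow amplitude modulation (3 μV RMS), frontal-dominant eye blinks
  (300 ms Hann pulses, 150 μV on EOG, 12/min Poisson), and optional 50 Hz
  common-mode line interference (off by default, since the emulated
  acquisition chain notches it out).

Per-subject MMN amplitudes and latencies are independent normal draws from
the published group means/SDs (three groups, four deviant classes),
truncated to amplitude ≤ 0 and latency ∈ [100, 250] ms. The published SDs
are used as between-subject SDs; trial-to-trial MMN variability is
unreported in the source cohort and defaults to zero (the amplitude knob
exists on the profile). With the default parameters the truncation is
3+ SDs from the means and its bias is negligible.

What the simulator does **not** emulate: volume-conduction head models,
channel-specific noise spectra, non-stationary artifacts (sweat, movement,
electrode pops), heartbeat, or overlapping-source topography differences
between N1/P2/MMN. Passing recovery tests therefore shows the analysis
chain is correct and unbiased under a linear-superposition model with
known truth — not that it is robust to every pathology of real EEG.

## Preprocessing

* Band-pass: 4th-order Butterworth, 1–20 Hz, applied forward-backward
  (`sosfiltfilt`) for zero phase; EOG channels filtered identically so the
  ICA sees a consistent mixture.
* Ocular removal: FastICA over scalp+EOG channels, PCA-reduced to 20
  components and fitted on 8-fold decimated samples for tractability,
  applied at full rate. Components whose time courses correlate with an
  EOG channel at |r| > 0.7 are identified automatically (replacing visual
  inspection) and only their contribution is subtracted, leaving variance
  outside the retained subspace untouched. A least-squares EOG regression
  is available by configuration and is the automatic fallback when the
  decomposition fails; recordings with silent EOG channels are returned
  unchanged.
* Epochs span −50…+900 ms around each onset (974 samples at 1,024 Hz);
  the prestimulus mean is subtracted per channel. Events without full
  epoch support are flagged (`edge`), never silently dropped.
* Rejection flags trials whose absolute post-baseline amplitude exceeds
  50 μV on any scalp channel (EOG excluded — it is not a scalp site);
  rejection runs after ICA. Warm-up standards are flagged (`warmup`)
  rather than deleted; all averaging uses kept trials only.

## Feature measurement

Features are measured on the ROI-averaged difference wave (collapse first,
then measure; measuring per electrode and averaging afterwards is exposed
as an alternative through the evoked API since peak-picking does not
commute with averaging). The MMN peak is the most negative sample in
100–250 ms, earliest sample on ties, at native sample resolution (<1 ms
quantisation at 1,024 Hz). The amplitude reference is the value of the
local maximum nearest in time to the peak, searched on both sides with the
preceding side preferred on ties, falling back to the 0 μV prestimulus
baseline when the wave has no interior maximum — a deterministic reading
of "nearest extremum" referencing. AUC integrates (reference − wave) by
the trapezoidal rule over the contiguous sub-reference interval containing
the peak, ending at linearly interpolated reference crossings or the epoch
edges.

Two consequences worth knowing. First, the 1 Hz high-pass slightly
attenuates the MMN pulse (a few percent for a 25 ms-SD Gaussian) — the
noise-free integrity check bounds the full-chain error at ~1.5 %, well
inside the 10 % filter-ringing allowance. Second, when the difference wave
hovers just below the reference level late in the epoch (the high-pass
recovery of neighbouring deviants' MMN leaks into standard epochs), the
AUC interval can extend to the epoch edge and inflate the area; this is a
property of the crossing-bounded definition itself, amplitude and latency
are unaffected.

## Statistics

Between groups: fixed-effects one-way ANOVA per feature × deviant class
with Tukey HSD post-hocs. Within groups: one-factor repeated-measures
ANOVA over the four deviant classes, F = MS_condition / MS_(condition ×
subject) with uncorrected df (3, 57) at n = 20 — matching the published
df convention — and Greenhouse–Geisser correction behind a flag; post-hocs
are paired t tests with Bonferroni adjustment (p × 6 pairs, capped at 1).
Demographics use pooled-variance (Student) two-sample t — recomputing the
published severity contrasts from their printed moments matches the pooled
form, not Welch — and two-sided Mann–Whitney U with tie correction (exact
for small untied samples). No correction is applied across the twelve
between-group ANOVAs, matching the source analysis plan; p-values are
reported to four decimals.

`anova_from_summary` and `t_from_summary` recompute the same tests from
group (mean, SD, n) alone; they agree with the raw-data forms to 1e−10
when fed a dataset's own moments. Recomputing the published tables from
their printed moments reproduces 20 of 28 rows within 2 %; the remainder
(including the higher-frequency amplitude F, 13.01 recomputed vs 13.41
printed) sit within ~5 %, consistent with the printed moments being rounded
to two decimals. One documented inconsistency in the source: its Results
prose calls the decompensated-group MMNs "larger" while the table, figures
and abstract show lower (less negative) amplitude and smaller AUC; the
package follows the table.

## Validation experiments and problem sizes

* Noise-free integrity: 6 subjects (2/group), full pipeline; max
  amplitude error ~1.4 %, mastoid reversal on 6/6.
* Type-I calibration: 5,000 summary-level null replicates (3 × 20 normal
  draws each), rejection at α = 0.05 within 5 % ± 1.5 %.
* Power: 1,000 summary-level replicates under the published
  higher-frequency amplitude separation; rejection at α = 0.01 > 95 %.
* Parameter recovery: 20 subjects/group, full 4 × 91-trial paradigm,
  default noise (1/f + alpha + blinks), ICA removal; recovered group means
  preserve the compensated < control < decompensated ordering, lie within
  2 SEM of the injected means, and the between-group ANOVA rejects far
  below α = 0.01. One replicate (~6 min on one CPU) — the recovery of a
  single cohort, not a sampling distribution over cohorts; the demo driver
  exposes a scaled-down n for quick runs.

## Known limitations

* The ICA criterion keys on EOG correlation only; cardiac or muscle
  components (not simulated) would pass through.
* Latencies are sample-quantised; no sub-sample interpolation.
* The AUC edge-truncation behaviour described above makes simulated AUCs
  larger than the published ones in absolute terms; comparisons across
  groups remain valid since the bias is shared.
* EDF+ export is not provided; recordings use the FIF container (data
  stored as float32 volts) with a sidecar events CSV.
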