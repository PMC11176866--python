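# Methods

This note records the analysis conventions, the synthetic-data design and
the numerical choices behind `hrvidh`, in the order of the pipeline.

## RR preprocessing

**Ectopic exclusion.** An interval is flagged ectopic when it deviates by
more than 20 % from the *most recent accepted* interval; the first
interval has no predecessor and is never flagged. Comparing against the
last accepted (rather than the immediately preceding raw) interval stops a
single ectopic from dragging the next normal beat over the threshold.
That rule has one failure mode: if the initial reference interval is
itself corrupted, every subsequent normal beat deviates from it and the
whole recording would be flagged. The filter therefore re-anchors after 5
consecutive flags by accepting the current interval. Flags never delete
data; downstream stages skip flagged intervals.

**Segmentation.** Analysis windows are 300 s, aligned to the wall clock
(00:00, 00:05, …) rather than to the recording start, so segment
boundaries are reproducible across devices. Only windows inside the
00:00–04:00 night window are analysed — night-time data avoid the
confounding of daytime activity on autonomic tone. A window is kept when
its accepted beats reach 80 % of the expected count (window length /
median accepted interval); this threshold doubles as the coverage rule
for windows only partly spanned by the recording. Both the window and the
threshold are configurable.

**Time-domain statistics.** SDNN is the *population* SD within a segment
(the n vs n−1 distinction is negligible at ~350 beats but is fixed for
exactness). Successive-difference statistics (RMSSD, NN50) use only pairs
that were adjacent in the original recording — an exclusion breaks the
chain instead of bridging it, because a bridged pair is not a physiologic
pair of successive beats. pNN50 divides NN50 by the number of intervals
(not pairs). The night average is the unweighted arithmetic mean over
segments; the LF:HF ratio is averaged as the mean of per-segment ratios,
not the ratio of pooled powers.

## Spectral analysis

The accepted intervals are interpolated linearly onto a 4-Hz grid (each
interval anchored at the time of the beat that ends it; excluded
intervals contribute no anchors and a bridged gap longer than 5 s marks
the segment low-quality). The PSD is a Welch periodogram: 64-s Hann
windows, 75 % overlap, per-window mean removal, one-sided density
normalised so its integral matches the signal variance (Parseval).

**Band integration.** Band powers are Riemann bin sums of the density
over half-open bands [low, high): with a 1/64-Hz bin width the VLF band
covers bins 1–2, LF bins 3–9 and HF bins 10–25. TP is the band-limited
integral over [0.003, 0.40) — the short-term convention — and because the
bins partition that range, **TP = VLF + LF + HF holds exactly**. A
trapezoidal rule was rejected: it leaves the panels straddling band
boundaries in no band, so TP exceeded the band sum by up to ~40 % on
realistic spectra. The LF:HF ratio is reported missing (not infinite)
when HF is zero.

**Known attenuations.** Two physical effects make band powers recovered
from beat-sampled data smaller than the generating amplitudes suggest:

* linear interpolation of a signal sampled at the beat rate f_b
  attenuates a sinusoid at f by sinc⁴(f/f_b) in power (≈ 0.77 for HF at
  75 bpm) — `resampling_attenuation()` gives the closed form;
* a 64-s window spans at most 2.5 VLF periods, so VLF power is only
  partially resolved (≈ 89 % of a 0.03-Hz sinusoid lands in the VLF band;
  a 0.01-Hz component is mostly absorbed by per-window mean removal).

Both are properties of the stated analysis settings, not defects; the
synthetic generator pre-emphasises its amplitudes by the inverse factors
so that *extracted* band powers land on the intended scale, and the
recovery tests assert the attenuated closed forms.

## Outcomes

A session is IDH when its nadir (minimum intradialytic SBP reading) is
≤ 90 mmHg, or ≤ 100 mmHg when the pre-dialysis SBP was ≥ 160 mmHg; both
thresholds inclusive, no drop-from-baseline requirement (eligibility
already guarantees pre-dialysis SBP ≥ 90). An unmonitored session is an
error, never a silent non-IDH. A patient is *any-IDH* after one such
session and *repeated-IDH* when strictly more than 10 % of monitored
sessions were IDH — so 1 of 12 does not qualify and 2 of 12 does.

## The index and model fitting

The published index applies its coefficients to raw-scale features (NN50
as a count, powers in ms², ratio dimensionless); evaluating it at the two
groups' mean profiles lands on opposite sides of the 0.544 cutoff (0.336
vs 0.713), which is the consistency check for that scale convention. The
published model ships as an immutable constant; refits never overwrite
it. Dysfunction classification is inclusive (index ≥ cutoff).

Refitting uses iteratively reweighted least squares: convergence when the
largest coefficient update < 1e-8, cap 100 iterations, weighted
least-squares step solved by `lstsq` for rank-safety. Complete separation
is detected when every fitted probability collapses onto its own label
(all |y − p̂| < 1e-6) and raises an explicit error instead of returning
divergent coefficients. Feature selection offers backward elimination by
Wald p (threshold 0.1, the default) or by AIC; the elimination path is
returned. The selection procedure used to develop the original index is not
public, so the default here is a documented choice, not a reproduction.

## Evaluation statistics

AUROC uses the rank (Mann–Whitney) formulation with mid-rank tie
handling; no AUROC CI is reported. The Youden cutoff is always an
observed score; ties are broken toward higher specificity (a fixed,
documented convention). Odds ratios are ad/bc with the Woolf interval
exp(ln OR ± 1.959964·√(1/a+1/b+1/c+1/d)); zero cells raise unless the
Haldane–Anscombe +0.5 correction is explicitly requested. Group
comparisons use the pooled-variance t-test for continuous variables and
Pearson chi-square (no continuity correction) with an automatic Fisher
fallback when any expected cell is below 5. Spearman ρ is the Pearson
correlation of mid-ranks and is reported missing for constant input.
Nagelkerke R² = (1 − (L0/L1)^(2/n)) / (1 − L0^(2/n)); the Hosmer–Lemeshow
test uses deciles of predicted risk (duplicate quantile edges merged),
χ² reference with g − 2 degrees of freedom, and is reported missing with
a reason when fewer than 3 groups survive merging. Degenerate two-group
comparisons with zero variance and equal means return p = 1 by
convention.

## Synthetic cohort design

The generator is the package's test-bed and demonstration cohort; its
defaults are fixed study conditions, not tuning knobs.

**RR series** are additive tachograms: interval(t) = mean + VLF + LF + HF
sinusoids + white jitter, with two sparse event processes — ectopics
(interval ×1.5, ground truth recorded, default rate 0.3 %), and "vagal
spikes" (single-beat ±~65 ms excursions) that create NN50 pairs without
crossing the 20 % ectopic threshold. The additive-sinusoid choice makes
every band power a closed form (A²/2), which is what lets the spectral
engine be verified exactly. Non-positive draws are resampled (> 1 %
triggers a warning). Generation is a pure function of (profile, seed).

**HRV tables.** Each patient belongs to an IDH-prone or non-prone group;
parameters are drawn from group-level truncated normal distributions
whose means/SDs follow the published group comparison. TP is derived as
VLF + LF + HF (the band-limited convention above) and the ratio as
LF / max(HF, 5) — drawing TP or the ratio independently would make the
records internally inconsistent and the index degenerate, since the TP
coefficient would then act on variation the band terms cannot cancel.
The two test occasions share a patient-level random effect with weight
`test_retest_corr` (default 0.95, calibrated so the index's test-retest
Spearman ρ lands near 0.86 — a calibration default, not a claim about
true within-patient variance, which is not publicly reported).
Cohort RR profiles encode the drawn band powers with the attenuation
pre-emphasis (VLF sinusoid placed at 0.03 Hz so the Welch window can
resolve it) and a spike rate targeting the drawn NN50.

**Sessions.** Pre-dialysis SBP is drawn per group (≈ N(146–150, 19–25),
truncated at 90 per eligibility). Intradialytic SBP declines linearly to
a total drop of `base_drop + score_gain·score` mmHg (clipped at 0) plus a
session-level Gaussian shock and small per-reading noise; the patient's
score is the published index evaluated on their first HRV test. Defaults
(base 0, gain 31, session SD 24, reading SD 3, 4 hourly readings) are
calibrated so that the induced session-level IDH incidence sits near
12.6 % with any-IDH ≈ 50 % and repeated-IDH ≈ 30 % of patients at the
70-patient scale. P(IDH) is non-decreasing in the score by construction.

**What the generator does not emulate.** Real RR series have broadband
1/f structure, circadian drift and autocorrelated ectopy rather than
stationary sinusoids plus white events; real time-domain and spectral
features co-vary through one physiology rather than through correlated
draws; and BP trajectories have intra-session interventions (saline,
ultrafiltration changes) that the linear-decline model ignores. Passing
tests therefore demonstrate that the *analysis chain* is correct and
calibrated under a known generative model — not that the index would
reproduce its published discrimination on new patients.

## Problem sizes and runtime

The default test suite simulates recordings of minutes-to-hours and
cohorts of 6–400 patients (5000 for coefficient recovery, 500 replicates
of n = 2000 for Hosmer–Lemeshow calibration); the full suite runs in
well under a minute on one CPU. The acceptance script uses ten 70-patient
replicate cohorts for incidence (8400 sessions) and the same recovery and
calibration sizes. The end-to-end study replica (70 patients × two 5-h
recordings) takes ~15 s, dominated by beat-by-beat RR generation.

## Known limitations

* Whether the original device computes TP as total variance or a
  band-limited integral is unknown; the band-limited choice is the main
  candidate source of scale discrepancy against the published table.
* The ectopic reference ("preceding beats") is read as the last accepted
  interval; the raw-predecessor reading would cascade after each ectopic.
* VLF at its physiological centre (~0.01 Hz) is not resolvable with 64-s
  windows; recovered VLF is meaningful only for components ≳ 0.025 Hz.
* The two operating points quoted for the published index (accuracy /
  recall / precision vs sensitivity / specificity) are not mutually
  consistent with a single confusion matrix; both are supported, neither
  asserted.
* Refit indices, selection paths and the multivariate model in the study
  replica are conditional on the synthetic cohort's simplifications
  listed above.
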