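# Methods

This note documents the models, rules and numerical choices behind
`arousalkit`, and what the synthetic-data experiments do and do not show.

## Preprocessing

Recordings are band-passed 0.5–70 Hz (Butterworth order 4, forward–backward
so segment boundaries are not phase-shifted) with a 50 Hz notch (Q = 30).
EOG channels get a lower high-pass edge (`filter.eog_low_hz`, default
0.1 Hz): slow eye movements live largely below 0.5 Hz and would otherwise be
removed before SEM detection.  EEG channels are re-referenced to their
common average (EOG excluded).  Ocular correction, done with ICA in the
study this package models, is replaced by an optional deterministic
least-squares EOG regression (`preprocess.eog_regression`, default off):
component selection is not reproducible from a methods description, a
projection is.

Artifact marking, manual in the original workflow, is replaced by explicit
rules on the 1-s segment grid: a segment is invalid when it overlaps an
`artifact` annotation, when any EEG channel's peak-to-peak amplitude
exceeds `artifact.pp_max_uv` (default 200 µV), or when any channel is flat
(< 0.5 µV peak-to-peak).  These defaults are conventional clinical-EEG
rejection values; the original workflow published none.  Masking is
monotone in the annotation set, and graphoelement annotations (spindle,
K-complex) never invalidate segments — they are staging evidence.

## Vigilance staging

Each valid 1-s segment is classified from scalp-region band powers
(periodogram of the segment, same Hanning/0.5 Hz machinery as the spectral
module, averaged within frontal {F3, F4, Fz}, central {C3, C4, Cz},
parietal {P3, P4, Pz} and occipital {O1, O2} regions).  Source localisation
is deliberately not used; the stage phenomenology (where alpha sits, how
strong slow activity is) is expressible on scalp topography, and an
anterior/posterior alpha ratio

    r = (frontal + central alpha power) / (parietal + occipital alpha power)

stands in for the anteriorisation the A-substages describe.  This is the
package's largest declared deviation from the staging tool used in the
modelled study, whose internal thresholds are not published; agreement with
that tool's numeric output is therefore not claimed anywhere.

Decision cascade, first match wins (deeper-stage evidence dominates —
consistent with a score that indexes depth of decline):

1. segment overlaps a spindle/K-complex annotation → **C**.  No automatic
   graphoelement detector is provided; the modelled workflow also relied on
   expert tagging.
2. ROI-mean (delta+theta) > `slow_ratio` × ROI-mean alpha **and** ROI-mean
   total power > `low_voltage_uv2` → **B2/3** (defaults 2.0 and 10 µV²).
3. posterior or global alpha > the calibrated alpha threshold →
   **A1** (r < 0.5), **A3** (r > 1.0), else **A2**.  An undefined ratio
   (zero posterior alpha) falls through.
4. otherwise **B1** when SEM evidence is present, else **0**.

The alpha threshold adapts to the subject: one third (`alpha_fraction`) of
the median posterior alpha power over the recording's alpha-rich segments
(those at or above the 25th percentile), floored at `alpha_floor_uv2`
(20 µV²) so alpha-poor recordings do not collapse the threshold onto the
noise floor.  The threshold therefore scales with the square of signal
amplitude, making staging amplitude-equivariant (the fixed artifact
ceiling, intentionally, is not).

SEM evidence: the horizontal EOG is filtered to 0.1–1 Hz; a segment carries
SEM evidence when a window of ±2 s around it contains a deflection
exceeding `sem_amp_uv` (30 µV) for at least `sem_min_s` (0.5 s).

## Stability score

Scanned exactly as defined in the README: sliding 60-s epochs, step 1 s;
fractions are computed over each epoch's *valid* seconds, and epochs with
fewer than 45 valid seconds are excluded from fulfilment scanning.  Reading
of the published criteria that needed a decision:

* "at least 1/3 of all segments" is read per 60-s epoch (the epochs are
  what the criteria are tested on); the "more than 2/3" criteria for scores
  10/11 carry no time qualifier and are read over the whole recording.
* Fulfilments are attributed to thirds by the epoch's *start* second
  (half-open boundaries at 300 s and 600 s); C occurrences by the segment's
  own second.
* When several conditions hold, the deepest stage wins, then the earliest
  third (C over B2/3 over B1) — a deeper decline is a steeper decline.
* A recording that fulfils nothing and is not 0/A-dominated gets the
  explicit sentinel `unclassified` rather than a forced score; silently
  assigning one would contaminate group statistics.
* Scoring requires ≥ 300 valid seconds (`stability.min_coverage_s`).

A brute-force evaluator (`stability_score_bruteforce`) enumerates every
epoch naively and applies the rules literally; the optimised sliding scorer
is required to agree with it exactly (value, condition and triggering
epoch) on randomised sequences.

The mean-vigilance time course averages the numeric stage values
(0→7 … C→1; the descending 7..1 mapping is this package's declared choice)
over consecutive 3-min blocks, valid seconds only.  The median split labels
scores below the sample median "unstable", above it "stable"; ties at the
median go to the side configured by `stability.at_median` (default stable,
matching the published group sizes where the median scorer sits in the
stable group).

## Spectral analysis

Band powers use the full recording at 256 Hz (polyphase down-sampling, no
upsampling), non-overlapping 1-s Hanning windows on the same grid as the
staging segments, sharing their validity mask.  A stated resolution of
0.5 Hz is not attainable from an unpadded 1-s window, so each window is
zero-padded to 2 s (`spectral.zero_pad`, switchable for sensitivity
analysis).  Powers are normalised by the window energy so a sinusoid of
amplitude *a* at an in-band frequency contributes exactly *a*²/2, which
makes the Parseval partition check exact.  Band edges are inclusive at the
0.5 Hz bin spacing (delta 1.0–3.0 Hz, …); the gaps between published band
limits (3→4, 7→8, 12→13 Hz) mean no bin is shared.  Window powers are
averaged per channel, channels per region, and the ln is taken last.

## Statistics

All statistics are computed from their formulas so they work from printed
group summaries (n, mean, sample SD) as well as raw columns: pooled t
(df = n₁+n₂−2), Welch t (Satterthwaite df), Pearson χ² without continuity
correction, η² = SSB/(SSB+SSW) with Eta = √η², Cohen's d = |Δmean|/pooled
SD.  Two-sided p-values throughout; no multiple-testing correction by
default (a Benjamini–Hochberg option exists, off, mirroring the modelled
analysis).  Sign conventions: t carries unstable − stable; signed Eta
carries stable − unstable.  The cohort report uses the pooled t unless the
group variance ratio exceeds 4 (`stats.welch_variance_ratio`), mirroring
the mix of integer and fractional dfs in the published tables.

The embedded reference table (`arousalkit.reference_values`) records which
published cells are *not* recomputable from their own printed inputs (the
BDI group T, the BDI-proportion χ², the age T, and the printed Cohen's d
values for the power contrasts, which match no standard d-from-t
conversion); these are reported but never asserted against, and the power
effect sizes used by the generator are derived from the published T
statistics instead (d = T·√(1/13+1/18)).

## Synthetic data: what it emulates, and what it does not

**Trajectories** are first-order Markov walks over the ordered stages with
per-second decline/recovery probabilities — the simplest process giving
monotone arousal decline with controllable steepness.  The `unstable`
profile (decline 0.025, recovery 0.004) reaches B2/3 or C early; the
`stable` profile (decline 0.005, recovery 0.02) mixes quickly with its
stationary mass in 0/A1, so group-mean vigilance stays flat across blocks —
the hyperstable "lack of downregulation" phenomenology.  `random_subject`
draws decline log-uniformly in [0.003, 0.03] with recovery a fraction
[0.05, 0.4] of it, spanning scores 1–11.  Every trajectory carries its
analytic ground-truth score from the brute-force evaluator.

**EEG synthesis** realises a trajectory as band-limited noise shaped by
per-stage region amplitude recipes (A1: occipitally dominant alpha; A2/A3:
progressively anteriorised alpha; B2/3 and C: dominant delta/theta; 0 and
B1: low-voltage broadband), with 100 ms crossfades at stage changes, a
0.7 µV broadband noise floor, one coherent 0.4 Hz / 60 µV SEM oscillation
per contiguous SEM span in the HEOG (per-second incoherent waveforms cancel
each other — a lesson learned and tested), spindle/K-complex annotations
during C seconds (rate 0.9/s), and SEM coverage of 0.9 per B1 second
(SEMs are definitional for B1).  Not modelled: 1/f background structure,
ECG/EMG contamination, electrode drift, inter-subject montage variation.
Pipeline round-trip results on this data bound *algorithmic* recovery — the
staging cascade, calibration and score rules — not performance on clinical
recordings.

**Cohorts** draw per-group stability scores from discrete distributions
matching the published means/SDs (unstable 3.08 (1.04) on {1..5}, stable
8.89 (1.37) on {7..11}); the stable support starts at 7 because group
labels are assigned by the pipeline's own median split on the drawn scores,
and reproducing the designed 13/18 groups through a data-driven split
requires the designed groups to be separated by the realised median (the
published stable group evidently contained median scorers, which a
data-driven split cannot re-create without relabeling).  Questionnaire,
demographic and nominal variables use the published per-group summaries and
proportions; the BDI is drawn as a clipped-at-zero normal whose generating
mean is pre-compensated (fixed-point on the truncation bias) so the clipped
sample mean matches the printed one.  ln band powers are normal with SD 0.8
(a typical between-subject spread for ln power) around band baselines
(δ 3.0, θ 2.5, α 3.0, β 1.5 ln µV²), with delta/theta group shifts of
d·SD implied by the published T statistics and no alpha/beta shifts.
Missingness is Bernoulli per variable at the published available-n rates.
Questionnaire values are drawn independently of the EEG synthesis; the
modelled study reports no within-subject coupling beyond group membership.

The "qualitative pattern" experiment tests, per replicate cohort, one
t-test per band on the region-averaged ln power (regions are independent
draws, so the region average is the natural band-level contrast; at the
published per-region effect sizes and n = 13/18, requiring all eight
delta/theta regional tests to reach p < 0.05 simultaneously would fail in
most replicates for power reasons alone) together with the group
time-course criteria (stable first-to-last block change < 0.5, unstable
decline > 1.5).

## Problem sizes

Defaults used by the test suite and the acceptance script: 900-s
recordings at 256 Hz with 13 channels; 100 subjects for the pipeline
round-trip; 1000 random sequences for the rule-evaluator equivalence; 1000
replicate cohorts for Eta recovery, 500 for type-I calibration, 200 for the
qualitative pattern.  These sizes keep the full run in the minutes range on
one CPU while leaving the Monte-Carlo standard errors well inside the
asserted margins.

## Known limitations

* The staging cascade is a declared approximation of the published staging
  tool's phenomenology, not of its implementation; no claim is made about
  per-segment agreement with it.
* Stage C recognition requires graphoelement annotations; recordings
  without expert (or generator) tags cannot score 1–3.
* The amplitude-rule artifact mask does not attempt muscle/sweat artifact
  classification; heavily contaminated real recordings would need manual
  annotation spans.
* The synthetic cohort draws each variable independently within group;
  correlations between questionnaires (e.g. CAARS and ASRS) are not
  reproduced, so multivariate analyses on synthetic cohorts are not
  meaningful.
* `unclassified` sequences are excluded from group statistics by design;
  their prevalence in real data is unknown.
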