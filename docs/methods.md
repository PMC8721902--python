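# Methods

This note documents the models and procedures `ictalfp` implements, the
parameters that matter, the numerical choices made where the procedure
admits more than one reading, and what the synthetic-data results do and
do not establish about real recordings.

## Spectral event detection

The detector computes a windowed short-time Fourier transform and
evaluates it directly at N = 50 geometrically spaced frequencies
between 1 and 150 Hz. For a window of L = round(0.128·fs) samples,
hop = L/2 (50% overlap) and Hamming window w,

    X(f_k, t) = Σ_n w[n] · x[t·hop + n] · exp(−2πi f_k n / fs),
    P(f_k, t) = |X(f_k, t)|² .

Evaluating the DFT at the exact target frequencies (rather than
interpolating an FFT grid) makes the computation reproducible by a
brute-force per-window DFT to ~1e-14 relative error; the test suite and
the acceptance script both exercise that oracle. The number of time
bins is floor((N_samples − L)/hop) + 1; bin *centers* sit at
(start + L/2)/fs and bin *outer edges* at start/fs and (start + L)/fs.

**Baseline z-scoring.** Each frequency row is normalized to the mean
and sample standard deviation (ddof = 1; the original denominator
convention is not recoverable, and at realistic bin counts the
difference is far below all tolerances) of the bins lying wholly inside
an annotated baseline epoch of at least 10 s. A constant-power
frequency row raises an error naming the frequency rather than
returning silent non-detections.

**Log-power transform (default).** The z-score is taken on log power.
Short-window power estimates are exponentially distributed per
frequency, so a "3 SD" threshold on *raw* power is exceeded by noise
with probability e⁻⁴ ≈ 1.8% per frequency; across ~17 effectively
independent frequency rows this marks ~27% of event-free bins and
smears detected event edges by adjacent noise bins (measured on
generated noise, 20 seeds). On log power the marginals are
near-Gaussian with a thin upper tail; the measured noise exceedance
fraction is ≈ 0% and recovered event edges align with the injected
schedule to within one bin. `SpectrogramSpec(power_transform="linear")`
restores the raw-power reading for comparison. The z-scoring operation
itself is an affine normalization of whatever matrix it receives, so
its unit semantics (baseline rows have mean 0, SD 1 exactly) hold under
either transform.

**Thresholding and segmentation.** A bin is suprathreshold when any
frequency with z > 3 lies outside the 48–52 Hz mains-omission band.
Omitted frequencies are retained in the stored spectrogram and flagged
by a mask — they never trigger detection, and by default they are also
excluded from band-power integration (configurable). Maximal runs of
suprathreshold bins form events; runs separated by at most
`merge_gap_bins` subthreshold bins merge when that option is raised
above its default of 0 (strict contiguity). Event onset/offset are the
outer edges of the first/last bin of the run — the finest resolution
the detector defines; sample-level refinement is deliberately not
implemented. Cumulative suprathreshold-bin counts, with first and
second differences (rate and acceleration of pathological activity),
are exposed alongside.

## Event classification and band power

Durations are bimodal by construction of the preparation: events longer
than 10 s (strictly) are seizure-like events; a short event is
*preictal* when it ends before the first SLE begins, *interictal*
otherwise; with no SLE all short events are preictal. Classification is
a pure function of durations and the first-SLE position.

Band power sums P(f, t) over the event's time bins and the frequency
centers falling in each band. Band membership is half-open [low, high)
with the topmost band closed, so every center belongs to exactly one
band and band powers partition the total. The high-γ band is set to
80–150 Hz — the remainder of the analyzed range above γ. Per-event
power is *summed* over bins ("total power"); a per-bin mean is
available as an option.

**Normalization.** For each band, normalized power is
(raw − baseline) / range, where baseline is the mean per-bin baseline
band power integrated over the median event length (so baseline and
event powers integrate over comparable spans; the original integration
length is unspecified), and range is the 95th percentile of per-event
band power across the recording minus that baseline. The two anchors
are thus the quiet baseline (0) and near-maximal ictal activity (1).
An alternative central-interpercentile reading
(`range_mode="interpercentile"`) is provided but not the default: the
text pairing "baseline" with "full ictal activity" as the two ends of
the range identifies the default reading. The γ/δ ratio is formed from
normalized bands; events whose normalized δ is ≤ 0 (possible since
normalization subtracts baseline) are flagged, logged, and excluded
from ratio statistics rather than producing unstable ratios.

**Epoch means.** Normalized band powers are averaged in sequential
epochs (default 200 s; the reduced-scale drivers use 50 s) keyed to
time before the first SLE; an event exactly on a boundary joins the
epoch closer to the SLE; empty epochs are reported as missing, not
zero.

## Dynamics metrics

All times are relative to the solution-switch time t0 (the synthetic
generator defines t0 as the end of the baseline epoch; for real data it
is supplied per recording). Latency to the first SLE is measured to SLE
*onset*. Inter-event intervals are onset-to-onset (offset-to-onset is a
config switch), with a first-15-events truncation available so that
groups producing very different event counts can be compared over the
same early epoch. The cumulative-duration gradient is the OLS slope of
cumulative event duration versus event number; for constant durations
it equals the duration exactly. IEI settling is fit as
iei(k) = settled + (initial − settled)·exp(−k/τ) by nonlinear least
squares; τ is the recoverable parameter (the index convention shifts
only the fitted "initial" value).

## Spike features

Detection: 1st-order zero-phase Butterworth high-pass (default 100 Hz),
polarity chosen by the dominant deflection, threshold at
`threshold_mad_multiple` (default 5) × MAD/0.6745, refractory enforced
via peak spacing (default 1 ms). Two choices depart from the most
obvious construction, both forced by the half-width accuracy
requirement (≤ 1 sample period across 0.3–2 ms):

- **Half-width on the raw trace.** Full width at half of
  peak-minus-local-baseline, with the baseline taken as the median of a
  ±10 ms neighborhood excluding ±2 ms around the peak, and crossings
  interpolated between samples. Zero-phase high-pass filtering distorts
  wide (1–2 ms) spikes by up to ~0.7 ms; the raw-trace measurement is
  accurate to ≤ 0.03 ms on rendered templates.
- **Satellite-lobe suppression.** Steep filters ring on wide spikes and
  produce suprathreshold side lobes a few ms from the main deflection;
  suprathreshold peaks below 35% of a neighbor within ±5 ms are
  discarded. True spikes of comparable amplitude are never suppressed,
  and bursts at the configured maximal rates (ISI ≥ ~7 ms) are
  unaffected.

On a noiseless trace the MAD is zero and MAD scaling is undefined; the
detector then keeps only deflections above half the maximum instead of
failing. Spikes are assigned to an event iff their time lies within
[onset, offset]; overlapping windows raise (assignment would be
ambiguous). "Frequency" is reported both as the within-event maximal
instantaneous rate (reciprocal of the minimum ISI; zero below two
spikes) and as the mean rate (count/duration). Event windows come from
the LFP detector; a whole-cell reference channel, where present, is not
used for timing.

## Group statistics

The two-sample Wilcoxon rank-sum test is used for cohort comparisons
(the experimental design is unpaired; a paired signed-rank variant is
provided but unused by the pipeline). When the smaller group has ≤ 10
observations, the pooled data are tie-free, and the number of rank
assignments is below 2·10⁶, the two-sided p is exact: the fraction of
all C(n₁+n₂, n₁) assignments whose rank sum deviates from its null mean
by at least the observed deviation (equivalently, double the smaller
tail — the null is symmetric). Otherwise the normal approximation with
tie and continuity correction is used (delegated to
`scipy.stats.mannwhitneyu`). The enumeration agrees with scipy's exact
method over *every* rank assignment with group sizes ≤ 6 (checked
exhaustively: 2,346 assignments).

Bootstrap SEM: resample with replacement at original size, 10,000
times; the SD of the resampled means estimates the SEM. Two Gaussian
fits of the resampled-mean density are reported — the
maximum-likelihood fit (σ = SD of the resampled means) and a
least-squares fit to the 50-bin histogram density — because the
original fitting procedure is not recoverable; they agree within a few
percent for unimodal data and the ML fit is the one used downstream.
Group differences are z = (m̄₁ − m̄₂)/√(SEM₁² + SEM₂²), two-sided p from
the standard normal. A single replicate's measured z scatters with unit
SD around the true standardized effect, so recovery claims about z are
made on replicate ensembles, not single draws.

ΔΔCt: per row ΔCt = Ct_target − Ct_reference; per gene
ΔΔCt = ΔCt − mean ΔCt of the control group; fold = 2^−ΔΔCt, with a
square-root transform for variance stabilization. Folds are invariant
to adding a constant to all Ct values. Downstream ANOVA/Tukey on the
transformed folds use scipy/statsmodels routines as-is.

## Synthetic generator

The generator emulates the *statistics* of the preparation, not its
mechanisms: no neurons, no chloride dynamics. A recording is

    noise (pink 1/f^α + white + optional 50 Hz line)
    + scheduled discharges (sums of band-limited tones under
      raised-cosine-edged envelopes)
    + seizure-like events (mixed-band carrier amplitude-modulated at
      the SLE rhythm, modulation floor 0.2 so the event never drops
      below threshold mid-SLE)
    + optional post-SLE interictal discharges.

Key defaults and why:

- **Units µV throughout.** No absolute amplitude calibration exists for
  the reference preparation (scale bars only), so amplitudes are
  conventions chosen for realistic SNR: baseline SD ≈ 9 µV (pink 8 +
  white 4 in quadrature, 2 µV line), discharge band amplitudes 20–60 µV
  (≥ 5× baseline SD at the δ tone), SLE amplitude 250 µV.
- **Band tones** at δ 2.5, θ 6, α 10, β 20, γ 60, high-γ 110 Hz; the γ
  tone deliberately avoids the 48–52 Hz omission band. A γ-only
  discharge keeps > 99.9% of its 1–150 Hz energy inside 30–80 Hz.
- **Durations** log-normal, median 0.35 s (σ_log 0.35), clipped to
  [0.15, 9.5] s — short events stay below the 10 s SLE threshold by
  construction; SLE durations are > 10 s by validation.
- **IEI settling** iei(k) = settled + (initial − settled)·exp(−k/τ):
  the observed rate settles over the first ~20 events and an
  exponential is the simplest law with that behavior. Full-scale
  defaults: 120 → 25 s with τ = 7 events, log-normal jitter (σ 0.2).
- **Escalation.** Per-event multiplicative amplitude growth toward the
  first SLE: all bands at `common_escalation_rate` and the γ/high-γ
  bands additionally at `gamma_escalation_rate`, each gain capped at 6
  (an uncapped multiplicative law diverges at knockout-like event
  counts). The genotype contrast lives in the γ rate: fast escalation
  in the wild-type-like configuration, nearly flat in the
  knockout-like one — the per-recording normalization makes absolute
  amplitude scalings invisible, so the *shape* of the escalation is
  the only channel through which a γ/δ group effect can be expressed.
- **Cohort spread.** Per-recording preictal counts are jittered
  log-normally (multiplier clipped to 0.3–2.3, the relative spread
  reported across real slices) with relative SD 0.28 (WT-like) / 0.5
  (KO-like full scale).
- **Full-scale conditions** (`default_*_config`): 10 kHz, 3600/6000 s,
  15 vs 85 preictal events — the reference cohort's sampling rate,
  duration and mean counts. **Reduced-scale conditions**
  (`reduced_*_config`): 500 Hz (Nyquist well above 150 Hz), 450/900 s,
  12 vs 36 preictal events with proportionally faster IEI settling
  (24 → 8 s, τ = 5) and γ-escalation rates 0.5 vs 0.02/event. These are
  the package's standard study conditions for replicate experiments:
  they preserve the full-scale structure (same detector settings, same
  bimodal durations, same contrast directions) at a problem size where
  a 100-replicate × 16-recording study completes in about two minutes.
- **Spike traces.** Biphasic template: Gaussian main lobe with FWHM =
  configured half-width plus a delayed (6σ), wide (3σ), small (−0.25)
  undershoot — far enough out that the template's measured FWHM stays
  within one sample of nominal. Within each event the first inter-spike
  interval is exactly 1/max_rate, pinning the ground-truth maximal
  rate; remaining spikes are placed at jittered intervals ≥ that
  minimum. Half-widths below 4 samples are rejected as unresolvable.

Determinism: every generator consumes a `numpy` Generator seeded from
the config; cohorts derive per-recording seeds from the cohort seed via
`SeedSequence`. Identical (config, seed) gives bit-identical traces.

**What passing tests show — and what they do not.** The synthetic
traces have stationary Gaussian-ish background noise, tone-based
discharges with smooth envelopes, and schedules that never overlap.
Real slice recordings contain electrode drift, movement and perfusion
artifacts, non-stationary baselines, discharge waveforms with sharp
transients and broadband edges, and occasional overlapping activity.
Detector recovery of 100% at ±1 bin therefore demonstrates the
*correctness of the implementation* under the stated model, and the
cohort studies demonstrate that the statistical machinery recovers
configured effects at realistic sample sizes — neither is a claim about
detector sensitivity or specificity on real tissue. The 3 SD / log
power operating point should be revalidated against annotated real
recordings before scientific use.

## Degenerate inputs and error policy

Constant traces raise at z-scoring (named frequency) rather than
returning empty detections; baseline windows must hold ≥ 2 whole bins;
recordings must exceed one window; f_max must lie below Nyquist;
schedules that overflow the recording raise a scheduling error rather
than truncating silently; unsorted event lists, overlapping spike
windows, empty statistical samples, non-positive normalization ranges
and missing reference Ct values all raise with the offending item
named. Pipeline runs isolate per-file failures, report them in
`failures.json`, and exit nonzero if any stage failed.

## Known limitations

- EDF files are read (via `mne`) but not written; interchange output is
  two-column delimited text plus a JSON ground-truth sidecar.
- No artifact rejection, multi-channel support, or online detection.
- The γ/δ ratio excludes events with non-positive normalized δ; in
  recordings where δ power barely exceeds baseline this can discard a
  nontrivial fraction of events (all exclusions are logged).
- The late-recurrent-discharge phase that follows repeated SLEs is not
  modeled or analyzed.
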