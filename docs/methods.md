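# Methods

This note documents the models implemented in `ultrarhythm`, their
assumptions and tunable parameters, what the synthetic generator does and
does not emulate, and the numerical choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

Activity is a series of nonnegative integer counts in uniform bins (6 min by
default, 240 bins/day) with naive local-clock timestamps marking bin starts;
bins are half-open `[t, t + width)`. The light schedule is defined by L hours
of light per day and a fixed lights-off clock time (18:00 by default); a bin
is dark iff its start lies in the dark span. At 6-min resolution with
on-the-hour transitions no bin straddles a transition. Timestamps are never
DST-adjusted: the colony light cycle is the clock.

## Photophase parsing

Records are split into per-day dark and light blocks and concatenated
earliest-first into one series per phase, truncated to exactly
`target_points` (default 900) bins; the final block is cut at its end, and a
partial leading block (a recording started mid-phase) is discarded. The
possibly fractional number of blocks consumed is reported (10.0 nights at
15 L, 7.5 at 12 L, 8 + 20/110 at 13 L). "Approximately equalize" is thus
operationalized as truncate-to-exactly-900; it reproduces the worked
arrangements above and makes series lengths comparable across photoperiods.

Retained bins keep their **absolute** timestamps, leaving nightly gaps in the
series. The Lomb-Scargle periodogram is defined for exactly this kind of
incomplete, evenly spaced sampling; re-indexing onto a contiguous axis would
distort any period spanning the gap, so it is available only behind
`reindex=True` for sensitivity analysis.

## Spectral detection

The classic variance-normalized Lomb power is computed at each grid period
(grids: 0.1–7.9 h step 0.02 h for URs; 22–26 h step 0.05 h for CRs — the
bands are conventions of the analysis, the steps our choice, fine enough that
a 0.1 h reporting granularity is not grid-limited). The implementation is
checked in the tests against two independent routes: `scipy.signal.lombscargle`
and the identity P = (SST − SSR)/(2σ̂²) with SSR from a brute-force
least-squares sinusoid fit of the centered data.

Presence of a rhythm uses the family-wise false-alarm threshold
z = −ln(1 − (1−α)^(1/M)) at α = 0.01 with M set to the **grid size**. The
effective number of independent frequencies of a gapped series is not
identifiable in general; the grid-size choice is conservative for our grids
(tested: the null presence rate on white noise stays below 1%), biases toward
fewer false URs, and is exposed as `m_indep`. Peaks are contiguous
supra-threshold runs collapsed to their maximum; two peaks must be separated
by a sub-threshold grid point; complexity is the number of peaks. Note a
consequence of this (deliberate) separation rule: complexity is not globally
monotone in the threshold, because a run containing two local maxima splits
when the threshold rises through the dip between them. On gapped series,
strong components also produce genuine supra-threshold gap aliases; the
complexity statistic counts them, as any spectral method on such sampling
must.

## Cosinor quantification

The single-component cosinor y(t) = M + A·cos(2π(t − tₐ)/τ) is fitted by
linear least squares on {1, cos, sin} at each grid period, directly on the
gapped timestamps (no imputation); τ′ maximizes robustness (100·R²), ties
breaking toward shorter τ for determinism. Quantification is gated on LSP
presence at α = 0.01; the zero-amplitude F test on (2, n−3) df uses α = 0.05.
A constant series fits gracefully (amplitude 0, robustness 0, p = 1) rather
than raising, matching the view that a flat record contains no rhythm rather
than an invalid one. Acrophase is reported as the time (and angle in
[0, 2π)) of the first fitted peak at or after the reference event —
lights-off for dark-phase and circadian fits, lights-on for light-phase fits.
Only a single harmonic is fitted; multi-periodicity is the periodogram's job
(complexity).

Circadian fits use the unparsed contiguous record (first 10 days, 240
bins/day) rather than the 900-point phase files; this split is hard-wired in
the orchestration.

## Activity duration (α)

All days are folded into a mean daily profile on the bin grid, smoothed with
a centered circular 5-bin (30 min) moving average, and thresholded; α is the
longest contiguous supra-threshold run, wrap-around allowed. The default
threshold is the **midrange** (halfway between profile minimum and maximum);
`"mean"` is available as an alternative. The midrange default makes the
estimator exact on a square-wave profile (a 9 h block of activity yields
α = 9.0 h) because the smoothing ramp is crossed symmetrically at half
height, whereas the mean threshold sits below half height whenever the active
fraction is under 50% and widens the run by one bin per edge. The estimator
assumes at least 5 complete days and a non-flat profile. Periods that divide
24 h evenly are a known hazard for any fold-based estimator: a phase-locked
ultradian component survives the fold and corrugates the profile (the
generator presets avoid such periods; see below).

## Synthetic generator

Counts are independent Poisson draws with mean
gate(t) × Π_k max(0, 1 + a_k·cos(2π(t − φ_k)/τ_k)). The gate is
`base_rate_dark` inside the nightly active window — a block of `alpha_hours`
starting at lights-off, onset jittered per day (Gaussian SD
`cr_onset_jitter`, default 0.25 h) — and `base_rate_light` elsewhere, with
light masking: the active rate never extends into the light span, so jitter
cannot leak high-rate bins past lights-on. Ultradian components are
multiplicative rectified cosines in absolute time; `ur_dark` components
modulate the active window, `ur_light` components the light phase. Poisson
was chosen because detector bins hold small nonnegative event counts;
the onset jitter keeps circadian robustness away from a degenerate 100%.

Photoperiod presets encode the qualitative dose-response the analysis is
meant to detect, anchored where group-level values are published:

| preset | dark τ′ (h) | dark rel. amp | light UR | α (h) | jitter (h) | dark rate |
|---|---|---|---|---|---|---|
| 15 L | 2.5 | 0.6 | none | 8.9 | 0.25 | 20 |
| 14 L | 2.5 | 0.6 | 1.3 h, 0.2 | 9.3 | 0.5 | 16 |
| 13 L–9 L | 3.8 | 0.8 | 1.3 h, 0.5 | 9.7–11.4 | 0.5 | 16 |
| SD-NR (≤12 L) | 5.5 | 0.6 | none | 8.9 | 0.25 | 20 |

α rises linearly from 8.9 h at 15 L to 11.4 h at 9 L. The short-day periods
3.8 h and 1.3 h are deliberately incommensurate with 24 h (see above). The
larger onset jitter in ≤14 L presets emulates the degraded circadian
organization of short days and keeps circadian robustness below the 15 L
level. The light floor is 1 count/bin; absolute rates are
order-of-magnitude choices exposed as parameters, not measured truths.
Metadata draws are consistent with phenotype (nonresponders: ETV ≥ 300,
summer fur, heavier; short-day responders: regressed ETV, moulted fur).

What the generator does **not** emulate: torpor bouts, body-temperature
rhythms, melatonin dynamics, re-entrainment transients after photoperiod
transfer (records represent steady state), detector dropouts, or
free-running period deviations from 24 h. Passing recovery tests therefore
show that the analysis chain is correct and well calibrated for entrained,
Poisson-like data — not that it is robust to every pathology of real
recordings.

## Cohort statistics

Phenotype rules: ≤12 L with ETV ≥ 300 **and** fur score 1 → SD-NR, otherwise
SD-R; 13 L and 14 L are labelled developed/undeveloped by the same inclusive
ETV ≥ 300 cut; 15 L animals are long-day controls. The prevalence χ² is the
uncorrected Pearson statistic (the continuity-corrected version does not
reproduce the published example values, the uncorrected one does). Polynomial
contrasts use the standard 7-level orthogonal codes entered jointly as
regressors on per-animal values (group-mean mode available); a perfect fit is
resolved exactly (zero coefficients get t = 0, not 0/0). OLS regression
reports zero-order R, b ± SE, standardized β, R², F and the standard error of
the estimate; photoperiod is coded 1 = 9 L … 7 = 15 L. Fisher's LSD uses the
pooled ANOVA MSE and reduces to the unpaired t test for two groups. No
multiple-testing correction is applied across endpoints, matching the
planned-comparisons framing. No Kruskal-Wallis/Mann-Whitney fur-score
analyses are provided: fur enters only as a classification input.

## Problem sizes and determinism

Monte-Carlo suites are sized to run on one CPU in minutes: the null
calibration uses 1000 white-noise series in the test suite (600 in the
acceptance script), parameter recovery 100 seeded animals (40 in the script),
and the directional cohort suite 50 cohorts of 3 animals per photoperiod
group plus 3 nonresponders (10 cohorts in the script). All simulation is
driven by explicit seeds; per-animal streams are spawned from a cohort seed,
so results are reproducible bit for bit and independent of analysis order.
The estimator classes follow the scikit-learn conventions (`fit`,
`get_params`/`set_params`, trailing-underscore attributes) and compose with
its model-selection utilities where that is useful.

## Known limitations

- The recovery suite's generator is jitter-free so that programmed mesor,
  amplitude and α have exact targets; preset-level jitter is exercised by the
  directional suite instead.
- The α estimator is biased low by roughly 0.1–0.2 h under onset jitter
  (fold smear crosses the midrange threshold slightly inside the window).
- M_indep for the LSP threshold is a convention, not an estimate; different
  choices rescale complexity and presence rates together.
- Relative amplitude is undefined (NaN) when the mesor is nonpositive.
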