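# ultrarhythm

Photophase-resolved analysis of ultradian and circadian locomotor rhythms
from binned home-cage activity counts.

Seasonal mammals such as Siberian hamsters reorganize their daily activity as
day length changes: the circadian (CR, ~24 h) waveform loses robustness and
amplitude in short photoperiods while ultradian rhythms (URs, period < ~8 h)
lengthen and gain amplitude — with different behavior in the light and the
dark portion of the day, and in animals whose gonads fail to regress
(photoperiod nonresponders). `ultrarhythm` is for chronobiologists who record
activity as counts in 6-min bins under a fixed light:dark schedule and want a
reproducible pipeline from raw actogram CSV files to cohort statistics:

1. **Photophase parsing** — each record is split into dark-only and
   light-only files ((24 − L) × 10 and L × 10 bins per day under L h of
   light) and concatenated, earliest block first, into series truncated to a
   fixed 900 points so lengths are comparable across photoperiods (10 nights
   at 15 L, 7.5 at 12 L, ...). Absolute timestamps are retained across the
   gaps.
2. **Lomb-Scargle detection** — the classic variance-normalized periodogram
   for unevenly sampled series,

   P(ω) = 1/(2σ̂²) { [Σ(y−ȳ)cos ω(t−τ₀)]²/Σcos²ω(t−τ₀)
                     + [Σ(y−ȳ)sin ω(t−τ₀)]²/Σsin²ω(t−τ₀) },

   scanned over 0.1–7.9 h (URs) or 22–26 h (CRs). Presence uses the
   false-alarm threshold z = −ln(1 − (1−α)^(1/M)) at family-wise α = 0.01;
   *complexity* is the number of significant peaks.
3. **Cosinor quantification** — for phases where a rhythm is present, the
   single-component model y(t) = M + A·cos(2π(t − tₐ)/τ) is fitted by least
   squares over the period grid; the best period τ′ maximizes *robustness*
   (100·R²). Reported per fit: mesor M, amplitude A (absolute and % mesor),
   acrophase (relative to lights-off, or lights-on for the light phase), and
   the zero-amplitude F test at α = 0.05. Nightly activity duration α is
   estimated from the folded, 30-min-smoothed daily profile.
4. **Cohort statistics** — phenotype classification (SD-R / SD-NR by the
   ETV ≥ 300 and fur-score-1 rules), prevalence χ² (no continuity
   correction), one-way ANOVA with Fisher's LSD, orthogonal polynomial
   photoperiod contrasts, and simple/multiple OLS regression.

A seeded synthetic actogram generator (Poisson counts, circadian gating with
day-to-day onset jitter, multiplicative ultradian components, photoperiod and
phenotype presets) stands in for animal recordings, so every stage is
testable against known ground truth.

## Worked example

```python
import ultrarhythm as ur
from ultrarhythm.pipeline import analyze_animal

params = ur.preset_params(10, seed=42)       # 10 L short-day responder preset
record, truth = ur.simulate_animal(params)   # 10 days x 240 six-min bins
summary = analyze_animal(record, params.schedule)

fit = summary.dark_ur.fit
print(fit.tau, fit.mesor, fit.amplitude_rel, fit.robustness)
print(summary.cr.fit.tau, summary.cr.fit.robustness, summary.alpha.alpha_hours)
```

prints (rounded)

```
3.8  12.49  76.9  40.3
24.0  44.5  10.7
```

i.e. the pipeline recovers the programmed 3.8 h dark-phase ultradian period
exactly on the 0.02 h grid; the ultradian waveform oscillates around a mesor
of 12.5 counts/bin with amplitude 77% of mesor and explains 40% of the
dark-phase variance; the circadian fit lands on 24.0 h; and the estimated
nightly activity duration is 10.7 h against a programmed 11.0 h.

The same analyses are scriptable from the shell:

```bash
ultrarhythm simulate --photoperiod 10 --n 8 --seed 1 --out cohort/
ultrarhythm cohort cohort/manifest.csv --out report/
ultrarhythm plot cohort/<animal>.csv -L 10 --out actogram.png
```

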