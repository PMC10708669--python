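# circabox

Chronobiology labs entrain mice to programmable light–dark (LD) schedules in
light-sealed boxes and read the animals' circadian state out of per-minute
passive-infrared (PIR) activity counts. `circabox` is a pure-software
counterpart to such a rig: it interprets flexible multi-phase light programs
— including T-cycles whose day length differs from 24 h — drives a virtual
mouse through them, logs activity in the standard multi-box per-minute TSV
dialect, and analyzes the result with double-plotted actograms, a
Hodrick–Prescott (HP) detrending + short-time Fourier transform (STFT)
spectrogram pipeline, and the Sokolove–Bushell chi-square periodogram.

It is intended for circadian researchers and methods developers who want to
prototype entrainment protocols (jet lag, photoperiod manipulations, Martian
sols), validate analysis code against data with known ground truth, or teach
the analysis chain without animals.

## The models at the core

**T-cycle scheduling.** Each schedule phase (up to 12 per box, 5 boxes) is
LD, DD or LL, starts at an explicit calendar time, and carries a cycle
length *T* (default 24 h). An internal clock advances against external Unix
time as

&nbsp;&nbsp;&nbsp;&nbsp;internal_time += 24/*T* × (sampling duration in seconds)

with 60-s sampling, and lights-on/off times are compared on that internal
axis, so an internal 12:12 program under *T* = 25 produces 12.5 h light /
12.5 h dark per 25 external hours. When ON precedes OFF the light is on
within the same (internal) day; when ON follows OFF the lit interval spans
midnight. Lights-off moving from 19:00 to 1:00 is thereby read as 25:00 — a
+6 h phase delay.

**Virtual mouse.** A circadian phase θ ∈ [0, 24) h (θ = 12 ≡ activity onset,
the CT12 convention) obeys

&nbsp;&nbsp;&nbsp;&nbsp;dθ/dt = 24/τ + L(t) · (K/24) · PRC(θ),&nbsp;&nbsp;PRC(θ) = −sin(2π(θ−12)/24)

with intrinsic period τ (C57BL/6J preset 23.7 h, inter-individual SD 10
min) and light input L(t) ∈ {0,1}. Light early in subjective night delays
the clock and late in subjective night advances it, giving stable
entrainment for cycle lengths within roughly τ ± 0.31·K h (K defaults to
6.0, covering T = 23…25 h). Counts are per-minute Poisson draws gated by
subjective night/day rates and multiplicatively suppressed under light
(masking).

**Analysis.** Counts are smoothed with an HP filter (λ = 5.184 × 10⁷ at
1-min resolution) and detrended by subtracting a heavy HP trend
(λ = 5.184 × 10¹¹); spectrograms use a 5-day sliding rectangular window
stepping 1 day, 8× zero padding, PSD on a 16–32 h period axis plus the
phase angle of the 24-h DFT bin; the dominant period comes from the
chi-square periodogram Qp over a 20–28 h grid (0.05-h steps) with a
Bonferroni-corrected χ² significance line.

## Worked example: seasons of Mars

The shipped `mars_t_cycles.json` program runs five boxes in parallel on a
24.7-h Martian sol at three photoperiods, one 25-h cycle, and a DD control:

```
$ circabox simulate --schedule mars_t_cycles.json --days 21 --seed 7 --out mars_log.tsv
INFO wrote 5-box log (21 days) to mars_log.tsv
$ head -3 mars_log.tsv | cut -c1-100
Time    Date    LED01   PIR01   LED02   PIR02   LED03   PIR03   LED04   PIR04   LED05   PIR05
07:00:00        2024-01-01      1       2       1       1       0       12      1       0       0       0
07:01:00        2024-01-01      1       0       1       0       0       18      1       1       0       0
$ circabox actogram --log mars_log.tsv --box 1 --fold 24.7 --out act_box1.svg
INFO rendered 21-day actogram to act_box1.svg
$ circabox periodogram --log mars_log.tsv --box 1
peak period: 24.70 h
$ circabox periodogram --log mars_log.tsv --box 5
peak period: 23.60 h
```

Box 1 has entrained to the 24.7-h sol — its activity period equals the
imposed cycle, and folding the actogram at 24.7 h shows a vertical
nocturnal band. Box 5 never saw light, so it free-runs near the strain
period; this particular animal (drawn from the population with a 10-min τ
SD) expresses 23.6 h. The log's 12 columns are time, date, then LED
state/PIR count pairs per box.

An end-to-end reproducible run (log + actograms + optional spectrograms and
periodograms + a manifest tying every output to the seed) is

```
circabox run --schedule mars_t_cycles.json --days 21 --seed 7 --out-dir run_out
```

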