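# Methods

## Scope and data model

`circabox` reproduces, in software, the behavior of a multi-box circadian
entrainment rig: a light-schedule engine, per-minute activity logging for
up to 5 boxes, and the downstream rhythm analyses. Since no animals are
involved, a simulator (the *virtual mouse*) generates activity; it is a
first-class, tested component, and every analysis result in this repository
is computed from data it produced.

## Schedule engine

A box schedule is an ordered list of 1–12 phases. Each phase has a mode
(LD/DD/LL), a calendar initiation time, optional internal-clock ON/OFF
times (required for LD), and a cycle length T (hours, default 24). The
governing phase at any instant is the one with the latest initiation not
after that instant; a query exactly at an initiation belongs to the later
phase (ties are impossible because validation requires strictly increasing
initiations). After the last phase its rules persist indefinitely.

Non-24-h cycles are realized by an internal clock advancing at 24/T
relative to external time, `internal += (24/T)·dt`, evaluated at the 60-s
sampling grid; over one complete external T-cycle the internal clock
accumulates exactly 24 h for every T > 0 (an algebraic identity the suite
asserts to machine precision). ON/OFF comparisons happen on the internal
axis. Design choices where the behavior was genuinely open:

- **Internal vs external comparison.** ON/OFF times are compared against
  the *internal* clock, which is what makes T-cycles work at all: an
  internal 12:12 program under T = 25 yields 12.5 h light / 12.5 h dark
  externally. This is flagged as an interpretation; the alternative
  (external comparison) would make T inert for LD phases.
- **Clock seeding.** At a phase's initiation the internal wall-clock equals
  the external wall-clock, preserving the anchoring role of the initiation
  time (a DD→LL transition lights up exactly at the initiation minute).
- **Boundary convention.** The lit interval is half-open [on, off), so a
  day partitions without double counting; ON = OFF denotes an empty lit
  interval. The two-case ON/OFF rule (same-day vs spanning-midnight) is
  complementary under swapping ON and OFF.
- **Time base.** Unix seconds throughout, naive datetimes read as UTC, no
  daylight-saving adjustments; calendar rendering is presentation only.

The JSON schedule schema (`boxes → box_id, phases → mode/from/on/off/T`) is
this package's definition; T omitted loads as 24.0.

## Virtual mouse

The animal is a single-phase velocity-response oscillator:

    dθ/dt = 24/τ + L(t)·(K/24)·PRC(θ),   PRC(θ) = −sin(2π(θ−12)/24)

integrated per minute (Euler, which at this step size is accurate to well
below the measurement resolution), with θ = 12 defined as activity onset
(CT12). The sinusoidal PRC delays in the early subjective night and
advances in the late subjective night — the minimal Type-1-like shape that
entrains stably across DD, LD, jet-lag and T-cycle protocols.

**Range of entrainment and the default K.** For a lit window of w internal
hours the largest net phase shift per cycle is

    Δφ_max = (K/24)·(τ/24)·(24/π)·2·sin(πw/24)  ≈ 0.31·K h  (w = 12),

so entrainment to cycle length T requires |24 − 24·T/τ| ≤ Δφ_max. A gain of
K = 3 gives Δφ_max ≈ 0.94 h, which cannot absorb the 1.32 h/cycle delay
that T = 25 demands at τ = 23.7; the default is therefore K = 6.0
(Δφ_max ≈ 1.89 h), covering T = 23–25 h with margin. The suite verifies
period locking for T ∈ {23, 24, 24.7, 25} via the oscillator's own CT12
crossings, i.e. genuine phase entrainment rather than masking artifact.

Under entrainment with a no-dead-zone sinusoidal PRC the stable phase angle
puts CT12 well before dark onset; the *observed* activity onset is
nevertheless locked to dark onset (within 0.25 h in the suite) because
masking suppresses lit activity — the same dissociation seen in real
nocturnal rodents.

Parameters (units, default, rationale):

- τ (h, 23.7): C57BL/6J free-running period preset.
- tau_sd (h, 10/60): inter-individual SD used by `simulate_population`,
  matching the strain's reported ~10-min spread.
- K (h shift per 24 h light, 6.0): see above.
- masking (unitless, 0.05): multiplicative, instantaneous suppression of
  activity under light; no rebound dynamics.
- rate_night / rate_day (counts/min, 15.0 / 0.5): plausible PIR count
  magnitudes; no published scale exists, and every analysis here is
  scale-invariant in count units.
- seed: drives the uniform initial phase and the Poisson count draws; the
  phase trajectory itself is deterministic given the light trace.

A zero-noise mode (counts = rounded expected rates) exists solely for
oracle tests. Per-animal seeds in `simulate_population` are
`master_seed + index`, making a size-1, zero-SD population an exact clone.

**What the simulator does not emulate:** ultradian bout structure,
wheel-running dynamics, light-history effects, aging, photoperiodic
after-effects, and phase noise in the oscillator. Passing tests therefore
demonstrate the correctness of the scheduling/analysis chain on data whose
rhythm obeys a clean one-oscillator model, not the behavior of real mice.

## Log and schedule I/O

The activity log is a TSV with a header row and one row per minute:
time (HH:MM:SS, seconds always 00), ISO date, then LED state / PIR count
pairs for boxes 1…5 (`LED01 PIR01 … LED05 PIR05`). Files with fewer
trailing box pairs load with those boxes explicitly absent (never
zero-filled, so analyses cannot silently consume empty channels);
headerless files are accepted positionally. Parse errors carry the 1-based
file line; a gap in the 60-s grid is an error unless `allow_gaps` is set
(truncated real recordings).

## Actograms

Activity and LED series are binned at 6 min (display only; analyses use the
raw 1-min data), one row per fold period (default 24 h, settable to T for
T-cycles), each rendered row showing day i beside day i+1. Shading is the
per-bin majority LED state, ties resolved unlit; a partial trailing day is
zero-padded, shaded unlit, and flagged. Binned counts conserve the raw
total. Folding at the true period minimizes the circular variance of onset
phase, which the suite checks on a T = 25 entrained simulation. Rendering
restricted to the last N days (default idea: N = 10) keeps redraws cheap
during long online recordings; SVG output is byte-deterministic.

## Rhythm analysis

- **HP filter.** `hp_filter` delegates to statsmodels' Hodrick–Prescott
  implementation; λ = 5.184 × 10⁷ smooths 1-min counts, and detrending
  subtracts the trend of a much heavier pass, λ_trend = 5.184 × 10¹¹
  (10⁴× the smoothing penalty; chosen so the trend tracks multi-week drift
  while leaving circadian structure untouched, and configurable). The λ→∞
  limit (least-squares line) and exact linearity are tested against
  closed-form regression.
- **STFT spectrogram.** 5-day rectangular windows, 1-day step, 8× zero
  padding. PSD is energy-normalized (2|X_k|²/Nfft one-sided), so summed
  over all bins it equals the window's signal energy despite padding
  (Parseval, asserted within 1%); displayed per 1/86400-Hz bin on a period
  axis clipped to 16–32 h. The 24-h phase angle is the phase of the padded
  DFT bin at exactly 1/86400 Hz (bin 40 of a 57600-point transform — the
  padded grid hits 24 h exactly).
- **Chi-square periodogram.** Counts aggregated into 6-min bins are folded
  modulo each candidate period (20–28 h, 0.05-h steps) into 6-min columns;
  Qp = N·Σ n_h(M_h − M)²/Σ(x_i − M)², compared to the χ²(columns − 1)
  quantile at α = 0.05 Bonferroni-corrected across the grid. The peak is
  the largest significant Qp; arrhythmic input returns no peak. Because
  candidate periods need not be integer multiples of the column width, the
  last column of a fold may be partially occupied; the statistic uses the
  actual occupancies n_h.
- **Onset detection.** The 1-min series is smoothed with a 31-min centered
  moving average and cut into consecutive cycles of a period hint (default
  24 h). Per cycle, the onset is the first upward threshold crossing
  (threshold = 50% of that cycle's 90th-percentile smoothed rate) sustained
  ≥ 30 min; crossings carried over from the previous cycle are ignored,
  cycles without a crossing contribute nothing, and a flat series yields
  an empty list. The defaults were fixed once and are exercised for
  sensitivity in the suite (zero-noise, LD-locked, and jet-lag data).
- **Phase shifts.** Onset times on each side of a transition are reduced to
  circular mean phases modulo the fold period; the difference is wrapped to
  (−12, +12] h, advances negative. At least 3 steady-state onsets per side
  are required.

### Null specificity of the spectrogram

The 16–32 h display band of a 5-day window spans only ~4 independent DFT
bins, so the white-noise max/median PSD ratio within the band is
heavy-tailed: Monte-Carlo calibration (100 seeds) puts its 95th percentile
near 13.5 and 99th near 18, while genuinely rhythmic simulated activity
exceeds 23 in every window. The suite therefore uses 20 as the
dominance bound separating noise from rhythm. The formal period-detection
null is carried by the chi-square periodogram's significance line, which
keeps the false-peak rate of shuffled data at or below α.

## Problem sizes and numerical choices

The shipped analyses run at the study scale the protocols imply: 14-day DD
recordings for free-run estimation, 20-cycle T-cycle entrainment runs with
the first 5 cycles discarded as transient, 25-day jet-lag protocols
(10 days baseline + 15 days after a 6-h advance), and 50-animal
populations for the period-variability estimate. The periodogram's 0.05-h
grid bounds period quantization error at ±0.025 h, well inside every
stated tolerance. Degenerate inputs (flat series, empty schedules,
non-positive steps, mis-aligned arrays) raise or return empty results as
documented per function rather than propagating NaNs.

## Known limitations

- One oscillator per animal: no split-rhythm, relative-coordination or
  dual-oscillator phenomena outside the range of entrainment.
- Masking is instantaneous and purely multiplicative; no negative masking
  (light-induced activity) or rebound.
- The onset detector assumes a reasonably consolidated nocturnal bout; it
  is not designed for arrhythmic or severely fragmented records.
- The spectrogram's PSD unit convention (energy per 1/86400-Hz bin) is a
  documented package choice; other software may scale PSDs differently,
  so compare shapes and peak locations, not raw magnitudes.
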