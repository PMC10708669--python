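"""Rhythm quantification for per-minute activity series.

The pipeline mirrors standard circadian practice: per-minute counts are
smoothed with a Hodrick-Prescott filter (penalty lambda = 5.184e7 at 1-min
resolution) and detrended by subtracting a much heavier HP trend; spectral
content is tracked with a short-time Fourier transform over a 5-day sliding
window stepping one day at a time (power spectral density over a period
axis plus the phase angle at the 24-h component); the dominant period is
estimated with the Sokolove-Bushell chi-square periodogram; activity onsets
are detected per cycle by a sustained threshold crossing, and phase shifts
(jet lag, DD-to-LD transitions) are measured as circular mean onset-phase
differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from statsmodels.tsa.filters.hp_filter import hpfilter

MINUTES_PER_DAY = 1440

#: HP smoothing penalty for 1-min activity data.
LAMBDA_SMOOTH = 5.184e7
#: Heavy HP penalty whose trend captures slow drift only (baseline shifts,
#: ageing); 1e4 x the smoothing penalty.
LAMBDA_TREND = 5.184e11


# --------------------------------------------------------------------------
# Hodrick-Prescott smoothing / detrending
# --------------------------------------------------------------------------

def hp_filter(series: np.ndarray, lambda_penalty: float) -> tuple[np.ndarray, np.ndarray]:
    """Split a series into an HP-smooth component and its residual.

    The smooth component s minimizes
        sum (y_t - s_t)^2 + lambda * sum (s_{t+1} - 2 s_t + s_{t-1})^2,
    an exactly linear operation; lambda = 0 returns the input, and as
    lambda grows the smooth converges to the least-squares line.

    Returns ``(smooth, residual)`` with ``residual = series - smooth``.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or len(series) < 4:
        raise ValueError("series must be 1-D with at least 4 samples")
    if lambda_penalty < 0:
        raise ValueError("lambda_penalty must be non-negative")
    cycle, trend = hpfilter(series, lamb=lambda_penalty)
    return np.asarray(trend), np.asarray(cycle)


def preprocess_activity(
    series: np.ndarray,
    lambda_smooth: float = LAMBDA_SMOOTH,
    lambda_trend: float = LAMBDA_TREND,
) -> np.ndarray:
    """Smooth per-minute counts and remove the heavy HP trend.

    Output = HP(series, lambda_smooth).smooth - HP(series, lambda_trend).smooth,
    i.e. the circadian-scale structure with both minute noise and multi-week
    drift stripped out; its mean over the full record is ~0.
    """
    smooth, _ = hp_filter(series, lambda_smooth)
    trend, _ = hp_filter(series, lambda_trend)
    return smooth - trend


# --------------------------------------------------------------------------
# Short-time Fourier transform spectrograms
# --------------------------------------------------------------------------

@dataclass
class SpectralResult:
    """Sliding-window power spectral density over a period axis.

    psd[i, j] is the PSD at period ``periods[i]`` (hours) in window j;
    windows are ``window_days`` long and start ``step_days`` apart.
    ``phase24`` is the phase angle (radians, (-pi, pi]) of the DFT bin at
    the 24-h period per window. PSD is normalized so that summed over all
    frequency bins it equals the window's signal energy (displayed per
    1/86400-Hz bin).
    """

    periods: np.ndarray  # hours, descending
    psd: np.ndarray  # (n_periods, n_windows)
    phase24: np.ndarray  # radians per window
    window_days: int
    step_days: int
    window_starts_days: np.ndarray


def _window_psd_phase(
    x: np.ndarray, pad_factor: int, dt_seconds: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """One-sided energy-normalized PSD of one window, with bin phases.

    Zero padding refines the period grid without adding energy; the
    normalization 2|X_k|^2 / Nfft (1x at DC and Nyquist) keeps Parseval:
    sum_k psd_k = sum_n x_n^2.
    """
    n = len(x)
    nfft = n * pad_factor
    X = np.fft.rfft(x, n=nfft)
    psd = np.abs(X) ** 2 / nfft
    psd[1:] *= 2.0
    if nfft % 2 == 0:
        psd[-1] /= 2.0
    freqs = np.fft.rfftfreq(nfft, d=dt_seconds)  # Hz
    phases = np.angle(X)
    return psd, phases, freqs, float(freqs[1])


def stft_spectrogram(
    series: np.ndarray,
    window_days: int = 5,
    step_days: int = 1,
    pad_factor: int = 8,
    period_range: Optional[tuple[float, float]] = (16.0, 32.0),
) -> SpectralResult:
    """Sliding-window DFT of a per-minute series mapped onto a period axis.

    Each window of ``window_days`` is transformed with a rectangular taper
    and ``pad_factor``-fold zero padding for a smooth period axis; the PSD
    is restricted to ``period_range`` hours for display (None keeps every
    bin including DC, preserving Parseval totals). The phase angle is read
    from the bin whose period is nearest 24.0 h on the padded grid.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be 1-D")
    nwin = window_days * MINUTES_PER_DAY
    nstep = step_days * MINUTES_PER_DAY
    if len(series) < nwin:
        raise ValueError(
            f"series of {len(series)} min is shorter than the "
            f"{window_days}-day window"
        )
    n_windows = (len(series) - nwin) // nstep + 1

    # frequency grid is identical across windows
    probe_psd, _, freqs, _ = _window_psd_phase(series[:nwin], pad_factor, 60.0)
    with np.errstate(divide="ignore"):
        periods_h = 1.0 / freqs / 3600.0  # inf at DC
    if period_range is None:
        keep = np.arange(len(freqs))
    else:
        lo, hi = period_range
        keep = np.where((periods_h >= lo) & (periods_h <= hi))[0]
    f24 = 1.0 / 86400.0
    k24 = int(np.argmin(np.abs(freqs - f24)))

    psd_mat = np.empty((len(keep), n_windows))
    phase24 = np.empty(n_windows)
    for j in range(n_windows):
        seg = series[j * nstep: j * nstep + nwin]
        psd, phases, _, _ = _window_psd_phase(seg, pad_factor, 60.0)
        psd_mat[:, j] = psd[keep]
        phase24[j] = phases[k24]
    return SpectralResult(
        periods=periods_h[keep],
        psd=psd_mat,
        phase24=phase24,
        window_days=window_days,
        step_days=step_days,
        window_starts_days=np.arange(n_windows) * step_days,
    )


# --------------------------------------------------------------------------
# Chi-square periodogram (Sokolove-Bushell)
# --------------------------------------------------------------------------

@dataclass
class PeriodogramResult:
    """Qp statistic over candidate periods with its significance line.

    ``peak_period`` is the candidate with the largest Qp among those
    exceeding the (Bonferroni-corrected) chi-square significance line, or
    None when nothing is significant (arrhythmic data).
    """

    periods: np.ndarray  # hours
    qp: np.ndarray
    significance_line: np.ndarray
    peak_period: Optional[float]

    @property
    def significant(self) -> np.ndarray:
        return self.qp > self.significance_line


def chi_square_periodogram(
    series: np.ndarray,
    period_min: float = 20.0,
    period_max: float = 28.0,
    step: float = 0.05,
    alpha: float = 0.05,
    bin_minutes: int = 6,
) -> PeriodogramResult:
    """Estimate the dominant period by folding at candidate periods.

    The per-minute series is first aggregated into ``bin_minutes`` bins.
    For each candidate period P the bins are folded modulo P into columns
    of ``bin_minutes`` width and the Sokolove-Bushell statistic

        Qp = N * sum_h n_h (M_h - M)^2 / sum_i (x_i - M)^2

    is computed (column means M_h with occupancy n_h, grand mean M, N total
    samples), which under the null follows a chi-square law with
    (columns - 1) degrees of freedom. The significance line is the
    chi-square quantile at alpha Bonferroni-corrected across the candidate
    grid.
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 7 * MINUTES_PER_DAY:
        raise ValueError("need at least 7 days of per-minute data")
    nb = len(series) // bin_minutes
    binned = series[: nb * bin_minutes].reshape(nb, bin_minutes).sum(axis=1)
    t_hours = np.arange(nb) * (bin_minutes / 60.0)  # bin start times

    total_var = np.sum((binned - binned.mean()) ** 2)
    periods = np.round(np.arange(period_min, period_max + step / 2, step), 10)
    qp = np.zeros(len(periods))
    sig = np.zeros(len(periods))
    grand = binned.mean()
    col_width = bin_minutes / 60.0
    n_tests = len(periods)
    for i, P in enumerate(periods):
        cols = (np.mod(t_hours, P) / col_width).astype(np.int64)
        ncols = int(np.ceil(P / col_width - 1e-9))
        cols = np.minimum(cols, ncols - 1)
        n_h = np.bincount(cols, minlength=ncols).astype(float)
        sums = np.bincount(cols, weights=binned, minlength=ncols)
        with np.errstate(invalid="ignore"):
            means = np.where(n_h > 0, sums / np.maximum(n_h, 1), grand)
        if total_var > 0:
            qp[i] = nb * np.sum(n_h * (means - grand) ** 2) / total_var
        sig[i] = stats.chi2.ppf(1.0 - alpha / n_tests, df=ncols - 1)
    above = qp > sig
    peak = float(periods[np.argmax(np.where(above, qp, -np.inf))]) if above.any() else None
    return PeriodogramResult(
        periods=periods, qp=qp, significance_line=sig, peak_period=peak
    )


# --------------------------------------------------------------------------
# Activity onsets and phase shifts
# --------------------------------------------------------------------------

def activity_onsets(
    series: np.ndarray,
    led: Optional[np.ndarray] = None,
    period_hint: float = 24.0,
    smooth_minutes: int = 31,
    threshold_frac: float = 0.5,
    min_sustained: int = 30,
) -> np.ndarray:
    """Detect one activity onset per circadian cycle.

    The per-minute series is smoothed with a centered ``smooth_minutes``
    moving average and cut into consecutive cycles of ``period_hint``
    hours. Within each cycle the onset is the first upward crossing of a
    threshold (``threshold_frac`` x that cycle's 90th-percentile smoothed
    rate) that stays above threshold for at least ``min_sustained``
    minutes. Cycles without such a crossing contribute nothing; a flat
    series returns an empty array. Times are hours from the series start.

    ``led`` is accepted (aligned to the series) for interface symmetry with
    logged data and is only length-checked.
    """
    series = np.asarray(series, dtype=float)
    if led is not None and len(led) != len(series):
        raise ValueError("led and series are not aligned")
    if len(series) == 0:
        return np.array([])
    kernel = np.ones(smooth_minutes) / smooth_minutes
    smooth = np.convolve(series, kernel, mode="same")
    cyc_len = int(round(period_hint * 60))
    onsets = []
    for start in range(0, len(series), cyc_len):
        window = smooth[start: start + cyc_len]
        if len(window) < min_sustained:
            break
        thr = threshold_frac * np.percentile(window, 90)
        if thr <= 0:
            continue
        above = window >= thr
        for i in range(len(window) - min_sustained + 1):
            if above[i] and (i == 0 or not above[i - 1]) and above[i: i + min_sustained].all():
                if i == 0 and start > 0 and smooth[start - 1] >= thr:
                    continue  # carried over from previous cycle, not an onset
                onsets.append((start + i) / 60.0)
                break
    return np.asarray(onsets)


def circular_mean_phase(times: np.ndarray, fold_period: float = 24.0) -> float:
    """Circular mean of event times folded at ``fold_period``, in hours."""
    ang = 2.0 * np.pi * (np.asarray(times) % fold_period) / fold_period
    mean = np.angle(np.mean(np.exp(1j * ang)))
    return (mean * fold_period / (2.0 * np.pi)) % fold_period


def measure_phase_shift(
    onsets_before: np.ndarray,
    onsets_after: np.ndarray,
    fold_period: float = 24.0,
) -> float:
    """Signed onset phase shift in hours: advances negative, delays positive.

    Each side's onsets are reduced to a circular mean phase modulo
    ``fold_period``; the difference (after - before) is wrapped into
    (-fold/2, +fold/2], so a 23-h delay reports as a 1-h advance.
    Requires at least 3 steady-state onsets on each side.
    """
    before = np.asarray(onsets_before, dtype=float)
    after = np.asarray(onsets_after, dtype=float)
    if len(before) < 3 or len(after) < 3:
        raise ValueError("need at least 3 onsets on each side of the transition")
    diff = circular_mean_phase(after, fold_period) - circular_mean_phase(before, fold_period)
    half = fold_period / 2.0
    shift = (diff + half) % fold_period - half
    if shift == -half:
        shift = half
    return float(shift)
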