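"""Period, phase and amplitude-persistence metrics with rhythmic/arrhythmic calls.

The classifier is an explicit threshold rule (all thresholds config-exposed):

    RHYTHMIC     iff n_peaks >= 3 and amplitude_ratio >= 0.2
                 and interpeak_cv <= 0.1 and period in [15, 40] h
    ARRHYTHMIC   iff n_peaks <= 1 or amplitude_ratio < 0.05
    INDETERMINATE otherwise

Phase statistics are circular (mean of unit vectors) to avoid wrap-around
artifacts near CT 0.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, lombscargle

from .clock_models import LightProtocol, ParameterSet, SplitCoupling
from .genotypes import KnockoutMode

__all__ = [
    "Call",
    "PeriodMethod",
    "RhythmThresholds",
    "RhythmReport",
    "PeriodEstimate",
    "InsufficientDataError",
    "detect_peaks",
    "estimate_period",
    "classify_rhythmicity",
    "peak_phase",
    "genotype_matrix",
]


class InsufficientDataError(ValueError):
    pass


class Call(enum.Enum):
    RHYTHMIC = "RHYTHMIC"
    ARRHYTHMIC = "ARRHYTHMIC"
    INDETERMINATE = "INDETERMINATE"


class PeriodMethod(enum.Enum):
    PEAK_INTERVAL = "peak_interval"
    SPECTRAL = "spectral"


@dataclass(frozen=True)
class RhythmThresholds:
    min_peaks_rhythmic: int = 3
    amplitude_ratio_rhythmic: float = 0.2
    amplitude_ratio_arrhythmic: float = 0.05
    interpeak_cv_max: float = 0.1
    period_band_h: tuple[float, float] = (15.0, 40.0)
    min_prominence: float = 0.25
    noise_prominence_factor: float = 5.0
    smooth_h: float = 2.0
    transient_discard_h: float = 24.0
    flat_range_fraction: float = 0.02


DEFAULT_THRESHOLDS = RhythmThresholds()


@dataclass(frozen=True)
class PeriodEstimate:
    period_h: float | None
    uncertainty_h: float | None
    method: PeriodMethod
    n_peaks: int

    @property
    def indeterminate(self) -> bool:
        return self.period_h is None


@dataclass(frozen=True)
class RhythmReport:
    component: str
    window_h: tuple[float, float]
    call: Call
    period_h: float | None
    period_uncertainty_h: float | None
    peak_phase_ct: float | None
    n_peaks: int
    amplitude_ratio: float | None
    interpeak_cv: float | None


def _linear_detrend(time: np.ndarray, values: np.ndarray) -> np.ndarray:
    coef = np.polyfit(time, values, 1)
    return values - np.polyval(coef, time)


def _moving_average(time: np.ndarray, values: np.ndarray, window_h: float) -> np.ndarray:
    """Centered moving average over ~window_h hours (reflect-padded)."""
    if window_h <= 0 or len(time) < 3:
        return values
    step = float(np.median(np.diff(time)))
    k = int(round(window_h / step))
    if k < 2:
        return values
    if k % 2 == 0:
        k += 1
    pad = k // 2
    padded = np.concatenate([values[pad:0:-1], values, values[-2:-2 - pad:-1]])
    kernel = np.full(k, 1.0 / k)
    return np.convolve(padded, kernel, mode="valid")


def _moving_average(time: np.ndarray, values: np.ndarray, window_h: float) -> np.ndarray:
    """Centered moving average over ~window_h hours (reflect-padded)."""
    if window_h <= 0 or len(time) < 3:
        return values
    step = float(np.median(np.diff(time)))
    k = int(round(window_h / step))
    if k < 2:
        return values
    if k % 2 == 0:
        k += 1
    pad = k // 2
    padded = np.concatenate([values[pad:0:-1], values, values[-2:-2 - pad:-1]])
    kernel = np.full(k, 1.0 / k)
    return np.convolve(padded, kernel, mode="valid")


def estimate_noise_sd(values) -> float:
    """Robust noise estimate from second differences.

    For a smooth signal sampled densely, second differences are dominated by
    independent additive noise (variance 6*sigma^2); the median absolute
    deviation makes the estimate robust to the oscillation itself.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 4:
        return 0.0
    d2 = np.diff(x, n=2)
    mad = np.median(np.abs(d2 - np.median(d2)))
    return float(1.4826 * mad / np.sqrt(6.0))


def detect_peaks(
    time,
    values,
    min_prominence: float = 0.05,
    detrend: bool = False,
    min_prominence_abs: float = 0.0,
):
    """Local maxima above a prominence threshold (fraction of signal range),
    refined by local quadratic interpolation.

    Requires >= 48 h of data sampled at <= 2 h.  Returns (peak_times,
    peak_heights); heights refer to the (possibly detrended) series.
    """
    t = np.asarray(time, dtype=float)
    x = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != x.shape:
        raise ValueError("time and values must be 1-D arrays of equal length")
    if len(t) < 3 or t[-1] - t[0] < 48.0:
        raise InsufficientDataError("need at least 48 h of data")
    if np.max(np.diff(t)) > 2.0 + 1e-9:
        raise InsufficientDataError("sampling interval must be <= 2 h")
    if detrend:
        x = _linear_detrend(t, x)
    rng = float(np.max(x) - np.min(x))
    if rng == 0:
        return np.array([]), np.array([])
    prominence = max(min_prominence * rng, min_prominence_abs)
    idx, _ = find_peaks(x, prominence=prominence)
    times = []
    heights = []
    for i in idx:
        if 0 < i < len(t) - 1:
            # quadratic through the three samples around the maximum
            y0, y1, y2 = x[i - 1], x[i], x[i + 1]
            denom = y0 - 2 * y1 + y2
            offset = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            offset = float(np.clip(offset, -1, 1))
            dt_l = t[i] - t[i - 1]
            times.append(t[i] + offset * dt_l)
            heights.append(y1 - 0.25 * (y0 - y2) * offset)
        else:
            times.append(t[i])
            heights.append(x[i])
    return np.asarray(times), np.asarray(heights)


def estimate_period(
    time,
    values,
    method: PeriodMethod = PeriodMethod.PEAK_INTERVAL,
    min_prominence: float = 0.05,
    band_h: tuple[float, float] = (15.0, 40.0),
) -> PeriodEstimate:
    """Dominant period of a sampled trace.

    PEAK_INTERVAL: mean +/- SD of inter-peak intervals (indeterminate with
    fewer than 3 peaks).  SPECTRAL: dominant Lomb-Scargle periodogram period
    within ``band_h`` (requires >= 72 h of data).
    """
    t = np.asarray(time, dtype=float)
    x = np.asarray(values, dtype=float)
    if method is PeriodMethod.PEAK_INTERVAL:
        try:
            pk_t, _ = detect_peaks(t, x, min_prominence=min_prominence)
        except InsufficientDataError:
            return PeriodEstimate(None, None, method, 0)
        if len(pk_t) < 3:
            return PeriodEstimate(None, None, method, len(pk_t))
        intervals = np.diff(pk_t)
        return PeriodEstimate(
            float(np.mean(intervals)), float(np.std(intervals, ddof=0)),
            method, len(pk_t),
        )
    if t[-1] - t[0] < 72.0:
        return PeriodEstimate(None, None, method, 0)
    xd = x - np.mean(x)
    periods = np.linspace(band_h[0], band_h[1], 2001)
    omega = 2 * np.pi / periods
    power = lombscargle(t, xd, omega)
    if not np.any(power > 0):
        return PeriodEstimate(None, None, method, 0)
    best = int(np.argmax(power))
    grid_step = periods[1] - periods[0]
    return PeriodEstimate(float(periods[best]), float(grid_step), method, 0)


def peak_phase(
    peak_times,
    cycle_h: float = 24.0,
    offset_h: float = 0.0,
) -> float | None:
    """Circular mean of peak times modulo ``cycle_h`` (hours in [0, cycle)).

    ``offset_h`` is subtracted first (e.g. the release time, so phases are
    circadian times).  Returns None with fewer than 2 peaks.
    """
    pk = np.asarray(peak_times, dtype=float)
    if len(pk) < 2:
        return None
    ang = (pk - offset_h) / cycle_h * 2 * np.pi
    vec = np.exp(1j * ang).mean()
    return float((np.angle(vec) % (2 * np.pi)) / (2 * np.pi) * cycle_h)


def classify_rhythmicity(
    time,
    values,
    component: str = "trace",
    thresholds: RhythmThresholds = DEFAULT_THRESHOLDS,
    reference_range: float | None = None,
    detrend: bool = False,
    ct_offset_h: float = 0.0,
) -> RhythmReport:
    """Classify a free-run series (time from release, hours).

    The first ``transient_discard_h`` hours are dropped as transient.
    ``reference_range`` (e.g. the entrained-segment amplitude) lets a
    near-flat free-run series be called arrhythmic even though peak metrics
    on its residual wiggle would be well-defined.
    """
    t = np.asarray(time, dtype=float)
    x = np.asarray(values, dtype=float)
    m = t >= t[0] + thresholds.transient_discard_h
    t, x = t[m], x[m]
    window = (float(t[0]), float(t[-1]))
    rng = float(np.max(x) - np.min(x)) if len(x) else 0.0

    flat = reference_range is not None and rng < thresholds.flat_range_fraction * reference_range
    if flat:
        return RhythmReport(component, window, Call.ARRHYTHMIC, None, None,
                            None, 0, 0.0, None)

    xs = _linear_detrend(t, x) if detrend else x
    noise_floor = thresholds.noise_prominence_factor * estimate_noise_sd(xs)
    xs = _moving_average(t, xs, thresholds.smooth_h)
    pk_t, _ = detect_peaks(t, xs, thresholds.min_prominence,
                           min_prominence_abs=noise_floor)
    tr_t, _ = detect_peaks(t, -xs, thresholds.min_prominence,
                           min_prominence_abs=noise_floor)
    n_peaks = len(pk_t)

    amplitude_ratio = None
    if n_peaks >= 2 and len(tr_t) >= 2:
        first_amp = _peak_to_trough(t, xs, pk_t[0], tr_t)
        last_amp = _peak_to_trough(t, xs, pk_t[-1], tr_t)
        if first_amp is not None and last_amp is not None and first_amp > 0:
            amplitude_ratio = float(last_amp / first_amp)

    period = cv = None
    if n_peaks >= 2:
        intervals = np.diff(pk_t)
        period = float(np.mean(intervals))
        if n_peaks >= 3:
            cv = float(np.std(intervals, ddof=0) / period)

    phase = peak_phase(pk_t, offset_h=ct_offset_h)

    lo, hi = thresholds.period_band_h
    if n_peaks <= 1 or (amplitude_ratio is not None
                        and amplitude_ratio < thresholds.amplitude_ratio_arrhythmic):
        call = Call.ARRHYTHMIC
    elif (
        n_peaks >= thresholds.min_peaks_rhythmic
        and amplitude_ratio is not None
        and amplitude_ratio >= thresholds.amplitude_ratio_rhythmic
        and cv is not None
        and cv <= thresholds.interpeak_cv_max
        and period is not None
        and lo <= period <= hi
    ):
        call = Call.RHYTHMIC
    else:
        call = Call.INDETERMINATE

    sd = float(np.std(np.diff(pk_t), ddof=0)) if n_peaks >= 3 else None
    return RhythmReport(component, window, call, period, sd, phase, n_peaks,
                        amplitude_ratio, cv)


def _peak_to_trough(t, x, peak_time, trough_times) -> float | None:
    """Amplitude of the peak at ``peak_time`` against the nearest trough."""
    if len(trough_times) == 0:
        return None
    nearest = trough_times[np.argmin(np.abs(trough_times - peak_time))]
    xp = float(np.interp(peak_time, t, x))
    xt = float(np.interp(nearest, t, x))
    return xp - xt


def genotype_matrix(
    variants,
    genotypes,
    base_params: ParameterSet,
    protocol: LightProtocol | None = None,
    components: tuple[str, ...] = ("CL_m", "P51_m"),
    mode: KnockoutMode = KnockoutMode.BASAL_AND_LIGHT,
    coupling: SplitCoupling = SplitCoupling.SUM_HALVED,
    thresholds: RhythmThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Rhythmicity calls per (variant, genotype, component) on free-run output.

    Returns a tidy DataFrame with one row per cell, containing the call and
    the raw metrics behind it.
    """
    from .clock_models import parameters_for_variant
    from .simulate import run_simulation

    protocol = protocol or LightProtocol()
    rows = []
    for variant in variants:
        vparams = parameters_for_variant(variant, base_params, coupling=coupling)
        for genotype in genotypes:
            traj = run_simulation(
                variant, vparams, genotype=genotype, protocol=protocol,
                knockout_mode=mode, coupling=coupling,
            )
            fr = traj.free_run()
            for comp in components:
                series = fr.component(comp)
                entr = traj.component(comp)[traj.time_h < traj.release_time_h]
                ref = float(np.max(entr) - np.min(entr)) if len(entr) else None
                report = classify_rhythmicity(
                    fr.time_h, series, component=comp, thresholds=thresholds,
                    reference_range=ref, ct_offset_h=traj.release_time_h,
                )
                rows.append({
                    "variant": traj.variant.name,
                    "genotype": traj.genotype.label,
                    "component": comp,
                    "call": report.call.value,
                    "period_h": report.period_h,
                    "n_peaks": report.n_peaks,
                    "amplitude_ratio": report.amplitude_ratio,
                    "interpeak_cv": report.interpeak_cv,
                    "peak_phase_ct": report.peak_phase_ct,
                })
    return pd.DataFrame(rows)


def matrix_text_report(matrix: pd.DataFrame) -> str:
    """Human-readable pivot of calls per variant/genotype/component."""
    lines = []
    for variant, sub in matrix.groupby("variant", sort=False):
        lines.append(f"{variant}:")
        pivot = sub.pivot(index="genotype", columns="component", values="call")
        lines.append(pivot.to_string())
        lines.append("")
    return "\n".join(lines)
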