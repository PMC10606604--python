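"""Respiration-cycle detection and period / peak-amplitude variability.

A respiration cycle on a centered motion waveform is delimited by two
successive end-expiratory peaks (local maxima in the superior-positive z
convention; the baseline is amplitude 0).  Peaks are found by prominence:
a candidate must rise at least ``min_prominence_frac`` times the waveform
SD above its surroundings and be at least ``min_period_s`` from the next
peak — conservative defaults for quiet breathing sampled at ~8 f/s.

Per-subject variability is the SD of the detected periods and of the
centered peak amplitudes; groups of per-subject SDs are compared with a
two-sided Welch t-test (default) or Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .errors import ConfigError, InsufficientCyclesError

__all__ = ["CycleStats", "detect_cycles", "compare_variability"]


@dataclass
class CycleStats:
    """Detected cycles of one waveform and their summary statistics."""

    peak_times: np.ndarray  # seconds
    peak_amplitudes: np.ndarray  # centered-waveform value at each peak, px
    periods: np.ndarray  # successive peak-time differences, seconds
    period_mean: float
    period_sd: float
    peak_amp_mean: float
    peak_amp_sd: float

    @property
    def n_cycles(self) -> int:
        return int(self.periods.size)

    def to_dict(self) -> dict:
        return {
            "n_cycles": self.n_cycles,
            "period_mean_s": float(self.period_mean),
            "period_sd_s": float(self.period_sd),
            "peak_amp_mean_px": float(self.peak_amp_mean),
            "peak_amp_sd_px": float(self.peak_amp_sd),
        }


def detect_cycles(
    waveform: np.ndarray,
    frame_rate: float,
    min_prominence_frac: float = 0.5,
    min_period_s: float = 1.5,
    times: np.ndarray | None = None,
) -> CycleStats:
    """Detect respiration peaks on a centered waveform and summarize cycles.

    Parameters
    ----------
    waveform : ndarray
        Centered vertical positions of one diaphragm column over frames.
    frame_rate : float
        Sampling rate in frames/s.
    min_prominence_frac : float
        Peak prominence threshold as a fraction of the waveform SD.
    min_period_s : float
        Minimum peak separation in seconds.
    times : ndarray, optional
        Frame acquisition times; defaults to a uniform grid at ``frame_rate``.

    Raises
    ------
    InsufficientCyclesError
        If fewer than two peaks are found (no complete cycle).
    """
    waveform = np.asarray(waveform, dtype=float)
    if waveform.ndim != 1:
        raise ConfigError("detect_cycles expects a single 1-D waveform")
    if waveform.size < 2 * min_period_s * frame_rate:
        raise InsufficientCyclesError(
            f"waveform of {waveform.size} frames is too short for cycles of "
            f">= {min_period_s} s at {frame_rate} f/s"
        )
    sd = float(waveform.std())
    if sd == 0.0:
        raise InsufficientCyclesError("insufficient cycles: constant waveform")
    distance = max(1, int(round(min_period_s * frame_rate)))
    peaks, _ = signal.find_peaks(
        waveform, prominence=min_prominence_frac * sd, distance=distance
    )
    if peaks.size < 2:
        raise InsufficientCyclesError(
            f"insufficient cycles: {peaks.size} peak(s) detected"
        )
    t = np.asarray(times, float) if times is not None else np.arange(waveform.size) / frame_rate
    peak_times = t[peaks]
    periods = np.diff(peak_times)
    amplitudes = waveform[peaks]
    return CycleStats(
        peak_times=peak_times,
        peak_amplitudes=amplitudes,
        periods=periods,
        period_mean=float(periods.mean()),
        period_sd=float(periods.std(ddof=1)) if periods.size > 1 else 0.0,
        peak_amp_mean=float(amplitudes.mean()),
        peak_amp_sd=float(amplitudes.std(ddof=1)) if amplitudes.size > 1 else 0.0,
    )


def compare_variability(group_a, group_b, test: str = "welch_t") -> float:
    """Two-sided p-value comparing two groups of per-subject SDs.

    ``test`` is ``"welch_t"`` (unequal-variance t-test) or
    ``"mann_whitney"``.  Identical groups give p = 1.0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigError("each group needs at least 2 subjects")
    if np.array_equal(a, b) and np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0  # degenerate: both groups constant and equal
    if test == "welch_t":
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    if test == "mann_whitney":
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    raise ConfigError(f"unknown test {test!r}; use 'welch_t' or 'mann_whitney'")
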