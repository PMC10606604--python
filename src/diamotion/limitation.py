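"""Motion limitation: diaphragm mid-position and mean absolute amplitude.

The mid-position y_mid is the round-half-up of the grand mean over all
valid frames of the per-frame mean flagged column index.  The limitation
metric samples 2K+1 equispaced columns y_mid + k*y_int (K = 5 columns on
each side, y_int = 5 px apart by default, i.e. 11 waveforms spanning
y_mid ± 25 px), centers each sampled column's position series by its own
temporal mean over the frames where the column is covered, and averages
the absolute centered excursion |z^| first over time, then over the 11
positions.  Unlike the scale-free NCC, this statistic is linear in the
motion amplitude: restricted diaphragm excursion lowers it directly.

All valid frames participate (not the common-range-filtered subset used
for the NCC), since profile pixels essentially always exist at or near the
mid-position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, CoverageError
from .profiles import ProfileSeries

__all__ = ["AmplitudeResult", "compute_y_mid", "mean_absolute_amplitude"]

K_DEFAULT = 5
Y_INT_DEFAULT = 5


@dataclass
class AmplitudeResult:
    """Mean absolute amplitude over 2K+1 columns around the mid-position."""

    y_mid: int
    sample_positions: np.ndarray  # y_mid + k*y_int, k = -K..K
    per_position_mean_abs: np.ndarray  # px, one per sampled position
    mean_abs_amplitude: float  # px
    mean_abs_amplitude_mm: float
    coverage: float  # fraction of (position, frame) samples with flag=1

    def to_dict(self) -> dict:
        return {
            "y_mid": int(self.y_mid),
            "sample_positions": [int(y) for y in self.sample_positions],
            "per_position_mean_abs_px": [float(v) for v in self.per_position_mean_abs],
            "mean_abs_amplitude_px": float(self.mean_abs_amplitude),
            "mean_abs_amplitude_mm": float(self.mean_abs_amplitude_mm),
            "coverage": float(self.coverage),
        }


def compute_y_mid(profiles: ProfileSeries) -> int:
    """Mid Y position of the diaphragm profile series.

    Averages, over all valid frames, the mean flagged-column index of each
    frame, then rounds half-up (floor(x + 0.5), not banker's rounding).
    """
    if profiles.frame_count == 0:
        raise ConfigError("no valid frames; cannot compute y_mid")
    cols = np.arange(profiles.width, dtype=float)
    per_frame_mean = (profiles.flags * cols).sum(axis=1) / profiles.lengths
    return int(math.floor(per_frame_mean.mean() + 0.5))


def mean_absolute_amplitude(
    profiles: ProfileSeries,
    y_mid: int | None = None,
    K: int = K_DEFAULT,
    y_int: int = Y_INT_DEFAULT,
    min_coverage: float = 0.9,
) -> AmplitudeResult:
    """Temporal-spatial mean absolute amplitude of diaphragm motion.

    Parameters
    ----------
    profiles : ProfileSeries
        Extracted profiles; all valid frames are used.
    y_mid : int, optional
        Mid-position; computed from ``profiles`` when omitted.
    K, y_int : int
        Number of sampled columns per side and their spacing in pixels
        (defaults 5 and 5: 11 columns spanning y_mid ± 25 px).
    min_coverage : float
        Minimum fraction of frames in which each sampled column must be
        flagged; frames where it is missing are skipped, but a column
        below this coverage is a hard error.

    Raises
    ------
    CoverageError
        If a sampled position falls outside the image or is flagged in
        fewer than ``min_coverage`` of the frames.
    """
    if K < 0 or y_int <= 0:
        raise ConfigError("K must be >= 0 and y_int > 0")
    if y_mid is None:
        y_mid = compute_y_mid(profiles)
    sample_positions = y_mid + y_int * np.arange(-K, K + 1)
    if sample_positions[0] < 0 or sample_positions[-1] >= profiles.width:
        raise CoverageError(
            f"sample positions {sample_positions[0]}..{sample_positions[-1]} "
            f"exceed image width {profiles.width}"
        )
    M = profiles.frame_count
    per_position = np.empty(sample_positions.size)
    covered = 0
    for k, y in enumerate(sample_positions):
        flag = profiles.flags[:, y]
        n_cov = int(flag.sum())
        covered += n_cov
        if n_cov < min_coverage * M:
            raise CoverageError(
                f"insufficient coverage at y={y}: column flagged in "
                f"{n_cov}/{M} frames (< {min_coverage:.0%})"
            )
        z = profiles.z_dia[flag, y]
        per_position[k] = np.abs(z - z.mean()).mean()
    mean_abs = float(per_position.mean())
    return AmplitudeResult(
        y_mid=int(y_mid),
        sample_positions=sample_positions,
        per_position_mean_abs=per_position,
        mean_abs_amplitude=mean_abs,
        mean_abs_amplitude_mm=mean_abs * profiles.pixel_spacing,
        coverage=covered / (sample_positions.size * M),
    )
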