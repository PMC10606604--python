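"""Common-range selection and per-position motion waveform construction.

Every Y column covered by the diaphragm profile in *all* retained frames
yields one motion waveform: the time series of that column's vertical
position.  The common range is ``[y_start_max, y_end_min]`` over frames.
When that range is short (<= 80 px by default) it is extended on the start
side only: the new start is the median of the per-frame start coordinates,
and frames whose profile begins after the median are discarded.  The lower
median is used so that at least half the frames always survive.

Waveforms are centered per position by their temporal mean over the
retained frames, so every waveform has mean zero by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SelectionError
from .profiles import ProfileSeries

__all__ = ["SelectionRecord", "WaveformSet", "select_common_range", "build_waveforms"]

COMMON_RANGE_THRESHOLD_PX = 80


@dataclass
class SelectionRecord:
    """Outcome of the common-range selection over a profile series."""

    y_end_min: int
    y_start_max: int
    y_start_med: int
    n_ori_common: int
    extended: bool
    y_start: int  # start actually used (y_start_max or y_start_med)
    n_common: int  # final common length N
    m_frames: int  # number of retained frames M
    m_ori: int  # valid frames before selection
    retained_frame_indices: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "y_end_min": int(self.y_end_min),
            "y_start_max": int(self.y_start_max),
            "y_start_med": int(self.y_start_med),
            "n_ori_common": int(self.n_ori_common),
            "extended": bool(self.extended),
            "y_start": int(self.y_start),
            "n_common": int(self.n_common),
            "m_frames": int(self.m_frames),
            "m_ori": int(self.m_ori),
        }


@dataclass
class WaveformSet:
    """N position waveforms of length M with their centering record.

    ``z_raw``, ``z_centered`` have shape (N positions, M frames);
    ``z_mean`` is the per-position temporal mean over retained frames.
    """

    positions: np.ndarray
    times: np.ndarray
    z_raw: np.ndarray
    z_mean: np.ndarray
    z_centered: np.ndarray
    pixel_spacing: float
    frame_rate: float
    subject_id: str = "subject"
    selection: SelectionRecord | None = None

    @property
    def n_positions(self) -> int:
        return self.z_centered.shape[0]

    @property
    def n_frames(self) -> int:
        return self.z_centered.shape[1]

    def write_csv(self, path) -> None:
        """Wide CSV (rows = frames, columns = y positions) of centered values."""
        import json
        from pathlib import Path

        import pandas as pd

        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(
            self.z_centered.T,
            index=pd.Index(self.times, name="time_s"),
            columns=[f"y{int(y)}" for y in self.positions],
        )
        df.to_csv(path, float_format="%.6g")
        if self.selection is not None:
            with open(path.with_suffix(".json"), "w") as fh:
                json.dump(self.selection.to_dict(), fh, indent=1)


def _lower_median(values: np.ndarray) -> int:
    """Lower median: element at index (n-1)//2 of the sorted values."""
    s = np.sort(np.asarray(values))
    return int(s[(s.size - 1) // 2])


def select_common_range(
    profiles: ProfileSeries, threshold: int = COMMON_RANGE_THRESHOLD_PX
) -> SelectionRecord:
    """Choose the Y range and frame subset used for waveform generation.

    If the all-frame common length ``y_end_min - y_start_max`` exceeds
    ``threshold`` pixels, every valid frame is retained.  Otherwise the
    start is moved back to the lower median of per-frame starts and frames
    starting after it are dropped, which guarantees that at least half the
    frames remain.

    Raises
    ------
    SelectionError
        If even the extended range has non-positive length.
    """
    if profiles.frame_count < 2:
        raise SelectionError("need at least 2 valid frames to select a common range")
    y_end_min = int(profiles.y_end.min())
    y_start_max = int(profiles.y_start.max())
    y_start_med = _lower_median(profiles.y_start)
    n_ori_common = y_end_min - y_start_max
    m_ori = profiles.frame_count

    if n_ori_common > threshold:
        retained = np.arange(m_ori)
        extended = False
        y_start, n_common = y_start_max, n_ori_common
    else:
        retained = np.flatnonzero(profiles.y_start <= y_start_med)
        extended = True
        y_start, n_common = y_start_med, y_end_min - y_start_med
    if n_common <= 0:
        raise SelectionError(
            f"no usable common range (N={n_common} from y_end_min={y_end_min}, "
            f"y_start={y_start})"
        )
    return SelectionRecord(
        y_end_min=y_end_min,
        y_start_max=y_start_max,
        y_start_med=y_start_med,
        n_ori_common=n_ori_common,
        extended=extended,
        y_start=y_start,
        n_common=n_common,
        m_frames=int(retained.size),
        m_ori=m_ori,
        retained_frame_indices=retained,
    )


def build_waveforms(profiles: ProfileSeries, sel: SelectionRecord) -> WaveformSet:
    """Emit the N centered motion waveforms over the M retained frames.

    Positions are the N columns ``sel.y_start .. sel.y_end_min - 1``; each
    retained frame must cover all of them (guaranteed by the selection rule
    for contiguous profiles).
    """
    positions = np.arange(sel.y_start, sel.y_start + sel.n_common)
    rows = sel.retained_frame_indices
    z_raw = profiles.z_dia[np.ix_(rows, positions)].T  # (N, M)
    if np.isnan(z_raw).any():
        bad = rows[np.isnan(z_raw).any(axis=0)]
        raise SelectionError(
            f"retained frame(s) {bad[:5].tolist()} missing columns inside the "
            "selected common range; selection contract violated"
        )
    z_mean = z_raw.mean(axis=1)
    return WaveformSet(
        positions=positions,
        times=profiles.frame_times[rows],
        z_raw=z_raw,
        z_mean=z_mean,
        z_centered=z_raw - z_mean[:, None],
        pixel_spacing=profiles.pixel_spacing,
        frame_rate=profiles.frame_rate,
        subject_id=profiles.subject_id,
        selection=sel,
    )
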