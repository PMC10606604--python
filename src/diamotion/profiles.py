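"""Per-frame diaphragm profile extraction from binary field masks.

Each sagittal frame's 2-D segmentation mask is collapsed to a 1-D profile:
one superior-inferior (Z) position per anterior-posterior (Y) column.  The
Z axis is oriented superior-positive, ``z = n_rows - 1 - row_index``, so the
diaphragm's inspiratory descent decreases z.  The profile is the superior
boundary of the field by default (the moving interface of the diaphragm
dome); a per-column centroid is available as an alternative collapse.

Columns with no foreground pixel in a frame are unflagged.  Single-column
interior gaps are treated as segmentation dropouts and repaired by linear
interpolation; wider interior gaps truncate the frame's profile to its
longest contiguous run, since they usually signal a bad mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ProfileError
from .mask_io import MaskSeries

__all__ = ["ProfileSeries", "extract_profile_series", "profile_lengths"]

logger = logging.getLogger(__name__)


@dataclass
class ProfileSeries:
    """Diaphragm profiles for the valid frames of a mask series.

    Arrays are indexed by *valid* frame (empty frames are dropped);
    ``frame_indices`` maps back to the original acquisition index.

    Attributes
    ----------
    flags : ndarray, bool, shape (M, width)
        Per-column membership flag f(y, t) after gap repair.
    z_dia : ndarray, float, shape (M, width)
        Superior-boundary position z_dia(y, t) in pixels (superior-positive);
        NaN where the flag is 0.
    lengths : ndarray, int, shape (M,)
        Per-frame flagged-column count N_ori(t_m).
    y_start, y_end : ndarray, int, shape (M,)
        First and last flagged column of each frame (inclusive).
    """

    flags: np.ndarray
    z_dia: np.ndarray
    lengths: np.ndarray
    y_start: np.ndarray
    y_end: np.ndarray
    frame_times: np.ndarray
    frame_indices: np.ndarray
    invalid_frame_indices: np.ndarray
    n_rows: int
    frame_rate: float
    pixel_spacing: float
    subject_id: str = "subject"
    collapse: str = "superior"

    @property
    def frame_count(self) -> int:
        """Number of valid frames M."""
        return self.flags.shape[0]

    @property
    def width(self) -> int:
        return self.flags.shape[1]

    def to_frame(self):
        """Long-format table (frame, y, z_dia) of all flagged samples."""
        import pandas as pd

        m_idx, y_idx = np.nonzero(self.flags)
        return pd.DataFrame(
            {
                "frame": self.frame_indices[m_idx],
                "y": y_idx,
                "z_dia": self.z_dia[m_idx, y_idx],
            }
        )

    def write_csv(self, path) -> None:
        """Write the long-format profile table plus a JSON metadata sidecar."""
        import json
        from pathlib import Path

        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(
                {
                    "subject_id": self.subject_id,
                    "frame_rate": self.frame_rate,
                    "pixel_spacing": self.pixel_spacing,
                    "n_rows": self.n_rows,
                    "collapse": self.collapse,
                    "z_convention": "superior-positive: z = n_rows - 1 - row_index",
                    "y_convention": "0-based column index, anterior to posterior",
                    "valid_frames": int(self.frame_count),
                    "invalid_frames": [int(i) for i in self.invalid_frame_indices],
                },
                fh,
                indent=1,
            )


def _collapse_frame(frame: np.ndarray, collapse: str) -> tuple[np.ndarray, np.ndarray]:
    """Collapse one binary frame to (flags, z) per column."""
    n_rows = frame.shape[0]
    flags = frame.any(axis=0)
    z = np.full(frame.shape[1], np.nan)
    if collapse == "superior":
        # first True row per column = superior-most foreground pixel
        top_row = frame.argmax(axis=0)
        z[flags] = (n_rows - 1) - top_row[flags]
    elif collapse == "centroid":
        rows = np.arange(n_rows)[:, None].astype(float)
        counts = frame.sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean_row = (frame * rows).sum(axis=0) / np.where(counts > 0, counts, 1)
        z[flags] = (n_rows - 1) - mean_row[flags]
    else:
        raise ProfileError(f"unknown profile collapse mode: {collapse!r}")
    return flags, z


def _repair_and_trim(flags: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate 1-px interior gaps, then keep the longest contiguous run."""
    flags = flags.copy()
    z = z.copy()
    # single-column gaps: pattern 1,0,1
    gap = (~flags[1:-1]) & flags[:-2] & flags[2:]
    idx = np.nonzero(gap)[0] + 1
    if idx.size:
        z[idx] = 0.5 * (z[idx - 1] + z[idx + 1])
        flags[idx] = True
    # longest contiguous flagged run (first wins on ties)
    padded = np.concatenate(([False], flags, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]  # [start, end) pairs
    if starts.size > 1:
        best = int(np.argmax(ends - starts))
        keep = np.zeros_like(flags)
        keep[starts[best] : ends[best]] = True
        z[~keep] = np.nan
        flags = keep
    return flags, z


def extract_profile_series(
    masks: MaskSeries,
    collapse: str = "superior",
    max_invalid_frac: float = 0.1,
) -> ProfileSeries:
    """Collapse a binary mask series to per-frame diaphragm profiles.

    Parameters
    ----------
    masks : MaskSeries
        Binary diaphragm-field masks with metadata.
    collapse : {"superior", "centroid"}
        How a column's foreground pixels map to one z value.
    max_invalid_frac : float
        Hard-error threshold on the fraction of empty (invalid) frames.

    Raises
    ------
    ProfileError
        If every frame is empty, or more than ``max_invalid_frac`` of the
        frames are.
    """
    valid = masks.valid_frame_mask()
    invalid_idx = np.flatnonzero(~valid)
    if invalid_idx.size:
        logger.warning(
            "%s: %d/%d empty mask frames excluded (indices %s%s)",
            masks.subject_id,
            invalid_idx.size,
            masks.frame_count,
            ", ".join(map(str, invalid_idx[:5])),
            "..." if invalid_idx.size > 5 else "",
        )
    if invalid_idx.size > max_invalid_frac * masks.frame_count:
        raise ProfileError(
            f"{invalid_idx.size}/{masks.frame_count} frames have empty masks "
            f"(> {max_invalid_frac:.0%} tolerance)"
        )
    valid_idx = np.flatnonzero(valid)
    if valid_idx.size == 0:
        raise ProfileError("mask series contains no non-empty frames")

    width = masks.shape[1]
    M = valid_idx.size
    all_flags = np.zeros((M, width), dtype=bool)
    all_z = np.full((M, width), np.nan)
    for out_m, m in enumerate(valid_idx):
        flags, z = _collapse_frame(masks.frames[m], collapse)
        flags, z = _repair_and_trim(flags, z)
        all_flags[out_m] = flags
        all_z[out_m] = z

    lengths = all_flags.sum(axis=1).astype(np.int64)
    y_start = all_flags.argmax(axis=1).astype(np.int64)
    y_end = (width - 1 - all_flags[:, ::-1].argmax(axis=1)).astype(np.int64)
    return ProfileSeries(
        flags=all_flags,
        z_dia=all_z,
        lengths=lengths,
        y_start=y_start,
        y_end=y_end,
        frame_times=masks.frame_times[valid_idx],
        frame_indices=valid_idx,
        invalid_frame_indices=invalid_idx,
        n_rows=masks.shape[0],
        frame_rate=masks.frame_rate,
        pixel_spacing=masks.pixel_spacing,
        subject_id=masks.subject_id,
        collapse=collapse,
    )


def profile_lengths(profiles: ProfileSeries) -> np.ndarray:
    """Per-frame diaphragm profile lengths N_ori(t_m) (flagged-column counts)."""
    return profiles.flags.sum(axis=1).astype(np.int64)
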