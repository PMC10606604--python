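"""Per-subject pipeline orchestration and group-level reporting.

``run_subject`` chains the stages — mask reading, profile extraction,
common-range selection, waveform building, cycle detection, NCC map and
mean absolute amplitude — and collects per-subject metrics plus QC flags.
A cycle-detection failure (too few breaths in a short series) is recorded
as a QC flag while the NCC and limitation metrics are still reported;
failures in earlier stages propagate.

``group_report`` aggregates subjects by group label (e.g. normal,
GOLD-III, GOLD-IV), reports per-group mean/SD of the mean NCC and the
mean absolute amplitude, and tests each metric between the reference
group and every other group (two-sided Welch t-test by default;
Mann-Whitney optional, no multiple-testing correction by default).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .asynchrony import build_ncc_map, render_ncc_map
from .cycles import CycleStats, compare_variability, detect_cycles
from .errors import ConfigError, InsufficientCyclesError
from .limitation import compute_y_mid, mean_absolute_amplitude
from .mask_io import MaskSeries, read_mask_series
from .profiles import ProfileSeries, extract_profile_series
from .waveforms import build_waveforms, select_common_range

__all__ = [
    "DEFAULT_CONFIG",
    "SubjectResult",
    "run_subject",
    "group_report",
    "motion_direction_overlay",
]

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "profile": {"collapse": "superior", "max_invalid_frac": 0.1},
    "selection": {"threshold_px": 80},
    "cycles": {"min_prominence_frac": 0.5, "min_period_s": 1.5},
    "limitation": {"K": 5, "y_int": 5, "min_coverage": 0.9},
    "report": {"test": "welch_t", "reference_group": "normal", "bonferroni": False},
}


def merge_config(user: dict | None) -> dict:
    """Overlay a (possibly partial) user config onto the defaults."""
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    for section, values in (user or {}).items():
        if section not in cfg:
            cfg[section] = {}
        if not isinstance(values, dict):
            raise ConfigError(f"config section {section!r} must be a mapping")
        cfg[section].update(values)
    return cfg


@dataclass
class SubjectResult:
    """Metrics and QC record for one subject's mask series."""

    subject_id: str
    group_label: str
    mean_ncc: float
    mean_abs_amplitude_px: float
    mean_abs_amplitude_mm: float
    y_mid: int
    cycle_stats: dict | None
    selection: dict
    qc_flags: list

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write_json(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def run_subject(
    masks: MaskSeries | str | Path,
    config: dict | None = None,
    out_dir: str | Path | None = None,
    group_label: str = "other",
) -> SubjectResult:
    """Run the full motion-evaluation pipeline on one mask series.

    ``masks`` may be a loaded :class:`MaskSeries` or a path readable by
    :func:`~diamotion.mask_io.read_mask_series`.  When ``out_dir`` is
    given, per-subject artifacts (profile CSV, waveform CSV, NCC matrix
    CSV + heat map, result JSON) are written there.
    """
    cfg = merge_config(config)
    if not isinstance(masks, MaskSeries):
        masks = read_mask_series(masks)
    qc: list[str] = []

    profiles = extract_profile_series(masks, **cfg["profile"])
    if profiles.invalid_frame_indices.size:
        qc.append(f"profile: {profiles.invalid_frame_indices.size} empty frame(s) excluded")

    sel = select_common_range(profiles, threshold=cfg["selection"]["threshold_px"])
    if sel.extended:
        qc.append(
            f"selection: common range extended ({sel.n_ori_common} -> {sel.n_common} px, "
            f"{sel.m_frames}/{sel.m_ori} frames kept)"
        )
    waves = build_waveforms(profiles, sel)

    y_mid = compute_y_mid(profiles)
    cycle_stats: CycleStats | None = None
    try:
        idx = int(np.clip(y_mid - sel.y_start, 0, waves.n_positions - 1))
        cycle_stats = detect_cycles(
            waves.z_centered[idx],
            frame_rate=profiles.frame_rate,
            times=waves.times,
            **cfg["cycles"],
        )
    except InsufficientCyclesError as exc:
        qc.append(f"cycles: {exc}")
        logger.warning("%s cycles stage failed: %s", profiles.subject_id, exc)

    ncc_map = build_ncc_map(waves)
    if ncc_map.excluded_positions.size:
        qc.append(f"ncc: {ncc_map.excluded_positions.size} degenerate waveform(s) excluded")
    amp = mean_absolute_amplitude(
        profiles,
        y_mid=y_mid,
        K=cfg["limitation"]["K"],
        y_int=cfg["limitation"]["y_int"],
        min_coverage=cfg["limitation"]["min_coverage"],
    )

    result = SubjectResult(
        subject_id=profiles.subject_id,
        group_label=group_label,
        mean_ncc=float(ncc_map.mean_ncc),
        mean_abs_amplitude_px=float(amp.mean_abs_amplitude),
        mean_abs_amplitude_mm=float(amp.mean_abs_amplitude_mm),
        y_mid=int(y_mid),
        cycle_stats=cycle_stats.to_dict() if cycle_stats is not None else None,
        selection=sel.to_dict(),
        qc_flags=qc,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sid = profiles.subject_id
        profiles.write_csv(out / f"{sid}_profiles.csv")
        waves.write_csv(out / f"{sid}_waveforms.csv")
        ncc_map.write_csv(out / f"{sid}_ncc.csv")
        render_ncc_map(ncc_map, out / f"{sid}_ncc.png")
        result.write_json(out / f"{sid}_result.json")
    return result


def group_report(
    results: list[SubjectResult],
    reference_group: str = "normal",
    test: str = "welch_t",
    out_dir: str | Path | None = None,
) -> dict:
    """Aggregate subject results by group and compare against a reference.

    Returns a dict with a ``groups`` table (mean/SD of each metric per
    group), a ``tests`` table (two-sided p-values of each metric between
    the reference group and every other group), and per-subject
    ``scatter`` data (mean NCC vs mean absolute amplitude).
    """
    if not results:
        raise ConfigError("no subject results to report")
    df = pd.DataFrame([r.to_dict() for r in results])
    by = df.groupby("group_label", sort=True)
    groups = by.agg(
        n=("subject_id", "size"),
        mean_ncc_mean=("mean_ncc", "mean"),
        mean_ncc_sd=("mean_ncc", lambda s: s.std(ddof=1)),
        amp_px_mean=("mean_abs_amplitude_px", "mean"),
        amp_px_sd=("mean_abs_amplitude_px", lambda s: s.std(ddof=1)),
        amp_mm_mean=("mean_abs_amplitude_mm", "mean"),
        amp_mm_sd=("mean_abs_amplitude_mm", lambda s: s.std(ddof=1)),
    ).reset_index()

    labels = list(groups["group_label"])
    tests_rows = []
    if len(labels) >= 2:
        if reference_group not in labels:
            raise ConfigError(f"reference group {reference_group!r} not among {labels}")
        if (groups["n"] < 2).any():
            raise ConfigError("every group needs >= 2 subjects for between-group tests")
        ref = df[df.group_label == reference_group]
        for lab in labels:
            if lab == reference_group:
                continue
            other = df[df.group_label == lab]
            tests_rows.append(
                {
                    "comparison": f"{reference_group} vs {lab}",
                    "p_mean_ncc": compare_variability(
                        ref["mean_ncc"], other["mean_ncc"], test=test
                    ),
                    "p_mean_abs_amplitude": compare_variability(
                        ref["mean_abs_amplitude_px"], other["mean_abs_amplitude_px"], test=test
                    ),
                    "test": test,
                }
            )
    report = {
        "groups": groups.to_dict(orient="records"),
        "tests": tests_rows,
        "scatter": df[
            ["subject_id", "group_label", "mean_ncc", "mean_abs_amplitude_px"]
        ].to_dict(orient="records"),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        groups.to_csv(out / "group_summary.csv", index=False, float_format="%.6g")
        pd.DataFrame(tests_rows).to_csv(out / "group_tests.csv", index=False, float_format="%.6g")
        with open(out / "group_report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, default=float)
        _render_scatter(df, out / "ncc_vs_amplitude.png")
    return report


def _render_scatter(df: pd.DataFrame, path: Path) -> None:
    """Mean NCC vs mean absolute amplitude, one marker per subject."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for marker, (lab, sub) in zip("os^Dv<>*", df.groupby("group_label", sort=True)):
        ax.scatter(sub["mean_ncc"], sub["mean_abs_amplitude_px"], label=lab, marker=marker)
    ax.set_xlabel("mean NCC")
    ax.set_ylabel("mean absolute amplitude (px)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def motion_direction_overlay(
    profiles: ProfileSeries,
    frame_a: int,
    frame_b: int,
    path: str | Path,
    subsample: int = 8,
) -> None:
    """Arrow overlay of per-position motion direction between two frames.

    Draws the diaphragm profile of ``frame_a`` (valid-frame index) and, at
    every ``subsample``-th column flagged in both frames, an arrow whose
    vertical direction is the sign of z(y, t_b) - z(y, t_a).  Opposed
    arrows at anterior vs posterior columns visualize paradoxical motion.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    M = profiles.frame_count
    if not (0 <= frame_a < M and 0 <= frame_b < M):
        raise ConfigError(f"frame indices {frame_a}, {frame_b} outside 0..{M - 1}")
    both = profiles.flags[frame_a] & profiles.flags[frame_b]
    ys = np.flatnonzero(both)[::subsample]
    za = profiles.z_dia[frame_a, ys]
    dz = profiles.z_dia[frame_b, ys] - za

    fig, ax = plt.subplots(figsize=(6, 4))
    ya_all = np.flatnonzero(profiles.flags[frame_a])
    ax.plot(ya_all, profiles.z_dia[frame_a, ya_all], color="0.4", lw=1.5, label="profile (t_a)")
    # fixed-length direction arrows; zero difference draws a dot-length arrow
    arrow_len = 6.0 * np.sign(dz)
    ax.quiver(
        ys, za, np.zeros_like(za), arrow_len,
        angles="xy", scale_units="xy", scale=1.0,
        color=np.where(dz >= 0, "tab:red", "tab:blue"),
        width=0.004,
    )
    ax.set_xlabel("Y (anterior -> posterior, px)")
    ax.set_ylabel("Z (superior-positive, px)")
    ax.set_title(f"motion direction: frames {frame_a} -> {frame_b}")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
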