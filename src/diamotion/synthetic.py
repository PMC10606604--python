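"""Synthetic diaphragm motion: waveform surfaces and rasterized mask series.

The generator emulates the acquisition geometry of dynamic sagittal
thoracic MRI (256 x 256 px frames, 8.33 frames/s, 1.5 mm/px, ~1200 frames
covering > 2 min of quiet breathing) with a controllable respiratory
structure:

* a quadratic dome baseline z0(y) for the diaphragm's superior boundary;
* per-cycle period and peak-amplitude jitter (independent truncated-normal
  draws per breath) to mimic natural cycle-to-cycle variability;
* an optional linear phase lag 0 -> phi_max across the anterior-posterior
  axis, modelling regional asynchronization;
* an optional anterior column fraction moving in antiphase (paradoxical
  motion, as seen in severe COPD);
* additive Gaussian vertical noise standing in for segmentation jitter.

The vertical position of column y at time t is

    z(y, t) = z0(y) - A(t) * sin(theta(t) + phi(y)) + eps,

where theta advances by 2*pi per breath through the drawn per-cycle
periods and A(t) interpolates linearly between consecutive per-cycle
amplitude draws (so the surface stays continuous across cycle
boundaries).  The initial phase puts an end-expiratory peak exactly at
each cycle start, which makes the drawn per-cycle parameters directly
recoverable from detected peaks.

Masks are realized as a band of fixed thickness hanging below the rounded
curve: only the superior boundary matters to the pipeline, so no anatomy
is painted.  Same seed and config give bit-identical output.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .errors import ConfigError
from .mask_io import MaskSeries
from .waveforms import WaveformSet

__all__ = ["SyntheticConfig", "simulate_waveforms", "rasterize_masks"]


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic breathing generator (defaults = study geometry)."""

    image_size: tuple[int, int] = (256, 256)  # (rows, cols)
    n_frames: int = 1200
    frame_rate: float = 8.33  # frames/s
    pixel_spacing: float = 1.5  # mm/px
    dome_span: tuple[int, int] = (40, 215)  # first/last dome column, inclusive
    dome_apex_z: float = 150.0  # apex height, px above the inferior edge
    dome_drop_px: float = 30.0  # how far the dome edges sit below the apex
    amplitude_px: float = 8.0  # mean breath amplitude A (12 mm at 1.5 mm/px)
    period_s: float = 4.0  # mean cycle period (15 breaths/min)
    period_jitter_sd: float = 0.4  # per-cycle period SD, s
    amplitude_jitter_sd: float = 0.8  # per-cycle amplitude SD, px
    phase_lag_max_rad: float = 0.0  # linear phase ramp across columns
    paradoxical_fraction: float = 0.0  # anterior fraction moving in antiphase
    field_thickness_px: int = 8
    noise_sd_px: float = 0.0
    seed: int = 0
    subject_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.amplitude_px < 0:
            raise ConfigError("amplitude_px must be >= 0")
        if self.period_s <= 0:
            raise ConfigError("period_s must be > 0")
        if not (0.0 <= self.paradoxical_fraction <= 1.0):
            raise ConfigError("paradoxical_fraction must lie in [0, 1]")
        if self.n_frames < 2 or self.frame_rate <= 0 or self.pixel_spacing <= 0:
            raise ConfigError("need n_frames >= 2, frame_rate > 0, pixel_spacing > 0")
        y0, y1 = self.dome_span
        if not (0 <= y0 < y1 < self.image_size[1]):
            raise ConfigError(f"dome_span {self.dome_span} outside image columns")
        if self.field_thickness_px < 1:
            raise ConfigError("field_thickness_px must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_size"] = list(self.image_size)
        d["dome_span"] = list(self.dome_span)
        return d


def _dome(cfg: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Columns and baseline curve z0(y) of the quadratic dome."""
    y0, y1 = cfg.dome_span
    cols = np.arange(y0, y1 + 1)
    yc = 0.5 * (y0 + y1)
    half = 0.5 * (y1 - y0)
    z0 = cfg.dome_apex_z - cfg.dome_drop_px * ((cols - yc) / half) ** 2
    return cols, z0


def _phase_lag(cfg: SyntheticConfig, n_cols: int) -> np.ndarray:
    """phi(y): linear 0 -> phi_max ramp; antiphase pi on the anterior block."""
    if n_cols > 1:
        phi = cfg.phase_lag_max_rad * np.arange(n_cols) / (n_cols - 1)
    else:
        phi = np.zeros(n_cols)
    n_par = int(round(cfg.paradoxical_fraction * n_cols))
    phi[:n_par] = np.pi
    return phi


def _draw_cycles(cfg: SyntheticConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle (periods, amplitudes) covering the full duration plus one."""
    duration = cfg.n_frames / cfg.frame_rate
    n_cycles = int(np.ceil(duration / cfg.period_s * 1.5)) + 3
    periods = rng.normal(cfg.period_s, cfg.period_jitter_sd, n_cycles)
    periods = np.clip(periods, 0.1 * cfg.period_s, None)  # keep periods positive
    while periods.sum() < duration:  # pragma: no cover - extreme jitter only
        extra = np.clip(rng.normal(cfg.period_s, cfg.period_jitter_sd, 4), 0.1 * cfg.period_s, None)
        periods = np.concatenate([periods, extra])
    amps = np.clip(rng.normal(cfg.amplitude_px, cfg.amplitude_jitter_sd, periods.size + 1), 0.0, None)
    return periods, amps


def simulate_waveforms(cfg: SyntheticConfig) -> tuple[WaveformSet, dict]:
    """Generate the motion surface z(y, t) and its ground-truth record.

    Returns
    -------
    (WaveformSet, dict)
        The waveform set holds raw, mean and centered positions for every
        dome column.  The ground-truth dict records the drawn per-cycle
        ``periods`` (s) and ``amplitudes`` (px), the ``cycle_starts``
        times, the per-column phase lag ``phi`` and the baseline ``z0``.
    """
    rng = np.random.default_rng(cfg.seed)
    cols, z0 = _dome(cfg)
    phi = _phase_lag(cfg, cols.size)
    periods, amps = _draw_cycles(cfg, rng)
    starts = np.concatenate([[0.0], np.cumsum(periods)])

    t = np.arange(cfg.n_frames) / cfg.frame_rate
    c = np.searchsorted(starts, t, side="right") - 1
    frac = (t - starts[c]) / periods[c]
    theta = 1.5 * np.pi + 2.0 * np.pi * (c + frac)  # peak (sin = -1) at cycle starts
    envelope = amps[c] + (amps[c + 1] - amps[c]) * frac

    surface = z0[:, None] - envelope[None, :] * np.sin(theta[None, :] + phi[:, None])
    if cfg.noise_sd_px > 0:
        surface = surface + rng.normal(0.0, cfg.noise_sd_px, surface.shape)

    z_mean = surface.mean(axis=1)
    waves = WaveformSet(
        positions=cols,
        times=t,
        z_raw=surface,
        z_mean=z_mean,
        z_centered=surface - z_mean[:, None],
        pixel_spacing=cfg.pixel_spacing,
        frame_rate=cfg.frame_rate,
        subject_id=cfg.subject_id,
        selection=None,
    )
    n_complete = int(np.searchsorted(starts[1:], t[-1], side="right"))
    truth = {
        "periods": periods[:n_complete],
        "amplitudes": amps[:n_complete],
        "cycle_starts": starts[:n_complete],
        "phi": phi,
        "z0": z0,
        "config": cfg.to_dict(),
    }
    return waves, truth


def rasterize_masks(waves: WaveformSet, cfg: SyntheticConfig) -> MaskSeries:
    """Render a simulated surface into a binary diaphragm-field mask series.

    Each frame paints, per dome column, a vertical band of
    ``field_thickness_px`` pixels whose top row is the rounded curve, so
    profile extraction recovers the surface within the 0.5 px rounding
    bound.

    Raises
    ------
    ConfigError
        If the curve (or its band) leaves the canvas vertically.
    """
    n_rows, n_cols = cfg.image_size
    z = np.asarray(waves.z_raw)
    top_row = (n_rows - 1) - np.rint(z).astype(np.int64)  # (N, M)
    if top_row.min() < 0 or (top_row.max() + cfg.field_thickness_px - 1) > n_rows - 1:
        raise ConfigError("amplitude exceeds canvas: diaphragm curve leaves the image")
    frames = np.zeros((waves.n_frames, n_rows, n_cols), dtype=bool)
    rows_grid = np.arange(n_rows)[:, None]
    for m in range(waves.n_frames):
        tops = top_row[:, m][None, :]  # (1, N)
        band = (rows_grid >= tops) & (rows_grid < tops + cfg.field_thickness_px)
        frames[m][:, waves.positions] = band
    return MaskSeries(
        frames=frames,
        frame_rate=cfg.frame_rate,
        pixel_spacing=cfg.pixel_spacing,
        subject_id=waves.subject_id,
    )
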