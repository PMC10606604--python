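import numpy as np
import pytest

from diamotion import MaskSeries, ProfileSeries, SyntheticConfig, simulate_waveforms


def make_mask_series(frames, frame_rate=8.33, pixel_spacing=1.5, subject_id="test"):
    return MaskSeries(
        frames=np.asarray(frames, dtype=bool),
        frame_rate=frame_rate,
        pixel_spacing=pixel_spacing,
        subject_id=subject_id,
    )


def make_profiles(starts, ends, width=120, z_value=50.0, n_rows=200, frame_rate=8.33):
    """ProfileSeries with one contiguous flat run [start, end] per frame."""
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    M = starts.size
    flags = np.zeros((M, width), dtype=bool)
    z = np.full((M, width), np.nan)
    for m in range(M):
        flags[m, starts[m] : ends[m] + 1] = True
        z[m, starts[m] : ends[m] + 1] = z_value
    return ProfileSeries(
        flags=flags,
        z_dia=z,
        lengths=flags.sum(axis=1).astype(np.int64),
        y_start=starts.astype(np.int64),
        y_end=ends.astype(np.int64),
        frame_times=np.arange(M) / frame_rate,
        frame_indices=np.arange(M),
        invalid_frame_indices=np.array([], dtype=np.int64),
        n_rows=n_rows,
        frame_rate=frame_rate,
        pixel_spacing=1.5,
    )


def profiles_from_surface(surface, positions, width=256, n_rows=256, frame_rate=8.0):
    """ProfileSeries whose z_dia is an exact (unrasterized) motion surface."""
    surface = np.asarray(surface)  # (N positions, M frames)
    N, M = surface.shape
    flags = np.zeros((M, width), dtype=bool)
    z = np.full((M, width), np.nan)
    flags[:, positions] = True
    z[:, positions] = surface.T
    return ProfileSeries(
        flags=flags,
        z_dia=z,
        lengths=flags.sum(axis=1).astype(np.int64),
        y_start=np.full(M, positions[0], dtype=np.int64),
        y_end=np.full(M, positions[-1], dtype=np.int64),
        frame_times=np.arange(M) / frame_rate,
        frame_indices=np.arange(M),
        invalid_frame_indices=np.array([], dtype=np.int64),
        n_rows=n_rows,
        frame_rate=frame_rate,
        pixel_spacing=1.5,
    )


@pytest.fixture(scope="session")
def integer_cycle_cfg():
    """Noiseless sinusoid sampled over exactly 10 cycles (32 frames each)."""
    return SyntheticConfig(
        n_frames=320,
        frame_rate=8.0,
        period_s=4.0,
        amplitude_px=8.0,
        period_jitter_sd=0.0,
        amplitude_jitter_sd=0.0,
        noise_sd_px=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def integer_cycle_waves(integer_cycle_cfg):
    waves, truth = simulate_waveforms(integer_cycle_cfg)
    return waves, truth
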