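"""Profile extraction: mask -> per-column superior boundary."""

import numpy as np
import pytest

from diamotion import (
    ProfileError,
    SyntheticConfig,
    extract_profile_series,
    profile_lengths,
    rasterize_masks,
    read_mask_series,
    simulate_waveforms,
    write_mask_series,
)

from conftest import make_mask_series


def test_superior_boundary_by_hand():
    """Foreground at (r2,c1), (r3,c1), (r2,c2) of a 5x5 frame: z = 4 - row."""
    frame = np.zeros((5, 5), dtype=bool)
    frame[2, 1] = frame[3, 1] = frame[2, 2] = True
    prof = extract_profile_series(make_mask_series([frame]))
    assert prof.flags[0].tolist() == [False, True, True, False, False]
    assert prof.z_dia[0, 1] == 2 and prof.z_dia[0, 2] == 2
    assert prof.lengths[0] == 2
    assert prof.y_start[0] == 1 and prof.y_end[0] == 2


def test_centroid_collapse():
    frame = np.zeros((5, 5), dtype=bool)
    frame[2, 1] = frame[3, 1] = frame[2, 2] = True
    prof = extract_profile_series(make_mask_series([frame]), collapse="centroid")
    # column 1 has rows 2,3 -> mean row 2.5 -> z = 4 - 2.5
    assert prof.z_dia[0, 1] == pytest.approx(1.5)
    assert prof.z_dia[0, 2] == pytest.approx(2.0)


def test_single_gap_repaired_by_interpolation():
    """Flags 1,0,1 at y=3,4,5 with z 10 and 12 -> z(4)=11, length 3."""
    frame = np.zeros((20, 8), dtype=bool)
    frame[19 - 10, 3] = True
    frame[19 - 12, 5] = True
    prof = extract_profile_series(make_mask_series([frame]))
    assert prof.flags[0, 3:6].all()
    assert prof.z_dia[0, 4] == pytest.approx(11.0)
    assert profile_lengths(prof)[0] == 3


def test_wide_gap_truncates_to_longest_run():
    frame = np.zeros((10, 10), dtype=bool)
    frame[5, 0:2] = True  # run of 2
    frame[5, 5:9] = True  # run of 4 (gap of 3 between)
    prof = extract_profile_series(make_mask_series([frame]))
    assert prof.flags[0].tolist() == [False] * 5 + [True] * 4 + [False]
    assert prof.y_start[0] == 5 and prof.y_end[0] == 8


def test_empty_frames_excluded_and_tolerance():
    good = np.zeros((6, 6), dtype=bool)
    good[3, 1:5] = True
    empty = np.zeros((6, 6), dtype=bool)
    frames = [good] * 19 + [empty]
    prof = extract_profile_series(make_mask_series(frames))
    assert prof.frame_count == 19
    assert prof.invalid_frame_indices.tolist() == [19]
    assert prof.frame_indices.tolist() == list(range(19))
    with pytest.raises(ProfileError):
        extract_profile_series(make_mask_series([good, empty, empty]))


def test_orientation_flip_negates_z():
    """Upside-down masks give z' = (n_rows - 1) - z for thickness-1 fields."""
    cfg = SyntheticConfig(n_frames=20, field_thickness_px=1, seed=3)
    waves, _ = simulate_waveforms(cfg)
    masks = rasterize_masks(waves, cfg)
    prof = extract_profile_series(masks)
    flipped = make_mask_series(masks.frames[:, ::-1, :], masks.frame_rate, masks.pixel_spacing)
    prof_f = extract_profile_series(flipped)
    np.testing.assert_allclose(
        prof_f.z_dia[prof.flags], (masks.shape[0] - 1) - prof.z_dia[prof.flags]
    )


def test_vertical_translation_preserves_lengths():
    cfg = SyntheticConfig(n_frames=10, seed=4)
    waves, _ = simulate_waveforms(cfg)
    masks = rasterize_masks(waves, cfg)
    prof = extract_profile_series(masks)
    shifted = make_mask_series(np.roll(masks.frames, 20, axis=1))
    prof_s = extract_profile_series(shifted)
    np.testing.assert_array_equal(profile_lengths(prof), profile_lengths(prof_s))
    np.testing.assert_allclose(prof_s.z_dia[prof.flags], prof.z_dia[prof.flags] - 20)


def test_extraction_idempotent_on_rasterized_profile():
    """Re-rasterizing an extracted profile and extracting again is a fixpoint."""
    cfg = SyntheticConfig(n_frames=15, seed=5, noise_sd_px=0.4)
    waves, _ = simulate_waveforms(cfg)
    masks = rasterize_masks(waves, cfg)
    prof1 = extract_profile_series(masks)
    # rebuild thickness-1 masks from the extracted profile
    n_rows = masks.shape[0]
    frames = np.zeros_like(masks.frames)
    for m in range(prof1.frame_count):
        ys = np.flatnonzero(prof1.flags[m])
        rows = (n_rows - 1 - np.rint(prof1.z_dia[m, ys])).astype(int)
        frames[m, rows, ys] = True
    prof2 = extract_profile_series(make_mask_series(frames))
    np.testing.assert_array_equal(prof1.flags, prof2.flags)
    np.testing.assert_allclose(prof1.z_dia[prof1.flags], prof2.z_dia[prof2.flags])


@pytest.mark.parametrize("fmt,suffix", [("tiff", ".tif"), ("nifti", ".nii.gz"), ("png", "")])
def test_reader_roundtrip(tmp_path, fmt, suffix):
    cfg = SyntheticConfig(n_frames=4, image_size=(64, 64), dome_span=(10, 50),
                          dome_apex_z=40.0, dome_drop_px=8.0, amplitude_px=3.0, seed=6)
    waves, _ = simulate_waveforms(cfg)
    masks = rasterize_masks(waves, cfg)
    if fmt == "png":
        import imageio.v3 as iio

        d = tmp_path / "frames"
        d.mkdir()
        for m in range(masks.frame_count):
            iio.imwrite(d / f"frame_{m:04d}.png", masks.frames[m].astype(np.uint8) * 255)
        back = read_mask_series(d, frame_rate=masks.frame_rate, pixel_spacing=1.5)
    else:
        path = write_mask_series(masks, tmp_path / f"s{suffix}", fmt=fmt)
        back = read_mask_series(path)
        assert back.frame_rate == pytest.approx(masks.frame_rate)
    np.testing.assert_array_equal(back.frames, masks.frames)
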