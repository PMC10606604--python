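"""Subject pipeline orchestration, group statistics and the CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from diamotion import (
    ConfigError,
    SyntheticConfig,
    extract_profile_series,
    group_report,
    motion_direction_overlay,
    rasterize_masks,
    run_subject,
    simulate_waveforms,
)
from diamotion.cli import main
from diamotion.report import SubjectResult


def _synthetic_masks(seed=1, n_frames=160, **kw):
    cfg = SyntheticConfig(n_frames=n_frames, frame_rate=8.0, seed=seed,
                          subject_id=f"s{seed}", **kw)
    waves, _ = simulate_waveforms(cfg)
    return rasterize_masks(waves, cfg), cfg


def test_run_subject_completes_with_artifacts(tmp_path):
    masks, _ = _synthetic_masks(seed=1)
    res = run_subject(masks, out_dir=tmp_path, group_label="normal")
    assert -1.0 <= res.mean_ncc <= 1.0
    assert res.mean_abs_amplitude_px >= 0.0
    assert res.cycle_stats is not None and res.cycle_stats["n_cycles"] >= 2
    for suffix in ["profiles.csv", "waveforms.csv", "ncc.csv", "ncc.png", "result.json"]:
        assert (tmp_path / f"s1_{suffix}").exists()
    stored = json.loads((tmp_path / "s1_result.json").read_text())
    assert stored["mean_ncc"] == pytest.approx(res.mean_ncc)


def test_run_subject_tiny_series_flags_cycles_but_reports_metrics():
    """A 10-frame series cannot contain cycles; NCC/limitation still computed."""
    masks, _ = _synthetic_masks(seed=2, n_frames=10)
    res = run_subject(masks)
    assert res.cycle_stats is None
    assert any("cycles" in f for f in res.qc_flags)
    assert np.isfinite(res.mean_ncc)
    assert np.isfinite(res.mean_abs_amplitude_px)


def test_run_subject_deterministic():
    masks, _ = _synthetic_masks(seed=3, noise_sd_px=0.3)
    r1 = run_subject(masks)
    r2 = run_subject(masks)
    assert r1.to_dict() == r2.to_dict()


def _fake_result(sid, group, ncc_val, amp):
    return SubjectResult(
        subject_id=sid, group_label=group, mean_ncc=ncc_val,
        mean_abs_amplitude_px=amp, mean_abs_amplitude_mm=amp * 1.5,
        y_mid=128, cycle_stats=None, selection={}, qc_flags=[],
    )


def test_group_report_identical_groups_p_one():
    res = [_fake_result(f"n{i}", "normal", v, a)
           for i, (v, a) in enumerate([(0.95, 5.0), (0.96, 5.2), (0.97, 5.4)])]
    res += [_fake_result(f"p{i}", "copd", v, a)
            for i, (v, a) in enumerate([(0.95, 5.0), (0.96, 5.2), (0.97, 5.4)])]
    rep = group_report(res, test="mann_whitney")
    assert rep["tests"][0]["p_mean_ncc"] == pytest.approx(1.0)
    assert rep["tests"][0]["p_mean_abs_amplitude"] == pytest.approx(1.0)


def test_group_report_single_group_summary_only(tmp_path):
    res = [_fake_result(f"n{i}", "normal", 0.9 + 0.01 * i, 5.0) for i in range(3)]
    rep = group_report(res, out_dir=tmp_path)
    assert rep["tests"] == []
    assert rep["groups"][0]["n"] == 3
    assert (tmp_path / "group_summary.csv").exists()
    assert (tmp_path / "ncc_vs_amplitude.png").exists()


def test_group_report_degenerate_group_errors():
    res = [_fake_result("n0", "normal", 0.95, 5.0), _fake_result("n1", "normal", 0.96, 5.1),
           _fake_result("p0", "copd", 0.5, 3.0)]
    with pytest.raises(ConfigError):
        group_report(res)


def test_simulated_groups_separate_on_mean_ncc():
    """Six synchronized vs six fully lagged subjects: mean-NCC p < 0.01."""
    results = []
    for i in range(6):
        for group, phi in (("normal", 0.0), ("copd", np.pi)):
            cfg = SyntheticConfig(n_frames=120, frame_rate=8.0, seed=100 + 10 * i + (phi > 0),
                                  phase_lag_max_rad=phi, noise_sd_px=0.3,
                                  subject_id=f"{group}{i}")
            waves, _ = simulate_waveforms(cfg)
            results.append(run_subject(rasterize_masks(waves, cfg), group_label=group))
    rep = group_report(results)
    assert rep["tests"][0]["p_mean_ncc"] < 0.01


def test_motion_direction_overlay(tmp_path):
    masks, _ = _synthetic_masks(seed=4, paradoxical_fraction=0.2)
    prof = extract_profile_series(masks)
    out = tmp_path / "dir.png"
    motion_direction_overlay(prof, 0, 8, out)
    assert out.stat().st_size > 0
    motion_direction_overlay(prof, 3, 3, tmp_path / "same.png")  # zero motion ok
    with pytest.raises(ConfigError):
        motion_direction_overlay(prof, 0, 10_000, tmp_path / "bad.png")


def test_cli_simulate_then_run_then_report(tmp_path):
    runner = CliRunner()
    cfg_yaml = tmp_path / "sim.yaml"
    cfg_yaml.write_text(
        "synthetic:\n  n_frames: 120\n  frame_rate: 8.0\n  subject_id: subj\n"
    )
    r = runner.invoke(main, ["simulate", "--config", str(cfg_yaml),
                             "--out", str(tmp_path / "sim"), "--seed", "5"])
    assert r.exit_code == 0, r.output
    tif = tmp_path / "sim" / "subj.tif"
    assert tif.exists() and (tmp_path / "sim" / "subj_truth.json").exists()

    r = runner.invoke(main, ["run", str(tif), "--out", str(tmp_path / "out"),
                             "--group", "normal"])
    assert r.exit_code == 0, r.output
    result = json.loads(r.output[r.output.index("{"):])
    assert 0.9 <= result["mean_ncc"] <= 1.0

    # second subject so the report has two entries in one group
    j2 = json.loads((tmp_path / "out" / "subj_result.json").read_text())
    j2["subject_id"] = "subj2"
    (tmp_path / "out" / "subj2_result.json").write_text(json.dumps(j2))
    r = runner.invoke(main, ["report", str(tmp_path / "out" / "subj_result.json"),
                             str(tmp_path / "out" / "subj2_result.json"),
                             "--out", str(tmp_path / "rep")])
    assert r.exit_code == 0, r.output
    assert (tmp_path / "rep" / "group_summary.csv").exists()


def test_cli_corrupt_input_exit_code(tmp_path):
    bad = tmp_path / "bad.tif"
    bad.write_bytes(b"not a tiff at all")
    r = CliRunner().invoke(main, ["run", str(bad), "--out", str(tmp_path / "o")])
    assert r.exit_code == 2  # reader stage
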