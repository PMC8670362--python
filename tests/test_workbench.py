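import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from petmc import model, phantom, workbench
from petmc.model import MotionEqNet, MotionNetConfig, TrainedModel
from petmc.motionsim import MotionTrace
from petmc.phantom import DynamicSequence, default_frame_schedule
from petmc.workbench import cli, load_sequence, load_trace, save_sequence, save_trace

SMALL_PHANTOM_YAML = {
    "phantom": {
        "grid_shape": [24, 24, 12],
        "lv_center": [14.5, 12.0, 6.0],
        "lv_pool_radii": [2.75, 2.75, 2.25],
        "myo_outer_radii": [4.75, 4.75, 3.75],
        "rv_center": [7.5, 12.0, 6.0],
        "rv_pool_radii": [3.0, 4.0, 2.25],
        "septal_mid": [11, 12, 6],
    },
    "n_sequences": 1,
}


@pytest.fixture
def runner():
    return CliRunner()


def _write_config(tmp_path, extra=None):
    cfg = dict(SMALL_PHANTOM_YAML)
    if extra:
        cfg.update(extra)
    path = tmp_path / "config.yaml"
    path.write_text(yaml.safe_dump(cfg))
    return path


class TestSequenceIO:
    def test_round_trip_bit_identical(self, tmp_path, small_seq):
        seq, _, _ = small_seq
        path = save_sequence(seq, tmp_path / "seq")
        loaded = load_sequence(path)
        np.testing.assert_array_equal(loaded.frames, seq.frames)
        np.testing.assert_array_equal(loaded.schedule.start_s, seq.schedule.start_s)
        assert loaded.voxel_mm == seq.voxel_mm

    def test_missing_sidecar_rejected(self, tmp_path, small_seq):
        seq, _, _ = small_seq
        path = save_sequence(seq, tmp_path / "seq")
        path.with_suffix(".json").unlink()
        with pytest.raises(FileNotFoundError, match="sidecar"):
            load_sequence(path)

    def test_frame_count_mismatch_rejected(self, tmp_path, small_seq):
        seq, _, _ = small_seq
        path = save_sequence(seq, tmp_path / "seq")
        sidecar = path.with_suffix(".json")
        meta = json.loads(sidecar.read_text())
        meta["start_s"] = meta["start_s"][:-1]
        meta["duration_s"] = meta["duration_s"][:-1]
        sidecar.write_text(json.dumps(meta))
        with pytest.raises(ValueError, match="frames"):
            load_sequence(path)


class TestTraceIO:
    def test_round_trip_exact(self, tmp_path):
        shifts = np.zeros((27, 3))
        shifts[5:9] = [1.2, -0.3, 2.1]
        trace = MotionTrace(shifts)
        path = save_trace(trace, tmp_path / "trace.csv", voxel_mm=(3.125, 3.125, 3.27))
        loaded = load_trace(path)
        np.testing.assert_array_equal(loaded.shifts, trace.shifts)
        mirror = json.loads((tmp_path / "trace.csv.json").read_text())
        assert mirror["voxel_mm"] == [3.125, 3.125, 3.27]

    def test_row_count_preserved(self, tmp_path):
        path = save_trace(MotionTrace.zero(27), tmp_path / "t.csv")
        assert len(load_trace(path)) == 27

    def test_unquantized_component_warns_and_quantizes(self, tmp_path):
        path = tmp_path / "t.csv"
        rows = ["frame_index,dx_vox,dy_vox,dz_vox"]
        rows += [f"{i + 1},0.0,0.0,0.0" for i in range(26)] + ["27,0.0,0.0,0.0"]
        rows[5] = "5,0.123,0.0,0.0"
        path.write_text("\n".join(rows))
        with pytest.warns(UserWarning, match="quantiz"):
            trace = load_trace(path)
        assert trace.shifts[4, 0] == pytest.approx(0.1)

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "t.csv"
        rows = ["frame_index,dx_vox,dy_vox,dz_vox"]
        rows += [f"{i + 1},0.0,0.0,0.0" for i in range(27)]
        rows[3] = "3,nan,0.0,0.0"
        path.write_text("\n".join(rows))
        with pytest.raises(ValueError, match="line 4"):
            load_trace(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("frame_index,dx_vox\n1,0.0\n")
        with pytest.raises(ValueError, match="_vox"):
            load_trace(path)


class TestCli:
    def test_simulate_deterministic(self, runner, tmp_path):
        cfg = _write_config(tmp_path)
        for name in ("a", "b"):
            result = runner.invoke(
                cli,
                ["simulate", "--config", str(cfg), "--seed", "7", "--out", str(tmp_path / name)],
            )
            assert result.exit_code == 0, result.output
        sa = load_sequence(tmp_path / "a" / "seq000.nii")
        sb = load_sequence(tmp_path / "b" / "seq000.nii")
        np.testing.assert_array_equal(sa.frames, sb.frames)
        run_meta = json.loads((tmp_path / "a" / "run.json").read_text())
        assert run_meta["seed"] == 7
        assert "config_hash" in run_meta

    def test_simulate_with_motion_writes_trace(self, runner, tmp_path):
        cfg = _write_config(tmp_path, {"motion": {"enabled": True, "type": "square"}})
        result = runner.invoke(
            cli, ["simulate", "--config", str(cfg), "--seed", "1", "--out", str(tmp_path / "o")]
        )
        assert result.exit_code == 0, result.output
        trace = load_trace(tmp_path / "o" / "seq000_trace.csv")
        assert 5 <= trace.motion_frame_count() <= 11

    def test_evaluate_zero_error_on_identical_traces(self, runner, tmp_path):
        shifts = np.zeros((27, 3))
        shifts[7:10] = [1.0, 1.0, 0]
        save_trace(MotionTrace(shifts), tmp_path / "t.csv")
        out = tmp_path / "metrics.json"
        result = runner.invoke(
            cli,
            [
                "evaluate",
                "--pred", str(tmp_path / "t.csv"),
                "--truth", str(tmp_path / "t.csv"),
                "--out", str(out),
            ],
        )
        assert result.exit_code == 0, result.output
        payload = json.loads(out.read_text())
        assert payload["mean_motion_error_mm"] == 0.0
        assert payload["max_motion_error_mm"] == 0.0

    def test_correct_with_zero_stub_equals_cropped_input(
        self, runner, tmp_path, small_seq
    ):
        from petmc.preprocess import crop_window

        seq, _, _ = small_seq
        save_sequence(seq, tmp_path / "seq")
        cfg = MotionNetConfig(
            conv_channels=(2, 2), in_channels=2, crop_size=(8, 8, 4)
        )
        net = MotionEqNet(cfg, np.random.default_rng(0))
        # zero the head so every prediction is exactly (0, 0, 0)
        net.head.weight.data[:] = 0
        net.head.bias.data[:] = 0
        stub = TrainedModel(
            net=net,
            net_config=cfg,
            fingerprint={"crop_size": [8, 8, 4], "center": [11, 12, 6]},
        )
        stub.save(tmp_path / "early")
        stub.save(tmp_path / "late")
        result = runner.invoke(
            cli,
            [
                "correct",
                "--input", str(tmp_path / "seq.nii"),
                "--early", str(tmp_path / "early"),
                "--late", str(tmp_path / "late"),
                "--out", str(tmp_path / "out"),
            ],
        )
        assert result.exit_code == 0, result.output
        corrected = load_sequence(tmp_path / "out" / "corrected.nii")
        expected = np.stack([crop_window(f, (11, 12, 6), (8, 8, 4)) for f in seq.frames])
        np.testing.assert_allclose(corrected.frames, expected, atol=1e-6)
        trace = load_trace(tmp_path / "out" / "trace.csv")
        assert trace.motion_frame_count() == 0
        log = json.loads((tmp_path / "out" / "iterations.json").read_text())
        assert log["iterations"] == {"early": 1, "late": 1}

    def test_unknown_flag_nonzero_exit(self, runner):
        result = runner.invoke(cli, ["simulate", "--bogus"])
        assert result.exit_code != 0


class TestTacIO:
    def test_round_trip(self, tmp_path, rng):
        from petmc.workbench import load_tac, save_tac

        sched = default_frame_schedule()
        tac = rng.random(27) * 1e4
        path = save_tac(tac, sched, tmp_path / "tac.csv")
        got, got_sched = load_tac(path)
        np.testing.assert_allclose(got, tac)
        np.testing.assert_allclose(got_sched.duration_s, sched.duration_s)

    def test_missing_column_rejected(self, tmp_path):
        from petmc.workbench import load_tac

        p = tmp_path / "bad.csv"
        p.write_text("frame_index,start_s\n1,0\n")
        with pytest.raises(ValueError, match="activity|duration"):
            load_tac(p)


class TestCliRegisterKinetics:
    def test_register_chain_on_motion_free_sequence(self, runner, tmp_path, small_seq):
        seq, _, _ = small_seq
        save_sequence(seq, tmp_path / "seq")
        out = tmp_path / "trace.csv"
        result = runner.invoke(
            cli,
            [
                "register",
                "--input", str(tmp_path / "seq.nii"),
                "--method", "chain",
                "--out", str(out),
            ],
        )
        assert result.exit_code == 0, result.output
        trace = load_trace(out)
        assert len(trace) == seq.n_frames
        # motion-free phantom: late frames register near zero (early frames
        # legitimately accumulate drift through the contrast change)
        assert np.all(trace.magnitudes_vox[14:] < 1.0)

    def test_kinetics_fit_outputs_parameters(self, runner, tmp_path, small_config):
        from petmc.phantom import generate_phantom
        from petmc.workbench import save_labels

        seq, labels, _ = generate_phantom(small_config, 4)
        save_sequence(seq, tmp_path / "seq")
        save_labels(labels, tmp_path / "labels", seq.voxel_mm)
        out = tmp_path / "fit.json"
        result = runner.invoke(
            cli,
            [
                "kinetics",
                "--input", str(tmp_path / "seq.nii"),
                "--labels", str(tmp_path / "labels.nii"),
                "--out", str(out),
            ],
        )
        assert result.exit_code == 0, result.output
        payload = json.loads(out.read_text())
        assert 0 < payload["K1"] < 10
        assert 0 <= payload["vb"] <= 1
        assert payload["wss"] >= 0


class TestCliTrain:
    def test_train_eq_writes_checkpoint(self, runner, tmp_path):
        cfg = _write_config(
            tmp_path,
            {
                "kind": "eq",
                "n_bases": 2,
                "crop_size": [8, 8, 4],
                "conv_channels": [2, 2],
                "center": [11, 12, 6],
                "train": {"total_samples": 16, "batch_size": 8},
            },
        )
        result = runner.invoke(
            cli, ["train", "--config", str(cfg), "--seed", "3", "--out", str(tmp_path / "m")]
        )
        assert result.exit_code == 0, result.output
        loaded = TrainedModel.load(tmp_path / "m" / "eq_net")
        assert loaded.net_config.head == "eq-classification"
        probs = loaded.predict_eq_probs(np.zeros((27, 1, 8, 8, 4)))
        assert probs.sum() == pytest.approx(1.0, abs=1e-5)
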