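"""I/O conventions and the command-line surface.

Sequences travel as uncompressed 4D NIfTI plus a JSON sidecar holding the
frame schedule and voxel size; labels as integer NIfTI; traces as CSV with
1-based frame indices; configuration as YAML.  Every artifact-producing
command records its config hash and seed in a run-metadata JSON.
"""

from __future__ import annotations

import hashlib
import json
import os
import warnings
from pathlib import Path

import click
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import baselines, correct, evaluate, kinetics, model, motionsim, phantom, preprocess
from .motionsim import MotionTrace
from .phantom import DynamicSequence, FrameSchedule, RoiLabels

__all__ = [
    "save_sequence",
    "load_sequence",
    "save_labels",
    "load_labels",
    "save_trace",
    "load_trace",
    "cli",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".json") if path.suffix == ".nii" else Path(
        str(path) + ".json"
    )


def _atomic_write(path: Path, writer) -> None:
    # keep the original extension on the temp name: nibabel infers the
    # format from the suffix
    tmp = path.with_name(path.stem + ".tmp" + path.suffix)
    writer(tmp)
    os.replace(tmp, path)


def save_sequence(seq: DynamicSequence, path) -> Path:
    """Write a 4D NIfTI (X, Y, Z, T) plus a JSON schedule sidecar."""
    path = Path(path)
    if path.suffix != ".nii":
        path = path.with_suffix(".nii")
    affine = np.diag(list(seq.voxel_mm) + [1.0])
    data = np.moveaxis(seq.frames, 0, -1)
    _atomic_write(path, lambda p: nib.save(nib.Nifti1Image(data, affine), str(p)))
    sidecar = {
        "start_s": seq.schedule.start_s.tolist(),
        "duration_s": seq.schedule.duration_s.tolist(),
        "voxel_mm": list(seq.voxel_mm),
    }
    _atomic_write(
        _sidecar_path(path), lambda p: p.write_text(json.dumps(sidecar, indent=1))
    )
    return path


def load_sequence(path) -> DynamicSequence:
    path = Path(path)
    if path.suffix != ".nii":
        path = path.with_suffix(".nii")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing schedule sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    img = nib.load(str(path))
    data = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
    schedule = FrameSchedule(
        np.asarray(meta["start_s"], float), np.asarray(meta["duration_s"], float)
    )
    if data.shape[0] != len(schedule):
        raise ValueError(
            f"sidecar lists {len(schedule)} frames but the image has {data.shape[0]}"
        )
    return DynamicSequence(
        frames=data, schedule=schedule, voxel_mm=tuple(meta["voxel_mm"])
    )


def save_labels(labels: RoiLabels, path, voxel_mm=(1.0, 1.0, 1.0)) -> Path:
    path = Path(path)
    if path.suffix != ".nii":
        path = path.with_suffix(".nii")
    affine = np.diag(list(voxel_mm) + [1.0])
    img = nib.Nifti1Image(labels.volume.astype(np.int16), affine)
    _atomic_write(path, lambda p: nib.save(img, str(p)))
    return path


def load_labels(path) -> RoiLabels:
    img = nib.load(str(path))
    return RoiLabels(np.asarray(img.dataobj).astype(np.int16))


def save_trace(trace: MotionTrace, path, voxel_mm=None) -> Path:
    """CSV with columns frame_index (1-based), dx_vox, dy_vox, dz_vox; a JSON
    mirror with voxel_mm is written when the voxel size is supplied."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "frame_index": np.arange(1, len(trace) + 1),
            "dx_vox": trace.shifts[:, 0],
            "dy_vox": trace.shifts[:, 1],
            "dz_vox": trace.shifts[:, 2],
        }
    )
    _atomic_write(path, lambda p: df.to_csv(p, index=False))
    if voxel_mm is not None:
        mirror = {
            "voxel_mm": list(voxel_mm),
            "shifts_vox": trace.shifts.tolist(),
        }
        _atomic_write(
            Path(str(path) + ".json"), lambda p: p.write_text(json.dumps(mirror))
        )
    return path


def save_tac(tac, schedule, path) -> Path:
    """TAC CSV: frame_index, start_s, duration_s, activity_bq_ml."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "frame_index": np.arange(1, len(tac) + 1),
            "start_s": np.asarray(schedule.start_s, float),
            "duration_s": np.asarray(schedule.duration_s, float),
            "activity_bq_ml": np.asarray(tac, float),
        }
    )
    _atomic_write(path, lambda p: df.to_csv(p, index=False))
    return path


def load_tac(path):
    """Returns ``(tac, schedule)`` from a TAC CSV."""
    df = pd.read_csv(path)
    for col in ("frame_index", "start_s", "duration_s", "activity_bq_ml"):
        if col not in df.columns:
            raise ValueError(f"TAC file {path} lacks column {col!r}")
    schedule = FrameSchedule(
        df["start_s"].to_numpy(float), df["duration_s"].to_numpy(float)
    )
    return df["activity_bq_ml"].to_numpy(float), schedule


def load_trace(path) -> MotionTrace:
    df = pd.read_csv(path)
    required = ["frame_index", "dx_vox", "dy_vox", "dz_vox"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"trace file {path} lacks column {col!r}")
    for i, row in df.iterrows():
        if not np.isfinite([row.dx_vox, row.dy_vox, row.dz_vox]).all():
            raise ValueError(f"malformed trace row at line {i + 2} of {path}")
    shifts = df[["dx_vox", "dy_vox", "dz_vox"]].to_numpy(dtype=float)
    q = motionsim.quantize(shifts)
    if not np.allclose(shifts, q, atol=1e-9):
        warnings.warn(
            f"{path}: shift components not multiples of 0.1 voxel; quantizing"
        )
    return MotionTrace(q)


# --------------------------------------------------------------------- CLI


def _load_config(path) -> dict:
    if path is None:
        return {}
    with open(path) as f:
        return yaml.safe_load(f) or {}


def _write_run_metadata(out_dir: Path, config: dict, seed: int) -> None:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    meta = {
        "config_hash": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "config": config,
    }
    _atomic_write(out_dir / "run.json", lambda p: p.write_text(json.dumps(meta, indent=1)))


def _phantom_config(config: dict) -> phantom.PhantomConfig:
    kw = dict(config.get("phantom", {}))
    for key in ("grid_shape", "voxel_mm", "delay_range_s", "k1_range", "k2_range", "vb_range"):
        if key in kw:
            kw[key] = tuple(kw[key])
    return phantom.PhantomConfig(**kw)


@click.group()
def cli():
    """Dynamic cardiac PET inter-frame motion simulation and correction."""


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", "out_dir", type=click.Path(), required=True)
def simulate(config_path, seed, out_dir):
    """Generate phantom sequences (optionally motion-corrupted)."""
    config = _load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    pcfg = _phantom_config(config)
    n_seq = int(config.get("n_sequences", 1))
    motion_cfg = config.get("motion", {})
    records = []
    for i in range(n_seq):
        seq, labels, n_eq = phantom.generate_phantom(pcfg, rng)
        stem = out / f"seq{i:03d}"
        save_sequence(seq, stem)
        save_labels(labels, Path(str(stem) + "_labels"), seq.voxel_mm)
        record = {"sequence": stem.name, "n_eq_truth": n_eq}
        if motion_cfg.get("enabled", False):
            mtype = motion_cfg.get("type") or rng.choice(motionsim.MOTION_TYPES)
            sim_cfg = motionsim.MotionSimConfig(
                motion_frames_range=tuple(motion_cfg.get("motion_frames_range", (5, 11))),
                initial_shift_vox=0.0,
                temporal_jitter=0,
            )
            trace = motionsim.simulate_trace(mtype, seq.n_frames, rng, sim_cfg)
            corrupted = motionsim.shift_frames(seq, trace)
            save_sequence(corrupted, Path(str(stem) + "_motion"))
            save_trace(trace, Path(str(stem) + "_trace.csv"), seq.voxel_mm)
            record["motion_type"] = str(mtype)
        records.append(record)
    _atomic_write(out / "sequences.json", lambda p: p.write_text(json.dumps(records, indent=1)))
    _write_run_metadata(out, config, seed)


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", "out_dir", type=click.Path(), required=True)
def train(config_path, seed, out_dir):
    """Train EQ and/or motion networks at the configured scale."""
    config = _load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    pcfg = _phantom_config(config)
    n_bases = int(config.get("n_bases", 8))
    bases, eqs = [], []
    for _ in range(n_bases):
        seq, _, n_eq = phantom.generate_phantom(pcfg, rng)
        bases.append(seq)
        eqs.append(n_eq)
    tcfg_kw = dict(config.get("train", {}))
    kind = config.get("kind", "motion")
    crop = tuple(config.get("crop_size", (16, 16, 8)))
    channels = tuple(config.get("conv_channels", (8, 16)))
    center = config.get("center")
    if kind == "eq":
        net_cfg = model.desk_scale_net_config("eq-classification", crop, channels)
        tcfg = model.TrainConfig(lr_decay=0.998, seed=seed, **tcfg_kw)
        trained = model.train_eq_net(bases, tcfg, net_cfg, rng, center=center)
        trained.save(out / "eq_net")
    else:
        normalized = []
        for seq, n_eq in zip(bases, eqs):
            norm, _ = preprocess.temporal_normalize(seq, n_eq)
            normalized.append(norm)
        net_cfg = model.desk_scale_net_config("motion-regression", crop, channels)
        tcfg = model.TrainConfig(seed=seed, **tcfg_kw)
        for phase in ("early", "late"):
            trained = model.train_motion_net(
                normalized, tcfg, net_cfg, rng, phase=phase, center=center
            )
            trained.save(out / f"motion_{phase}")
            pd.DataFrame(trained.train_log, columns=["step", "loss", "lr"]).to_csv(
                out / f"motion_{phase}_log.csv", index=False
            )
    _write_run_metadata(out, config, seed)


@cli.command("correct")
@click.option("--input", "input_path", type=click.Path(exists=True), required=True)
@click.option("--early", "early_path", type=click.Path(), required=True)
@click.option("--late", "late_path", type=click.Path(), required=True)
@click.option("--center", type=str, default=None, help="comma-separated voxel center")
@click.option("--out", "out_dir", type=click.Path(), required=True)
@click.option("--seed", type=int, default=0, show_default=True)
def correct_cmd(input_path, early_path, late_path, center, out_dir, seed):
    """Iteratively correct a motion-corrupted sequence."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seq = load_sequence(input_path)
    early = model.TrainedModel.load(early_path)
    late = model.TrainedModel.load(late_path)
    center_v = [int(c) for c in center.split(",")] if center else None
    result = correct.iterative_correct(early, late, seq, center=center_v)
    save_sequence(result.corrected, out / "corrected")
    save_trace(result.cumulative, out / "trace.csv", seq.voxel_mm)
    log = {
        "iterations": result.iterations,
        "per_iteration_total_vox": [
            float(np.linalg.norm(t, axis=1).sum()) for t in result.per_iteration
        ],
    }
    _atomic_write(out / "iterations.json", lambda p: p.write_text(json.dumps(log, indent=1)))
    _write_run_metadata(out, {"input": str(input_path)}, seed)


@cli.command()
@click.option("--input", "input_path", type=click.Path(exists=True), required=True)
@click.option("--method", type=click.Choice(["individual", "chain"]), default="individual")
@click.option("--out", "out_path", type=click.Path(), required=True)
def register(input_path, method, out_path):
    """Registration-baseline motion estimation."""
    seq = load_sequence(input_path)
    fn = (
        baselines.individual_registration
        if method == "individual"
        else baselines.chain_registration
    )
    save_trace(fn(seq), out_path, seq.voxel_mm)


@cli.command("kinetics")
@click.option("--input", "input_path", type=click.Path(exists=True), required=True)
@click.option("--labels", "labels_path", type=click.Path(exists=True), required=True)
@click.option("--out", "out_path", type=click.Path(), required=True)
def kinetics_cmd(input_path, labels_path, out_path):
    """Fit the myocardial TAC with the 1T model using the LV-pool IDIF."""
    seq = load_sequence(input_path)
    labels = load_labels(labels_path)
    idif = kinetics.sample_roi_tac(seq, labels, phantom.LABEL_LV_POOL)
    myo = kinetics.sample_roi_tac(seq, labels, phantom.LABEL_MYOCARDIUM)
    totals = seq.frames.reshape(seq.n_frames, -1).sum(axis=1)
    weights = kinetics.frame_weights(seq.schedule, totals)
    fit = kinetics.fit_1t_wls(myo, idif, seq.schedule, weights)
    payload = {
        "K1": fit.params.K1,
        "k2": fit.params.k2,
        "vb": fit.params.vb,
        "wss": fit.wss,
        "converged": fit.converged,
    }
    _atomic_write(Path(out_path), lambda p: p.write_text(json.dumps(payload, indent=1)))


@cli.command("evaluate")
@click.option("--pred", "pred_path", type=click.Path(exists=True), required=True)
@click.option("--truth", "truth_path", type=click.Path(exists=True), required=True)
@click.option("--voxel-mm", type=str, default="3.125,3.125,3.270", show_default=True)
@click.option("--out", "out_path", type=click.Path(), required=True)
def evaluate_cmd(pred_path, truth_path, voxel_mm, out_path):
    """Motion-error metrics between a predicted and a ground-truth trace."""
    pred = load_trace(pred_path)
    truth = load_trace(truth_path)
    vox = [float(v) for v in voxel_mm.split(",")]
    payload = {
        "mean_motion_error_mm": evaluate.mean_motion_error(pred, truth, vox),
        "max_motion_error_mm": evaluate.max_motion_error(pred, truth, vox),
    }
    _atomic_write(Path(out_path), lambda p: p.write_text(json.dumps(payload, indent=1)))


if __name__ == "__main__":
    cli()
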