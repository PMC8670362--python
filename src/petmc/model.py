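"""Motion-regression and EQ-frame-classification networks.

Both heads share one trunk: per-frame [Conv3D(stride 2) + ReLU] x 2 followed
by a bidirectional ConvLSTM-3D, repeated with a wider channel count, then a
per-frame flatten -> dropout -> ReLU -> fully-connected head.  No pooling
layers anywhere; spatial halving comes from the stride-2 convolutions.

The motion head regresses one (dx, dy, dz) voxel-unit vector per frame from
dual-channel inputs (frame + reference).  The EQ head emits one logit per
frame from single-channel inputs, softmaxed over the temporal axis.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import kinetics, motionsim, phantom, preprocess
from .nn import autodiff as ad
from .nn.layers import BiConvLSTM3d, Conv3d, Linear, Module
from .nn.optim import Adam

__all__ = [
    "MotionNetConfig",
    "TrainConfig",
    "TrainedModel",
    "MotionEqNet",
    "desk_scale_net_config",
    "desk_scale_train_config",
    "motion_net_forward",
    "eq_net_forward",
    "train_motion_net",
    "train_eq_net",
    "predict_eq_frame",
]


@dataclass(frozen=True)
class MotionNetConfig:
    """Architecture settings.

    Full-scale defaults follow the published recipe: two conv blocks with 64
    then 128 kernels, stride 2, dropout 0.5.  Kernel size 3 and
    hidden-channel counts equal to the preceding conv width are
    implementation choices.
    """

    conv_channels: tuple = (64, 128)
    conv_stride: int = 2
    kernel_size: int = 3
    dropout: float = 0.5
    head: str = "motion-regression"  # or "eq-classification"
    in_channels: int = 2
    crop_size: tuple = (64, 64, 36)

    def __post_init__(self) -> None:
        if self.conv_stride < 1:
            raise ValueError("stride must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.head not in ("motion-regression", "eq-classification"):
            raise ValueError(f"unknown head {self.head!r}")

    @property
    def out_dim(self) -> int:
        return 3 if self.head == "motion-regression" else 1


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    learning_rate: float = 1e-3
    lr_decay: float = 0.999  # 0.998 for the EQ network
    lr_decay_every: int = 10
    total_samples: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.total_samples < 0:
            raise ValueError("counts must be positive")
        if not 0.0 < self.lr_decay <= 1.0:
            raise ValueError("lr_decay must lie in (0, 1]")


def desk_scale_net_config(
    head: str = "motion-regression", crop_size=(16, 16, 8), conv_channels=(8, 16)
) -> MotionNetConfig:
    """CPU-trainable configuration with the same architecture shape."""
    return MotionNetConfig(
        conv_channels=conv_channels,
        head=head,
        in_channels=2 if head == "motion-regression" else 1,
        crop_size=crop_size,
    )


def desk_scale_train_config(total_samples: int = 4000, **kw) -> TrainConfig:
    return TrainConfig(total_samples=total_samples, **kw)


class MotionEqNet(Module):
    def __init__(self, config: MotionNetConfig, rng: np.random.Generator):
        c1, c2 = config.conv_channels
        k, s = config.kernel_size, config.conv_stride
        self.config = config
        self.conv1a = Conv3d(config.in_channels, c1, k, s, rng)
        self.conv1b = Conv3d(c1, c1, k, s, rng)
        self.lstm1 = BiConvLSTM3d(c1, c1, k, rng)
        self.conv2a = Conv3d(2 * c1, c2, k, s, rng)
        self.conv2b = Conv3d(c2, c2, k, s, rng)
        self.lstm2 = BiConvLSTM3d(c2, c2, k, rng)
        sp = config.crop_size
        for _ in range(4):
            sp = ad.conv_output_shape(sp, k, s)
        self.feature_shape = (2 * c2,) + sp
        self.head = Linear(int(np.prod(self.feature_shape)), config.out_dim, rng)

    def forward(self, x, training: bool = False, rng: np.random.Generator | None = None):
        """x: (B, T, C, X, Y, Z) array or Tensor -> (B, T, out_dim) Tensor."""
        if not isinstance(x, ad.Tensor):
            x = ad.Tensor(np.ascontiguousarray(x, dtype=np.float32))
        B, T = x.shape[:2]
        if x.shape[2] != self.config.in_channels or tuple(x.shape[3:]) != tuple(
            self.config.crop_size
        ):
            raise ValueError(
                f"input shape {x.shape[2:]} does not match the configured "
                f"({self.config.in_channels}, *{self.config.crop_size})"
            )
        flat = ad.reshape(x, (B * T,) + tuple(x.shape[2:]))
        h = ad.relu(self.conv1b(ad.relu(self.conv1a(flat))))
        sp1 = h.shape[1:]
        h = ad.reshape(h, (B, T) + tuple(sp1))
        frames = [
            ad.reshape(ad.narrow(h, 1, t, 1), (B,) + tuple(sp1)) for t in range(T)
        ]
        frames = self.lstm1.forward_sequence(frames)
        frames = [ad.relu(self.conv2b(ad.relu(self.conv2a(f)))) for f in frames]
        frames = self.lstm2.forward_sequence(frames)
        outs = []
        for f in frames:
            v = ad.reshape(f, (B, -1))
            v = ad.dropout(v, self.config.dropout, rng, training=training)
            v = ad.relu(v)
            outs.append(ad.reshape(self.head(v), (B, 1, self.config.out_dim)))
        return ad.concat(outs, axis=1)


@dataclass
class TrainedModel:
    """A fitted network plus its configuration and preprocessing fingerprint.

    The fingerprint records the settings the inputs must satisfy (crop size,
    EQ reference index, normalization/filter flags) so that mismatched
    pipelines fail loudly instead of predicting garbage.
    """

    net: MotionEqNet
    net_config: MotionNetConfig
    fingerprint: dict = field(default_factory=dict)
    train_log: list = field(default_factory=list)

    def predict(self, inputs: np.ndarray) -> np.ndarray:
        """Deterministic forward pass (dropout off) on a (T, C, X, Y, Z) stack."""
        with ad.no_grad():
            out = self.net.forward(np.asarray(inputs, dtype=np.float32)[None])
        return out.data[0].astype(float)

    def predict_shifts(self, inputs: np.ndarray) -> np.ndarray:
        if self.net_config.head != "motion-regression":
            raise ValueError("not a motion-regression model")
        return self.predict(inputs)

    def predict_eq_probs(self, inputs: np.ndarray) -> np.ndarray:
        if self.net_config.head != "eq-classification":
            raise ValueError("not an EQ-classification model")
        logits = self.predict(inputs)[:, 0]
        return ad.softmax(logits, axis=0)

    def save(self, path):
        """Serialize weights (npz) and configuration (JSON sidecar)."""
        path = str(path)
        arrays = {f"p{i}": a for i, a in enumerate(self.net.state_arrays())}
        np.savez(path if path.endswith(".npz") else path + ".npz", **arrays)
        meta = {
            "net_config": asdict(self.net_config),
            "fingerprint": self.fingerprint,
            "train_log": self.train_log,
        }
        with open((path[:-4] if path.endswith(".npz") else path) + ".json", "w") as f:
            json.dump(meta, f, indent=1)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        path = str(path)
        base = path[:-4] if path.endswith(".npz") else path
        with open(base + ".json") as f:
            meta = json.load(f)
        ncfg = meta["net_config"]
        for key in ("conv_channels", "crop_size"):
            ncfg[key] = tuple(ncfg[key])
        config = MotionNetConfig(**ncfg)
        net = MotionEqNet(config, np.random.default_rng(0))
        with np.load(base + ".npz") as z:
            net.load_state_arrays([z[f"p{i}"] for i in range(len(z.files))])
        return cls(
            net=net,
            net_config=config,
            fingerprint=meta["fingerprint"],
            train_log=[tuple(r) for r in meta["train_log"]],
        )


def motion_net_forward(model: TrainedModel, inputs: np.ndarray) -> np.ndarray:
    """(T, 2, X, Y, Z) dual-channel stack -> (T, 3) predicted voxel shifts."""
    return model.predict_shifts(inputs)


def eq_net_forward(model: TrainedModel, inputs: np.ndarray) -> np.ndarray:
    """(T, 1, X, Y, Z) single-channel stack -> temporal probability vector."""
    return model.predict_eq_probs(inputs)


def _prefilter(seqs):
    return [
        np.stack([preprocess.median_filter3(f) for f in np.asarray(s.frames, float)])
        for s in seqs
    ]


def train_motion_net(
    base_seqs,
    train_cfg: TrainConfig,
    net_cfg: MotionNetConfig,
    rng: np.random.Generator | None = None,
    phase: str = "early",
    sim_cfg: motionsim.MotionSimConfig = motionsim.MotionSimConfig(),
    center=None,
    log_every: int = 10,
) -> TrainedModel:
    """Train one phase's motion network on on-the-fly simulated samples.

    ``base_seqs`` are motion-free, temporally normalized sequences; samples
    come from :func:`petmc.motionsim.make_training_sample` with MSE loss,
    Adam, and the stepped learning-rate decay.  ``total_samples == 0``
    returns the freshly initialized network untouched.
    """
    if len(base_seqs) == 0:
        raise ValueError("need at least one base sequence")
    if rng is None:
        rng = np.random.default_rng(train_cfg.seed)
    net = MotionEqNet(net_cfg, rng)
    opt = Adam(
        net.parameters(),
        lr=train_cfg.learning_rate,
        lr_decay=train_cfg.lr_decay,
        decay_every=train_cfg.lr_decay_every,
    )
    filtered = _prefilter(base_seqs)
    if center is None:
        center = [s // 2 for s in np.asarray(base_seqs[0].frames).shape[1:]]

    log = []
    n_batches = -(-train_cfg.total_samples // train_cfg.batch_size)
    for step in range(n_batches):
        xs, ys = [], []
        for _ in range(train_cfg.batch_size):
            b = int(rng.integers(len(base_seqs)))
            inp, tgt, _ = motionsim.make_training_sample(
                base_seqs[b],
                rng,
                sim_cfg,
                phase=phase,
                center=center,
                crop_size=net_cfg.crop_size,
                filtered_frames=filtered[b],
            )
            xs.append(inp)
            ys.append(tgt)
        x = np.stack(xs).astype(np.float32)
        y = np.stack(ys).astype(np.float32)
        pred = net.forward(x, training=True, rng=rng)
        loss = ad.mse_loss(pred, y)
        opt.zero_grad()
        loss.backward()
        opt.step()
        if step % log_every == 0 or step == n_batches - 1:
            log.append((step, float(loss.data), opt.lr))

    fingerprint = {
        "crop_size": list(net_cfg.crop_size),
        "center": [int(c) for c in center],
        "n_ref": preprocess.PreprocessConfig().n_ref,
        "phase": phase,
        "median_filter": True,
        "intensity_normalize": True,
    }
    return TrainedModel(net=net, net_config=net_cfg, fingerprint=fingerprint, train_log=log)


def _rule_based_eq(seq) -> int:
    """EQ label from the rule-based oracle on the sequence's own ROI TACs."""
    if seq.labels is None:
        raise ValueError("sequence has no ROI labels; cannot derive the EQ label")
    lv = kinetics.sample_roi_tac(seq, seq.labels, phantom.LABEL_LV_POOL)
    rv = kinetics.sample_roi_tac(seq, seq.labels, phantom.LABEL_RV_POOL)
    return preprocess.find_eq_frame(lv, rv)


def make_eq_sample(
    filtered_frames: np.ndarray,
    n_eq: int,
    rng: np.random.Generator,
    sim_cfg: motionsim.MotionSimConfig,
    center,
    crop_size,
    jitter: int = 3,
):
    """One EQ-training sample: single-channel crops with simulated motion, an
    initial window shift, and temporal jitter up to +-``jitter`` frames
    (label moves with the jitter).  Returns ``(inputs (T,1,*crop), label0)``
    with a 0-based label."""
    n_frames = filtered_frames.shape[0]
    lo = max(-jitter, n_eq - n_frames)  # keep the label inside 1..n_frames
    hi = min(jitter, n_eq - 1)
    j = int(rng.integers(lo, hi + 1)) if hi >= lo else 0
    frames = filtered_frames
    if j > 0:  # towards the early phase
        frames = np.concatenate([frames[j:], np.repeat(frames[-1:], j, axis=0)])
    elif j < 0:
        frames = np.concatenate([np.zeros_like(frames[:-j]), frames[: n_frames + j]])
    label = n_eq - j

    motion_type = motionsim.MOTION_TYPES[
        rng.choice(len(motionsim.MOTION_TYPES), p=sim_cfg.type_probabilities)
    ]
    trace = motionsim.simulate_trace(motion_type, n_frames, rng, sim_cfg)
    cap = int(round(sim_cfg.initial_shift_vox / motionsim.QUANT_STEP))
    w0 = (
        motionsim.quantize(
            [rng.integers(-cap, cap + 1) * motionsim.QUANT_STEP for _ in range(3)]
        )
        if cap > 0
        else np.zeros(3)
    )
    inputs = np.empty((n_frames, 1) + tuple(crop_size))
    for n in range(n_frames):
        inputs[n, 0] = preprocess.intensity_normalize(
            motionsim._sample_window(frames[n], center, crop_size, w0 + trace.shifts[n])
        )
    return inputs, label - 1


def train_eq_net(
    base_seqs,
    train_cfg: TrainConfig,
    net_cfg: MotionNetConfig,
    rng: np.random.Generator | None = None,
    sim_cfg: motionsim.MotionSimConfig = motionsim.MotionSimConfig(),
    center=None,
    eq_labels=None,
    jitter: int = 3,
    log_every: int = 10,
) -> TrainedModel:
    """Train the EQ-frame classifier (cross-entropy over the temporal axis).

    ``base_seqs`` are original (not temporally normalized) sequences; labels
    default to the rule-based oracle applied to each sequence's ROI TACs.
    """
    if len(base_seqs) == 0:
        raise ValueError("need at least one base sequence")
    if net_cfg.head != "eq-classification":
        raise ValueError("net_cfg must use the eq-classification head")
    if rng is None:
        rng = np.random.default_rng(train_cfg.seed)
    if eq_labels is None:
        eq_labels = [_rule_based_eq(s) for s in base_seqs]
    net = MotionEqNet(net_cfg, rng)
    opt = Adam(
        net.parameters(),
        lr=train_cfg.learning_rate,
        lr_decay=train_cfg.lr_decay,
        decay_every=train_cfg.lr_decay_every,
    )
    filtered = _prefilter(base_seqs)
    if center is None:
        center = [s // 2 for s in np.asarray(base_seqs[0].frames).shape[1:]]

    log = []
    n_batches = -(-train_cfg.total_samples // train_cfg.batch_size)
    for step in range(n_batches):
        xs, ys = [], []
        for _ in range(train_cfg.batch_size):
            b = int(rng.integers(len(base_seqs)))
            inp, label0 = make_eq_sample(
                filtered[b], eq_labels[b], rng, sim_cfg, center, net_cfg.crop_size,
                jitter=jitter,
            )
            xs.append(inp)
            ys.append(label0)
        x = np.stack(xs).astype(np.float32)
        y = np.asarray(ys, dtype=int)
        logits = net.forward(x, training=True, rng=rng)
        logits = ad.reshape(logits, (x.shape[0], x.shape[1]))
        loss = ad.softmax_cross_entropy(logits, y)
        opt.zero_grad()
        loss.backward()
        opt.step()
        if step % log_every == 0 or step == n_batches - 1:
            log.append((step, float(loss.data), opt.lr))

    fingerprint = {
        "crop_size": list(net_cfg.crop_size),
        "center": [int(c) for c in center],
        "median_filter": True,
        "intensity_normalize": True,
    }
    return TrainedModel(net=net, net_config=net_cfg, fingerprint=fingerprint, train_log=log)


def predict_eq_frame(model: TrainedModel, seq, center=None) -> int:
    """Predicted 1-based EQ index for a sequence (argmax of the head)."""
    frames = np.asarray(seq.frames, dtype=float)
    if center is None:
        center = model.fingerprint.get("center") or [s // 2 for s in frames.shape[1:]]
    crop = tuple(model.net_config.crop_size)
    inputs = np.empty((frames.shape[0], 1) + crop)
    for n in range(frames.shape[0]):
        vol = preprocess.median_filter3(frames[n])
        inputs[n, 0] = preprocess.intensity_normalize(
            preprocess.crop_window(vol, center, crop)
        )
    probs = model.predict_eq_probs(inputs)
    return int(np.argmax(probs)) + 1
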