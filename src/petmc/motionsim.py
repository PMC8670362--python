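"""Ground-truth inter-frame translation simulation and application.

Three motion archetypes are simulated on a 0.1-voxel grid — "square"
(one constant vector over a run of frames), "triangle" (linear ramp up to a
peak vector and back) and "spike" (independent vector per frame) — and
applied by shifting a sub-voxel crop window with trilinear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "MOTION_TYPES",
    "MotionTrace",
    "MotionSimConfig",
    "EvalReplicate",
    "eligible_frame_indices",
    "simulate_trace",
    "apply_motion",
    "shift_frames",
    "make_training_sample",
    "make_evaluation_set",
]

MOTION_TYPES = ("square", "triangle", "spike")

#: quantization step of every shift component, in voxels
QUANT_STEP = 0.1


def quantize(x) -> np.ndarray:
    """Snap shift components to the 0.1-voxel grid."""
    return np.round(np.asarray(x, dtype=float) * 10.0) / 10.0


@dataclass(frozen=True)
class MotionTrace:
    """Per-frame (dx, dy, dz) translations in voxel units.

    Axes follow the x = left-right, y = anterior-posterior,
    z = superior-inferior convention.  Components are quantized to 0.1
    voxel and the reference (last) frame shift is exactly zero.
    """

    shifts: np.ndarray

    def __post_init__(self) -> None:
        shifts = np.asarray(self.shifts, dtype=float)
        if shifts.ndim != 2 or shifts.shape[1] != 3:
            raise ValueError("shifts must be (n_frames, 3)")
        q = quantize(shifts)
        if not np.allclose(shifts, q, atol=1e-9):
            raise ValueError("shift components must be multiples of 0.1 voxel")
        if np.any(q[-1] != 0.0):
            raise ValueError("the reference (last) frame shift must be zero")
        object.__setattr__(self, "shifts", q)

    def __len__(self) -> int:
        return self.shifts.shape[0]

    @property
    def magnitudes_vox(self) -> np.ndarray:
        return np.linalg.norm(self.shifts, axis=1)

    def magnitudes_mm(self, voxel_mm) -> np.ndarray:
        return np.linalg.norm(self.shifts * np.asarray(voxel_mm, float), axis=1)

    def motion_frame_count(self) -> int:
        return int(np.count_nonzero(self.magnitudes_vox > 0))

    @classmethod
    def zero(cls, n_frames: int) -> "MotionTrace":
        return cls(np.zeros((n_frames, 3)))


@dataclass(frozen=True)
class MotionSimConfig:
    """Knobs of the motion simulator.

    ``motion_frames_range`` is inclusive; the training default is (2, 7) and
    the evaluation protocol uses (5, 11).  ``max_shift_vox`` caps each axis;
    ``initial_shift_vox`` caps the common window-shift augmentation, and
    ``temporal_jitter`` the whole-sequence frame jitter.
    """

    type_probabilities: tuple = (1 / 3, 1 / 3, 1 / 3)
    motion_frames_range: tuple = (2, 7)
    max_shift_vox: float = 4.0
    initial_shift_vox: float = 3.0
    temporal_jitter: int = 1

    def __post_init__(self) -> None:
        lo, hi = self.motion_frames_range
        if lo < 1 or hi < lo:
            raise ValueError("motion_frames_range must be a nonempty range")
        if self.max_shift_vox < 0 or self.initial_shift_vox < 0:
            raise ValueError("shift caps must be nonnegative")
        if abs(sum(self.type_probabilities) - 1.0) > 1e-9:
            raise ValueError("type probabilities must sum to 1")


EVAL_CONFIG = MotionSimConfig(
    motion_frames_range=(5, 11), initial_shift_vox=0.0, temporal_jitter=0
)


def eligible_frame_indices(n_frames: int) -> np.ndarray:
    """0-based indices that may carry motion: all but the first 3 frames and
    the final reference frame (23 of 27 for the clinical schedule)."""
    return np.arange(3, n_frames - 1)


def _draw_axis_shift(rng: np.random.Generator, cap: float) -> float:
    """Magnitude uniform on {0.1, ..., cap}, sign uniform."""
    steps = int(round(cap / QUANT_STEP))
    if steps == 0:
        return 0.0
    mag = rng.integers(1, steps + 1) * QUANT_STEP
    sign = 1.0 if rng.random() < 0.5 else -1.0
    return sign * mag


def _draw_vector(rng: np.random.Generator, cap: float) -> np.ndarray:
    return quantize([_draw_axis_shift(rng, cap) for _ in range(3)])


def _triangle_fractions(k: int) -> np.ndarray:
    """Linear ramp to the peak at the centre frame and back; endpoints nonzero.

    The peak sits on the middle frame of the run (for even runs, the earlier
    of the two central frames), e.g. k=5 gives (1/3, 2/3, 1, 2/3, 1/3).
    """
    c = (k - 1) // 2
    frac = np.empty(k)
    for i in range(k):
        frac[i] = (i + 1) / (c + 1) if i <= c else (k - i) / (k - c)
    return frac


def simulate_trace(
    motion_type: str,
    n_frames: int,
    rng: np.random.Generator,
    config: MotionSimConfig = MotionSimConfig(),
    eligible: tuple | None = None,
) -> MotionTrace:
    """Simulate one ground-truth trace of the given type.

    Motion occupies a contiguous run of k frames (k drawn uniformly from the
    configured range) placed uniformly within the eligible frames — never the
    first 3 frames nor the last (reference) frame.  ``eligible`` may restrict
    the run further to a 0-based inclusive (lo, hi) window.
    """
    if motion_type not in MOTION_TYPES:
        raise ValueError(f"unknown motion type {motion_type!r}")
    if n_frames < 5:
        raise ValueError("need at least 5 frames (3 leading + 1 motion + reference)")
    lo_e, hi_e = 3, n_frames - 2
    if eligible is not None:
        lo_e, hi_e = max(lo_e, eligible[0]), min(hi_e, eligible[1])
    n_elig = hi_e - lo_e + 1
    if n_elig < 1:
        raise ValueError("no eligible frames for motion")

    k_lo, k_hi = config.motion_frames_range
    k = int(rng.integers(k_lo, min(k_hi, n_elig) + 1))
    start = int(rng.integers(lo_e, hi_e - k + 2))

    shifts = np.zeros((n_frames, 3))
    cap = config.max_shift_vox
    if motion_type == "square":
        vec = _draw_vector(rng, cap)
        shifts[start : start + k] = vec
    elif motion_type == "triangle":
        peak = _draw_vector(rng, cap)
        frac = _triangle_fractions(k)
        shifts[start : start + k] = quantize(frac[:, None] * peak[None, :])
    else:  # spike
        for i in range(k):
            shifts[start + i] = _draw_vector(rng, cap)
    return MotionTrace(shifts)


def _sample_window(
    volume: np.ndarray, center, size, shift=(0.0, 0.0, 0.0)
) -> np.ndarray:
    """Trilinear sample of the window centered at ``center + shift``;
    positions outside the grid read as zero."""
    coords = np.meshgrid(
        *[
            c - w // 2 + s + np.arange(w, dtype=float)
            for c, w, s in zip(center, size, shift)
        ],
        indexing="ij",
    )
    return ndimage.map_coordinates(
        np.asarray(volume, dtype=float), np.stack(coords), order=1, mode="constant", cval=0.0
    )


def apply_motion(seq, trace: MotionTrace, center, window) -> "object":
    """Crop every frame at a window displaced by that frame's shift.

    A zero trace reduces to a plain crop.  Output is a DynamicSequence over
    the window grid (labels dropped).
    """
    frames = np.asarray(seq.frames, dtype=float)
    if len(trace) != frames.shape[0]:
        raise ValueError("trace length must equal the frame count")
    window = tuple(int(w) for w in window)
    # padding policy allows at most one window-width of zero padding per side
    if any(w > 3 * g for w, g in zip(window, frames.shape[1:])):
        raise ValueError("window larger than the padded grid")
    out = np.empty((frames.shape[0],) + window)
    for n in range(frames.shape[0]):
        out[n] = _sample_window(frames[n], center, window, trace.shifts[n])
    np.clip(out, 0.0, None, out=out)
    return replace(seq, frames=out, labels=None)


def shift_frames(seq, trace: MotionTrace):
    """Materialize the motion-corrupted sequence on the full grid.

    Frame n reads the motion-free frame at position x + shift_n, so a
    subsequent crop at ``center`` equals ``apply_motion`` with this trace.
    """
    frames = np.asarray(seq.frames, dtype=float)
    if len(trace) != frames.shape[0]:
        raise ValueError("trace length must equal the frame count")
    out = np.empty_like(frames)
    for n in range(frames.shape[0]):
        s = trace.shifts[n]
        if np.all(s == 0):
            out[n] = frames[n]
        else:
            out[n] = ndimage.shift(frames[n], -s, order=1, mode="constant", cval=0.0)
    np.clip(out, 0.0, None, out=out)
    return replace(seq, frames=out, labels=None)


def _phase_indices(n_frames: int, phase: str, n_early: int = 15):
    """0-based source frame indices of a phase set (early appends the reference)."""
    if phase == "early":
        return list(range(n_early - 1)) + [n_frames - 1]
    if phase == "late":
        return list(range(n_early - 1, n_frames))
    raise ValueError("phase must be 'early' or 'late'")


def _phase_eligible(n_frames: int, phase: str, n_early: int = 15):
    """Eligible motion window (0-based inclusive) within one phase."""
    if phase == "early":
        return (3, n_early - 2)
    return (n_early - 1, n_frames - 2)


def make_training_sample(
    seq,
    rng: np.random.Generator,
    config: MotionSimConfig = MotionSimConfig(),
    phase: str = "early",
    center=None,
    crop_size=(64, 64, 36),
    filtered_frames: np.ndarray | None = None,
    normalize=None,
):
    """One on-the-fly training sample for the motion network.

    Draws a motion type (1/3 each), simulates a trace confined to the phase's
    eligible frames, applies an initial common window shift (capped per axis,
    excluded from the target), jitters the whole sequence temporally by up to
    ``config.temporal_jitter`` frames, and assembles the dual-channel cropped
    input.  Returns ``(inputs (T,2,*crop), target (T,3), motion_type)``.

    ``filtered_frames`` lets callers pass pre-median-filtered frames (the
    filter commutes with the window shift for integer shifts); ``normalize``
    defaults to mean-intensity normalization.  The third return value is an
    info dict with the drawn motion type, initial shift and temporal jitter.
    """
    from .preprocess import intensity_normalize, median_filter3

    frames = np.asarray(seq.frames, dtype=float)
    n_frames = frames.shape[0]
    if center is None:
        center = [s // 2 for s in frames.shape[1:]]
    if normalize is None:
        normalize = intensity_normalize
    if filtered_frames is None:
        filtered_frames = np.stack([median_filter3(f) for f in frames])

    # temporal jitter of the whole sequence
    j = int(rng.integers(-config.temporal_jitter, config.temporal_jitter + 1))
    if j > 0:  # towards the early phase: drop leading frames, repeat the last
        filtered_frames = np.concatenate(
            [filtered_frames[j:], np.repeat(filtered_frames[-1:], j, axis=0)]
        )
    elif j < 0:  # towards the late phase: zero-pad at the front
        filtered_frames = np.concatenate(
            [np.zeros_like(filtered_frames[:-j]), filtered_frames[: n_frames + j]]
        )

    motion_type = MOTION_TYPES[
        rng.choice(len(MOTION_TYPES), p=config.type_probabilities)
    ]
    trace = simulate_trace(
        motion_type, n_frames, rng, config, eligible=_phase_eligible(n_frames, phase)
    )

    w0 = (
        quantize(
            [
                rng.integers(
                    -int(round(config.initial_shift_vox / QUANT_STEP)),
                    int(round(config.initial_shift_vox / QUANT_STEP)) + 1,
                )
                * QUANT_STEP
                for _ in range(3)
            ]
        )
        if config.initial_shift_vox > 0
        else np.zeros(3)
    )

    idx = _phase_indices(n_frames, phase)
    ref = normalize(_sample_window(filtered_frames[-1], center, crop_size, w0))
    inputs = np.empty((len(idx), 2) + tuple(crop_size))
    target = np.zeros((len(idx), 3))
    for row, n in enumerate(idx):
        shift = trace.shifts[n] if not (phase == "early" and row == len(idx) - 1) else np.zeros(3)
        inputs[row, 0] = normalize(
            _sample_window(filtered_frames[n], center, crop_size, w0 + shift)
        )
        inputs[row, 1] = ref
        target[row] = shift
    if phase == "early":
        target[-1] = 0.0  # appended reference frame
    info = {"motion_type": motion_type, "initial_shift": w0, "jitter": j}
    return inputs, target, info


@dataclass(frozen=True)
class EvalReplicate:
    """One motion-corrupted evaluation replicate, stored lazily.

    Holds the base-sequence index, the ground-truth trace and the motion
    type; ``corrupted(base_seq)`` materializes the full-grid corrupted
    sequence on demand (keeping 600 clinical-size replicates in memory at
    once is not viable).
    """

    base_index: int
    trace: MotionTrace
    motion_type: str

    def corrupted(self, base_seq):
        return shift_frames(base_seq, self.trace)


def make_evaluation_set(
    base_seqs,
    rng: np.random.Generator,
    config: MotionSimConfig = EVAL_CONFIG,
    replicates_per_type: int = 10,
):
    """The evaluation protocol: per base sequence, ``replicates_per_type``
    replicates of each motion type, motion over the whole sequence (except
    the first 3 frames and the reference), 5-11 motion frames, no initial
    window shift, no temporal jitter."""
    if len(base_seqs) == 0:
        raise ValueError("need at least one base sequence")
    out = []
    for b, seq in enumerate(base_seqs):
        n_frames = np.asarray(seq.frames).shape[0]
        for motion_type in MOTION_TYPES:
            for _ in range(replicates_per_type):
                trace = simulate_trace(motion_type, n_frames, rng, config)
                out.append(EvalReplicate(b, trace, motion_type))
    return out
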