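"""Model-driven motion estimation and iterative correction.

The early and late networks each predict their phase's per-frame shifts;
the assembled 27-frame estimate drives a window re-crop in the original
(uncropped, unfiltered) image space.  Detection is iterated — windows are
displaced by the cumulative estimate, never re-resampled images, so
interpolation blur does not compound — until the per-pass detected motion
drops below tolerance or the iteration cap is hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import motionsim, preprocess
from .motionsim import MotionTrace, _phase_indices, _sample_window, quantize

__all__ = ["CorrectionResult", "predict_motion", "iterative_correct", "apply_correction"]

MAX_ITER = 5
TOL_VOX = 0.1


def _check_fingerprint(model, window) -> None:
    fp = getattr(model, "fingerprint", None) or {}
    crop = fp.get("crop_size")
    if crop is not None and tuple(crop) != tuple(window):
        raise ValueError(
            f"model was trained for crop {tuple(crop)}, requested window {tuple(window)}"
        )


def _resolve_geometry(model, seq, center, window):
    fp = getattr(model, "fingerprint", None) or {}
    if window is None:
        window = fp.get("crop_size")
    if window is None:
        raise ValueError("no window size given and the model has no fingerprint")
    if center is None:
        center = fp.get("center") or [s // 2 for s in np.asarray(seq.frames).shape[1:]]
    return [int(c) for c in center], tuple(int(w) for w in window)


def _phase_inputs(filtered, center, window, offsets, idx):
    """Dual-channel detection inputs for one phase, with per-frame window
    offsets (the negated cumulative correction)."""
    ref = preprocess.intensity_normalize(
        _sample_window(filtered[-1], center, window, offsets[-1])
    )
    out = np.empty((len(idx), 2) + window)
    for row, n in enumerate(idx):
        out[row, 0] = preprocess.intensity_normalize(
            _sample_window(filtered[n], center, window, offsets[n])
        )
        out[row, 1] = ref
    return out


def _predict_phase(model, filtered, center, window, offsets, phase, n_frames):
    idx = _phase_indices(n_frames, phase)
    inputs = _phase_inputs(filtered, center, window, offsets, idx)
    pred = np.asarray(model.predict_shifts(inputs), dtype=float)
    if pred.shape != (len(idx), 3):
        raise ValueError(f"model returned shape {pred.shape}, expected ({len(idx)}, 3)")
    if phase == "early":
        pred = pred[:-1]  # appended-reference prediction is discarded
        idx = idx[:-1]
    return idx, quantize(pred)


def predict_motion(
    early_model, late_model, seq, center=None, window=None
) -> MotionTrace:
    """One-pass 27-frame motion estimate from the early and late networks.

    The early model covers frames 1-14 (its appended-reference output is
    dropped), the late model frames 15-27; the reference entry is forced to
    zero.  Inputs are median-filtered, cropped and mean-normalized.
    """
    center, window = _resolve_geometry(early_model, seq, center, window)
    _check_fingerprint(early_model, window)
    _check_fingerprint(late_model, window)
    frames = np.asarray(seq.frames, dtype=float)
    n_frames = frames.shape[0]
    filtered = np.stack([preprocess.median_filter3(f) for f in frames])
    offsets = np.zeros((n_frames, 3))
    shifts = np.zeros((n_frames, 3))
    for model, phase in ((early_model, "early"), (late_model, "late")):
        idx, pred = _predict_phase(model, filtered, center, window, offsets, phase, n_frames)
        shifts[idx] = pred
    shifts[-1] = 0.0
    return MotionTrace(quantize(shifts))


@dataclass
class CorrectionResult:
    corrected: object  # DynamicSequence over the window grid
    cumulative: MotionTrace
    per_iteration: list = field(default_factory=list)  # (n_frames, 3) arrays
    iterations: dict = field(default_factory=dict)  # per-phase iteration counts

    @property
    def n_iter(self) -> int:
        return max(self.iterations.values())


def iterative_correct(
    early_model,
    late_model,
    seq,
    center=None,
    window=None,
    max_iter: int = MAX_ITER,
    tol_vox: float = TOL_VOX,
) -> CorrectionResult:
    """Iterative motion correction with the published stopping rules.

    Each phase iterates independently: predict, add to the cumulative
    estimate, stop when the iteration count reaches ``max_iter`` or the sum
    of that pass's detected motion magnitudes falls below ``tol_vox``
    (0.1 voxels).  Detection re-reads the original frames through windows
    displaced by the cumulative trace; the corrected output frames are
    produced from the unfiltered originals.
    """
    center, window = _resolve_geometry(early_model, seq, center, window)
    _check_fingerprint(early_model, window)
    _check_fingerprint(late_model, window)
    frames = np.asarray(seq.frames, dtype=float)
    n_frames = frames.shape[0]
    filtered = np.stack([preprocess.median_filter3(f) for f in frames])

    cum = np.zeros((n_frames, 3))
    per_iteration: list[np.ndarray] = []
    iterations = {}
    for model, phase in ((early_model, "early"), (late_model, "late")):
        for it in range(1, max_iter + 1):
            idx, pred = _predict_phase(
                model, filtered, center, window, -cum, phase, n_frames
            )
            if phase == "late":
                pred[-1] = 0.0  # reference frame
            iterations[phase] = it
            cum[idx] += pred
            if len(per_iteration) < it:
                per_iteration.append(np.zeros((n_frames, 3)))
            per_iteration[it - 1][idx] += pred
            if float(np.linalg.norm(pred, axis=1).sum()) < tol_vox:
                break

    cum[-1] = 0.0
    trace = MotionTrace(quantize(cum))
    corrected = apply_correction(seq, trace, center, window)
    return CorrectionResult(
        corrected=corrected,
        cumulative=trace,
        per_iteration=per_iteration,
        iterations=iterations,
    )


def apply_correction(original_seq, trace: MotionTrace, center, window):
    """Re-crop every frame with its window displaced against the predicted
    shift so the content realigns to the reference; a zero trace is a plain
    crop.  Interpolation is trilinear; integer shifts resample losslessly."""
    frames = np.asarray(original_seq.frames, dtype=float)
    if len(trace) != frames.shape[0]:
        raise ValueError("trace length must equal the frame count")
    neg = MotionTrace(quantize(-trace.shifts))
    return motionsim.apply_motion(original_seq, neg, center, window)
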