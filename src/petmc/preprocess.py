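"""Detection-side preprocessing of dynamic sequences.

Noise filtering, window cropping with zero padding, mean-intensity
normalization, EQ-frame logic, temporal normalization to a fixed EQ index,
early/late phase splitting, and dual-channel input assembly.

Frame indices at this module's interface are 1-based (frame 1 .. frame N);
arrays are 0-indexed internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "PreprocessConfig",
    "median_filter3",
    "crop_window",
    "intensity_normalize",
    "find_eq_frame",
    "temporal_normalize",
    "split_early_late",
    "make_dual_channel",
    "N_EARLY",
    "N_LATE",
]

#: Sizes of the phase sets for a 27-frame sequence: the first 14 frames plus
#: an appended copy of the reference make the early set, the last 13 the late set.
N_EARLY = 15
N_LATE = 13


@dataclass(frozen=True)
class PreprocessConfig:
    median_window: int = 3
    crop_size: tuple = (64, 64, 36)
    n_ref: int = 7
    low_activity_ratio: float = 0.1
    n_early: int = N_EARLY
    n_late: int = N_LATE


def median_filter3(volume: np.ndarray, window: int = 3) -> np.ndarray:
    """Per-voxel median over the window^3 neighbourhood, reflect-padded.

    Applied only to motion-detection inputs; the images used for kinetic
    fitting stay unfiltered.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("median_filter3 expects a 3D volume")
    return ndimage.median_filter(volume, size=window, mode="reflect")


def crop_window(volume: np.ndarray, center, size) -> np.ndarray:
    """Fixed-size integer crop centered at ``center``; out-of-grid voxels are 0.

    For even window sizes the center voxel maps to output index size//2.
    """
    volume = np.asarray(volume)
    center = [int(round(c)) for c in center]
    size = tuple(int(s) for s in size)
    out = np.zeros(size, dtype=volume.dtype)
    src, dst = [], []
    for c, w, g in zip(center, size, volume.shape):
        start = c - w // 2
        lo, hi = max(start, 0), min(start + w, g)
        if lo >= hi:
            return out
        src.append(slice(lo, hi))
        dst.append(slice(lo - start, hi - start))
    out[tuple(dst)] = volume[tuple(src)]
    return out


def intensity_normalize(frame_window: np.ndarray) -> np.ndarray:
    """Divide by the mean of the cropped region; all-zero frames pass through."""
    frame_window = np.asarray(frame_window, dtype=float)
    m = frame_window.mean()
    if m <= 0:
        return frame_window.copy()
    return frame_window / m


def find_eq_frame(lv_tac, rv_tac) -> int:
    """First 1-based frame index with LV pool activity >= RV pool activity."""
    lv = np.asarray(lv_tac, dtype=float)
    rv = np.asarray(rv_tac, dtype=float)
    if lv.shape != rv.shape:
        raise ValueError("LV and RV TACs must have equal length")
    ge = np.nonzero(lv >= rv)[0]
    if len(ge) == 0:
        raise ValueError("LV activity never reaches the RV activity; no EQ frame")
    return int(ge[0]) + 1


def _shift_frames_early(frames: np.ndarray, mapping: list, k: int):
    """Drop k leading frames, duplicate the last frame k times."""
    out = np.concatenate([frames[k:], np.repeat(frames[-1:], k, axis=0)], axis=0)
    new_map = mapping[k:] + [mapping[-1]] * k
    return out, new_map


def _shift_frames_late(frames: np.ndarray, mapping: list, k: int):
    """Prepend k all-zero frames, drop k trailing frames."""
    zeros = np.zeros_like(frames[:k])
    out = np.concatenate([zeros, frames[:-k]], axis=0)
    new_map = [0] * k + mapping[:-k]
    return out, new_map


def temporal_normalize(
    seq,
    n_eq: int,
    n_ref: int = 7,
    low_activity_ratio: float = 0.1,
):
    """Align the EQ frame to index ``n_ref`` while preserving sequence length.

    Steps: (i) drop the first two frames and duplicate the last frame twice
    (always; those frames carry no or minimal activity); (ii) shift the
    re-indexed EQ frame (n_eq - 2 after the pre-step) onto ``n_ref`` by
    dropping leading frames / duplicating the last frame, or prepending
    zero frames / dropping trailing frames; (iii) zero any pre-EQ frame
    whose total activity is below ``low_activity_ratio`` of the EQ frame's.

    Returns ``(sequence, mapping)`` where ``mapping[i]`` is the 1-based
    source frame index feeding output frame i+1 (0 for inserted zero frames).

    Raises if the early-phase shift would discard a frame whose total
    activity is at or above the zeroing threshold (information loss).
    """
    frames = np.asarray(seq.frames, dtype=float)
    n = frames.shape[0]
    if not 1 <= n_eq <= n:
        raise ValueError(f"n_eq={n_eq} outside the frame range 1..{n}")
    if not 1 <= n_ref <= n:
        raise ValueError(f"n_ref={n_ref} outside the frame range 1..{n}")

    eq_total = frames[n_eq - 1].sum()
    threshold = low_activity_ratio * eq_total

    mapping = list(range(1, n + 1))
    out, mapping = _shift_frames_early(frames, mapping, 2)
    eq_idx = n_eq - 2  # 1-based index of the EQ frame after the pre-step

    if eq_idx > n_ref:
        k = eq_idx - n_ref
        discarded = out[:k]
        if np.any(discarded.reshape(k, -1).sum(axis=1) >= threshold):
            raise ValueError(
                "temporal shift would discard pre-EQ frames with significant activity"
            )
        out, mapping = _shift_frames_early(out, mapping, k)
    elif eq_idx < n_ref:
        out, mapping = _shift_frames_late(out, mapping, n_ref - eq_idx)

    # zero low-activity frames before the (aligned) EQ frame
    out = out.copy()
    for i in range(n_ref - 1):
        if out[i].sum() < threshold:
            out[i] = 0.0

    if hasattr(seq, "with_frames"):
        return seq.with_frames(out), mapping
    return out, mapping


def split_early_late(seq, n_early: int = N_EARLY, n_late: int = N_LATE):
    """Split a normalized 27-frame sequence into the early and late sets.

    Early = frames 1..14 plus a copy of the reference (last) frame; late =
    frames 15..27.  Returns plain frame arrays ``(early, late)``.
    """
    frames = np.asarray(seq.frames if hasattr(seq, "frames") else seq)
    expected = (n_early - 1) + n_late
    if frames.shape[0] != expected:
        raise ValueError(f"expected a {expected}-frame sequence, got {frames.shape[0]}")
    early = np.concatenate([frames[: n_early - 1], frames[-1:]], axis=0)
    late = frames[n_early - 1 :]
    return early, late


def make_dual_channel(frames: np.ndarray, reference_frame: np.ndarray | None = None):
    """Stack frames into a (T, C, X, Y, Z) network input.

    With a reference, channel 1 is the frame and channel 2 the shared
    reference; without one the output is single-channel (EQ-network mode).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 4:
        raise ValueError("frames must be (T, X, Y, Z)")
    if reference_frame is None:
        return frames[:, None]
    ref = np.asarray(reference_frame, dtype=float)
    if ref.shape != frames.shape[1:]:
        raise ValueError(
            f"reference shape {ref.shape} does not match frame shape {frames.shape[1:]}"
        )
    ref_stack = np.broadcast_to(ref, frames.shape)
    return np.stack([frames, ref_stack], axis=1)
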