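"""Conventional registration baselines.

Translation-only rigid registration driven by Mattes-style mutual
information over a 3-level multi-resolution pyramid, plus the two
whole-sequence strategies: individual registration of every frame to the
reference, and chain registration of adjacent frames with backward
accumulation.  The exact optimizer (Powell on the negative MI with 32
histogram bins and linear-interpolated resampling) is configuration, not
contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .motionsim import MotionTrace, eligible_frame_indices, quantize
from .preprocess import median_filter3

__all__ = [
    "RegistrationConfig",
    "mutual_information",
    "register_translation",
    "individual_registration",
    "chain_registration",
]


@dataclass(frozen=True)
class RegistrationConfig:
    n_bins: int = 32
    n_resolutions: int = 3
    median_filter: bool = True
    #: Gaussian pre-smoothing of both volumes; plays the role of the Parzen
    #: window in Mattes MI and removes the grid-alignment local maxima that a
    #: plain joint histogram exhibits.
    smoothing_sigma: float = 1.0
    max_shift_vox: float = 8.0


def mutual_information(a: np.ndarray, b: np.ndarray, n_bins: int = 32) -> float:
    """Histogram mutual information of two equally-shaped volumes (nats)."""
    hist, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=n_bins)
    pxy = hist / hist.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))


def _downsample(vol: np.ndarray) -> np.ndarray:
    return ndimage.zoom(ndimage.gaussian_filter(vol, 1.0), 0.5, order=1)


def _neg_mi(shift, moving, fixed, n_bins):
    shifted = ndimage.shift(moving, shift, order=1, mode="constant", cval=0.0)
    return -mutual_information(shifted, fixed, n_bins)


def register_translation(
    moving: np.ndarray,
    fixed: np.ndarray,
    config: RegistrationConfig = RegistrationConfig(),
) -> np.ndarray:
    """Estimate the 3-vector translation (voxels) aligning ``moving`` to
    ``fixed`` by maximizing mutual information coarse-to-fine.

    The returned shift is the content displacement: shifting ``moving`` by
    it (scipy convention) best matches ``fixed``.  Degenerate (constant)
    images return a zero shift with a warning.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed volumes must share a shape")
    if np.ptp(moving) == 0 or np.ptp(fixed) == 0:
        warnings.warn("constant image in registration; returning zero shift")
        return np.zeros(3)
    if config.median_filter:
        moving = median_filter3(moving)
        fixed = median_filter3(fixed)
    if config.smoothing_sigma > 0:
        moving = ndimage.gaussian_filter(moving, config.smoothing_sigma)
        fixed = ndimage.gaussian_filter(fixed, config.smoothing_sigma)

    pyramids = [(moving, fixed)]
    for _ in range(config.n_resolutions - 1):
        m, f = pyramids[-1]
        if min(m.shape) < 8:
            break
        pyramids.append((_downsample(m), _downsample(f)))

    shift = np.zeros(3)
    for level, (m, f) in enumerate(reversed(pyramids)):
        if level > 0:
            shift = shift * 2.0
        cap = config.max_shift_vox / 2 ** (len(pyramids) - 1 - level)
        res = optimize.minimize(
            _neg_mi,
            shift,
            args=(m, f, config.n_bins),
            method="Powell",
            bounds=[(s - cap, s + cap) for s in shift],
            options={"xtol": 0.05, "ftol": 1e-5},
        )
        shift = res.x
    return np.asarray(shift, dtype=float)


def _registered_trace(seq, estimator) -> MotionTrace:
    """Shared driver: estimate shifts for the eligible frames only (the
    first 3 frames carry negligible activity and the last is the reference),
    quantized to the 0.1-voxel trace grid."""
    frames = np.asarray(seq.frames, dtype=float)
    n = frames.shape[0]
    if n < 2:
        raise ValueError("need at least 2 frames")
    shifts = np.zeros((n, 3))
    estimator(frames, shifts)
    shifts[-1] = 0.0
    return MotionTrace(quantize(shifts))


def individual_registration(
    seq, config: RegistrationConfig = RegistrationConfig()
) -> MotionTrace:
    """Register each eligible frame directly to the reference (last) frame.

    The reported shift is the window displacement that realigns the frame,
    matching the simulator's trace convention.
    """

    def estimator(frames, shifts):
        fixed = frames[-1]
        for n in eligible_frame_indices(len(frames)):
            # ndimage.shift moves content by +s; content displaced by -M needs
            # s = +M, so the estimated content shift equals the trace entry.
            shifts[n] = register_translation(frames[n], fixed, config)

    return _registered_trace(seq, estimator)


def chain_registration(
    seq, config: RegistrationConfig = RegistrationConfig()
) -> MotionTrace:
    """Register each frame to its next frame, accumulating backward from the
    reference: entry n is the sum of the pairwise estimates from n to the
    reference.  Only eligible frames are registered (23 for 27 frames)."""

    def estimator(frames, shifts):
        n = len(frames)
        eligible = set(int(i) for i in eligible_frame_indices(n))
        acc = np.zeros(3)
        for m in range(n - 2, -1, -1):
            if m not in eligible:
                break
            pairwise = quantize(register_translation(frames[m], frames[m + 1], config))
            acc = acc + pairwise
            shifts[m] = acc

    return _registered_trace(seq, estimator)
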