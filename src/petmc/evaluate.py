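"""Quantitative evaluation metrics.

Motion-estimation mean/max errors in mm over the included frame range
(frames 3..N-1, 1-based: the first two low-activity frames and the final
reference frame are excluded), MBF bias and symmetric percent difference,
motion-severity classification, and replicate-level summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "included_frame_mask",
    "framewise_error_mm",
    "mean_motion_error",
    "max_motion_error",
    "mbf_percent_bias",
    "mbf_percent_difference",
    "MotionClassification",
    "classify_motion",
    "summarize_replicates",
]


def _shift_arrays(pred, truth):
    p = np.asarray(pred.shifts if hasattr(pred, "shifts") else pred, dtype=float)
    t = np.asarray(truth.shifts if hasattr(truth, "shifts") else truth, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"trace shapes differ: {p.shape} vs {t.shape}")
    if p.shape[0] < 4:
        raise ValueError("need at least 4 frames")
    return p, t


def included_frame_mask(n_frames: int) -> np.ndarray:
    """Boolean mask of the frames entering the error metrics: 1-based
    3..N-1, i.e. everything but frames 1, 2 and the reference frame N."""
    mask = np.ones(n_frames, dtype=bool)
    mask[:2] = False
    mask[-1] = False
    return mask


def framewise_error_mm(pred, truth, voxel_mm) -> np.ndarray:
    """Per-frame Euclidean error in mm over the included range."""
    p, t = _shift_arrays(pred, truth)
    d = (p - t) * np.asarray(voxel_mm, dtype=float)
    return np.linalg.norm(d, axis=1)[included_frame_mask(p.shape[0])]


def mean_motion_error(pred, truth, voxel_mm) -> float:
    """(1/(N-3)) * sum over frames 3..N-1 of the Euclidean error (mm)."""
    return float(framewise_error_mm(pred, truth, voxel_mm).mean())


def max_motion_error(pred, truth, voxel_mm) -> float:
    """Maximum per-frame Euclidean error (mm) over frames 3..N-1."""
    return float(framewise_error_mm(pred, truth, voxel_mm).max())


def mbf_percent_bias(mbf_m: float, mbf_mf: float) -> float:
    """(MBF_M - MBF_MF) / MBF_MF x 100%, against the motion-free value."""
    if mbf_mf <= 0:
        raise ValueError("reference MBF must be positive")
    return (mbf_m - mbf_mf) / mbf_mf * 100.0


def mbf_percent_difference(mbf_uc: float, mbf_mc: float) -> float:
    """Symmetric percent difference 2(UC - MC)/(UC + MC) x 100%."""
    s = mbf_uc + mbf_mc
    if s <= 0:
        raise ValueError("MBF values must have a positive sum")
    return 2.0 * (mbf_uc - mbf_mc) / s * 100.0


@dataclass(frozen=True)
class MotionClassification:
    motion_free: bool
    magnitudes_mm: np.ndarray
    n_frames_over_3mm: int
    total_motion_mm: float


def classify_motion(trace, voxel_mm, rule: str = "total") -> MotionClassification:
    """Motion-free screening: total motion (sum over frames of per-frame
    magnitude relative to the reference) at most 3 mm.

    ``rule='max'`` uses the maximum per-frame magnitude instead.  Also
    reports per-frame mm magnitudes and the count of frames above 3 mm
    (mild-or-worse motion).
    """
    shifts = np.asarray(trace.shifts if hasattr(trace, "shifts") else trace, dtype=float)
    mags = np.linalg.norm(shifts * np.asarray(voxel_mm, dtype=float), axis=1)
    total = float(mags.sum())
    stat = total if rule == "total" else float(mags.max())
    return MotionClassification(
        motion_free=bool(stat <= 3.0),
        magnitudes_mm=mags,
        n_frames_over_3mm=int(np.count_nonzero(mags > 3.0)),
        total_motion_mm=total,
    )


def summarize_replicates(results, group_key: str = "motion_type") -> pd.DataFrame:
    """Mean +- sample std of every numeric metric per motion type and overall.

    ``results`` is an iterable of dicts (one per replicate) containing the
    grouping key and numeric metric values.  Returns a table indexed by
    group with ``<metric>_mean``, ``<metric>_std`` and ``n`` columns;
    standard deviations use the sample (n-1) convention.
    """
    df = pd.DataFrame(list(results))
    if df.empty:
        raise ValueError("no replicate results to summarize")
    metrics = [c for c in df.columns if c != group_key and np.issubdtype(df[c].dtype, np.number)]
    rows = {}
    groups = [(g, sub) for g, sub in df.groupby(group_key)] + [("overall", df)]
    for name, sub in groups:
        row = {"n": len(sub)}
        for m in metrics:
            row[f"{m}_mean"] = sub[m].mean()
            row[f"{m}_std"] = sub[m].std(ddof=1) if len(sub) > 1 else 0.0
        rows[name] = row
    return pd.DataFrame.from_dict(rows, orient="index")
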