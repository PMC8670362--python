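"""Synthetic 4D dynamic cardiac PET phantom.

Generates motion-free dynamic sequences on a voxel grid with an RV blood
pool, an LV blood pool, an LV-myocardium shell and (optionally) a soft
background, driven by a gamma-variate bolus input and a one-tissue forward
model for the myocardium.  Every sequence carries its frame schedule and a
label volume, and the ground-truth EQ frame (first frame with LV pool
activity >= RV pool activity) is returned alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import kinetics

__all__ = [
    "FrameSchedule",
    "PhantomConfig",
    "DynamicSequence",
    "RoiLabels",
    "LABEL_BACKGROUND",
    "LABEL_MYOCARDIUM",
    "LABEL_LV_POOL",
    "LABEL_RV_POOL",
    "default_frame_schedule",
    "small_phantom_config",
    "input_function",
    "generate_phantom",
    "PhantomDraw",
    "sample_draw",
    "build_labels",
    "region_tacs",
]

LABEL_BACKGROUND = 0
LABEL_MYOCARDIUM = 1
LABEL_LV_POOL = 2
LABEL_RV_POOL = 3


@dataclass(frozen=True)
class FrameSchedule:
    """Frame start times and durations in seconds (contiguous frames)."""

    start_s: np.ndarray
    duration_s: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start_s, dtype=float)
        dur = np.asarray(self.duration_s, dtype=float)
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "duration_s", dur)
        if start.shape != dur.shape or start.ndim != 1:
            raise ValueError("start_s and duration_s must be 1D arrays of equal length")
        if np.any(dur <= 0):
            raise ValueError("frame durations must be strictly positive")
        if not np.allclose(start[1:], start[:-1] + dur[:-1]):
            raise ValueError("frames must be contiguous")

    def __len__(self) -> int:
        return len(self.start_s)

    @property
    def total_s(self) -> float:
        return float(self.start_s[-1] + self.duration_s[-1])

    @property
    def mid_s(self) -> np.ndarray:
        return self.start_s + self.duration_s / 2.0

    @classmethod
    def from_durations(cls, durations) -> "FrameSchedule":
        dur = np.asarray(durations, dtype=float)
        start = np.concatenate([[0.0], np.cumsum(dur[:-1])])
        return cls(start, dur)


def small_phantom_config(noise_scale: float = 0.3, **overrides) -> "PhantomConfig":
    """Desk-scale 24x24x12 phantom with halved geometry.

    Fast enough for CPU training loops and registration sweeps while keeping
    the clinical voxel size (mm thresholds stay meaningful).
    """
    kw = dict(
        grid_shape=(24, 24, 12),
        lv_center=(14.5, 12.0, 6.0),
        lv_pool_radii=(2.75, 2.75, 2.25),
        myo_outer_radii=(4.75, 4.75, 3.75),
        rv_center=(7.5, 12.0, 6.0),
        rv_pool_radii=(3.0, 4.0, 2.25),
        septal_mid=(11, 12, 6),
        noise_scale=noise_scale,
    )
    kw.update(overrides)
    return PhantomConfig(**kw)


def default_frame_schedule() -> FrameSchedule:
    """The clinical rebinning schedule: 14x5s, 6x10s, 3x20s, 3x30s, 1x90s."""
    durations = [5.0] * 14 + [10.0] * 6 + [20.0] * 3 + [30.0] * 3 + [90.0]
    return FrameSchedule.from_durations(durations)


@dataclass(frozen=True)
class RoiLabels:
    """Integer label volume; codes are the LABEL_* module constants."""

    volume: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "volume", np.asarray(self.volume))

    @property
    def shape(self):
        return self.volume.shape


@dataclass(frozen=True)
class DynamicSequence:
    """A 4D activity array (frames x X x Y x Z, Bq/mL) with its schedule."""

    frames: np.ndarray
    schedule: FrameSchedule
    voxel_mm: tuple
    labels: RoiLabels | None = None

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "voxel_mm", tuple(float(v) for v in self.voxel_mm))
        if frames.ndim != 4:
            raise ValueError("frames must be 4D (T, X, Y, Z)")
        if frames.shape[0] != len(self.schedule):
            raise ValueError(
                f"{frames.shape[0]} frames but schedule has {len(self.schedule)}"
            )
        if np.any(frames < 0):
            raise ValueError("activity must be nonnegative")
        if len(self.voxel_mm) != 3:
            raise ValueError("voxel_mm must have 3 components")
        if self.labels is not None and self.labels.shape != frames.shape[1:]:
            raise ValueError("label volume shape must match the spatial frame shape")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def spatial_shape(self):
        return self.frames.shape[1:]

    def with_frames(self, frames: np.ndarray) -> "DynamicSequence":
        return replace(self, frames=np.asarray(frames, dtype=float))


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, kinetics and noise settings of the synthetic phantom.

    Desk-scale default grid is 48x48x24 with the clinical voxel size so that
    mm thresholds keep their meaning; the clinical 128x128x47 grid is a
    config change away.  All per-sequence random draws (bolus delay,
    myocardial kinetics, amplitude) are taken from the ``*_range`` fields.
    """

    grid_shape: tuple = (48, 48, 24)
    voxel_mm: tuple = (3.125, 3.125, 3.270)

    # region geometry in voxel coordinates
    lv_center: tuple = (29.0, 24.0, 12.0)
    lv_pool_radii: tuple = (5.5, 5.5, 4.5)
    myo_outer_radii: tuple = (9.5, 9.5, 7.5)
    rv_center: tuple = (15.0, 24.0, 12.0)
    rv_pool_radii: tuple = (6.0, 8.0, 4.5)
    septal_mid: tuple = (22, 24, 12)

    # bolus: gamma-variate shape, arrival and RV->LV transit delay (seconds).
    # The RV pool additionally carries a small early baseline (venous side of
    # the injection) so that the LV never ties with an exactly-zero RV.
    # A steep bolus (alpha=3, beta=2 s) keeps the LV/RV crossing decisive:
    # with a broad bolus a large fraction of draws sit within noise of the
    # crossing at some frame, which no EQ detector can resolve.
    bolus_amplitude: float = 5.0e4
    bolus_alpha: float = 3.0
    bolus_beta_s: float = 2.0
    arrival_range_s: tuple = (9.0, 40.0)
    delay_range_s: tuple = (4.0, 10.0)
    rv_baseline_fraction: float = 1e-4
    #: Minimum |LV - RV| margin (fraction of the LV peak) required at the EQ
    #: frame and the frame before it; timing draws violating it are redrawn.
    #: A crossing that lands exactly on a frame boundary makes the EQ label
    #: depend on sub-percent activity differences no detector can resolve.
    #: Set to 0 to disable the rejection step.
    eq_margin_min: float = 0.15

    # myocardium kinetics ranges (1T forward model of the LV curve)
    k1_range: tuple = (0.6, 1.4)
    k2_range: tuple = (0.2, 0.6)
    vb_range: tuple = (0.2, 0.4)

    # background tissue (off by default; fraction of LV peak when enabled)
    background_fraction: float = 0.0

    noise_scale: float = 0.0
    schedule: FrameSchedule = field(default_factory=default_frame_schedule)

    def __post_init__(self) -> None:
        if self.delay_range_s[0] < 0 or self.arrival_range_s[0] < 0:
            raise ValueError("bolus arrival and RV-to-LV delay must be nonnegative")
        if self.bolus_beta_s <= 0:
            raise ValueError("bolus dispersion beta must be positive")
        if not all(
            0 <= c < s for c, s in zip(self.septal_mid, self.grid_shape)
        ):
            raise ValueError("septal mid-point must lie inside the grid")


def input_function(
    t,
    amplitude: float = 5.0e4,
    arrival_s: float = 10.0,
    alpha: float = 2.5,
    beta_s: float = 6.0,
):
    """Gamma-variate bolus: zero before arrival, peak ``amplitude`` at
    ``arrival_s + alpha * beta_s``, decaying tail."""
    if beta_s <= 0:
        raise ValueError("beta_s (dispersion) must be positive")
    t = np.asarray(t, dtype=float)
    dt = t - arrival_s
    out = np.zeros_like(dt)
    pos = dt > 0
    x = dt[pos] / (alpha * beta_s)
    out[pos] = amplitude * x**alpha * np.exp(alpha * (1.0 - x))
    return out


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return r2 <= 1.0


def build_labels(config: PhantomConfig) -> RoiLabels:
    """Rasterize the region geometry into a label volume.

    Regions are made disjoint by assignment priority: blood pools overwrite
    the myocardial shell; an overlap between LV and RV pools is an error.
    """
    shape = tuple(config.grid_shape)
    lv_pool = _ellipsoid_mask(shape, config.lv_center, config.lv_pool_radii)
    myo = _ellipsoid_mask(shape, config.lv_center, config.myo_outer_radii) & ~lv_pool
    rv_pool = _ellipsoid_mask(shape, config.rv_center, config.rv_pool_radii)
    if (lv_pool & rv_pool).any():
        raise ValueError("LV and RV blood pools overlap; adjust the geometry")
    myo = myo & ~rv_pool
    vol = np.zeros(shape, dtype=np.int16)
    vol[myo] = LABEL_MYOCARDIUM
    vol[lv_pool] = LABEL_LV_POOL
    vol[rv_pool] = LABEL_RV_POOL
    return RoiLabels(vol)


def region_tacs(
    config: PhantomConfig, arrival_s: float, delay_s: float, k1: float, k2: float, vb: float
):
    """Frame-averaged analytic TACs (rv, lv, myo, background) for one draw."""
    sched = config.schedule
    baseline = config.rv_baseline_fraction * config.bolus_amplitude

    def rv_curve(t):
        t = np.asarray(t, dtype=float)
        return (
            input_function(
                t, config.bolus_amplitude, arrival_s, config.bolus_alpha, config.bolus_beta_s
            )
            + baseline * (1.0 - np.exp(-np.maximum(t, 0.0) / 5.0))
        )

    def lv_curve(t):
        return input_function(
            t,
            config.bolus_amplitude,
            arrival_s + delay_s,
            config.bolus_alpha,
            config.bolus_beta_s,
        )

    params = kinetics.KineticParams(k1, k2, vb)
    rv = kinetics.model_tac(kinetics.KineticParams(0.0, 0.0, 1.0), rv_curve, sched)
    lv = kinetics.model_tac(kinetics.KineticParams(0.0, 0.0, 1.0), lv_curve, sched)
    myo = kinetics.model_tac(params, lv_curve, sched)
    bg = config.background_fraction * np.max(lv) * (1.0 - np.exp(-sched.mid_s / 60.0))
    return rv, lv, myo, np.broadcast_to(bg, rv.shape).astype(float)


@dataclass(frozen=True)
class PhantomDraw:
    """Per-sequence random draw: bolus timing and myocardial kinetics."""

    arrival_s: float
    delay_s: float
    k1: float
    k2: float
    vb: float


def _eq_margin(config: PhantomConfig, arrival_s: float, delay_s: float) -> float:
    """Worst-case |LV - RV| margin (fraction of LV peak) at the EQ frame and
    the frame before it, for the pool TACs implied by a timing draw."""
    from .preprocess import find_eq_frame

    rv, lv, _, _ = region_tacs(config, arrival_s, delay_s, 0.0, 0.0, 0.0)
    n_eq = find_eq_frame(lv, rv)
    scale = float(lv.max())
    at = (lv[n_eq - 1] - rv[n_eq - 1]) / scale
    before = (rv[n_eq - 2] - lv[n_eq - 2]) / scale if n_eq >= 2 else np.inf
    return float(min(at, before))


def sample_draw(config: PhantomConfig, rng: np.random.Generator) -> PhantomDraw:
    """Draw per-sequence parameters; bolus timings whose LV/RV crossing falls
    within ``eq_margin_min`` of a frame boundary are rejected and redrawn."""
    for _ in range(200):
        arrival = float(rng.uniform(*config.arrival_range_s))
        delay = float(rng.uniform(*config.delay_range_s))
        if config.eq_margin_min <= 0 or _eq_margin(config, arrival, delay) >= config.eq_margin_min:
            break
    else:
        raise RuntimeError("could not draw a decisive EQ timing in 200 attempts")
    return PhantomDraw(
        arrival_s=arrival,
        delay_s=delay,
        k1=float(rng.uniform(*config.k1_range)),
        k2=float(rng.uniform(*config.k2_range)),
        vb=float(rng.uniform(*config.vb_range)),
    )


def generate_phantom(
    config: PhantomConfig,
    seed: int | np.random.Generator = 0,
    draw: PhantomDraw | None = None,
):
    """Generate one motion-free dynamic sequence.

    Returns ``(sequence, labels, n_eq_truth)`` where ``n_eq_truth`` is the
    1-based index of the first frame whose noise-free LV pool TAC is >= the
    RV pool TAC.  Identical seeds give bit-identical sequences.  Supplying a
    ``draw`` pins the per-sequence kinetics (useful for recovery tests).
    """
    from .preprocess import find_eq_frame  # local import avoids a cycle

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    labels = build_labels(config)

    if draw is None:
        draw = sample_draw(config, rng)
    rv, lv, myo, bg = region_tacs(
        config, draw.arrival_s, draw.delay_s, draw.k1, draw.k2, draw.vb
    )
    n_eq = find_eq_frame(lv, rv)

    sched = config.schedule
    shape = (len(sched),) + tuple(config.grid_shape)
    frames = np.zeros(shape, dtype=float)
    region_curves = {
        LABEL_BACKGROUND: bg,
        LABEL_MYOCARDIUM: myo,
        LABEL_LV_POOL: lv,
        LABEL_RV_POOL: rv,
    }
    for code, tac in region_curves.items():
        mask = labels.volume == code
        if not mask.any():
            continue
        frames[:, mask] = tac[:, None]

    if config.noise_scale > 0:
        dur = sched.duration_s
        for n in range(len(sched)):
            sigma = config.noise_scale * np.sqrt(
                np.maximum(frames[n], 0.0) / dur[n]
            )
            frames[n] += rng.standard_normal(frames[n].shape) * sigma
        np.clip(frames, 0.0, None, out=frames)

    seq = DynamicSequence(
        frames=frames, schedule=sched, voxel_mm=config.voxel_mm, labels=labels
    )
    return seq, labels, n_eq
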