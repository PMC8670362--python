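import numpy as np
import pytest

from petmc import motionsim
from petmc.motionsim import (
    EVAL_CONFIG,
    MOTION_TYPES,
    MotionSimConfig,
    MotionTrace,
    _triangle_fractions,
    apply_motion,
    eligible_frame_indices,
    make_evaluation_set,
    make_training_sample,
    quantize,
    shift_frames,
    simulate_trace,
)
from petmc.phantom import DynamicSequence, default_frame_schedule


def _tiny_seq(n=27, shape=(6, 6, 4)):
    frames = np.zeros((n,) + shape)
    frames[:, 2:4, 2:4, 1:3] = 1.0
    return DynamicSequence(
        frames=frames, schedule=default_frame_schedule(), voxel_mm=(3.125, 3.125, 3.27)
    )


class TestMotionTrace:
    def test_quantization_enforced(self):
        with pytest.raises(ValueError, match="0.1"):
            MotionTrace(np.array([[0.05, 0, 0]] + [[0, 0, 0]] * 4))

    def test_reference_frame_must_be_zero(self):
        shifts = np.zeros((5, 3))
        shifts[-1] = [1.0, 0, 0]
        with pytest.raises(ValueError, match="reference"):
            MotionTrace(shifts)

    def test_zero_constructor(self):
        t = MotionTrace.zero(27)
        assert len(t) == 27
        assert t.motion_frame_count() == 0

    def test_magnitudes_mm(self):
        shifts = np.zeros((4, 3))
        shifts[1] = [1.0, 0, 0]
        t = MotionTrace(shifts)
        assert t.magnitudes_mm((3.125, 3.125, 3.27))[1] == pytest.approx(3.125)


class TestSimulateTrace:
    def test_eligible_frames_27(self):
        idx = eligible_frame_indices(27)
        assert len(idx) == 23
        assert idx[0] == 3 and idx[-1] == 25

    @pytest.mark.parametrize("motion_type", MOTION_TYPES)
    def test_leading_and_reference_frames_zero(self, motion_type, rng):
        for _ in range(20):
            t = simulate_trace(motion_type, 27, rng)
            assert np.all(t.shifts[:3] == 0)
            assert np.all(t.shifts[-1] == 0)

    @pytest.mark.parametrize("motion_type", MOTION_TYPES)
    def test_components_quantized(self, motion_type, rng):
        for _ in range(20):
            t = simulate_trace(motion_type, 27, rng)
            np.testing.assert_allclose(t.shifts, quantize(t.shifts), atol=1e-12)

    def test_square_identical_vectors(self, rng):
        for _ in range(20):
            t = simulate_trace("square", 27, rng)
            nz = np.nonzero(t.magnitudes_vox)[0]
            assert len(nz) >= 2
            assert np.all(np.diff(nz) == 1)  # contiguous run
            np.testing.assert_array_equal(t.shifts[nz], np.tile(t.shifts[nz[0]], (len(nz), 1)))

    def test_triangle_fraction_oracle(self):
        # 5 frames, peak 3.0 at the centre -> magnitudes (1, 2, 3, 2, 1)
        np.testing.assert_allclose(_triangle_fractions(5) * 3.0, [1, 2, 3, 2, 1])
        # even run: peak on the earlier central frame, descent over the rest
        np.testing.assert_allclose(_triangle_fractions(4), [0.5, 1.0, 2 / 3, 1 / 3])
        np.testing.assert_allclose(_triangle_fractions(2), [1.0, 0.5])

    def test_triangle_ramp_matches_fractions(self, rng):
        for _ in range(20):
            t = simulate_trace("triangle", 27, rng)
            nz = np.nonzero(t.magnitudes_vox)[0]
            k = len(nz)
            peak = t.shifts[nz[(k - 1) // 2]]
            expected = quantize(_triangle_fractions(k)[:, None] * peak[None, :])
            np.testing.assert_allclose(t.shifts[nz], expected, atol=1e-12)

    def test_spike_vectors_can_differ(self, rng):
        distinct = False
        for _ in range(20):
            t = simulate_trace("spike", 27, rng)
            nz = np.nonzero(t.magnitudes_vox)[0]
            if len(np.unique(t.shifts[nz], axis=0)) > 1:
                distinct = True
        assert distinct

    def test_max_shift_cap(self, rng):
        for motion_type in MOTION_TYPES:
            for _ in range(30):
                t = simulate_trace(motion_type, 27, rng)
                assert np.all(np.abs(t.shifts) <= 4.0 + 1e-12)

    def test_too_few_frames_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_trace("square", 4, rng)

    def test_unknown_type_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_trace("sawtooth", 27, rng)


class TestApplyMotion:
    def test_zero_trace_is_plain_crop(self):
        seq = _tiny_seq()
        out = apply_motion(seq, MotionTrace.zero(27), (3, 3, 2), (4, 4, 4))
        from petmc.preprocess import crop_window

        for n in range(27):
            np.testing.assert_array_equal(
                out.frames[n], crop_window(seq.frames[n], (3, 3, 2), (4, 4, 4))
            )

    def test_integer_shift_moves_impulse(self):
        frames = np.zeros((5, 9, 9, 9))
        frames[:, 4, 4, 4] = 1.0
        seq = DynamicSequence(
            frames=frames,
            schedule=default_frame_schedule().from_durations([5.0] * 5),
            voxel_mm=(1, 1, 1),
        )
        shifts = np.zeros((5, 3))
        shifts[1] = [1.0, 0, 0]
        out = apply_motion(seq, MotionTrace(shifts), (4, 4, 4), (5, 5, 5))
        # window reads original position center+1: impulse appears one voxel lower
        assert out.frames[0][2, 2, 2] == 1.0
        assert out.frames[1][1, 2, 2] == 1.0

    def test_half_voxel_shift_on_linear_ramp(self):
        # ramp along x: value = x; sampling at x + 0.5 gives x + 0.5 exactly
        ramp = np.tile(np.arange(12, dtype=float)[:, None, None], (1, 8, 8))
        frames = np.stack([ramp, ramp])
        seq = DynamicSequence(
            frames=frames,
            schedule=default_frame_schedule().from_durations([5.0, 5.0]),
            voxel_mm=(1, 1, 1),
        )
        shifts = np.array([[0.5, 0, 0], [0, 0, 0]])
        out = apply_motion(seq, MotionTrace(shifts), (6, 4, 4), (4, 4, 4))
        expected = np.tile((np.arange(4) + 4 + 0.5)[:, None, None], (1, 4, 4))
        np.testing.assert_allclose(out.frames[0], expected, atol=1e-12)

    def test_trace_length_mismatch(self):
        seq = _tiny_seq()
        with pytest.raises(ValueError):
            apply_motion(seq, MotionTrace.zero(5), (3, 3, 2), (4, 4, 4))

    def test_shift_frames_consistent_with_apply_motion(self, rng):
        seq = _tiny_seq()
        trace = simulate_trace("square", 27, rng)
        full = shift_frames(seq, trace)
        from petmc.preprocess import crop_window

        windowed = apply_motion(seq, trace, (3, 3, 2), (2, 2, 2))
        for n in range(27):
            np.testing.assert_allclose(
                crop_window(full.frames[n], (3, 3, 2), (2, 2, 2)),
                windowed.frames[n],
                atol=1e-12,
            )


class TestMakeTrainingSample:
    def test_type_frequencies_near_uniform(self, rng, small_seq):
        seq, _, n_eq = small_seq
        from petmc.preprocess import temporal_normalize

        norm, _ = temporal_normalize(seq, n_eq)
        n = 600
        counts = {t: 0 for t in MOTION_TYPES}
        filtered = np.asarray(norm.frames)  # skip the median filter for speed
        for _ in range(n):
            _, _, info = make_training_sample(
                norm, rng, phase="early", crop_size=(8, 8, 4), filtered_frames=filtered
            )
            counts[info["motion_type"]] += 1
        sigma = np.sqrt(n * (1 / 3) * (2 / 3))
        for t in MOTION_TYPES:
            assert abs(counts[t] - n / 3) < 3 * sigma

    def test_target_and_initial_shift_caps(self, rng, small_seq):
        seq, _, n_eq = small_seq
        filtered = np.asarray(seq.frames)
        for _ in range(50):
            _, target, info = make_training_sample(
                seq, rng, phase="late", crop_size=(8, 8, 4), filtered_frames=filtered
            )
            assert np.all(np.abs(target) <= 4.0 + 1e-12)
            assert np.all(np.abs(info["initial_shift"]) <= 3.0 + 1e-12)
            assert abs(info["jitter"]) <= 1

    def test_early_sample_shapes_and_reference_target(self, rng, small_seq):
        seq, _, _ = small_seq
        filtered = np.asarray(seq.frames)
        inputs, target, _ = make_training_sample(
            seq, rng, phase="early", crop_size=(8, 8, 4), filtered_frames=filtered
        )
        assert inputs.shape == (15, 2, 8, 8, 4)
        assert target.shape == (15, 3)
        np.testing.assert_array_equal(target[-1], 0)
        np.testing.assert_array_equal(target[:3], 0)

    def test_late_sample_shapes(self, rng, small_seq):
        seq, _, _ = small_seq
        filtered = np.asarray(seq.frames)
        inputs, target, _ = make_training_sample(
            seq, rng, phase="late", crop_size=(8, 8, 4), filtered_frames=filtered
        )
        assert inputs.shape == (13, 2, 8, 8, 4)
        np.testing.assert_array_equal(target[-1], 0)


class TestMakeEvaluationSet:
    def test_replicate_count_600(self, rng):
        bases = [_tiny_seq() for _ in range(20)]
        reps = make_evaluation_set(bases, rng)
        assert len(reps) == 600

    def test_motion_frame_counts_in_5_to_11(self, rng):
        bases = [_tiny_seq() for _ in range(3)]
        for rep in make_evaluation_set(bases, rng):
            assert 5 <= rep.trace.motion_frame_count() <= 11

    def test_reference_frame_zero(self, rng):
        bases = [_tiny_seq()]
        for rep in make_evaluation_set(bases, rng):
            np.testing.assert_array_equal(rep.trace.shifts[-1], 0)

    def test_types_balanced_exactly(self, rng):
        bases = [_tiny_seq() for _ in range(2)]
        reps = make_evaluation_set(bases, rng)
        for t in MOTION_TYPES:
            assert sum(r.motion_type == t for r in reps) == 20

    def test_empty_base_list_rejected(self, rng):
        with pytest.raises(ValueError):
            make_evaluation_set([], rng)

    def test_no_cap_violation_with_eval_config(self, rng):
        bases = [_tiny_seq()]
        for rep in make_evaluation_set(bases, rng):
            assert np.all(np.abs(rep.trace.shifts) <= 4.0 + 1e-12)


class TestRoundTrip:
    def test_integer_motion_then_correction_is_lossless(self, rng, small_seq):
        from petmc.correct import apply_correction

        seq, _, _ = small_seq
        shifts = np.zeros((27, 3))
        shifts[5:12] = [2.0, -1.0, 1.0]
        trace = MotionTrace(shifts)
        corrupted = shift_frames(seq, trace)
        center, window = (11, 12, 6), (8, 8, 4)
        recovered = apply_correction(corrupted, trace, center, window)
        clean = apply_motion(seq, MotionTrace.zero(27), center, window)
        np.testing.assert_allclose(recovered.frames, clean.frames, atol=1e-9)

    def test_subvoxel_round_trip_bounded_and_improves_with_smoothing(self, small_seq):
        from scipy.ndimage import gaussian_filter

        from petmc.correct import apply_correction

        seq, _, _ = small_seq
        shifts = np.zeros((27, 3))
        shifts[10:15] = [0.5, 0.3, -0.4]
        trace = MotionTrace(shifts)
        center, window = (11, 12, 6), (8, 8, 4)
        clean = apply_motion(seq, MotionTrace.zero(27), center, window)

        def round_trip_error(frames):
            s = DynamicSequence(frames=frames, schedule=seq.schedule, voxel_mm=seq.voxel_mm)
            rec = apply_correction(shift_frames(s, trace), trace, center, window)
            ref = apply_motion(s, MotionTrace.zero(27), center, window)
            return np.max(np.abs(rec.frames - ref.frames))

        err_raw = round_trip_error(seq.frames)
        smooth = np.stack([gaussian_filter(f, 1.5) for f in seq.frames])
        err_smooth = round_trip_error(smooth)
        assert err_raw <= 0.5 * seq.frames.max()  # bounded by local variation
        assert err_smooth < err_raw


class TestQuantizationProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(seed=st.integers(0, 10_000), mtype=st.sampled_from(MOTION_TYPES))
    @settings(max_examples=30, deadline=None)
    def test_simulated_traces_always_valid(self, seed, mtype):
        rng = np.random.default_rng(seed)
        t = simulate_trace(mtype, 27, rng)
        # quantized to the 0.1-voxel grid
        np.testing.assert_allclose(t.shifts, quantize(t.shifts), atol=1e-12)
        # leading and reference frames motion-free
        assert np.all(t.shifts[:3] == 0) and np.all(t.shifts[-1] == 0)
        # within the per-axis cap
        assert np.all(np.abs(t.shifts) <= 4.0 + 1e-12)
        # contiguous motion run
        nz = np.nonzero(t.magnitudes_vox)[0]
        if len(nz) > 1:
            assert np.all(np.diff(nz) == 1)
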