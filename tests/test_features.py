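"""Descriptor-set correctness: oracles, invariants and degenerate cases."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wristbow.features import (
    DESCRIPTOR_NAMES,
    acceleration_range,
    dispersion,
    dispersion_bruteforce,
    rmsr,
    segment_descriptors,
    session_descriptors,
    subject_statistical_features,
    vector_magnitude,
)
from wristbow.segmentation import WindowSpec


def const_block(x, y, z, n=20):
    return np.tile([x, y, z], (n, 1)).astype(float)


class TestVectorMagnitude:
    def test_pure_gravity(self):
        assert vector_magnitude(const_block(0, 0, 1)) == pytest.approx(1.0)

    def test_three_four_five(self):
        assert vector_magnitude(const_block(3, 4, 0)) == pytest.approx(5.0)

    def test_matches_sample_loop(self, rng):
        block = rng.normal(size=(37, 3))
        expected = np.mean([np.sqrt(s @ s) for s in block])
        assert vector_magnitude(block) == pytest.approx(expected, abs=1e-12)

    def test_empty_segment_errors(self):
        with pytest.raises(ValueError):
            vector_magnitude(np.empty((0, 3)))


class TestRMSR:
    def test_single_axis(self, rng):
        block = np.zeros((50, 3))
        block[:, 0] = rng.normal(size=50)
        out = rmsr(block)
        assert out == pytest.approx((1.0, 0.0, 0.0))

    def test_equal_axes_symmetry(self):
        block = const_block(0.3, 0.3, 0.3)
        assert rmsr(block) == pytest.approx((1 / np.sqrt(3),) * 3)

    def test_matches_independent_rms(self, rng):
        block = rng.normal(size=(64, 3))
        rms = np.sqrt((block**2).mean(axis=0))
        expected = rms / np.linalg.norm(rms)
        assert rmsr(block) == pytest.approx(tuple(expected), abs=1e-12)

    def test_all_zero_is_flagged_null(self):
        out = rmsr(np.zeros((10, 3)))
        assert all(np.isnan(v) for v in out)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_unit_norm_invariant(self, seed):
        block = np.random.default_rng(seed).normal(size=(30, 3))
        out = np.asarray(rmsr(block))
        assert np.sum(out**2) == pytest.approx(1.0, abs=1e-12)


class TestDispersion:
    def test_constant_segment_is_zero(self):
        assert dispersion(const_block(1, 2, 3)) == (0.0, 0.0, 0.0)

    def test_two_samples_dispersion_two(self):
        # population z-scores of two distinct values are +/-1 -> |z1-z2| = 2
        block = np.zeros((2, 3))
        block[:, 1] = [0.1, 0.5]
        assert dispersion(block) == pytest.approx((0.0, 2.0, 0.0))

    @given(st.integers(0, 2**32 - 1), st.integers(2, 120))
    @settings(max_examples=80, deadline=None)
    def test_fast_path_equals_pair_enumeration(self, seed, n):
        """Sorted prefix-sum identity == O(m^2) double loop, incl. outliers."""
        rng = np.random.default_rng(seed)
        block = rng.normal(size=(n, 3))
        if rng.random() < 0.5:  # plant outliers beyond |z| = 2
            block[rng.integers(n)] += 10.0
        fast = np.asarray(dispersion(block))
        slow = np.asarray(dispersion_bruteforce(block))
        np.testing.assert_allclose(fast, slow, atol=1e-9)

    def test_single_valid_sample_is_zero_not_nan(self):
        # two wildly different samples on a third axis force outliers elsewhere
        block = np.array([[0.0, 0, 0], [0.0, 0, 0], [9.0, 0, 0]])
        out = dispersion(block)
        assert np.all(np.isfinite(out))


class TestRange:
    def test_constant_and_ramp(self):
        assert acceleration_range(const_block(1, 1, 1)) == (0.0, 0.0, 0.0)
        block = np.zeros((11, 3))
        block[:, 2] = np.linspace(0, 0.5, 11)
        assert acceleration_range(block) == pytest.approx((0.0, 0.0, 0.5))

    def test_matches_scan(self, rng):
        block = rng.normal(size=(40, 3))
        expected = tuple(block[:, i].max() - block[:, i].min() for i in range(3))
        assert acceleration_range(block) == pytest.approx(expected)


class TestInvariances:
    def test_time_reversal(self, rng):
        block = rng.normal(size=(60, 3))
        np.testing.assert_allclose(
            segment_descriptors(block), segment_descriptors(block[::-1]), atol=1e-12
        )

    def test_sign_flip_vm_rmsr(self, rng):
        block = rng.normal(size=(60, 3))
        a = segment_descriptors(block)
        b = segment_descriptors(-block)
        np.testing.assert_allclose(a[:4], b[:4], atol=1e-12)  # vm + rmsr


class TestBatchPath:
    def test_session_descriptors_match_per_segment(self, rng):
        """The vectorized stack equals per-segment scalar computation."""
        samples = rng.normal(size=(160, 3)) * 0.3 + [0, 0, 1]
        spec = WindowSpec(2.0, 10.0)
        batch = session_descriptors(samples, spec)
        from wristbow.segmentation import segment_starts

        for i, s in enumerate(segment_starts(160, spec)):
            ref = segment_descriptors(samples[s : s + spec.length])
            np.testing.assert_allclose(batch[i], ref, atol=1e-9)


class TestSubjectFeatures:
    def test_single_segment_equals_descriptors(self, rng):
        from wristbow.synth import RecordingSession

        samples = (rng.normal(size=(20, 3)) * 0.2 + [0, 0, 1]).astype(np.float32)
        session = RecordingSession("A", "HE", 10.0, 2.0, samples, 0)
        feats = subject_statistical_features(session, [2.0])
        ref = segment_descriptors(samples.astype(np.float64))
        np.testing.assert_allclose(feats.to_numpy(), ref, atol=1e-6)
        assert list(feats.index) == [f"{d}_2s" for d in DESCRIPTOR_NAMES]

    def test_mean_over_identical_segments_idempotent(self, rng):
        """A hop-periodic signal makes every window identical, so the subject
        average equals any single window's descriptors."""
        from wristbow.synth import RecordingSession

        half = rng.normal(size=(5, 3)).astype(np.float32)
        samples = np.tile(half, (4, 1))  # every 10-sample window = [half, half]
        session = RecordingSession("A", "HE", 10.0, 2.0, samples, 0)
        multi = subject_statistical_features(session, [1.0])
        window = np.tile(half, (2, 1)).astype(np.float64)
        np.testing.assert_allclose(
            multi.to_numpy(), segment_descriptors(window), atol=1e-6
        )

    def test_too_short_raises(self):
        from wristbow.segmentation import SegmentationError
        from wristbow.synth import RecordingSession

        session = RecordingSession(
            "A", "HE", 10.0, 1.0, np.zeros((10, 3), np.float32), 0
        )
        with pytest.raises(SegmentationError):
            subject_statistical_features(session, [5.0])
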