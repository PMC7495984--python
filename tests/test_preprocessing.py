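"""Preprocessing: neighbor geometry, referencing, decimation, Hjorth filter,
segmentation and artifact rejection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eeggc import (EventTimeline, Montage, Recording, average_rereference,
                   build_neighbor_map, downsample, hjorth_filter,
                   segment_and_reject, standard_montage_31)


class TestNeighborMap:
    def test_square_corners(self, square_montage):
        nm = square_montage.neighbor_map
        assert set(nm["A"]) == {"B", "C", "D"}

    def test_collinear_points(self):
        names = ["a", "b", "c", "d", "e"]
        coords = np.array([[0.0, 0], [1, 0], [2, 0], [3, 0], [10, 0]])
        nm = build_neighbor_map(names, coords)
        assert nm["a"] == ["b", "c", "d"]
        assert nm["e"] == ["d", "c", "b"]

    def test_random_montage_matches_brute_force(self):
        rng = np.random.default_rng(5)
        names = [f"ch{i}" for i in range(31)]
        coords = rng.uniform(-1, 1, (31, 2))
        nm = build_neighbor_map(names, coords)
        for i, name in enumerate(names):
            dists = sorted(
                (np.hypot(*(coords[j] - coords[i])), names[j])
                for j in range(31) if j != i
            )
            assert nm[name] == [n for _, n in dists[:3]]

    def test_duplicate_coordinates_warn(self):
        coords = np.array([[0.0, 0], [0, 0], [1, 0], [2, 0], [3, 0]])
        with pytest.warns(UserWarning, match="duplicate"):
            build_neighbor_map(list("abcde"), coords)

    def test_too_few_channels(self):
        with pytest.raises(ValueError):
            build_neighbor_map(["a", "b"], np.zeros((2, 2)))


class TestAverageRereference:
    def test_identical_channels_zeroed(self):
        x = np.tile(np.sin(np.linspace(0, 10, 100)), (5, 1))
        assert np.allclose(average_rereference(x), 0.0)

    def test_two_channel_closed_form(self):
        a, b = np.arange(10.0), np.ones(10)
        out = average_rereference(np.stack([a, b]))
        assert np.allclose(out[0], (a - b) / 2)
        assert np.allclose(out[1], (b - a) / 2)

    def test_idempotent_and_zero_sum(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((6, 200))
        once = average_rereference(x)
        assert np.allclose(once.sum(axis=0), 0.0, atol=1e-12)
        assert np.allclose(average_rereference(once), once)


class TestDownsample:
    def test_decimation_indices(self):
        x = np.arange(1000.0)[None]
        y = downsample(x, 250.0, 125.0)
        assert y.shape[1] == 500
        assert np.array_equal(y[0], x[0, ::2])

    def test_identity_factor(self):
        x = np.random.default_rng(1).standard_normal((2, 100))
        assert np.array_equal(downsample(x, 125.0, 125.0), x)

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ValueError, match="integer multiple"):
            downsample(np.zeros((1, 100)), 200.0, 125.0)

    def test_tone_survives_decimation(self):
        """A 5-Hz tone sampled at 250 Hz keeps its spectral peak at 5 Hz
        after plain decimation to 125 Hz (periodogram oracle)."""
        from scipy.signal import periodogram

        t = np.arange(0, 8, 1 / 250)
        x = np.sin(2 * np.pi * 5 * t)[None]
        y = downsample(x, 250.0, 125.0)
        f, p = periodogram(y[0], fs=125.0)
        assert abs(f[np.argmax(p)] - 5.0) < 0.2


class TestHjorthFilter:
    def test_identical_channels_cancel(self, montage31):
        x = np.tile(np.sin(np.linspace(0, 20, 500)), (31, 1))
        assert np.allclose(hjorth_filter(x, montage31), 0.0)

    def test_single_active_channel(self, montage31):
        """Channel c keeps its own signal; channels having c as a neighbor
        output -x/3."""
        x = np.zeros((31, 50))
        ci = montage31.index("Cz")
        x[ci] = 1.0
        out = hjorth_filter(x, montage31)
        assert np.allclose(out[ci], 1.0)
        for ch, nbs in montage31.neighbor_map.items():
            expected = -1.0 / 3 if "Cz" in nbs else 0.0
            if ch != "Cz":
                assert np.allclose(out[montage31.index(ch)], expected)

    def test_gradient_field_cancels_at_symmetric_channels(self):
        """A linear potential gradient vanishes wherever the three neighbors
        average to the channel's own position (constructed montage)."""
        names = ("L", "R", "U", "D", "C")
        coords = np.array([[-1, 0], [1, 0], [0, 1], [0, -1], [0, 0.0]])
        nm = {"C": ["L", "R", "U"], "L": ["C", "U", "D"], "R": ["C", "U", "D"],
              "U": ["L", "R", "C"], "D": ["L", "R", "C"]}
        montage = Montage(names, coords, nm)
        x = coords[:, [0]] * np.ones((1, 20))  # potential = x coordinate
        out = hjorth_filter(x, montage)
        assert np.allclose(out[4], 0.0)  # C: mean(L, R, U) x-coord = 0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_common_mode_rejection(self, seed):
        """Adding any constant-across-channels signal leaves the output
        unchanged, exactly."""
        montage = standard_montage_31()
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((31, 64))
        common = rng.standard_normal(64)
        assert np.allclose(hjorth_filter(x + common, montage),
                           hjorth_filter(x, montage), atol=1e-12)


def _recording(signal, fs=125.0, montage=None):
    montage = montage or standard_montage_31()
    return Recording(signal=signal, sample_rate=fs, montage=montage,
                     events=EventTimeline())


class TestSegmentAndReject:
    def test_trailing_partial_segment_dropped(self, montage31):
        rec = _recording(np.random.default_rng(0).standard_normal((31, 1250)))
        grid = segment_and_reject(rec)
        assert grid.n_segments == 2
        assert grid.blocks.shape == (2, 31, 500)

    def test_amplitude_threshold_is_strict(self, montage31):
        x = np.random.default_rng(1).standard_normal((31, 500))
        x[3, 100] = 201.0
        x[5, 200] = 200.0
        grid = segment_and_reject(_recording(x), z_normalize=False)
        assert not grid.valid[0, 3]   # above 200 µV -> invalid
        assert grid.valid[0, 5]       # exactly 200 µV -> still valid

    def test_whole_segment_rejection_scope(self, montage31):
        x = np.random.default_rng(1).standard_normal((31, 1000))
        x[3, 100] = 300.0
        grid = segment_and_reject(_recording(x), reject_whole_segment=True)
        assert not grid.valid[0].any()
        assert grid.valid[1].all()

    def test_z_normalization_stats(self, montage31):
        rec = _recording(np.random.default_rng(2).standard_normal((31, 2000)) * 30)
        grid = segment_and_reject(rec)
        mu = grid.blocks.mean(axis=2)
        sd = grid.blocks.std(axis=2)
        assert np.abs(mu[grid.valid]).max() < 1e-9
        assert np.abs(sd[grid.valid] - 1).max() < 1e-9

    def test_zero_variance_block_invalid(self, montage31):
        x = np.random.default_rng(3).standard_normal((31, 500))
        x[7] = 5.0  # flat channel
        grid = segment_and_reject(_recording(x))
        assert not grid.valid[0, 7]

    def test_default_synthetic_session_artifact_accounting(self, short_session):
        """On the synthetic session, exactly the artifact-bearing channel
        blocks (plus any flat blocks, of which there are none) are rejected
        post-filtering."""
        from eeggc import preprocess

        rec, truth = short_session
        _, grid = preprocess(rec)
        seg_len = 4.0
        idx = {c: i for i, c in enumerate(rec.montage.names)}
        expected = set()
        spread = set()  # Hjorth can push an artifact's neighbors past 200 µV
        for t0, ch in truth["artifacts"]:
            for t in (t0, t0 + 0.3):
                s = int(t // seg_len)
                if s < grid.n_segments:
                    expected.add((s, idx[ch]))
                    for nb in rec.montage.neighbor_map[ch]:
                        spread.add((s, idx[nb]))
        flagged = {tuple(x) for x in np.argwhere(~grid.valid)}
        assert flagged <= expected | spread
        # every injected artifact is caught in at least one of its segments
        caught = {(s, c) for s, c in expected if (s, c) in flagged}
        assert {c for _, c in caught} == {idx[ch] for _, ch in truth["artifacts"]}
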