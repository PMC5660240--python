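"""Eye-gaze ISC: fixation detection, drift correction, heatmaps, group test."""

import numpy as np
import pytest

from natisc.eyeisc import (FixationSet, detect_fixations, drift_correct,
                           eisc_group_test, eisc_pairwise, pair_mean_eisc,
                           qc_gaze, window_heatmaps)
from natisc.synthetic import (GazeSpec, displaced_sequence,
                              make_attractor_sequence, simulate_gaze)


def _stream(duration=10.0, fs=250.0, x=12.0, y=9.0):
    n = int(duration * fs)
    t = np.arange(n) / fs
    return t, np.full(n, x), np.full(n, y)


class TestFixationDetection:
    def test_constant_gaze_is_one_long_fixation(self):
        t, x, y = _stream(duration=10.0)
        fs = detect_fixations(t, x, y)
        assert len(fs) == 1
        assert fs.durations[0] == pytest.approx(10.0, abs=0.02)
        assert fs.x[0] == pytest.approx(12.0)

    def test_instantaneous_jump_splits_into_two_fixations(self):
        t, x, y = _stream(duration=4.0)
        x = x.copy()
        x[len(x) // 2:] += 10.0  # 10 deg in one sample >> 30 deg/s
        fs = detect_fixations(t, x, y)
        assert len(fs) == 2
        assert fs.x[0] == pytest.approx(12.0, abs=0.01)
        assert fs.x[1] == pytest.approx(22.0, abs=0.01)

    def test_subthreshold_smooth_jitter_keeps_single_fixation(self):
        # 0.1 deg sinusoidal jitter at 10 Hz: peak velocity ~6 deg/s,
        # peak acceleration ~400 deg/s^2, both below threshold
        t = np.arange(0, 4.0, 1 / 250)
        x = 12.0 + 0.1 * np.sin(2 * np.pi * 10 * t)
        y = np.full_like(t, 9.0)
        fs = detect_fixations(t, x, y)
        assert len(fs) == 1

    def test_blink_gap_splits_fixation(self):
        t, x, y = _stream(duration=4.0)
        valid = np.ones_like(t, dtype=bool)
        valid[400:600] = False
        fs = detect_fixations(t, x, y, valid=valid)
        assert len(fs) == 2

    def test_empty_stream_gives_empty_set(self):
        fs = detect_fixations(np.empty(0), np.empty(0), np.empty(0))
        assert len(fs) == 0


class TestDriftCorrect:
    def _fixset(self, rid, xs, ys):
        n = len(xs)
        return FixationSet(rid, "g", np.arange(n, dtype=float),
                           np.full(n, 0.3), np.asarray(xs, float),
                           np.asarray(ys, float))

    def test_single_recording_unchanged(self):
        fs = self._fixset(0, [1.0, 2.0], [3.0, 4.0])
        out = drift_correct([fs])[0]
        np.testing.assert_allclose(out.x, fs.x)

    def test_offset_recordings_coincide_after_correction(self):
        a = self._fixset(0, [10.0, 12.0], [8.0, 10.0])
        b = self._fixset(1, [12.0, 14.0], [8.0, 10.0])  # +2 deg in x
        out = drift_correct([a, b])
        np.testing.assert_allclose(out[0].mean_location, out[1].mean_location,
                                   atol=1e-12)

    def test_planted_drift_recovered_exactly(self):
        seq = make_attractor_sequence(12.0, seed=3)
        base_spec = GazeSpec(duration_s=12.0, attractors={"g": seq, "n": seq},
                             seed=9)
        drift_spec = GazeSpec(duration_s=12.0, attractors={"g": seq, "n": seq},
                              seed=9, drift_deg={0: (2.0, 1.0)})
        base = simulate_gaze(base_spec, {"g": 2, "n": 0})
        drifted = simulate_gaze(drift_spec, {"g": 2, "n": 0})
        fs_base = [detect_fixations(r.t, r.x, r.y, recording_id=r.recording_id)
                   for r in base]
        fs_drift = [detect_fixations(r.t, r.x, r.y, recording_id=r.recording_id)
                    for r in drifted]
        shift = fs_drift[0].mean_location - fs_base[0].mean_location
        np.testing.assert_allclose(shift, [2.0, 1.0], atol=1e-9)
        corr = drift_correct(fs_drift)
        grand = np.mean([fs.mean_location for fs in fs_drift], axis=0)
        for fs in corr:
            np.testing.assert_allclose(fs.mean_location, grand, atol=1e-12)


def _one_fixation_set(x, y, onset=0.0, dur=2.0, rid=0, group="g"):
    return FixationSet(rid, group, np.array([onset]), np.array([dur]),
                       np.array([x]), np.array([y]))


class TestHeatmaps:
    def test_movie_length_gives_712_windows(self):
        duration = 23 * 60 + 44.0
        fs = _one_fixation_set(12.0, 9.0)
        stack = window_heatmaps(fs, duration_s=duration)
        assert stack.maps.shape[0] == 712

    def test_single_fixation_has_unit_mass(self):
        stack = window_heatmaps(_one_fixation_set(12.0, 9.0), duration_s=2.0)
        assert stack.maps[0].sum() == pytest.approx(1.0, abs=1e-9)

    def test_coincident_fixations_double_the_peak(self):
        fs1 = _one_fixation_set(12.0, 9.0)
        fs2 = FixationSet(0, "g", np.array([0.0, 0.5]), np.array([0.4, 0.4]),
                          np.array([12.0, 12.0]), np.array([9.0, 9.0]))
        one = window_heatmaps(fs1, duration_s=2.0).maps[0]
        two = window_heatmaps(fs2, duration_s=2.0).maps[0]
        assert two.max() == pytest.approx(2 * one.max(), rel=1e-9)

    def test_fixation_contributes_to_every_overlapped_window(self):
        fs = _one_fixation_set(12.0, 9.0, onset=1.0, dur=4.0)
        stack = window_heatmaps(fs, duration_s=8.0)
        assert (~stack.missing).tolist() == [True, True, True, False]

    def test_windows_without_fixations_flagged_missing(self):
        fs = _one_fixation_set(12.0, 9.0, onset=0.0, dur=1.0)
        stack = window_heatmaps(fs, duration_s=6.0)
        assert stack.missing.tolist() == [False, True, True]

    def test_coarse_grid_rejected(self):
        with pytest.raises(ValueError, match="resolution"):
            window_heatmaps(_one_fixation_set(12.0, 9.0), duration_s=2.0,
                            grid_res_deg=0.6)


class TestEiscPairwise:
    def test_identical_recordings_hit_the_clamp(self):
        fs = _one_fixation_set(10.0, 9.0, dur=4.0)
        stacks = [window_heatmaps(fs, duration_s=4.0) for _ in range(2)]
        m = eisc_pairwise(stacks)
        np.testing.assert_allclose(np.tanh(m.z), 1.0, atol=1e-6)

    def test_distant_fixations_anticorrelate(self):
        a = window_heatmaps(_one_fixation_set(6.0, 9.0), duration_s=2.0)
        b = window_heatmaps(_one_fixation_set(16.0, 9.0), duration_s=2.0)
        m = eisc_pairwise([a, b])
        assert m.z[0, 0] < 0

    def test_mean_eisc_matches_direct_recomputation(self):
        rng = np.random.default_rng(4)
        seq = make_attractor_sequence(12.0, seed=5)
        spec = GazeSpec(duration_s=12.0, attractors={"g": seq, "n": seq},
                        seed=6)
        recs = simulate_gaze(spec, {"g": 2, "n": 1})
        stacks = []
        for r in recs:
            fs = detect_fixations(r.t, r.x, r.y, recording_id=r.recording_id,
                                  group=r.group)
            stacks.append(window_heatmaps(fs, duration_s=12.0))
        m = eisc_pairwise(stacks)
        means = pair_mean_eisc(m)
        for col in range(m.z.shape[1]):
            zcol = m.z[:, col]
            brute = np.tanh(np.mean(zcol[~np.isnan(zcol)]))
            assert means[col] == pytest.approx(brute, abs=1e-12)

    def test_pair_classes_label_same_group_pairs(self):
        fs = _one_fixation_set(10.0, 9.0)
        stacks = [window_heatmaps(
            FixationSet(i, g, fs.onsets, fs.durations, fs.x, fs.y),
            duration_s=2.0) for i, g in enumerate(["a", "a", "b"])]
        m = eisc_pairwise(stacks)
        assert m.pair_classes == ["both-a", "mixed", "mixed"]


def _gaze_matrix(displacement, n_per_group=6, duration=16.0, seed=0):
    # a planted effect must be stochastic per recording: members of the
    # displaced group independently follow the displaced attractor half the
    # time, which degrades their within-group gaze agreement
    seq = make_attractor_sequence(duration, seed=seed + 100)
    spec = GazeSpec(duration_s=duration,
                    attractors={"genetic": seq, "nongenetic": seq},
                    seed=seed)
    if displacement:
        spec.mixture = {"nongenetic": (
            displaced_sequence(seq, displacement, fraction=1.0,
                               seed=seed + 200), 0.5)}
    recs = simulate_gaze(spec, {"genetic": n_per_group,
                                "nongenetic": n_per_group})
    fixsets = [detect_fixations(r.t, r.x, r.y, recording_id=r.recording_id,
                                group=r.group) for r in recs]
    fixsets = drift_correct(fixsets)
    stacks = [window_heatmaps(fs, duration_s=duration) for fs in fixsets]
    return eisc_pairwise(stacks)


class TestGroupTest:
    def test_zero_observed_difference_gives_p_one(self):
        fs = _one_fixation_set(10.0, 9.0, dur=4.0)
        stacks = []
        for i, g in enumerate(["a", "a", "b", "b"]):
            stacks.append(window_heatmaps(
                FixationSet(i, g, fs.onsets, fs.durations, fs.x, fs.y),
                duration_s=4.0))
        res = eisc_group_test(eisc_pairwise(stacks), n_permutations=500, seed=0)
        assert res.observed_difference == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_label_swap_symmetry(self):
        m = _gaze_matrix(0.0, seed=1)
        res = eisc_group_test(m, n_permutations=2000, seed=3)
        m_swapped = _gaze_matrix(0.0, seed=1)
        m_swapped.groups = ["nongenetic" if g == "genetic" else "genetic"
                            for g in m_swapped.groups]
        res_swapped = eisc_group_test(m_swapped, n_permutations=2000, seed=3)
        assert res.p_value == pytest.approx(res_swapped.p_value, abs=0.03)
        assert res.observed_difference == pytest.approx(
            -res_swapped.observed_difference, abs=1e-12)

    def test_planted_displacement_detected(self):
        m = _gaze_matrix(5.0, n_per_group=8, seed=2)
        res = eisc_group_test(m, n_permutations=2000, seed=4)
        assert res.p_value < 0.01

    def test_null_not_rejected(self):
        m = _gaze_matrix(0.0, seed=5)
        res = eisc_group_test(m, n_permutations=2000, seed=6)
        assert res.p_value > 0.05

    def test_tiny_group_rejected(self):
        m = _gaze_matrix(0.0, n_per_group=6, seed=7)
        m.groups = ["genetic"] * 11 + ["nongenetic"]
        with pytest.raises(ValueError):
            eisc_group_test(m, n_permutations=200, seed=0)


class TestQc:
    def test_heavy_blinking_fails(self):
        t = np.arange(0, 10, 1 / 250)
        valid = np.ones_like(t, dtype=bool)
        valid[:len(t) // 5] = False  # 20% blink
        res = qc_gaze(t, valid)
        assert not res.passed
        assert res.blink_fraction == pytest.approx(0.2, abs=0.01)

    def test_clean_recording_passes(self):
        t, x, y = _stream(duration=10.0)
        fs = detect_fixations(t, x, y)
        res = qc_gaze(t, np.ones_like(t, dtype=bool), fs)
        assert res.passed
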