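import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ecogvad.datatypes import FrameDataset
from ecogvad.labeling import (
    LabelingError,
    SpeechWindow,
    apply_passive_exclusion,
    balance_dataset,
    balance_trial,
    frames_to_labels,
    label_imagined_frames,
    passive_dataset,
    performed_label_matrix,
    surrogate_imagined_timing,
    windows_from_trials,
)


def _frames(times, trial_ids, labels=None, n_features=2):
    times = np.asarray(times, dtype=float)
    return FrameDataset(
        X=np.zeros((len(times), n_features)),
        times=times,
        trial_ids=np.asarray(trial_ids),
        labels=np.zeros(len(times), dtype=int) if labels is None else np.asarray(labels),
    )


class TestFramesToLabels:
    def test_boundaries_inclusive(self):
        frames = _frames([0.9, 1.0, 2.0, 2.5, 2.6], [0] * 5)
        out = frames_to_labels(frames, [SpeechWindow(0, 1.0, 2.5)])
        np.testing.assert_array_equal(out.labels, [-1, 1, 1, 1, -1])

    def test_missing_window_errors_towards_surrogate(self):
        frames = _frames([0.5], [3])
        with pytest.raises(LabelingError, match="surrogate"):
            frames_to_labels(frames, [])

    def test_window_validation(self):
        with pytest.raises(ValueError, match="onset"):
            SpeechWindow(0, 2.0, 1.0)

    def test_windows_from_trials_skips_imagined(self):
        trials = pd.DataFrame(
            dict(trial=[0, 1], mode=["performed", "imagined"],
                 speech_onset=[1.0, np.nan], speech_offset=[2.0, np.nan])
        )
        assert [w.trial for w in windows_from_trials(trials)] == [0]


class TestBalanceTrial:
    def _trial(self, n_speech, n_before, n_after):
        labels = [-1] * n_before + [1] * n_speech + [-1] * n_after
        return _frames(np.arange(len(labels), dtype=float), [0] * len(labels), labels)

    def test_symmetric_split(self):
        frames = self._trial(8, 20, 20)
        idx = balance_trial(frames, 0)
        sel = frames.labels[idx]
        assert (sel == 1).sum() == 8 and (sel == -1).sum() == 8
        before = (frames.times[idx][sel == -1] < 20).sum()
        assert before == 4  # 4 before + 4 after

    def test_short_after_takes_more_before(self):
        frames = self._trial(8, 20, 2)
        idx = balance_trial(frames, 0)
        sel = frames.labels[idx]
        assert (sel == -1).sum() == 8
        after = (frames.times[idx][sel == -1] > 27).sum()
        assert after == 2  # all 2 available after, 6 before

    def test_silence_adjacent_to_window(self):
        frames = self._trial(4, 10, 10)
        idx = balance_trial(frames, 0)
        silence_times = frames.times[idx][frames.labels[idx] == -1]
        np.testing.assert_array_equal(np.sort(silence_times), [8, 9, 14, 15])

    def test_no_speech_skipped_with_warning(self, caplog):
        frames = _frames([0.0, 1.0], [0, 0], [-1, -1])
        idx = balance_trial(frames, 0)
        assert len(idx) == 0

    def test_insufficient_silence_errors_with_counts(self):
        frames = self._trial(8, 2, 1)
        with pytest.raises(LabelingError, match="2 before \\+ 1 after"):
            balance_trial(frames, 0)

    def test_unlabeled_frames_never_selected(self):
        labels = [0, -1, 1, 1, -1, 0]
        frames = _frames(np.arange(6.0), [0] * 6, labels)
        idx = balance_trial(frames, 0)
        assert np.all(frames.labels[idx] != 0)

    @given(
        n_speech=st.integers(1, 12),
        n_before=st.integers(0, 15),
        n_after=st.integers(0, 15),
    )
    @settings(max_examples=60, deadline=None)
    def test_exact_balance_property(self, n_speech, n_before, n_after):
        frames = self._trial(n_speech, n_before, n_after)
        if n_before + n_after < n_speech:
            with pytest.raises(LabelingError):
                balance_trial(frames, 0)
            return
        idx = balance_trial(frames, 0)
        sel = frames.labels[idx]
        assert (sel == 1).sum() == (sel == -1).sum() == n_speech

    def test_balance_dataset_global_and_per_trial(self, rng):
        times, ids, labels = [], [], []
        for t in range(5):
            n_speech = int(rng.integers(2, 8))
            lab = [-1] * 10 + [1] * n_speech + [-1] * 10
            times.extend(np.arange(len(lab)) + t * 100.0)
            ids.extend([t] * len(lab))
            labels.extend(lab)
        balanced = balance_dataset(_frames(times, ids, labels))
        for t in range(5):
            sel = balanced.labels[balanced.trial_ids == t]
            assert (sel == 1).sum() == (sel == -1).sum() > 0


def surrogate_oracle(m, go_index, frame_rate):
    """Brute-force frame-by-frame evaluation of the 0.9/0.1/500 ms rules."""
    avg = np.asarray(m, dtype=float).mean(axis=0)
    n = len(avg)
    # longest contiguous run of avg > 0.9 (first on ties)
    best = (0, 0)
    for i in range(n):
        if avg[i] <= 0.9:
            continue
        j = i
        while j < n and avg[j] > 0.9:
            j += 1
        if j - i > best[1] - best[0]:
            best = (i, j)
    speech = np.zeros(n, bool)
    speech[best[0]: best[1]] = True
    if not speech.any():
        return None
    n_end = int(round(0.5 * frame_rate))
    silence = np.zeros(n, bool)
    for i in range(n):
        if i < go_index and avg[i] < 0.1:
            silence[i] = True
        elif i >= max(n - n_end, go_index) and avg[i] < 0.1 and not speech[i]:
            silence[i] = True
    discarded = ~(speech | silence)
    return speech, silence, discarded


class TestSurrogateTiming:
    def test_spec_example(self):
        # counts over 10 trials per frame; go cue before frame 2; 500 ms = 1 frame
        counts = np.array([0, 0, 2, 9, 10, 10, 9, 1, 0])
        m = np.array([(np.arange(10) < c).astype(float) for c in counts]).T
        timing = surrogate_imagined_timing(m, go_index=2, frame_rate=2.0)
        np.testing.assert_array_equal(np.flatnonzero(timing.speech_mask), [4, 5])
        np.testing.assert_array_equal(np.flatnonzero(timing.silence_mask), [0, 1, 8])
        np.testing.assert_array_equal(np.flatnonzero(timing.discarded_mask), [2, 3, 6, 7])

    def test_all_trials_identical_recovers_common_window(self):
        m = np.zeros((5, 20))
        m[:, 6:15] = 1.0
        timing = surrogate_imagined_timing(m, go_index=4, frame_rate=4.0)
        np.testing.assert_array_equal(np.flatnonzero(timing.speech_mask), np.arange(6, 15))

    def test_exactly_point_nine_is_not_speech(self):
        m = np.zeros((10, 5))
        m[:9, 2] = 1.0  # avg exactly 0.9
        m[:, 3] = 1.0
        timing = surrogate_imagined_timing(m, go_index=1, frame_rate=4.0)
        assert not timing.speech_mask[2]
        assert timing.speech_mask[3]

    def test_no_consensus_errors(self):
        m = np.zeros((4, 6))
        m[:2, 3] = 1.0
        with pytest.raises(LabelingError, match="no consensus"):
            surrogate_imagined_timing(m, go_index=1, frame_rate=4.0)

    def test_masks_disjoint_and_t_on_positive(self, rng):
        for _ in range(20):
            m, go = _random_label_matrix(rng)
            try:
                timing = surrogate_imagined_timing(m, go, frame_rate=8.0)
            except LabelingError:
                continue
            total = timing.speech_mask.astype(int) + timing.silence_mask + timing.discarded_mask
            assert np.all(total == 1)
            assert timing.t_on > 0

    def test_oracle_equivalence_random(self, rng):
        checked = 0
        for _ in range(200):
            m, go = _random_label_matrix(rng)
            oracle = surrogate_oracle(m, go, 8.0)
            if oracle is None:
                with pytest.raises(LabelingError):
                    surrogate_imagined_timing(m, go, 8.0)
                continue
            timing = surrogate_imagined_timing(m, go, 8.0)
            np.testing.assert_array_equal(timing.speech_mask, oracle[0])
            np.testing.assert_array_equal(timing.silence_mask, oracle[1])
            np.testing.assert_array_equal(timing.discarded_mask, oracle[2])
            checked += 1
        assert checked > 50

    def test_conservatism(self, rng):
        # surrogate onset >= earliest trial onset; offset <= latest offset
        for _ in range(30):
            m, go = _random_label_matrix(rng, contiguous=True)
            try:
                timing = surrogate_imagined_timing(m, go, 8.0)
            except LabelingError:
                continue
            onsets = [np.flatnonzero(row)[0] for row in m if row.any()]
            offsets = [np.flatnonzero(row)[-1] for row in m if row.any()]
            s = np.flatnonzero(timing.speech_mask)
            assert s[0] >= min(onsets)
            assert s[-1] <= max(offsets)


def _random_label_matrix(rng, n_trials=None, n_frames=None, contiguous=True):
    """Jittered-consensus speech labels resembling go-cue-aligned trials."""
    n_trials = n_trials or int(rng.integers(2, 12))
    n_frames = n_frames or int(rng.integers(16, 40))
    go = int(rng.integers(1, max(2, n_frames // 4)))
    base_on = int(rng.integers(go + 1, go + max(2, (n_frames - go) // 3)))
    base_off = int(rng.integers(base_on + 1, n_frames))
    m = np.zeros((n_trials, n_frames))
    for i in range(n_trials):
        if rng.random() < 0.05:
            continue  # silent trial
        on = int(np.clip(base_on + rng.integers(-2, 3), go, n_frames - 1))
        off = int(np.clip(base_off + rng.integers(-2, 3), on, n_frames - 1))
        m[i, on: off + 1] = 1.0
    if not contiguous:
        m = (rng.random(m.shape) < m * 0.95 + 0.02).astype(float)
    return m, go


class TestPerformedLabelMatrix:
    def test_alignment_and_window(self):
        trials = pd.DataFrame(
            dict(
                trial=[0, 1], mode=["performed"] * 2,
                trial_start=[0.0, 20.0], cue_onset=[2.0, 22.0],
                go_onset=[5.0, 25.5], speech_onset=[6.0, 26.5],
                speech_offset=[9.0, 29.5], trial_end=[12.0, 32.0],
            )
        )
        m, go_index = performed_label_matrix(trials, frame_rate=4.0)
        assert m.shape[0] == 2
        # both trials speak exactly 1.0 s after their own go cue
        post_go = m[:, go_index:]
        np.testing.assert_array_equal(post_go[0], post_go[1])
        assert post_go[0][int(4 * 1.0)] == 1.0

    def test_requires_two_observable_trials(self):
        trials = pd.DataFrame(
            dict(trial=[0], mode=["performed"], trial_start=[0.0], cue_onset=[1.0],
                 go_onset=[2.0], speech_onset=[3.0], speech_offset=[4.0], trial_end=[6.0])
        )
        with pytest.raises(LabelingError):
            performed_label_matrix(trials, 4.0)


class TestLabelImagined:
    def test_pre_go_silence_window_speech_tail_silence(self):
        trials = pd.DataFrame(
            dict(trial=[7], mode=["imagined"], trial_start=[0.0], cue_onset=[2.0],
                 go_onset=[5.0], speech_onset=[np.nan], speech_offset=[np.nan], trial_end=[12.0])
        )
        m = np.zeros((4, 48))  # 4 performed trials, 12 s at 4 Hz, go at frame 20
        m[:, 24:36] = 1.0      # speech 1.0 - 4.0 s post-go
        timing = surrogate_imagined_timing(m, go_index=20, frame_rate=4.0)
        frames = _frames(np.arange(0, 12, 0.25), [7] * 48)
        out = label_imagined_frames(frames, trials, timing)
        t = frames.times
        assert np.all(out.labels[t < 5.0] == -1)
        assert np.all(out.labels[(t >= 6.0) & (t <= 8.75)] == 1)
        assert np.all(out.labels[(t > 9.0) & (t < 11.5)] == 0)
        assert np.all(out.labels[t >= 11.5] == -1)


class TestPassiveDataset:
    def _frames_one_trial(self):
        fs = 256.0
        times = np.arange(0, 12 * 256) / fs
        return _frames(times, [0] * len(times))

    def test_4s_window_has_1024_frames(self):
        frames = self._frames_one_trial()
        out = passive_dataset(frames, {0: 6.0}, width=4.0)
        assert out.n_frames == 1024

    def test_zero_width_empty(self):
        out = passive_dataset(self._frames_one_trial(), {0: 6.0}, width=0.0)
        assert out.n_frames == 0

    def test_all_labels_minus_one(self):
        out = passive_dataset(self._frames_one_trial(), {0: 6.0}, width=4.0)
        assert np.all(out.labels == -1)


class TestPassiveExclusion:
    @pytest.mark.parametrize(
        "active,passive,expected",
        [
            (74.0, 45.0, (50.0, True)),
            (74.0, 50.0, (74.0, False)),
            (50.0, 90.0, (50.0, False)),
        ],
    )
    def test_rule(self, active, passive, expected):
        assert apply_passive_exclusion(active, passive) == expected

    def test_range_validation(self):
        with pytest.raises(ValueError):
            apply_passive_exclusion(120.0, 50.0)
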