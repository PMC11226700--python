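"""Frame labels: observed speech windows, class balancing, surrogate
timing for imagined trials, and the cue-centered passive dataset.

Performed and perceived trials have observable speech windows, so frames
get direct +1 (speech) / -1 (silence) labels.  Imagined trials have no
behavioral timing; their labels come from the consensus timing of the
performed trials (trial-averaged label > 0.9 for speech, < 0.1 for
silence, go-cue aligned), which deliberately overestimates the onset
delay and underestimates the offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import FrameDataset

logger = logging.getLogger(__name__)

SPEECH_THRESHOLD = 0.9     # strict >
SILENCE_THRESHOLD = 0.1    # strict <
TRIAL_END_SILENCE_MAX = 0.5  # seconds of end-of-trial silence usable


class LabelingError(ValueError):
    pass


@dataclass(frozen=True)
class SpeechWindow:
    trial: int
    onset: float
    offset: float

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValueError(f"trial {self.trial}: onset {self.onset} must precede offset {self.offset}")


def windows_from_trials(trials: pd.DataFrame) -> list[SpeechWindow]:
    """Observable speech windows for performed/perceived trials."""
    out = []
    for row in trials.itertuples():
        if np.isnan(row.speech_onset) or np.isnan(row.speech_offset):
            continue
        out.append(SpeechWindow(trial=row.trial, onset=row.speech_onset, offset=row.speech_offset))
    return out


def frames_to_labels(frames: FrameDataset, windows: list[SpeechWindow]) -> FrameDataset:
    """+1 inside the trial's [onset, offset] (inclusive), -1 elsewhere."""
    by_trial = {w.trial: w for w in windows}
    labels = np.full(frames.n_frames, -1, dtype=int)
    for trial in frames.trials:
        w = by_trial.get(trial)
        if w is None:
            raise LabelingError(
                f"trial {trial} has no speech window; for imagined trials use the "
                "surrogate-timing path (surrogate_imagined_timing)"
            )
        sel = frames.trial_ids == trial
        t = frames.times[sel]
        labels[np.flatnonzero(sel)[(t >= w.onset) & (t <= w.offset)]] = 1
    return frames.with_labels(labels)


def balance_trial(frames: FrameDataset, trial) -> np.ndarray:
    """Indices (into ``frames``) of a class-balanced selection for one trial.

    All speech frames are kept.  Silence is drawn contiguously adjacent to
    the speech window, split equally before and after; when one side runs
    short by k frames, the other side contributes k extra.  Unlabeled
    frames (label 0) are never selected.
    """
    sel = np.flatnonzero(frames.trial_ids == trial)
    sel = sel[np.argsort(frames.times[sel], kind="stable")]
    labels = frames.labels[sel]
    speech = sel[labels == 1]
    if len(speech) == 0:
        logger.warning("balance_trial: trial %r has no speech frames; skipped", trial)
        return np.array([], dtype=int)
    t_first = frames.times[speech].min()
    t_last = frames.times[speech].max()
    silence = sel[labels == -1]
    before = silence[frames.times[silence] < t_first]
    after = silence[frames.times[silence] > t_last]

    n = len(speech)
    n_after = n // 2
    n_before = n - n_after
    if len(after) < n_after:          # short after the window -> take more before
        n_before += n_after - len(after)
        n_after = len(after)
    if len(before) < n_before:        # and symmetrically
        n_after = min(len(after), n_after + (n_before - len(before)))
        n_before = len(before)
    if n_before + n_after < n:
        raise LabelingError(
            f"trial {trial}: need {n} silence frames, only "
            f"{len(before)} before + {len(after)} after available"
        )
    chosen_before = before[len(before) - n_before:]  # nearest to the window
    chosen_after = after[:n_after]
    return np.sort(np.concatenate([chosen_before, speech, chosen_after]))


def balance_dataset(frames: FrameDataset) -> FrameDataset:
    """Apply :func:`balance_trial` to every trial and concatenate."""
    idx = [balance_trial(frames, t) for t in frames.trials]
    idx = np.concatenate([i for i in idx if len(i)]) if any(len(i) for i in idx) else np.array([], dtype=int)
    return frames.subset(idx)


def performed_label_matrix(
    trials: pd.DataFrame, frame_rate: float
) -> tuple[np.ndarray, int]:
    """Go-cue-aligned 0/1 speech-label matrix for performed trials.

    The shared frame axis covers the span common to every trial,
    ``[max(trial_start - go), min(trial_end - go)]``.  Returns the matrix
    and the index of the go cue on that axis.
    """
    obs = trials.dropna(subset=["speech_onset", "speech_offset"])
    if len(obs) < 2:
        raise LabelingError("need >= 2 trials with observable speech windows")
    rel_start = (obs["trial_start"] - obs["go_onset"]).max()
    rel_end = (obs["trial_end"] - obs["go_onset"]).min()
    lo = int(np.ceil(rel_start * frame_rate))
    hi = int(np.floor(rel_end * frame_rate))
    t = np.arange(lo, hi + 1) / frame_rate
    go_index = -lo
    m = np.zeros((len(obs), len(t)))
    for i, row in enumerate(obs.itertuples()):
        on = row.speech_onset - row.go_onset
        off = row.speech_offset - row.go_onset
        m[i] = (t >= on) & (t <= off)
    return m, go_index


@dataclass
class SurrogateTiming:
    """Consensus go-cue-relative timing extracted from performed trials.

    Masks are defined on the go-cue-aligned frame axis of the label matrix
    the timing was derived from; ``t_on``/``t_off`` are seconds relative
    to the go cue.
    """

    speech_mask: np.ndarray
    silence_mask: np.ndarray
    discarded_mask: np.ndarray
    go_index: int
    frame_rate: float

    def __post_init__(self) -> None:
        if np.any(self.speech_mask & self.silence_mask) or np.any(
            self.speech_mask & self.discarded_mask
        ) or np.any(self.silence_mask & self.discarded_mask):
            raise ValueError("speech/silence/discarded masks must be disjoint")

    @property
    def t_on(self) -> float:
        return (int(np.flatnonzero(self.speech_mask)[0]) - self.go_index) / self.frame_rate

    @property
    def t_off(self) -> float:
        return (int(np.flatnonzero(self.speech_mask)[-1]) - self.go_index) / self.frame_rate


def surrogate_imagined_timing(
    performed_labels: np.ndarray, go_index: int, frame_rate: float
) -> SurrogateTiming:
    """Derive imagined-trial labels from go-cue-aligned performed labels.

    Parameters
    ----------
    performed_labels:
        ``(n_trials, n_frames)`` 0/1 matrix, trials aligned at the go cue.
    go_index:
        Frame index of the go cue on the shared axis.
    frame_rate:
        Frames per second of the label matrix.

    The speech window is the longest contiguous span whose trial-averaged
    label strictly exceeds 0.9.  Silence is taken before the go cue and in
    at most 500 ms at the trial end, where the average is strictly below
    0.1.  Everything else is discarded as ambiguous.
    """
    m = np.asarray(performed_labels, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise LabelingError("need a (n_trials >= 2, n_frames) performed-label matrix")
    n_frames = m.shape[1]
    avg = m.mean(axis=0)

    above = avg > SPEECH_THRESHOLD
    if not above.any():
        raise LabelingError("no consensus speech window: no frame has averaged label > 0.9")
    speech_mask = _longest_run(above)

    below = avg < SILENCE_THRESHOLD
    silence_mask = np.zeros(n_frames, dtype=bool)
    silence_mask[:go_index] = below[:go_index]
    n_end = int(round(TRIAL_END_SILENCE_MAX * frame_rate))
    if n_end > 0:
        tail = slice(max(n_frames - n_end, go_index), n_frames)
        silence_mask[tail] |= below[tail] & ~speech_mask[tail]

    discarded_mask = ~(speech_mask | silence_mask)
    return SurrogateTiming(
        speech_mask=speech_mask,
        silence_mask=silence_mask,
        discarded_mask=discarded_mask,
        go_index=go_index,
        frame_rate=frame_rate,
    )


def _longest_run(mask: np.ndarray) -> np.ndarray:
    """Boolean mask of the longest contiguous True run (first on ties)."""
    out = np.zeros(len(mask), dtype=bool)
    best_len, best_start = 0, 0
    i = 0
    while i < len(mask):
        if mask[i]:
            j = i
            while j < len(mask) and mask[j]:
                j += 1
            if j - i > best_len:
                best_len, best_start = j - i, i
            i = j
        else:
            i += 1
    out[best_start: best_start + best_len] = True
    return out


def label_imagined_frames(
    frames: FrameDataset, trials: pd.DataFrame, timing: SurrogateTiming
) -> FrameDataset:
    """Apply surrogate timing to the frames of imagined trials.

    Per trial: +1 inside ``[go + t_on, go + t_off]``; -1 before the go cue
    and in the last 500 ms of the trial; 0 (discarded) in between.
    """
    labels = np.zeros(frames.n_frames, dtype=int)
    rows = trials.set_index("trial")
    for trial in frames.trials:
        row = rows.loc[trial]
        sel = np.flatnonzero(frames.trial_ids == trial)
        t = frames.times[sel]
        go = float(row["go_onset"])
        end = float(row["trial_end"])
        lab = np.zeros(len(sel), dtype=int)
        lab[(t >= go + timing.t_on) & (t <= go + timing.t_off)] = 1
        lab[t < go] = -1
        in_tail = (t >= end - TRIAL_END_SILENCE_MAX) & (t > go + timing.t_off)
        lab[in_tail] = -1
        labels[sel] = lab
    return frames.with_labels(labels)


def passive_dataset(frames: FrameDataset, cue_times: dict, width: float = 4.0) -> FrameDataset:
    """Frames in a ``width``-second window centered on each trial's task
    cue, all labeled -1 (no intentional speech assumed there)."""
    keep = np.zeros(frames.n_frames, dtype=bool)
    for trial in frames.trials:
        cue = cue_times[trial]
        sel = frames.trial_ids == trial
        keep |= sel & (frames.times >= cue - width / 2) & (frames.times < cue + width / 2)
    out = frames.subset(keep)
    return out.with_labels(np.full(out.n_frames, -1, dtype=int))


def apply_passive_exclusion(active_acc: float, passive_acc: float) -> tuple[float, bool]:
    """Report 50% (flagged excluded) when the passive-window accuracy falls
    strictly below 50%; otherwise report the active accuracy."""
    for name, v in (("active_acc", active_acc), ("passive_acc", passive_acc)):
        if not 0 <= v <= 100:
            raise ValueError(f"{name} must be in [0, 100], got {v}")
    if passive_acc < 50.0:
        return 50.0, True
    return float(active_acc), False
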