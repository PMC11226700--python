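"""Core data containers shared across pipeline stages.

Conventions
-----------
* Time is expressed in seconds, 0-based from recording start.
* Signals are stored channels x samples in microvolts.
* Trial tables are :class:`pandas.DataFrame` objects with one row per trial
  and (at least) the columns ``trial``, ``mode``, ``trial_start``,
  ``cue_onset``, ``go_onset``, ``speech_onset``, ``speech_offset``,
  ``trial_end``.  Speech on/offsets are NaN when unobservable (imagined
  trials).
* Frame labels are +1 (speech), -1 (silence) or 0 (unlabeled).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .bands import LAG_OFFSETS, BandSet, DEFAULT_BANDS

SPEECH_MODES = ("performed", "perceived", "imagined")
REGIONS = ("motor", "temporal", "other")


@dataclass
class EcogRecording:
    """Multichannel ECoG signal plus channel metadata.

    Parameters
    ----------
    data:
        ``(n_channels, n_samples)`` float array, microvolts.
    sampling_rate:
        Samples per second.
    channels:
        Channel identifiers, one per row of ``data``.
    grids:
        Grid membership per channel (used for the per-grid common average
        reference).
    regions:
        Optional anatomical tag per channel (``motor``/``temporal``/``other``).
    """

    data: np.ndarray
    sampling_rate: float
    channels: list[str]
    grids: list[str]
    regions: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel list length does not match data rows")
        if len(self.grids) != self.data.shape[0]:
            raise ValueError("grid list length does not match data rows")
        if self.regions is not None and len(self.regions) != self.data.shape[0]:
            raise ValueError("region list length does not match data rows")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def channel_index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise KeyError(f"unknown channel {channel!r}") from None

    def select_channels(self, mask: np.ndarray) -> "EcogRecording":
        mask = np.asarray(mask, dtype=bool)
        return EcogRecording(
            data=self.data[mask],
            sampling_rate=self.sampling_rate,
            channels=[c for c, m in zip(self.channels, mask) if m],
            grids=[g for g, m in zip(self.grids, mask) if m],
            regions=None
            if self.regions is None
            else [r for r, m in zip(self.regions, mask) if m],
        )

    def copy(self) -> "EcogRecording":
        return replace(self, data=self.data.copy())


@dataclass
class EnvelopeTensor:
    """Smoothed Hilbert envelopes, ``(n_channels, n_bands, n_samples)``."""

    values: np.ndarray
    sampling_rate: float
    band_set: BandSet = field(default_factory=lambda: DEFAULT_BANDS)
    channels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be channels x bands x samples")
        if self.values.shape[1] != len(self.band_set):
            raise ValueError("band axis does not match band set")

    @property
    def n_samples(self) -> int:
        return self.values.shape[2]

    def channel_index(self, channel) -> int:
        if isinstance(channel, (int, np.integer)):
            return int(channel)
        if self.channels is None:
            raise KeyError("envelope tensor carries no channel names")
        return self.channels.index(channel)


def feature_names(band_set: BandSet, band_indices: Sequence[int]) -> list[str]:
    """Column names in the fixed band-major, lag-minor order."""
    names = []
    for b in band_indices:
        for lag in LAG_OFFSETS:
            names.append(f"{band_set[b].name}@{int(lag * 1000):+d}ms")
    return names


@dataclass
class FrameDataset:
    """Per-frame feature rows with trial bookkeeping and labels.

    ``X`` is ``(n_frames, n_features)`` where features are ordered
    band-major, lag-minor (delta@-125ms, delta@+0ms, delta@+125ms,
    theta@-125ms, ...).
    """

    X: np.ndarray
    times: np.ndarray
    trial_ids: np.ndarray
    labels: np.ndarray
    band_subset: str = "full"
    columns: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.trial_ids = np.asarray(self.trial_ids)
        self.labels = np.asarray(self.labels, dtype=int)
        n = len(self.X)
        if not (len(self.times) == len(self.trial_ids) == len(self.labels) == n):
            raise ValueError("frame arrays must share their first dimension")
        bad = set(np.unique(self.labels)) - {-1, 0, 1}
        if bad:
            raise ValueError(f"labels must be in {{-1, 0, +1}}, found {sorted(bad)}")

    @property
    def n_frames(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def trials(self) -> np.ndarray:
        """Unique trial ids in order of first appearance."""
        _, idx = np.unique(self.trial_ids, return_index=True)
        return self.trial_ids[np.sort(idx)]

    def subset(self, mask: np.ndarray) -> "FrameDataset":
        mask = np.asarray(mask)
        return FrameDataset(
            X=self.X[mask],
            times=self.times[mask],
            trial_ids=self.trial_ids[mask],
            labels=self.labels[mask],
            band_subset=self.band_subset,
            columns=self.columns,
        )

    def labeled(self) -> "FrameDataset":
        return self.subset(self.labels != 0)

    def for_trial(self, trial) -> "FrameDataset":
        return self.subset(self.trial_ids == trial)

    def with_labels(self, labels: np.ndarray) -> "FrameDataset":
        out = self.subset(np.ones(self.n_frames, dtype=bool))
        out.labels = np.asarray(labels, dtype=int)
        if len(out.labels) != out.n_frames:
            raise ValueError("label length mismatch")
        return out

    def to_frame(self) -> pd.DataFrame:
        cols = self.columns or [f"f{i}" for i in range(self.n_features)]
        df = pd.DataFrame(self.X, columns=cols)
        df.insert(0, "label", self.labels)
        df.insert(0, "time", self.times)
        df.insert(0, "trial", self.trial_ids)
        return df


@dataclass
class ZScoreStats:
    mean: np.ndarray
    std: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / np.where(self.std > 0, self.std, 1.0)


@dataclass
class DetectorModel:
    """Linear frame-wise detector: ``decision = sign(X @ weights + intercept)``.

    An output of exactly 0 is classified as speech (non-negative -> speech).
    """

    weights: np.ndarray
    intercept: float
    band_subset: str = "full"
    zstats: ZScoreStats | None = None
    activation_pattern: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()


@dataclass
class CVResult:
    """Leave-one-trial-out cross-validation summary for one detector."""

    trial_ids: np.ndarray
    trial_accuracies: np.ndarray  # percent, one per trial
    outputs: np.ndarray           # continuous output per frame (CV order)
    frame_labels: np.ndarray
    frame_trials: np.ndarray
    activation_pattern: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        """Unweighted mean of per-trial accuracies (percent)."""
        return float(np.mean(self.trial_accuracies))
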