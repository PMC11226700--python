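"""Raw ECoG -> per-band Hilbert envelopes -> frame features.

The feature for a frame at time ``t`` is the smoothed envelope of each
band sampled at ``t - 125 ms``, ``t`` and ``t + 125 ms`` — 21 values for
the full 7-band set, ordered band-major, lag-minor.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy.signal import hilbert

from .bands import BandSet, DEFAULT_BANDS, LAG_OFFSETS
from .datatypes import EcogRecording, EnvelopeTensor, FrameDataset, ZScoreStats, feature_names
from .filters import bandpass_sos, bandstop_sos, filtfilt_reflect, lowpass_sos, pad_samples

logger = logging.getLogger(__name__)

#: Amplitude-artifact screening limit (uV): signals should not exceed 1 mV.
DEFAULT_AMPLITUDE_LIMIT = 1000.0

#: Envelope smoother cutoff (Hz).
ENVELOPE_LOWPASS_HZ = 0.25


def screen_artifacts(rec: EcogRecording, limit: float = DEFAULT_AMPLITUDE_LIMIT) -> np.ndarray:
    """Boolean keep-mask; False for channels that ever exceed ``limit`` (uV).

    Masked channels must be excluded from everything downstream, including
    the common-average reference.
    """
    if limit <= 0:
        raise ValueError("limit must be > 0")
    if rec.n_samples == 0:
        return np.ones(rec.n_channels, dtype=bool)
    return np.max(np.abs(rec.data), axis=1) <= limit


def common_average_reference(rec: EcogRecording, grid_map: dict[str, str] | None = None) -> EcogRecording:
    """Subtract, per grid and per sample, the mean of that grid's channels.

    ``grid_map`` overrides the recording's own channel->grid assignment.
    """
    grids = [grid_map[c] for c in rec.channels] if grid_map is not None else list(rec.grids)
    out = rec.copy()
    for grid in dict.fromkeys(grids):
        idx = [i for i, g in enumerate(grids) if g == grid]
        if not idx:
            raise ValueError(f"grid {grid!r} has no retained channels")
        out.data[idx] -= rec.data[idx].mean(axis=0, keepdims=True)
    return out


def notch_line_noise(
    rec: EcogRecording, line_freq: float = 50.0, harmonics: int = 2, half_width: float = 2.0
) -> EcogRecording:
    """Zero-phase band-stop at the line frequency and its harmonics.

    Stops ``line_freq``, ``2*line_freq``, ... up to ``harmonics`` terms,
    skipping any that reach Nyquist.
    """
    nyq = rec.sampling_rate / 2.0
    if line_freq >= nyq:
        raise ValueError(f"line frequency {line_freq} Hz >= Nyquist {nyq} Hz")
    out = rec.copy()
    for k in range(1, harmonics + 1):
        f = line_freq * k
        if f + half_width >= nyq:
            break
        sos = bandstop_sos(f, rec.sampling_rate, half_width)
        pad = pad_samples(f - half_width, rec.sampling_rate)
        out.data = filtfilt_reflect(sos, out.data, pad)
    return out


def extract_envelopes(
    rec: EcogRecording, bands: BandSet = DEFAULT_BANDS
) -> EnvelopeTensor:
    """Band-pass, Hilbert-envelope and 0.25 Hz smooth every channel.

    Each band uses a 4th-order Butterworth applied forward-backward; the
    envelope (analytic-signal magnitude) is then low-pass filtered below
    0.25 Hz, again 4th-order zero-phase Butterworth.  The output keeps the
    input length and sampling rate.
    """
    bands.validate_rate(rec.sampling_rate)
    fs = rec.sampling_rate
    if rec.n_samples / fs < 20.0:
        warnings.warn(
            f"recording of {rec.n_samples / fs:.1f} s is short relative to the "
            f"{ENVELOPE_LOWPASS_HZ} Hz envelope smoother; expect edge bias",
            stacklevel=2,
        )

    smooth_sos = lowpass_sos(ENVELOPE_LOWPASS_HZ, fs)
    smooth_pad = pad_samples(ENVELOPE_LOWPASS_HZ, fs)
    n = rec.n_samples

    values = np.empty((rec.n_channels, len(bands), n))
    for bi, band in enumerate(bands):
        sos = bandpass_sos(band.low, band.high, fs)
        pad = min(pad_samples(band.low, fs), n - 1)
        # Pad once: the band-pass, Hilbert transform and smoother all see
        # the reflected extension, so none of them rings at the edges.
        x = np.pad(rec.data, [(0, 0), (pad, pad)], mode="reflect") if pad > 0 else rec.data
        xb = filtfilt_reflect(sos, x, 0)
        env = np.abs(hilbert(xb, axis=-1))
        env = filtfilt_reflect(smooth_sos, env, max(smooth_pad - pad, 0))
        values[:, bi, :] = env[:, pad: pad + n] if pad > 0 else env

    return EnvelopeTensor(values=values, sampling_rate=fs, band_set=bands, channels=list(rec.channels))


def build_features(
    env: EnvelopeTensor,
    channel,
    frame_times: np.ndarray,
    band_subset: str = "full",
    trial_ids: np.ndarray | None = None,
) -> FrameDataset:
    """Assemble per-frame feature rows for one electrode.

    Frames closer than 125 ms to either record edge are dropped (count
    logged).  Columns are ordered band-major, lag-minor; the ``full``
    subset has 21 columns, ``low`` 15 and ``gamma`` 6.
    """
    fs = env.sampling_rate
    ci = env.channel_index(channel)
    band_idx = env.band_set.subset_indices(band_subset)
    lag = int(round(0.125 * fs))

    frame_times = np.asarray(frame_times, dtype=float)
    samples = np.round(frame_times * fs).astype(int)
    ok = (samples - lag >= 0) & (samples + lag < env.n_samples)
    n_dropped = int(np.sum(~ok))
    if n_dropped:
        logger.info("build_features: dropped %d frame(s) within 125 ms of record edges", n_dropped)
    samples = samples[ok]
    if trial_ids is None:
        trial_ids = np.zeros(len(frame_times), dtype=int)
    trial_ids = np.asarray(trial_ids)[ok]

    cols = []
    for b in band_idx:
        for off in (-lag, 0, lag):
            cols.append(env.values[ci, b, samples + off])
    X = np.stack(cols, axis=1) if cols else np.empty((len(samples), 0))

    return FrameDataset(
        X=X,
        times=samples / fs,
        trial_ids=trial_ids,
        labels=np.zeros(len(samples), dtype=int),
        band_subset=band_subset,
        columns=feature_names(env.band_set, band_idx),
    )


def zscore_stats(train_X: np.ndarray) -> ZScoreStats:
    """Column means/sds from the training frames only; constant columns get
    sd 0 and are mapped to all-zero after centering."""
    mean = train_X.mean(axis=0)
    std = train_X.std(axis=0, ddof=0)
    return ZScoreStats(mean=mean, std=std)


def zscore_features(train: FrameDataset, apply_to: FrameDataset | None = None) -> FrameDataset:
    """Standardize ``apply_to`` (default: the training set itself) using
    statistics estimated on ``train`` only."""
    stats = zscore_stats(train.X)
    target = train if apply_to is None else apply_to
    if target.n_features != train.n_features:
        raise ValueError("feature-count mismatch between train and apply_to")
    out = target.subset(np.ones(target.n_frames, dtype=bool))
    out.X = stats.apply(target.X)
    return out


def frame_grid(
    trials, stride: int = 1, sampling_rate: float | None = None, margin: float = 0.125
) -> tuple[np.ndarray, np.ndarray]:
    """Regular frame times covering every trial interval.

    Returns (times, trial_ids) with one frame every ``stride`` samples
    inside ``[trial_start + margin, trial_end - margin)`` of each trial.
    """
    fs = sampling_rate if sampling_rate is not None else float(trials.attrs.get("sampling_rate", 256.0))
    times, ids = [], []
    for row in trials.itertuples():
        start = int(np.ceil((row.trial_start + margin) * fs))
        stop = int(np.floor((row.trial_end - margin) * fs))
        s = np.arange(start, stop, stride)
        times.append(s / fs)
        ids.append(np.full(len(s), row.trial))
    return np.concatenate(times), np.concatenate(ids)


#: Number of feature columns per band subset (7 bands x 3 lags for "full").
N_FEATURES = {name: len(idx) * len(LAG_OFFSETS) for name, idx in
              {"full": range(7), "low": range(5), "gamma": range(2)}.items()}
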