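"""Paradigm-structured synthetic ECoG with known ground truth.

The generator emulates a cued sentence task: each trial shows a task cue
(1 s), waits through a jittered preparation window, presents a go cue, and
the (simulated) participant speaks/listens/imagines for a few seconds.
Every electrode carries band-limited background noise whose amplitude is
modulated around the true speech window, so the injected per-band
modulation depth maps directly onto the envelope change the downstream
detector is trained to find.

Channel model (per electrode)::

    x(t) = sum_b a[b] * (1 + m[mode][b] * s_mode(t)) * n_b(t)
           + line_noise + cue_locked_burst

where ``n_b`` is unit-variance Gaussian noise band-passed with the same
4th-order zero-phase Butterworth used by the preprocessing stage and
``s_mode`` is the 0/1 speech indicator of that mode's trials, smoothed by
250 ms raised-cosine ramps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .bands import BandSet, DEFAULT_BANDS
from .datatypes import EcogRecording, REGIONS, SPEECH_MODES
from .filters import bandpass_sos, filtfilt_reflect, pad_samples


class ConfigurationError(ValueError):
    """Raised when a paradigm configuration field is invalid."""


class LayoutError(ValueError):
    """Raised when trial intervals overlap or fall outside the recording."""


@dataclass(frozen=True)
class ParadigmConfig:
    """Timing of the cued-sentence paradigm.

    Defaults follow the study layout: 20 sentences per speech mode, a 1 s
    task cue, a 2 s preparation window with up to 1 s of jitter, and
    recordings sampled at 256 Hz.
    """

    n_trials_per_mode: int = 20
    cue_duration: float = 1.0
    prep_duration: float = 2.0
    prep_jitter_max: float = 1.0
    pre_cue_duration: float = 2.5
    speech_duration_mean: float = 3.0
    speech_duration_sd: float = 0.25
    onset_delay_mean: float = 0.5
    onset_delay_sd: float = 0.1
    inter_trial_gap: float = 3.0
    sampling_rate: float = 256.0
    modes: tuple[str, ...] = SPEECH_MODES

    def __post_init__(self) -> None:
        positive = (
            "cue_duration",
            "prep_duration",
            "pre_cue_duration",
            "speech_duration_mean",
            "inter_trial_gap",
            "sampling_rate",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("prep_jitter_max", "speech_duration_sd", "onset_delay_mean", "onset_delay_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_trials_per_mode < 1:
            raise ConfigurationError(f"n_trials_per_mode must be >= 1, got {self.n_trials_per_mode}")
        if self.prep_jitter_max > self.prep_duration:
            raise ConfigurationError(
                f"prep_jitter_max ({self.prep_jitter_max}) must not exceed "
                f"prep_duration ({self.prep_duration})"
            )
        unknown = set(self.modes) - set(SPEECH_MODES)
        if unknown:
            raise ConfigurationError(f"unknown speech modes: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["modes"] = list(self.modes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParadigmConfig":
        d = dict(d)
        if "modes" in d:
            d["modes"] = tuple(d["modes"])
        return cls(**d)


@dataclass
class GroundTruth:
    """True speech windows for every trial (imagined included) and, once a
    recording has been synthesized, the injected per-electrode modulation.

    Kept separate from the observable trial table so that imagined trials
    never leak behavioral timing into the pipeline.
    """

    windows: pd.DataFrame  # columns: trial, mode, onset, offset (absolute s)
    modulation: dict = field(default_factory=dict)  # electrode -> {mode: m[7]}

    def __post_init__(self) -> None:
        bad = self.windows[self.windows["onset"] >= self.windows["offset"]]
        if len(bad):
            raise ValueError(f"ground-truth onset >= offset for trials {bad['trial'].tolist()}")


@dataclass
class ElectrodeProfile:
    """Generative description of one synthetic electrode."""

    electrode: str
    grid: str
    region: str
    modulation: dict[str, np.ndarray]  # mode -> fractional amplitude change, len 7
    amplitudes: np.ndarray             # baseline band amplitudes, uV
    cue_response_gain: float = 0.0
    line_noise_amp: float = 0.0

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; choose from {REGIONS}")
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if np.any(self.amplitudes < 0):
            raise ValueError("baseline amplitudes must be >= 0")
        self.modulation = {m: np.asarray(v, dtype=float) for m, v in self.modulation.items()}
        for mode, m in self.modulation.items():
            if np.any(m <= -1):
                raise ValueError(f"modulation for {mode} must stay > -1 (amplitude must stay positive)")


# Per-band fractional amplitude modulation templates.  Signs encode the
# region/mode structure the detector is expected to recover: motor-like
# electrodes gain gamma and lose delta/theta in every mode; temporal-like
# electrodes behave the same except that imagined speech drives no gamma
# change; "other" electrodes are null.
_MOTOR_BASE = np.array([-0.40, -0.35, -0.15, -0.10, 0.10, 0.50, 0.50])
_TEMPORAL_BASE = np.array([-0.40, -0.35, -0.15, -0.10, 0.10, 0.50, 0.55])
_TEMPORAL_IMAGINED = np.array([-0.40, -0.35, -0.20, -0.15, -0.10, 0.0, 0.0])
_MODE_SCALE = {"performed": 1.0, "perceived": 0.8, "imagined": 0.9}


def default_profiles(region: str, mode: str) -> np.ndarray:
    """Default band-modulation vector for a (region, mode) pair."""
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}; choose from {REGIONS}")
    if mode not in SPEECH_MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {SPEECH_MODES}")
    if region == "other":
        return np.zeros(7)
    if region == "motor":
        return _MOTOR_BASE * _MODE_SCALE[mode]
    if mode == "imagined":
        return _TEMPORAL_IMAGINED.copy()
    return _TEMPORAL_BASE * _MODE_SCALE[mode]


def default_amplitudes(band_set: BandSet = DEFAULT_BANDS, scale: float = 40.0) -> np.ndarray:
    """1/f baseline band amplitudes: ``a[b] = scale / center_frequency``."""
    return np.array([scale / b.center for b in band_set])


def make_profile(
    electrode: str,
    region: str,
    grid: str = "G1",
    band_set: BandSet = DEFAULT_BANDS,
    amplitude_scale: float = 40.0,
    cue_response_gain: float = 0.0,
    line_noise_amp: float = 0.0,
    modulation_scale: float = 1.0,
) -> ElectrodeProfile:
    """Build an :class:`ElectrodeProfile` from the default region templates."""
    modulation = {
        mode: default_profiles(region, mode) * modulation_scale for mode in SPEECH_MODES
    }
    return ElectrodeProfile(
        electrode=electrode,
        grid=grid,
        region=region,
        modulation=modulation,
        amplitudes=default_amplitudes(band_set, amplitude_scale),
        cue_response_gain=cue_response_gain,
        line_noise_amp=line_noise_amp,
    )


def make_paradigm(cfg: ParadigmConfig, seed: int) -> tuple[pd.DataFrame, GroundTruth]:
    """Lay out one randomized trial sequence and its hidden ground truth.

    Returns the observable trial table (speech on/offsets are NaN for
    imagined trials) and a :class:`GroundTruth` holding true windows for
    every trial.
    """
    rng = np.random.default_rng(seed)
    pairs = [(s, m) for s in range(cfg.n_trials_per_mode) for m in cfg.modes]
    order = rng.permutation(len(pairs))

    rows, truth_rows = [], []
    cursor = 0.0
    for trial, k in enumerate(order):
        sentence, mode = pairs[k]
        trial_start = cursor
        cue_onset = trial_start + cfg.pre_cue_duration
        prep = cfg.prep_duration - rng.uniform(0.0, cfg.prep_jitter_max) if cfg.prep_jitter_max else cfg.prep_duration
        go_onset = cue_onset + cfg.cue_duration + prep
        delay = max(0.05, rng.normal(cfg.onset_delay_mean, cfg.onset_delay_sd))
        duration = max(0.5, rng.normal(cfg.speech_duration_mean, cfg.speech_duration_sd))
        onset = go_onset + delay
        offset = onset + duration
        trial_end = offset + cfg.inter_trial_gap
        observable = mode != "imagined"
        rows.append(
            dict(
                trial=trial,
                sentence=sentence,
                mode=mode,
                trial_start=trial_start,
                cue_onset=cue_onset,
                go_onset=go_onset,
                speech_onset=onset if observable else np.nan,
                speech_offset=offset if observable else np.nan,
                trial_end=trial_end,
            )
        )
        truth_rows.append(dict(trial=trial, mode=mode, onset=onset, offset=offset))
        cursor = trial_end

    trials = pd.DataFrame(rows)
    trials.attrs["sampling_rate"] = cfg.sampling_rate
    truth = GroundTruth(windows=pd.DataFrame(truth_rows))
    return trials, truth


def _smooth_indicator(
    n_samples: int, sampling_rate: float, windows: np.ndarray, ramp: float
) -> np.ndarray:
    """0/1 indicator of the given (onset, offset) windows with raised-cosine
    ramps of total width ``ramp`` centered on each boundary."""
    t = np.arange(n_samples) / sampling_rate
    s = np.zeros(n_samples)
    half = ramp / 2.0
    for onset, offset in windows:
        if ramp > 0:
            rise = (t >= onset - half) & (t < onset + half)
            s[rise] = np.maximum(s[rise], 0.5 * (1 - np.cos(np.pi * (t[rise] - onset + half) / ramp)))
            fall = (t >= offset - half) & (t < offset + half)
            s[fall] = np.maximum(s[fall], 0.5 * (1 + np.cos(np.pi * (t[fall] - offset + half) / ramp)))
        core = (t >= onset + half) & (t < offset - half)
        s[core] = 1.0
    return s


def _cue_burst_window(n_samples: int, sampling_rate: float, cue_onsets: np.ndarray, width: float = 0.3) -> np.ndarray:
    """Raised-cosine (Hann) gain window at each task-cue onset."""
    t = np.arange(n_samples) / sampling_rate
    w = np.zeros(n_samples)
    for cue in cue_onsets:
        sel = (t >= cue) & (t < cue + width)
        w[sel] = np.maximum(w[sel], 0.5 * (1 - np.cos(2 * np.pi * (t[sel] - cue) / width)))
    return w


def synthesize_ecog(
    trials: pd.DataFrame,
    gt: GroundTruth,
    profiles: list[ElectrodeProfile],
    seed: int,
    band_set: BandSet = DEFAULT_BANDS,
    ramp: float = 0.25,
    line_freq: float = 50.0,
    pad_duration: float = 1.0,
) -> EcogRecording:
    """Render the trial layout into a multichannel recording."""
    if not profiles:
        raise ValueError("profiles must be non-empty")
    fs = _infer_sampling_rate(trials)
    _check_layout(trials)

    n_samples = int(np.ceil((trials["trial_end"].max() + pad_duration) * fs))
    rng = np.random.default_rng(seed)

    # One smoothed speech indicator per mode, shared across channels.
    indicators = {}
    for mode in trials["mode"].unique():
        trial_ids = trials.loc[trials["mode"] == mode, "trial"]
        win = gt.windows[gt.windows["trial"].isin(trial_ids)][["onset", "offset"]].to_numpy()
        indicators[mode] = _smooth_indicator(n_samples, fs, win, ramp)

    cue_window = _cue_burst_window(n_samples, fs, trials["cue_onset"].to_numpy())
    t = np.arange(n_samples) / fs

    sos_per_band = [bandpass_sos(b.low, b.high, fs) for b in band_set]
    pads = [pad_samples(b.low, fs) for b in band_set]

    data = np.zeros((len(profiles), n_samples))
    for ci, prof in enumerate(profiles):
        x = np.zeros(n_samples)
        for bi, band in enumerate(band_set):
            noise = rng.standard_normal(n_samples)
            nb = filtfilt_reflect(sos_per_band[bi], noise, pads[bi])
            sd = nb.std()
            if sd > 0:
                nb /= sd
            gain = np.ones(n_samples)
            for mode, s in indicators.items():
                m = prof.modulation.get(mode)
                if m is not None and m[bi] != 0.0:
                    gain += m[bi] * s
            x += prof.amplitudes[bi] * gain * nb
        if prof.line_noise_amp > 0:
            x += prof.line_noise_amp * np.sin(2 * np.pi * line_freq * t + rng.uniform(0, 2 * np.pi))
        if prof.cue_response_gain > 0:
            rms = float(np.sqrt(np.sum(prof.amplitudes**2)))
            x += prof.cue_response_gain * rms * cue_window * rng.standard_normal(n_samples)
        data[ci] = x
        gt.modulation[prof.electrode] = {m: v.copy() for m, v in prof.modulation.items()}

    return EcogRecording(
        data=data,
        sampling_rate=fs,
        channels=[p.electrode for p in profiles],
        grids=[p.grid for p in profiles],
        regions=[p.region for p in profiles],
    )


def _infer_sampling_rate(trials: pd.DataFrame) -> float:
    return float(trials.attrs.get("sampling_rate", 256.0))


def _check_layout(trials: pd.DataFrame) -> None:
    ordered = trials.sort_values("trial_start")
    starts = ordered["trial_start"].to_numpy()
    ends = ordered["trial_end"].to_numpy()
    if np.any(ends[:-1] > starts[1:] + 1e-9):
        raise LayoutError("trial intervals overlap")
    for col in ("cue_onset", "go_onset"):
        if np.any(ordered[col].to_numpy() < starts - 1e-9) or np.any(ordered[col].to_numpy() > ends + 1e-9):
            raise LayoutError(f"{col} outside its trial interval")
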