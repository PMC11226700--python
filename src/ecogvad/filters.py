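"""Zero-phase Butterworth filtering helpers.

All filters are 4th-order Butterworth designs applied forward-backward
(zero phase).  Edge transients are controlled by reflection-padding the
signal by at least three time constants of the slowest pole before
filtering; this matters mostly for the 0.25 Hz envelope smoother whose
impulse response spans seconds.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

FILTER_ORDER = 4


def bandpass_sos(low: float, high: float, sampling_rate: float) -> np.ndarray:
    nyq = sampling_rate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"invalid band edges {low}-{high} Hz at fs={sampling_rate}")
    return signal.butter(FILTER_ORDER, [low, high], btype="bandpass", fs=sampling_rate, output="sos")


def lowpass_sos(cutoff: float, sampling_rate: float) -> np.ndarray:
    if not 0 < cutoff < sampling_rate / 2.0:
        raise ValueError(f"invalid low-pass cutoff {cutoff} Hz at fs={sampling_rate}")
    return signal.butter(FILTER_ORDER, cutoff, btype="lowpass", fs=sampling_rate, output="sos")


def bandstop_sos(center: float, sampling_rate: float, half_width: float = 2.0) -> np.ndarray:
    nyq = sampling_rate / 2.0
    lo, hi = center - half_width, center + half_width
    if not 0 < lo < hi < nyq:
        raise ValueError(f"notch at {center} Hz does not fit below Nyquist {nyq} Hz")
    return signal.butter(FILTER_ORDER, [lo, hi], btype="bandstop", fs=sampling_rate, output="sos")


def pad_samples(low_edge_hz: float, sampling_rate: float, n_constants: float = 3.0) -> int:
    """Reflection-pad length covering ``n_constants`` periods of the slowest edge."""
    return int(np.ceil(n_constants / low_edge_hz * sampling_rate))


def filtfilt_reflect(sos: np.ndarray, x: np.ndarray, pad: int) -> np.ndarray:
    """Forward-backward filter with explicit even reflection padding.

    ``pad`` is clipped to one less than the signal length, matching the
    maximum meaningful reflection.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    pad = int(min(pad, n - 1))
    if pad > 0:
        xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="reflect")
    else:
        xp = x
    y = signal.sosfiltfilt(sos, xp, axis=-1, padlen=0)
    return y[..., pad: pad + n] if pad > 0 else y
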