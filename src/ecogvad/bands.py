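"""Canonical frequency-band definitions used throughout the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Band:
    name: str
    low: float
    high: float

    @property
    def center(self) -> float:
        """Geometric-mean center frequency (Hz)."""
        return (self.low * self.high) ** 0.5


_DEFAULT_BANDS = (
    Band("delta", 0.5, 4.0),
    Band("theta", 4.0, 8.0),
    Band("alpha", 8.0, 12.0),
    Band("beta1", 12.0, 24.0),
    Band("beta2", 24.0, 40.0),
    Band("low_gamma", 40.0, 70.0),
    Band("high_gamma", 70.0, 120.0),
)

#: Band subsets selectable for feature construction.
BAND_SUBSETS = {
    "full": tuple(range(7)),
    "low": tuple(range(5)),      # delta ... beta2
    "gamma": (5, 6),             # low_gamma + high_gamma
}

#: Relative time offsets of the three feature lags (seconds).
LAG_OFFSETS = (-0.125, 0.0, 0.125)


@dataclass(frozen=True)
class BandSet:
    """An ordered collection of band-pass edges.

    The default is the 7-band ladder from delta (0.5-4 Hz) up to
    high gamma (70-120 Hz).
    """

    bands: tuple[Band, ...] = field(default=_DEFAULT_BANDS)

    def __post_init__(self) -> None:
        for b in self.bands:
            if not 0 <= b.low < b.high:
                raise ValueError(f"band {b.name}: need 0 <= low < high, got {b.low}-{b.high}")

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    def __getitem__(self, i: int) -> Band:
        return self.bands[i]

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bands]

    def validate_rate(self, sampling_rate: float) -> None:
        nyq = sampling_rate / 2.0
        for b in self.bands:
            if b.high >= nyq:
                raise ValueError(
                    f"band {b.name} upper edge {b.high} Hz >= Nyquist {nyq} Hz"
                )

    def subset_indices(self, subset: str) -> tuple[int, ...]:
        if len(self.bands) != 7 and subset != "full":
            raise ValueError("named subsets are defined for the default 7-band set")
        if subset == "full":
            return tuple(range(len(self.bands)))
        try:
            return BAND_SUBSETS[subset]
        except KeyError:
            raise ValueError(
                f"unknown band subset {subset!r}; choose from {sorted(BAND_SUBSETS)}"
            ) from None


DEFAULT_BANDS = BandSet()
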