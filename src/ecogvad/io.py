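"""Readers and writers.

The native container is a single HDF5 file per recording (``/signals``
plus channel metadata) and one per frame collection (one group per
electrode/mode).  Events go to tab-separated, UTF-8, header-rowed TSV in
a BIDS-iEEG flavor (onset, duration, trial, mode, event_type).  EDF
reading is supported when ``pyedflib`` is installed; it is optional
because the container format is lossless and text-adjacent formats are
preferred for interchange.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .bands import BandSet, Band
from .datatypes import EcogRecording, FrameDataset
from .synthetic import GroundTruth


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# recordings

def save_recording(path, rec: EcogRecording) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("signals", data=rec.data)
        d.attrs["units"] = "uV"
        f.attrs["sampling_rate"] = rec.sampling_rate
        str_dt = h5py.string_dtype("utf-8")
        f.create_dataset("channels", data=np.array(rec.channels, dtype=object), dtype=str_dt)
        f.create_dataset("grids", data=np.array(rec.grids, dtype=object), dtype=str_dt)
        if rec.regions is not None:
            f.create_dataset("regions", data=np.array(rec.regions, dtype=object), dtype=str_dt)


def load_recording(path, fmt: str | None = None) -> EcogRecording:
    """Load a recording from the HDF5 container or (optionally) EDF.

    ``fmt`` is inferred from the suffix when omitted.  EDF requires a
    sidecar channel table (``<stem>_channels.tsv``) because EDF itself
    carries no grid assignment; channels without one are rejected.
    """
    path = Path(path)
    fmt = fmt or ("edf" if path.suffix.lower() == ".edf" else "container")
    if fmt == "container":
        return _load_container(path)
    if fmt == "edf":
        return _load_edf(path)
    raise ValueError(f"unknown recording format {fmt!r}")


def _load_container(path: Path) -> EcogRecording:
    try:
        with h5py.File(path, "r") as f:
            if "grids" not in f or "channels" not in f:
                raise ParseError(f"{path}: missing channel/grid table in container")
            return EcogRecording(
                data=f["signals"][()],
                sampling_rate=float(f.attrs["sampling_rate"]),
                channels=[c.decode() if isinstance(c, bytes) else str(c) for c in f["channels"][()]],
                grids=[g.decode() if isinstance(g, bytes) else str(g) for g in f["grids"][()]],
                regions=None
                if "regions" not in f
                else [r.decode() if isinstance(r, bytes) else str(r) for r in f["regions"][()]],
            )
    except OSError as e:
        raise ParseError(f"{path}: not a readable HDF5 container ({e})") from e


def _load_edf(path: Path) -> EcogRecording:
    try:
        import pyedflib
    except ImportError:
        raise ImportError(
            "EDF support requires pyedflib, which is not installed; "
            "use the HDF5 container format instead"
        ) from None
    table_path = path.with_name(path.stem + "_channels.tsv")
    if not table_path.exists():
        raise ParseError(f"missing channel table {table_path} (required for grid assignment)")
    table = read_channel_table(table_path)
    with pyedflib.EdfReader(str(path)) as r:
        labels = r.getSignalLabels()
        fs = r.getSampleFrequency(0)
        data = np.vstack([r.readSignal(i) for i in range(r.signals_in_file)])
    missing = [c for c in labels if c not in set(table["channel"])]
    if missing:
        raise ParseError(f"channels without grid assignment: {missing}")
    lookup = table.set_index("channel")
    return EcogRecording(
        data=data,
        sampling_rate=float(fs),
        channels=list(labels),
        grids=[str(lookup.loc[c, "grid"]) for c in labels],
        regions=[str(lookup.loc[c, "region"]) for c in labels] if "region" in table.columns else None,
    )


def read_channel_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "channel" not in df.columns or "grid" not in df.columns:
        raise ParseError(f"{path}: channel table needs 'channel' and 'grid' columns")
    return df


def write_channel_table(path, rec: EcogRecording) -> None:
    df = pd.DataFrame({"channel": rec.channels, "grid": rec.grids})
    if rec.regions is not None:
        df["region"] = rec.regions
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# trials / events

def write_trials_tsv(path, trials: pd.DataFrame) -> None:
    trials.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_trials_tsv(path, sampling_rate: float = 256.0) -> pd.DataFrame:
    trials = pd.read_csv(path, sep="\t", na_values=["n/a"])
    required = {"trial", "mode", "trial_start", "cue_onset", "go_onset", "trial_end"}
    missing = required - set(trials.columns)
    if missing:
        raise ParseError(f"{path}: trial table missing columns {sorted(missing)}")
    trials.attrs["sampling_rate"] = sampling_rate
    return trials


def write_events_tsv(path, trials: pd.DataFrame) -> None:
    """BIDS-iEEG-flavored long event table (onset, duration, trial, mode,
    event_type)."""
    rows = []
    for row in trials.itertuples():
        rows.append(dict(onset=row.cue_onset, duration=0.0, trial=row.trial, mode=row.mode, event_type="cue"))
        rows.append(dict(onset=row.go_onset, duration=0.0, trial=row.trial, mode=row.mode, event_type="go"))
        if not (np.isnan(row.speech_onset) or np.isnan(row.speech_offset)):
            rows.append(
                dict(
                    onset=row.speech_onset,
                    duration=row.speech_offset - row.speech_onset,
                    trial=row.trial,
                    mode=row.mode,
                    event_type="speech",
                )
            )
    pd.DataFrame(rows).sort_values("onset").to_csv(path, sep="\t", index=False)


def write_ground_truth_tsv(path, gt: GroundTruth) -> None:
    """Hidden ground truth; never read back by the pipeline."""
    gt.windows.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# frame datasets

def save_frames(path, datasets: dict[str, FrameDataset]) -> None:
    """Store frame datasets, one group per key (e.g. ``E1/performed``)."""
    with h5py.File(path, "w") as f:
        for key, d in datasets.items():
            g = f.create_group(key)
            g.create_dataset("X", data=d.X)
            g.create_dataset("times", data=d.times)
            g.create_dataset("trial_ids", data=np.asarray(d.trial_ids))
            g.create_dataset("labels", data=d.labels)
            g.attrs["band_subset"] = d.band_subset
            if d.columns is not None:
                g.attrs["columns"] = json.dumps(d.columns)


def load_frames(path) -> dict[str, FrameDataset]:
    out: dict[str, FrameDataset] = {}

    def visit(name, obj):
        if isinstance(obj, h5py.Group) and "X" in obj:
            out[name] = FrameDataset(
                X=obj["X"][()],
                times=obj["times"][()],
                trial_ids=obj["trial_ids"][()],
                labels=obj["labels"][()],
                band_subset=obj.attrs.get("band_subset", "full"),
                columns=json.loads(obj.attrs["columns"]) if "columns" in obj.attrs else None,
            )

    with h5py.File(path, "r") as f:
        f.visititems(visit)
    return out


# ---------------------------------------------------------------------------
# misc

def save_json(path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"unserializable {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def band_set_from_config(bands_cfg) -> BandSet:
    if bands_cfg is None:
        from .bands import DEFAULT_BANDS

        return DEFAULT_BANDS
    return BandSet(tuple(Band(str(n), float(lo), float(hi)) for n, lo, hi in bands_cfg))
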