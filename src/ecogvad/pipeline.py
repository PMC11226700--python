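"""End-to-end orchestration: simulate -> preprocess -> label -> detect ->
ensemble -> transfer -> stats, with tabular outputs.

Also hosts the mid-level helpers that glue stages together (building a
balanced, labeled frame dataset for one electrode and speech mode); the
unit-testable primitives live in their own modules.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as evio
from .bands import DEFAULT_BANDS
from .datatypes import EcogRecording, EnvelopeTensor, FrameDataset
from .detector import gamma_activation, loto_cv
from .ensemble import multi_electrode_cv, select_optimal_count
from .labeling import (
    balance_dataset,
    frames_to_labels,
    label_imagined_frames,
    passive_dataset,
    performed_label_matrix,
    surrogate_imagined_timing,
    windows_from_trials,
)
from .preprocessing import (
    build_features,
    common_average_reference,
    extract_envelopes,
    frame_grid,
    notch_line_noise,
    screen_artifacts,
)
from .stats import permutation_test_cv
from .synthetic import ParadigmConfig, make_paradigm, make_profile, synthesize_ecog
from .transfer import transfer_evaluate

logger = logging.getLogger(__name__)


def preprocess_recording(
    rec: EcogRecording,
    car: bool = True,
    notch: bool = True,
    line_freq: float = 50.0,
    amplitude_limit: float = 1000.0,
) -> tuple[EnvelopeTensor, np.ndarray]:
    """Artifact screening, per-grid CAR, notch, envelope extraction.

    Returns the envelope tensor of the retained channels and the keep-mask
    over the original channels.
    """
    mask = screen_artifacts(rec, amplitude_limit)
    if not mask.all():
        logger.info("preprocess: removed %d channel(s) exceeding %.0f uV", int((~mask).sum()), amplitude_limit)
    rec = rec.select_channels(mask)
    if car:
        rec = common_average_reference(rec)
    if notch:
        rec = notch_line_noise(rec, line_freq)
    return extract_envelopes(rec), mask


def mode_frames(
    env: EnvelopeTensor,
    trials: pd.DataFrame,
    mode: str,
    electrode,
    stride: int = 1,
    band_subset: str = "full",
    balance: bool = True,
) -> FrameDataset:
    """Balanced, labeled frame dataset for one electrode and speech mode.

    Performed/perceived trials use their observable windows; imagined
    trials get surrogate labels from the consensus timing of this table's
    performed trials.
    """
    sub = trials[trials["mode"] == mode]
    if len(sub) == 0:
        raise ValueError(f"no trials with mode {mode!r}")
    times, ids = frame_grid(sub, stride=stride, sampling_rate=env.sampling_rate)
    frames = build_features(env, electrode, times, band_subset=band_subset, trial_ids=ids)
    if mode == "imagined":
        frame_rate = env.sampling_rate / stride
        m, go_index = performed_label_matrix(trials[trials["mode"] == "performed"], frame_rate)
        timing = surrogate_imagined_timing(m, go_index, frame_rate)
        frames = label_imagined_frames(frames, sub, timing)
    else:
        frames = frames_to_labels(frames, windows_from_trials(sub))
    return balance_dataset(frames) if balance else frames


def passive_frames(
    env: EnvelopeTensor,
    trials: pd.DataFrame,
    electrode,
    stride: int = 1,
    band_subset: str = "full",
    width: float = 4.0,
) -> FrameDataset:
    """Cue-centered passive dataset for the imagined trials."""
    sub = trials[trials["mode"] == "imagined"]
    times, ids = frame_grid(sub, stride=stride, sampling_rate=env.sampling_rate)
    frames = build_features(env, electrode, times, band_subset=band_subset, trial_ids=ids)
    cues = dict(zip(sub["trial"], sub["cue_onset"]))
    return passive_dataset(frames, cues, width=width)


DEFAULT_CONFIG = {
    "paradigm": {"n_trials_per_mode": 8},
    "electrodes": [
        {"electrode": "M1", "region": "motor", "grid": "GA"},
        {"electrode": "M2", "region": "motor", "grid": "GA"},
        {"electrode": "T1", "region": "temporal", "grid": "GB"},
        {"electrode": "T2", "region": "temporal", "grid": "GB"},
        {"electrode": "O1", "region": "other", "grid": "GA"},
        {"electrode": "O2", "region": "other", "grid": "GB"},
    ],
    "line_noise_amp": 2.0,
    "stride": 16,
    "car": True,
    "notch": True,
    "line_freq": 50.0,
    "modes": ["performed", "perceived", "imagined"],
    "band_subsets": ["full", "low", "gamma"],
    "max_electrodes": 3,
    "n_perm": 200,
}


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:12]


def _write_table(path: Path, df: pd.DataFrame, chash: str, seed: int) -> None:
    with open(path, "w") as f:
        f.write(f"# config_hash={chash} seed={seed}\n")
        df.to_csv(f, sep="\t", index=False)


def run_pipeline(config: dict | None = None, out_dir="results/pipeline", seed: int = 0) -> dict:
    """Execute the full demo pipeline on synthetic data.

    Emits per-electrode accuracy tables, accuracy-vs-k curves, band-subset
    comparisons, activation patterns, cross-mode transfer matrices and a
    permutation test, as TSV/JSON under ``out_dir``.  Deterministic for a
    fixed (config, seed).
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    chash = config_hash(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    report: dict = {"config_hash": chash, "seed": seed, "stages": []}

    def stage(name):
        logger.info("pipeline stage: %s", name)
        report["stages"].append(name)

    try:
        stage("simulate")
        para = ParadigmConfig.from_dict(cfg["paradigm"])
        trials, gt = make_paradigm(para, seed)
        profiles = [
            make_profile(
                e["electrode"],
                e["region"],
                grid=e.get("grid", "G1"),
                cue_response_gain=e.get("cue_response_gain", 0.0),
                line_noise_amp=e.get("line_noise_amp", cfg["line_noise_amp"]),
            )
            for e in cfg["electrodes"]
        ]
        rec = synthesize_ecog(trials, gt, profiles, seed=seed + 1)
        evio.save_recording(out / "recording.h5", rec)
        evio.write_trials_tsv(out / "trials.tsv", trials)
        evio.write_events_tsv(out / "events.tsv", trials)
        evio.write_ground_truth_tsv(out / "ground_truth.tsv", gt)

        stage("preprocess")
        env, _ = preprocess_recording(
            rec, car=cfg["car"], notch=cfg["notch"], line_freq=cfg["line_freq"]
        )
        stride = int(cfg["stride"])
        electrodes = [e["electrode"] for e in cfg["electrodes"]]

        stage("label+detect")
        acc_rows, pattern_rows, subset_rows = [], [], []
        datasets: dict[tuple, FrameDataset] = {}
        for mode in cfg["modes"]:
            for elec in electrodes:
                for subset in cfg["band_subsets"]:
                    frames = mode_frames(env, trials, mode, elec, stride=stride, band_subset=subset)
                    datasets[(elec, mode, subset)] = frames
                    cv = loto_cv(frames)
                    subset_rows.append(
                        dict(electrode=elec, mode=mode, band_subset=subset, accuracy=cv.mean_accuracy)
                    )
                    if subset == "full":
                        acc_rows.append(dict(electrode=elec, mode=mode, accuracy=cv.mean_accuracy))
                        pat = cv.activation_pattern
                        for bi, band in enumerate(DEFAULT_BANDS.names):
                            pattern_rows.append(
                                dict(
                                    electrode=elec, mode=mode, band=band,
                                    lag_m125=pat[bi, 0], lag_0=pat[bi, 1], lag_p125=pat[bi, 2],
                                )
                            )
                        if mode == "imagined":
                            acc_rows[-1]["gamma_activation"] = gamma_activation(pat)
        acc_df = pd.DataFrame(acc_rows)
        _write_table(out / "accuracy_per_electrode.tsv", acc_df, chash, seed)
        _write_table(out / "band_subsets.tsv", pd.DataFrame(subset_rows), chash, seed)
        _write_table(out / "activation_patterns.tsv", pd.DataFrame(pattern_rows), chash, seed)

        stage("ensemble")
        for mode in cfg["modes"]:
            by_elec = {e: datasets[(e, mode, "full")] for e in electrodes}
            curves = multi_electrode_cv(by_elec, max_k=cfg["max_electrodes"])
            k_opt, means = select_optimal_count(curves)
            _write_table(
                out / f"ensemble_curve_{mode}.tsv",
                pd.DataFrame({"k": np.arange(1, len(means) + 1), "mean_accuracy": means,
                              "optimal": np.arange(1, len(means) + 1) == k_opt}),
                chash, seed,
            )

        stage("transfer")
        full_acc = acc_df.pivot(index="electrode", columns="mode", values="accuracy")
        best_elec = full_acc.mean(axis=1).idxmax()
        rows = []
        for src in cfg["modes"]:
            for tgt in cfg["modes"]:
                res = transfer_evaluate(datasets[(best_elec, src, "full")], datasets[(best_elec, tgt, "full")])
                rows.append(dict(train=src, test=tgt, accuracy=res.mean_accuracy))
        _write_table(out / "transfer_modes.tsv", pd.DataFrame(rows), chash, seed)

        stage("stats")
        best_mode = full_acc.loc[best_elec].idxmax()
        perm = permutation_test_cv(datasets[(best_elec, best_mode, "full")], n_perm=int(cfg["n_perm"]), seed=seed)
        evio.save_json(
            out / "permtest.json",
            dict(
                electrode=best_elec, mode=best_mode, observed=perm.observed,
                p_value=perm.p_value, n_perm=perm.n_perm, seed=perm.seed,
                null_mean=float(perm.null_accuracies.mean()),
            ),
        )

        report["best_electrode"] = str(best_elec)
        report["best_mode"] = str(best_mode)
        report["elapsed_s"] = time.time() - t0
        evio.save_json(out / "report.json", report)
        return report
    except Exception as e:
        raise RuntimeError(
            f"pipeline failed in stage {report['stages'][-1]!r} (config {chash}): {e}"
        ) from e
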