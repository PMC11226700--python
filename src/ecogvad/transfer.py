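"""Cross-mode and cross-subject transfer of trained detectors, plus the
pooled multi-subject model.

Transfer mirrors the offline evaluation protocol: the model is trained on
the full source dataset and tested on the full target dataset, with each
dataset standardized by its *own* statistics.  This is deliberately not a
causal/deployable scheme — target statistics are used at test time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datatypes import FrameDataset
from .detector import fit_detector, predict_frames
from .preprocessing import zscore_features

logger = logging.getLogger(__name__)


@dataclass
class TransferResult:
    trial_ids: np.ndarray
    trial_accuracies: np.ndarray  # percent
    outputs: np.ndarray
    frame_labels: np.ndarray
    frame_trials: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.trial_accuracies))


def transfer_evaluate(
    source: FrameDataset, target: FrameDataset, band_subset: str | None = None
) -> TransferResult:
    """Fit on all (labeled) source frames, score per target trial.

    Both datasets are individually z-scored with their own full-set
    statistics.  ``band_subset`` is a consistency check only: the datasets
    must already be built with matching feature columns.
    """
    src = source.labeled()
    tgt = target.labeled()
    if src.n_features != tgt.n_features:
        raise ValueError(
            f"feature-count mismatch: source has {src.n_features}, target {tgt.n_features}"
        )
    if band_subset is not None and band_subset not in (src.band_subset, "stacked"):
        raise ValueError(
            f"requested band subset {band_subset!r} but source was built with {src.band_subset!r}"
        )
    src_z = zscore_features(src)
    tgt_z = zscore_features(tgt)
    model = fit_detector(src_z.X, src_z.labels, band_subset=src.band_subset)
    out, dec = predict_frames(model, tgt_z.X)
    trial_ids = tgt_z.trials
    accs = np.array(
        [100.0 * np.mean(dec[tgt_z.trial_ids == t] == tgt_z.labels[tgt_z.trial_ids == t]) for t in trial_ids]
    )
    return TransferResult(
        trial_ids=trial_ids,
        trial_accuracies=accs,
        outputs=out,
        frame_labels=tgt_z.labels,
        frame_trials=tgt_z.trial_ids,
        meta={"band_subset": src.band_subset},
    )


@dataclass
class PooledCVResult:
    """Cross-validated pooled model: one held-out trial per subject per fold."""

    subjects: list
    trial_accuracies: dict  # subject -> per-trial percent accuracies
    n_folds: int
    meta: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(np.concatenate([self.trial_accuracies[s] for s in self.subjects])))

    def subject_mean(self, subject) -> float:
        return float(np.mean(self.trial_accuracies[subject]))


def fit_pooled(
    datasets: dict[str, FrameDataset] | list[FrameDataset], seed: int = 0
) -> PooledCVResult:
    """Pooled multi-subject cross-validation.

    Each subject's frames are z-scored with that subject's own statistics,
    trial counts are equalized by seeded subsampling of the larger
    subjects, and each CV fold holds out exactly one trial per subject.
    Subjects with fewer than 2 trials are excluded (logged).
    """
    if not isinstance(datasets, dict):
        datasets = {f"S{i}": d for i, d in enumerate(datasets)}
    rng = np.random.default_rng(seed)

    prepared: dict[str, tuple[FrameDataset, np.ndarray]] = {}
    for subject in sorted(datasets):
        d = datasets[subject].labeled()
        trials = d.trials
        if len(trials) < 2:
            logger.warning("fit_pooled: subject %r has < 2 trials; excluded", subject)
            continue
        prepared[subject] = (zscore_features(d), trials)
    if not prepared:
        raise ValueError("no subject has >= 2 trials")

    n_common = min(len(t) for _, t in prepared.values())
    kept: dict[str, tuple[FrameDataset, np.ndarray]] = {}
    for subject, (d, trials) in prepared.items():
        if len(trials) > n_common:
            trials = np.sort(rng.choice(trials, size=n_common, replace=False))
        kept[subject] = (d, trials)

    subjects = list(kept)
    accs = {s: [] for s in subjects}
    for fold in range(n_common):
        Xtr, ytr, tests = [], [], {}
        for s in subjects:
            d, trials = kept[s]
            held = trials[fold]
            train_mask = np.isin(d.trial_ids, trials) & (d.trial_ids != held)
            test_mask = d.trial_ids == held
            Xtr.append(d.X[train_mask])
            ytr.append(d.labels[train_mask])
            tests[s] = (d.X[test_mask], d.labels[test_mask])
        model = fit_detector(np.vstack(Xtr), np.concatenate(ytr))
        for s in subjects:
            Xte, yte = tests[s]
            _, dec = predict_frames(model, Xte)
            accs[s].append(100.0 * np.mean(dec == yte))

    return PooledCVResult(
        subjects=subjects,
        trial_accuracies={s: np.asarray(a) for s, a in accs.items()},
        n_folds=n_common,
        meta={"seed": seed, "trials_per_subject": n_common},
    )
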