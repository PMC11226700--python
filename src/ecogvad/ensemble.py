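"""Multi-electrode stacking: correlation-based electrode ranking, a
second-level regressor over single-electrode outputs, and recursive
selection of the electrode count."""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats as sps

from .datatypes import CVResult, DetectorModel, FrameDataset
from .detector import N_LAGS, fit_detector, predict_frames
from .preprocessing import zscore_stats

logger = logging.getLogger(__name__)


def electrode_score(X: np.ndarray, y: np.ndarray, n_lags: int = N_LAGS) -> float:
    """Max over bands of |band-averaged feature-label Pearson correlation|.

    Each feature's correlation with the labels is computed, the values are
    averaged within each band (across the 3 lags), and the score is the
    largest absolute band average.  Constant features contribute r = 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (xc * yc[:, None]).sum(axis=0) / denom, 0.0)
    band_avg = r.reshape(-1, n_lags).mean(axis=1)
    return float(np.max(np.abs(band_avg)))


def rank_electrodes(features: dict, labels: np.ndarray) -> list:
    """Electrode ids ordered by descending score, ties broken by id.

    ``features`` maps electrode id -> (n_frames, n_features) training
    matrix; all matrices must be row-aligned with ``labels``.
    """
    if len(features) < 2:
        raise ValueError("need at least 2 electrodes to rank")
    scores = {e: electrode_score(X, labels) for e, X in features.items()}
    return sorted(scores, key=lambda e: (-scores[e], e))


def fit_stacked(first_level_outputs: np.ndarray, labels: np.ndarray) -> DetectorModel:
    """Second-level linear regressor over k continuous electrode outputs."""
    Z = np.asarray(first_level_outputs, dtype=float)
    if Z.ndim != 2 or Z.shape[1] == 0:
        raise ValueError("need a (n_frames, k >= 1) first-level output matrix")
    return fit_detector(Z, labels, band_subset="stacked")


def multi_electrode_cv(
    frames_by_electrode: dict[str, FrameDataset], max_k: int | None = None
) -> list[CVResult]:
    """LOTO evaluation of the stacked model for every k = 1..K.

    All electrodes must share the same frame grid (trials, times, labels).
    The electrode ordering is recomputed inside every fold from the
    training trials only; the reported curve uses those per-fold orders.
    """
    electrodes = sorted(frames_by_electrode)
    ref = frames_by_electrode[electrodes[0]].labeled()
    trials = list(ref.trials)
    if len(trials) < 3:
        raise ValueError("leave-one-trial-out needs >= 3 trials")
    K = min(max_k or len(electrodes), len(electrodes))
    if K < 1:
        raise ValueError("max_k must be >= 1")

    labeled = {e: frames_by_electrode[e].labeled() for e in electrodes}
    accs = np.empty((K, len(trials)))
    fold_orders = []
    for fi, trial in enumerate(trials):
        test_mask = ref.trial_ids == trial
        y_train = ref.labels[~test_mask]
        y_test = ref.labels[test_mask]

        train_X = {e: labeled[e].X[~test_mask] for e in electrodes}
        order = rank_electrodes(train_X, y_train) if len(electrodes) > 1 else electrodes
        fold_orders.append(order)

        z_train, z_test = [], []
        for e in order[:K]:
            stats = zscore_stats(train_X[e])
            Xtr = stats.apply(train_X[e])
            Xte = stats.apply(labeled[e].X[test_mask])
            model = fit_detector(Xtr, y_train)
            z_train.append(predict_frames(model, Xtr)[0])
            z_test.append(predict_frames(model, Xte)[0])

        for k in range(1, K + 1):
            Ztr = np.stack(z_train[:k], axis=1)
            Zte = np.stack(z_test[:k], axis=1)
            stacked = fit_stacked(Ztr, y_train)
            _, dec = predict_frames(stacked, Zte)
            accs[k - 1, fi] = 100.0 * np.mean(dec == y_test)

    return [
        CVResult(
            trial_ids=np.asarray(trials),
            trial_accuracies=accs[k - 1],
            outputs=np.array([]),
            frame_labels=np.array([]),
            frame_trials=np.array([]),
            meta={"k": k, "fold_orders": fold_orders},
        )
        for k in range(1, K + 1)
    ]


def select_optimal_count(cv_results: list[CVResult], alpha: float = 0.05) -> tuple[int, np.ndarray]:
    """Recursive incumbent test over the accuracy-vs-k curve.

    Starting from k = 1, each larger model replaces the incumbent when it
    wins a one-sided paired Wilcoxon signed-rank test over the per-trial
    accuracies (alpha = 0.05, zero differences dropped).  If no model ever
    wins, the k with the highest mean accuracy is returned (first under
    ties).
    """
    if not cv_results:
        raise ValueError("need results for at least k = 1")
    means = np.array([r.mean_accuracy for r in cv_results])
    incumbent = 0
    updated = False
    for k in range(1, len(cv_results)):
        diff = cv_results[k].trial_accuracies - cv_results[incumbent].trial_accuracies
        if np.all(diff == 0):
            continue
        p = sps.wilcoxon(diff, alternative="greater", zero_method="wilcox").pvalue
        if p < alpha:
            incumbent = k
            updated = True
    if not updated:
        incumbent = int(np.argmax(means))
        logger.info("select_optimal_count: no significant win; falling back to argmax k=%d", incumbent + 1)
    return incumbent + 1, means
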