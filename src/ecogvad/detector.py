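"""Single-electrode frame-wise speech detection.

A plain linear regressor is fit to +/-1 labels and thresholded at zero
(non-negative output -> speech).  Interpretation uses Haufe-style
activation patterns, ``A = Cov(X) w / Var(X w)``, computed per training
fold, averaged across folds and normalized to a maximum absolute entry
of 1.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from sklearn.linear_model import LinearRegression, Ridge

from .datatypes import CVResult, DetectorModel, FrameDataset
from .preprocessing import zscore_stats

logger = logging.getLogger(__name__)

#: Lags per band in the feature layout.
N_LAGS = 3


def fit_detector(X: np.ndarray, y: np.ndarray, band_subset: str = "full", ridge: float = 0.0) -> DetectorModel:
    """Ordinary least squares to +/-1 targets (optionally ridge-penalized)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    classes = set(np.unique(y))
    if not classes <= {-1.0, 1.0}:
        raise ValueError(f"labels must be +/-1, got {sorted(classes)}")
    if len(classes) < 2:
        raise ValueError("both classes must be present to fit a detector")
    est = Ridge(alpha=ridge) if ridge > 0 else LinearRegression()
    est.fit(X, y)
    return DetectorModel(
        weights=est.coef_,
        intercept=float(est.intercept_),
        band_subset=band_subset,
    )


def predict_frames(model: DetectorModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Continuous outputs and thresholded decisions.

    Output exactly 0 counts as speech: decision = +1 iff output >= 0.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(model.weights):
        raise ValueError(f"expected {len(model.weights)} features, got {X.shape[1]}")
    out = X @ model.weights + model.intercept
    decisions = np.where(out >= 0, 1, -1)
    return out, decisions


def activation_pattern(
    weights: np.ndarray, X_train: np.ndarray, outputs_train: np.ndarray, n_lags: int = N_LAGS
) -> np.ndarray:
    """Forward-model pattern for a linear backward model (single latent):
    ``A = Cov(X) w / Var(output)``, reshaped band-major x lag."""
    w = np.asarray(weights, dtype=float).ravel()
    X = np.asarray(X_train, dtype=float)
    out = np.asarray(outputs_train, dtype=float)
    var_out = out.var(ddof=0)
    if var_out <= 0:
        logger.warning("activation_pattern: zero-variance model output; returning zero pattern")
        shape = (len(w), 1) if len(w) % n_lags else (len(w) // n_lags, n_lags)
        return np.zeros(shape)
    cov = np.atleast_2d(np.cov(X, rowvar=False, ddof=0))
    a = np.atleast_1d(cov @ w) / var_out
    if len(w) % n_lags:  # non-band-structured feature sets stay flat
        return a.reshape(len(w), 1)
    return a.reshape(len(w) // n_lags, n_lags)


def normalize_pattern(pattern: np.ndarray) -> np.ndarray:
    """Scale so the maximum absolute entry is 1 (zero pattern unchanged)."""
    peak = np.max(np.abs(pattern))
    return pattern / peak if peak > 0 else pattern.copy()


def gamma_activation(pattern: np.ndarray) -> float:
    """Mean of the low-gamma and high-gamma rows of a full 7-band pattern."""
    pattern = np.asarray(pattern)
    if pattern.shape[0] != 7:
        raise ValueError(
            f"gamma_activation needs a full 7-band pattern, got {pattern.shape[0]} rows"
        )
    return float(pattern[5:7].mean())


class LotoEngine:
    """Precomputed leave-one-trial-out machinery for one frame dataset.

    Fold-wise OLS predictions are invariant to the per-column scale of the
    z-scoring (only centering matters), so the engine solves the centered
    normal equations directly.  Per-fold Gram factorizations are cached,
    which makes repeated evaluation under trial-wise label flips (the
    permutation tests) cheap: only the right-hand side changes.
    """

    def __init__(self, frames: FrameDataset):
        frames = frames.labeled()
        if frames.n_frames == 0:
            raise ValueError("no labeled frames")
        self.trials = []
        self._X, self._y, self._n, self._S1, self._G, self._Xty, self._sy = ([] for _ in range(7))
        for trial in frames.trials:
            sel = frames.trial_ids == trial
            if not sel.any():
                continue
            X = frames.X[sel]
            y = frames.labels[sel].astype(float)
            self.trials.append(trial)
            self._X.append(X)
            self._y.append(y)
            self._n.append(len(y))
            self._S1.append(X.sum(axis=0))
            self._G.append(X.T @ X)
            self._Xty.append(X.T @ y)
            self._sy.append(y.sum())
        if len(self.trials) < 2:
            raise ValueError("leave-one-trial-out needs at least 2 trials with labeled frames")
        self._N = int(np.sum(self._n))
        self._S1tot = np.sum(self._S1, axis=0)
        self._Gtot = np.sum(self._G, axis=0)
        self._prep_folds()

    def _prep_folds(self) -> None:
        self._mu, self._solve, self._Xc = [], [], []
        for f in range(len(self.trials)):
            n = self._N - self._n[f]
            mu = (self._S1tot - self._S1[f]) / n
            gram = (self._Gtot - self._G[f]) - n * np.outer(mu, mu)
            self._mu.append(mu)
            self._Xc.append(self._X[f] - mu)
            try:
                c = cho_factor(gram + 1e-10 * np.trace(gram) / gram.shape[0] * np.eye(gram.shape[0]))
                self._solve.append(lambda b, c=c: cho_solve(c, b))
            except LinAlgError:
                pinv = np.linalg.pinv(gram)
                self._solve.append(lambda b, pinv=pinv: pinv @ b)

    def run(self, flip: np.ndarray | None = None, return_outputs: bool = False):
        """Per-trial accuracies (percent) with optional label flips.

        ``flip`` is a +/-1 factor per trial (aligned with ``self.trials``);
        trial ``t``'s labels become ``flip[t] * labels``.
        """
        k = len(self.trials)
        flip = np.ones(k) if flip is None else np.asarray(flip, dtype=float)
        Xty_tot = np.sum([f * v for f, v in zip(flip, self._Xty)], axis=0)
        sy_tot = float(np.sum([f * v for f, v in zip(flip, self._sy)]))
        acc = np.empty(k)
        outputs = [] if return_outputs else None
        for f in range(k):
            n = self._N - self._n[f]
            b = (Xty_tot - flip[f] * self._Xty[f]) - self._mu[f] * (sy_tot - flip[f] * self._sy[f])
            w = self._solve[f](b)
            ybar = (sy_tot - flip[f] * self._sy[f]) / n
            out = ybar + self._Xc[f] @ w
            y_true = flip[f] * self._y[f]
            acc[f] = 100.0 * np.mean(np.where(out >= 0, 1.0, -1.0) == y_true)
            if return_outputs:
                outputs.append(out)
        if return_outputs:
            return acc, outputs
        return acc


def loto_cv(
    frames: FrameDataset,
    band_subset: str | None = None,
    compute_patterns: bool = True,
    ridge: float = 0.0,
) -> CVResult:
    """Leave-one-trial-out evaluation of the single-electrode detector.

    Per fold: z-score on the training trials only, fit OLS, score the
    held-out trial as the percentage of frames correctly classified.
    Activation patterns are computed per training fold, averaged across
    folds, and normalized to max |entry| = 1.
    """
    labeled = frames.labeled()
    subset = band_subset or frames.band_subset
    trials = [t for t in labeled.trials]
    dropped = set(frames.trials) - set(trials)
    if dropped:
        logger.info("loto_cv: skipping %d trial(s) without labeled frames", len(dropped))
    if len(trials) < 3:
        raise ValueError(f"leave-one-trial-out needs >= 3 trials, got {len(trials)}")

    accs, outputs_all, labels_all, trials_all, patterns = [], [], [], [], []
    for trial in trials:
        test_mask = labeled.trial_ids == trial
        train = labeled.subset(~test_mask)
        test = labeled.subset(test_mask)
        stats = zscore_stats(train.X)
        Xtr = stats.apply(train.X)
        Xte = stats.apply(test.X)
        model = fit_detector(Xtr, train.labels, band_subset=subset, ridge=ridge)
        out, dec = predict_frames(model, Xte)
        accs.append(100.0 * np.mean(dec == test.labels))
        outputs_all.append(out)
        labels_all.append(test.labels)
        trials_all.append(test.trial_ids)
        if compute_patterns:
            train_out, _ = predict_frames(model, Xtr)
            patterns.append(activation_pattern(model.weights, Xtr, train_out))

    pattern = normalize_pattern(np.mean(patterns, axis=0)) if patterns else None
    return CVResult(
        trial_ids=np.asarray(trials),
        trial_accuracies=np.asarray(accs),
        outputs=np.concatenate(outputs_all),
        frame_labels=np.concatenate(labels_all),
        frame_trials=np.concatenate(trials_all),
        activation_pattern=pattern,
        meta={"band_subset": subset, "n_trials": len(trials)},
    )
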