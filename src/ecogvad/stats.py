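"""Significance machinery: trial-wise permutation tests and nonparametric
accuracy comparisons.

The permutation scheme reverses the labels of a random half of the trials
(never per-frame), keeping the low-frequency structure of the labels and
making the test conservative.  P-values follow ``(N + 1)/(n_perm + 1)``
with ``N`` the number of null replicates at least as extreme as the
observed accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import stats as sps

from .datatypes import FrameDataset
from .detector import LotoEngine


@dataclass
class PermutationResult:
    observed: float               # percent
    null_accuracies: np.ndarray   # percent, length n_perm
    n_perm: int
    seed: int
    strict: bool = False          # if True, N counts null > observed instead of >=
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.null_accuracies = np.asarray(self.null_accuracies, dtype=float)
        if len(self.null_accuracies) != self.n_perm:
            raise ValueError("null vector length must equal n_perm")
        if not 0 < self.p_value <= 1:
            raise AssertionError("p-value invariant violated")

    @property
    def n_extreme(self) -> int:
        if self.strict:
            return int(np.sum(self.null_accuracies > self.observed))
        return int(np.sum(self.null_accuracies >= self.observed))

    @property
    def p_value(self) -> float:
        return (self.n_extreme + 1) / (self.n_perm + 1)


def _half_flip(n_trials: int, rng: np.random.Generator) -> np.ndarray:
    """+/-1 flip vector reversing a random floor(n/2)-subset of trials."""
    flip = np.ones(n_trials)
    flip[rng.choice(n_trials, size=n_trials // 2, replace=False)] = -1.0
    return flip


def permutation_test_cv(
    frames: FrameDataset,
    n_perm: int = 10_000,
    seed: int = 0,
    strict: bool = False,
    engine: LotoEngine | None = None,
) -> PermutationResult:
    """Trial-wise permutation test of the LOTO-CV mean accuracy.

    Every replicate reverses the labels of a random half of the trials and
    reruns the full leave-one-trial-out cross-validation.  ``n_perm`` is
    10,000 by default; use a few hundred for desk-scale runs.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    eng = engine if engine is not None else LotoEngine(frames)
    if len(eng.trials) < 4:
        raise ValueError("permutation test needs >= 4 trials")
    observed = float(np.mean(eng.run()))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = np.mean(eng.run(flip=_half_flip(len(eng.trials), rng)))
    return PermutationResult(
        observed=observed, null_accuracies=null, n_perm=n_perm, seed=seed, strict=strict,
        meta={"kind": "cv", "n_trials": len(eng.trials)},
    )


def permutation_test_transfer(
    outputs: np.ndarray,
    labels: np.ndarray,
    trial_ids: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    strict: bool = False,
) -> PermutationResult:
    """Permutation test for a fixed (already-trained) model.

    Only the validation labels are shuffled: each replicate reverses the
    labels of a random half of the target trials; the model outputs are
    untouched, so a reversed trial's accuracy becomes ``100 - acc``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    outputs = np.asarray(outputs, dtype=float)
    labels = np.asarray(labels)
    trial_ids = np.asarray(trial_ids)
    dec = np.where(outputs >= 0, 1, -1)
    trials = np.unique(trial_ids)
    per_trial = np.array([100.0 * np.mean(dec[trial_ids == t] == labels[trial_ids == t]) for t in trials])
    observed = float(per_trial.mean())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        flip = _half_flip(len(trials), rng)
        null[i] = np.mean(np.where(flip > 0, per_trial, 100.0 - per_trial))
    return PermutationResult(
        observed=observed, null_accuracies=null, n_perm=n_perm, seed=seed, strict=strict,
        meta={"kind": "transfer", "n_trials": len(trials)},
    )


class ComparisonResult(NamedTuple):
    p_value: float
    degenerate: bool = False


def compare_paired(a, b, alternative: str = "greater") -> ComparisonResult:
    """One-sided Wilcoxon signed-rank test on paired per-trial accuracies.

    ``alternative='greater'`` tests whether ``a`` exceeds ``b``.  Zero
    differences are dropped; if every difference is zero the comparison is
    degenerate and p = 1 is reported with a flag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diff = a - b
    if np.all(diff == 0):
        return ComparisonResult(1.0, degenerate=True)
    p = sps.wilcoxon(diff, alternative=alternative, zero_method="wilcox").pvalue
    return ComparisonResult(float(p))


def compare_unpaired(a, b, alternative: str = "greater") -> ComparisonResult:
    """One-sided Wilcoxon rank-sum (Mann-Whitney U) test on independent
    samples; exact distribution at small n, normal approximation with
    ties/large n."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("samples must be non-empty")
    p = sps.mannwhitneyu(a, b, alternative=alternative, method="auto").pvalue
    return ComparisonResult(float(p))


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni-adjusted p-values (helper; not applied by default)."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(p * len(p), 1.0)
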