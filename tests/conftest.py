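import numpy as np
import pytest

from ecogvad.datatypes import FrameDataset
from ecogvad.pipeline import preprocess_recording
from ecogvad.synthetic import (
    ParadigmConfig,
    make_paradigm,
    make_profile,
    synthesize_ecog,
)


@pytest.fixture(scope="session")
def sim_bundle():
    """One shared synthetic session: motor/temporal/null electrodes,
    10 trials per speech mode.  CAR and notch are exercised in their own
    unit tests; the shared bundle keeps the generative signal clean."""
    cfg = ParadigmConfig(n_trials_per_mode=10)
    trials, gt = make_paradigm(cfg, seed=11)
    profiles = [
        make_profile("M1", "motor", grid="GA"),
        make_profile("T1", "temporal", grid="GB"),
        make_profile("O1", "other", grid="GC"),
    ]
    rec = synthesize_ecog(trials, gt, profiles, seed=12)
    env, _ = preprocess_recording(rec, car=False, notch=False)
    return {"cfg": cfg, "trials": trials, "gt": gt, "rec": rec, "env": env}


def make_feature_frames(
    rng,
    n_trials=12,
    frames_per_trial=16,
    n_features=21,
    signal=0.0,
    signal_features=(0,),
    frame_rate=32.0,
):
    """Feature-level frame dataset: iid Gaussian features with an optional
    label-aligned mean shift on selected features.  Balanced per trial."""
    n = n_trials * frames_per_trial
    half = frames_per_trial // 2
    labels = np.tile(np.r_[np.ones(half), -np.ones(frames_per_trial - half)], n_trials).astype(int)
    X = rng.standard_normal((n, n_features))
    for j in signal_features:
        X[:, j] += signal * labels
    return FrameDataset(
        X=X,
        times=np.arange(n) / frame_rate,
        trial_ids=np.repeat(np.arange(n_trials), frames_per_trial),
        labels=labels,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
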