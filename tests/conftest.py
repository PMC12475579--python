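import numpy as np
import pytest

from mupool import lowdim, preprocess, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def exact_corr():
    """Factory: Gaussian data whose *sample* correlation equals R exactly.

    Draw, empirically whiten (sample correlation -> identity), then color
    with chol(R); closed-form eigen/KMO oracles then hold to float precision.
    """

    def make(R: np.ndarray, n: int = 2000, seed: int = 0) -> np.ndarray:
        rng = np.random.default_rng(seed)
        c = R.shape[0]
        X = rng.standard_normal((n, c))
        X -= X.mean(axis=0)
        cov = X.T @ X / n
        X = X @ np.linalg.cholesky(np.linalg.inv(cov))
        return X @ np.linalg.cholesky(np.asarray(R, dtype=float)).T

    return make


def equicorrelated(c: int, r: float) -> np.ndarray:
    R = np.full((c, c), r)
    np.fill_diagonal(R, 1.0)
    return R


def preprocess_trial(trial, window_s):
    """Standard pipeline for one trial: binarize -> smooth -> detrend/z-score."""
    spikes = preprocess.binarize(trial.trains, *window_s)
    return preprocess.detrend_standardize(preprocess.smooth_rates(spikes))


@pytest.fixture(scope="session")
def single_input_cohort():
    """Default-condition 3-trial cohort with one shared input (seed 42)."""
    return synthetic.generate_cohort(n_trials=3, seed=42)


@pytest.fixture(scope="session")
def single_input_matrices(single_input_cohort):
    sim = single_input_cohort
    return [
        preprocess_trial(t, sim.analysis_window_s) for t in sim.cohort.trials
    ]
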