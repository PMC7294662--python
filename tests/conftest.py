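import warnings

import numpy as np
import pytest

import cofracnet as cn
from cofracnet import preprocess as pre


@pytest.fixture(scope="session")
def small_truth():
    """Ten disjoint complexes among 60 proteins, no rewiring."""
    return cn.generate_complex_truth(60, 10, (3, 4), 0.0, seed=1)


@pytest.fixture(scope="session")
def zero_noise_matrices(small_truth):
    config = cn.SimulationConfig(
        n_proteins=60, noise_sd=0.0, missing_rate=0.0, spike_rate=0.0, seed=2
    )
    matrices, spikes = cn.simulate_chromatograms(small_truth, config)
    return matrices, spikes


@pytest.fixture(scope="session")
def noisy_run():
    """One default-noise simulation shared by feature/classifier tests."""
    truth = cn.generate_complex_truth(60, 10, (3, 4), 0.0, seed=10)
    config = cn.SimulationConfig(n_proteins=60, seed=100)
    matrices, spikes = cn.simulate_chromatograms(truth, config)
    return truth, matrices, spikes


def build_channel_model(truth, matrices, channel, seed=0):
    """Preprocess one channel end to end and fit the pair classifier."""
    from cofracnet import features as feat
    from cofracnet import inference as inf

    per_rep = {}
    for m in matrices:
        if m.channel != channel:
            continue
        cleaned = pre.clean_matrix(m)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cleaned = cn.remove_outliers(cleaned, cn.detect_outliers(cleaned))
        smoothed = pre.smooth_matrix(cleaned)
        fits, _ = pre.fit_matrix(smoothed)
        per_rep[m.replicate] = feat.compute_pair_features(cleaned, smoothed, fits)
    table = feat.assemble_feature_table(per_rep)
    universe = set(table.index.get_level_values(0)) | set(
        table.index.get_level_values(1)
    )
    gold = inf.build_gold_standard(truth.complexes, universe)
    return inf.CoComplexModel(table, gold).fit(seed=seed)


@pytest.fixture(scope="session")
def fitted_medium(noisy_run):
    truth, matrices, _ = noisy_run
    return truth, build_channel_model(truth, matrices, "medium", seed=0)


def random_missing(rng, values, rate):
    out = values.astype(float).copy()
    out[rng.random(out.shape) < rate] = np.nan
    return out
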