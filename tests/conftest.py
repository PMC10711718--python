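import numpy as np
import pytest

from betaburst import (DetectionConfig, SimConfig, compute_psd, detect_epochs,
                       find_bands, generate_dataset, group_periodic_mean,
                       parameterize)


def sparse_config(**overrides) -> SimConfig:
    """Sparse, high-SNR burst process: individually resolvable events.

    Used by recovery-style tests; the dense default process is exercised by
    the rhythm-statistics tests.
    """
    params = dict(
        n_trials=30, n_participants=1, epoch_phases=("start",),
        channels=["C3_1", "C4_1"], burst_base_rate=0.6, refractory=0.3,
        burst_amplitude_mean=18.0, burst_amplitude_sd=2.0,
        burst_duration_mean=5.0, burst_duration_sd=0.5, seed=7,
    )
    params.update(overrides)
    return SimConfig(**params)


@pytest.fixture(scope="session")
def sparse_dataset():
    cfg = sparse_config()
    epochs, truth = generate_dataset(cfg)
    return cfg, epochs, truth


@pytest.fixture(scope="session")
def spectral_model(sparse_dataset):
    _, epochs, _ = sparse_dataset
    psd = compute_psd(epochs)
    models = [parameterize(psd, channel=ci) for ci in range(epochs.n_channels)]
    group = group_periodic_mean(models)
    bands = find_bands(group)
    beta = next(b for b in bands if b.label == "beta")
    return group, beta


@pytest.fixture(scope="session")
def detection_products(sparse_dataset, spectral_model):
    cfg, epochs, truth = sparse_dataset
    group, beta = spectral_model
    catalog, waveforms = detect_epochs(
        epochs, group, DetectionConfig(band=beta), window_samples=74,
        channels=["C3_1", "C4_1"])
    return catalog, waveforms


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
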