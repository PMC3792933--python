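"""Shared fixtures. Heavy end-to-end runs are session-scoped and reused."""
from __future__ import annotations

import numpy as np
import pytest

from dcespect.phantom import PhantomConfig, simulate_study, noise_sd_for_snr
from dcespect.pipeline import analyze_study


def small_config(**kw) -> PhantomConfig:
    """Quick phantom for unit tests (~1000 tumor voxels)."""
    defaults = dict(
        grid_shape=(28, 28, 12),
        voxel_size_mm=(0.4, 0.4, 0.8),
        tumor_semiaxes_mm=(3.2, 2.8, 3.0),
        seed=0,
    )
    defaults.update(kw)
    return PhantomConfig(**defaults)


@pytest.fixture(scope="session")
def noiseless_run():
    """Default-size noiseless study plus its full analysis (criterion 2)."""
    cfg = PhantomConfig(seed=1, noise_sd=0.0, spect_counts_per_kbq=0.0)
    study = simulate_study(cfg)
    result = analyze_study(study, dataset_id="noiseless")
    return study, result


@pytest.fixture(scope="session")
def snr20_run():
    """Default-size study at peak-enhancement SNR 20 (criterion 3 gate check)."""
    sd = noise_sd_for_snr(PhantomConfig(seed=2), 20.0)
    cfg = PhantomConfig(seed=2, noise_sd=sd)
    study = simulate_study(cfg)
    result = analyze_study(study, dataset_id="snr20")
    return study, result


@pytest.fixture(scope="session")
def four_dataset_runs():
    """Four default-seed studies through the full pipeline (criterion 7)."""
    out = []
    for seed in (1, 2, 3, 4):
        study = simulate_study(PhantomConfig(seed=seed))
        out.append((study, analyze_study(study, dataset_id=f"d{seed}")))
    return out


@pytest.fixture(scope="session")
def small_study():
    study = simulate_study(small_config(seed=5))
    return study


@pytest.fixture(scope="session")
def small_run(small_study):
    return small_study, analyze_study(small_study, dataset_id="small")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
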