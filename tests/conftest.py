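import numpy as np
import pytest

from stillsmerge.pipeline import apply_partiality
from stillsmerge.simulate import SimulationConfig, generate_dataset


def dense_config(**kw) -> SimulationConfig:
    """Desk-scale recovery conditions: typical-crystal mosaicity and a broader
    SASE band give the pairwise-overlap density that the experimental regime
    reaches through sheer image numbers."""
    base = dict(mosaicity_deg=0.3, beam_sigma=0.003)
    base.update(kw)
    return SimulationConfig(**base)


def correct_with_truth(images, truth, cutoff: float = 0.3) -> None:
    """Apply the partiality correction using the generator's true per-pulse
    mean wavelengths (isolates downstream stages from refinement)."""
    cfg = truth.config
    for im, mu in zip(images, truth.mus):
        im.mu_estimate = mu
        apply_partiality(im, cfg.beam_sigma, cfg.rlp, cutoff)


@pytest.fixture(scope="session")
def small_dataset():
    """40 noiseless stills, half reindexed, dense desk conditions, corrected."""
    cfg = dense_config()
    images, truth = generate_dataset(40, reindex_fraction=0.5, seed=11, config=cfg)
    correct_with_truth(images, truth)
    return images, truth


@pytest.fixture(scope="session")
def default_regime_images():
    """A few stills under the experimental regime (mosaicity 0.03 deg)."""
    cfg = SimulationConfig()
    images, truth = generate_dataset(6, reindex_fraction=0.0, seed=3, config=cfg)
    return images, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
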