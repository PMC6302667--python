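"""Shared fixtures: small synthetic systems and a quickly trained model.

Everything is generated at test time from seeds; no data files.
"""

import numpy as np
import pytest

from foldcvae.cvae import CVAEHyperparams, build_model, train
from foldcvae.featurize import compute_contact_maps, pad_maps, split_dataset
from foldcvae.synthetic import (
    StateSpec,
    SyntheticConfig,
    generate_folding_trajectory,
    preset_config,
)

# smallest architecture the hyperparameter bounds allow: fast tests
TINY_HP = dict(n_conv_layers=2, n_filters=16, kernel=3, n_dense=32,
               latent_dim=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def two_state_config():
    return SyntheticConfig(
        n_residues=21, n_frames=600,
        states=(StateSpec("folded", 0.95, 0.5),
                StateSpec("unfolded", 0.1, 0.5)),
        noise_sd=0.3, switch_prob=0.2, seed=77)


@pytest.fixture(scope="session")
def two_state_traj(two_state_config):
    return generate_folding_trajectory(two_state_config)


@pytest.fixture(scope="session")
def misfolded_traj():
    cfg = preset_config("fs21-misfolded", n_frames=600, noise_sd=0.3, seed=5)
    return generate_folding_trajectory(cfg)


@pytest.fixture(scope="session")
def two_state_maps(two_state_traj):
    return pad_maps(compute_contact_maps(two_state_traj.frames))


@pytest.fixture(scope="session")
def two_state_split(two_state_maps):
    return split_dataset(two_state_maps.n_frames, mode="contiguous")


@pytest.fixture(scope="session")
def trained_tiny_model(two_state_maps, two_state_split):
    """A small CVAE trained briefly on the two-state system; enough for
    reconstruction/embedding behaviour to be meaningful."""
    hp = CVAEHyperparams(**TINY_HP, epochs=8)
    model = build_model(hp, (two_state_maps.size,) * 2, seed=3)
    train(model, two_state_maps, two_state_split, seed=3)
    return model
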