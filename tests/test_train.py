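"""Training contracts: determinism, the L = E_r + E_l identity,
convergence, encode/decode behaviour, checkpointing, hyperparameter
search, and cross-trajectory transfer."""

import numpy as np
import pytest

from foldcvae.cvae import (
    CVAEHyperparams,
    HYPERPARAM_BOUNDS,
    build_model,
    decode,
    encode,
    hyperparameter_search,
    load_model,
    save_model,
    train,
    transfer_project,
)
from foldcvae.errors import ConfigurationError, DataError
from foldcvae.featurize import compute_contact_maps, pad_maps, split_dataset
from foldcvae.synthetic import generate_paired_trajectories
from tests.conftest import TINY_HP


def _weight_snapshot(model):
    return [p.copy() for layer in model.layers for p in layer.params.values()]


class TestArchitecture:
    def test_default_model_on_24x24(self):
        model = build_model(CVAEHyperparams(), (24, 24))
        assert model.hyperparams.latent_dim == 3
        x = np.zeros((2, 24, 24), dtype=np.float32)
        mu, lv = model._encode_batch(x)
        assert mu.shape == (2, 3) and lv.shape == (2, 3)
        out = decode(model, np.zeros((2, 3)))
        assert out.shape == (2, 24, 24)

    def test_lower_bound_latent_dim_valid(self):
        hp = CVAEHyperparams(latent_dim=2)
        model = build_model(hp, (24, 24))
        assert decode(model, np.zeros((1, 2))).shape == (1, 24, 24)

    @pytest.mark.parametrize("field,value", [
        ("n_conv_layers", 5), ("n_conv_layers", 0), ("n_filters", 126),
        ("n_filters", 15), ("kernel", 8), ("n_dense", 101),
        ("latent_dim", 1), ("latent_dim", 17)])
    def test_out_of_bounds_hyperparams_rejected(self, field, value):
        with pytest.raises(ConfigurationError):
            CVAEHyperparams(**{field: value})

    def test_incompatible_input_size_reports_smallest_fix(self):
        with pytest.raises(ConfigurationError, match="24"):
            build_model(CVAEHyperparams(), (21, 21))


class TestTraining:
    def test_zero_epochs_is_noop(self, two_state_maps, two_state_split):
        hp = CVAEHyperparams(**TINY_HP, epochs=0)
        model = build_model(hp, (two_state_maps.size,) * 2, seed=0)
        before = _weight_snapshot(model)
        train(model, two_state_maps, two_state_split, seed=0)
        after = _weight_snapshot(model)
        assert all(np.array_equal(a, b) for a, b in zip(before, after))
        assert len(model.loss_trace) == 0

    def test_same_seed_gives_identical_traces(self, two_state_maps,
                                              two_state_split):
        traces = []
        for _ in range(2):
            hp = CVAEHyperparams(**TINY_HP, epochs=2)
            model = build_model(hp, (two_state_maps.size,) * 2, seed=9)
            train(model, two_state_maps, two_state_split, seed=9)
            traces.append(model.loss_trace)
        assert traces[0].train_total == traces[1].train_total
        assert traces[0].val_total == traces[1].val_total

    def test_total_is_sum_of_parts_each_epoch(self, trained_tiny_model):
        tr = trained_tiny_model.loss_trace
        for total, recon, latent in zip(tr.train_total, tr.train_recon,
                                        tr.train_latent):
            assert total == pytest.approx(recon + latent, rel=1e-6)
            assert latent >= 0
        for total, recon, latent in zip(tr.val_total, tr.val_recon,
                                        tr.val_latent):
            assert total == pytest.approx(recon + latent, rel=1e-6)

    def test_loss_decreases_on_synthetic_data(self, trained_tiny_model):
        tr = trained_tiny_model.loss_trace
        assert tr.train_total[-1] < tr.train_total[0]

    def test_empty_training_set_rejected(self, two_state_maps):
        split = split_dataset(two_state_maps.n_frames)
        split.train_idx = np.array([], dtype=np.int64)
        hp = CVAEHyperparams(**TINY_HP, epochs=1)
        model = build_model(hp, (two_state_maps.size,) * 2)
        with pytest.raises(ConfigurationError):
            train(model, two_state_maps, split, seed=0)

    @pytest.mark.parametrize("optimizer", ["rmsprop", "adam", "adamax",
                                           "adagrad"])
    def test_all_four_optimizers_step(self, optimizer, two_state_maps,
                                      two_state_split):
        hp = CVAEHyperparams(**TINY_HP, epochs=1, optimizer=optimizer)
        model = build_model(hp, (two_state_maps.size,) * 2, seed=2)
        before = _weight_snapshot(model)
        train(model, two_state_maps, two_state_split, seed=2)
        after = _weight_snapshot(model)
        assert any(not np.array_equal(a, b) for a, b in zip(before, after))
        assert np.isfinite(model.loss_trace.train_total[0])


class TestEncodeDecode:
    def test_decode_strictly_inside_unit_interval(self, trained_tiny_model,
                                                  rng):
        z = rng.normal(size=(16, 3))
        out = decode(trained_tiny_model, z)
        assert out.min() > 0.0 and out.max() < 1.0

    def test_duplicated_frames_get_identical_mu(self, trained_tiny_model,
                                                two_state_maps):
        x = two_state_maps.as_float()[:1]
        dup = np.repeat(x, 4, axis=0)
        emb = encode(trained_tiny_model, dup)
        assert np.array_equal(emb.mu[0], emb.mu[1])
        assert np.array_equal(emb.mu[0], emb.mu[3])

    def test_reparameterization_identity(self, trained_tiny_model,
                                         two_state_maps):
        emb = encode(trained_tiny_model, two_state_maps, seed=5)
        eps = (emb.z - emb.mu) / np.exp(0.5 * emb.log_var)
        expected = np.random.default_rng(5).standard_normal(emb.mu.shape)
        assert np.allclose(eps, expected)

    def test_trained_model_reconstructs_own_frames(self, trained_tiny_model,
                                                   two_state_maps,
                                                   two_state_split):
        n = two_state_maps.n_residues
        x = two_state_maps.as_float()[two_state_split.test_idx]
        emb = encode(trained_tiny_model, x)
        f = decode(trained_tiny_model, emb.mu)
        correct = ((f[:, :n, :n] > 0.5) ==
                   (x[:, :n, :n] > 0.5)).mean()
        assert correct >= 0.88

    def test_latent_separates_states_for_kmeans(self, trained_tiny_model,
                                                two_state_maps,
                                                two_state_traj):
        from sklearn.cluster import KMeans
        emb = encode(trained_tiny_model, two_state_maps)
        labels = KMeans(n_clusters=2, random_state=0,
                        n_init=10).fit_predict(emb.mu)
        truth = (two_state_traj.labels == "folded").astype(int)
        purity = max((labels == truth).mean(), (labels != truth).mean())
        assert purity >= 0.90


class TestCheckpoint:
    def test_round_trip_preserves_everything(self, trained_tiny_model,
                                             two_state_maps, tmp_path):
        path = tmp_path / "model.ckpt.npz"
        save_model(trained_tiny_model, path)
        back = load_model(path)
        assert back.hyperparams == trained_tiny_model.hyperparams
        assert back.trained_epochs == trained_tiny_model.trained_epochs
        assert back.loss_trace.train_total == \
            trained_tiny_model.loss_trace.train_total
        x = two_state_maps.as_float()[:8]
        a = encode(trained_tiny_model, x).mu
        b = encode(back, x).mu
        assert np.array_equal(a, b)


class TestHyperparameterSearch:
    def test_degenerate_box_returns_single_point(self, two_state_maps,
                                                 two_state_split):
        point = {"n_conv_layers": (2, 2), "n_filters": (16, 16),
                 "kernel": (3, 3), "n_dense": (32, 32), "latent_dim": (3, 3)}
        out = hyperparameter_search(two_state_maps, two_state_split,
                                    bounds=point, budget=1, seed=0, epochs=1)
        assert len(out) == 1
        hp, er = out[0]
        assert (hp.n_conv_layers, hp.n_filters, hp.kernel, hp.n_dense,
                hp.latent_dim) == (2, 16, 3, 32, 3)
        assert np.isfinite(er)

    def test_random_strategy_deterministic_per_seed(self, two_state_maps,
                                                    two_state_split):
        small = {"n_conv_layers": (1, 2), "n_filters": (16, 32),
                 "kernel": (2, 4), "n_dense": (32, 48), "latent_dim": (2, 4)}
        a = hyperparameter_search(two_state_maps, two_state_split,
                                  bounds=small, budget=3, seed=12, epochs=1)
        b = hyperparameter_search(two_state_maps, two_state_split,
                                  bounds=small, budget=3, seed=12, epochs=1)
        assert [hp for hp, _ in a] == [hp for hp, _ in b]
        assert [er for _, er in a] == [er for _, er in b]

    def test_bayesian_strategy_runs_and_is_seeded(self, two_state_maps,
                                                  two_state_split):
        small = {"n_conv_layers": (1, 2), "n_filters": (16, 32),
                 "kernel": (2, 4), "n_dense": (32, 48), "latent_dim": (2, 4)}
        a = hyperparameter_search(two_state_maps, two_state_split,
                                  bounds=small, budget=4, strategy="bayesian",
                                  seed=8, epochs=1)
        b = hyperparameter_search(two_state_maps, two_state_split,
                                  bounds=small, budget=4, strategy="bayesian",
                                  seed=8, epochs=1)
        assert len(a) == 4
        assert [hp for hp, _ in a] == [hp for hp, _ in b]
        assert [er for _, er in a] == sorted(er for _, er in a)

    def test_results_sorted_by_validation_error(self, two_state_maps,
                                                two_state_split):
        small = {"n_conv_layers": (1, 2), "n_filters": (16, 32),
                 "kernel": (2, 4), "n_dense": (32, 48), "latent_dim": (2, 4)}
        out = hyperparameter_search(two_state_maps, two_state_split,
                                    bounds=small, budget=4, seed=3, epochs=1)
        errs = [er for _, er in out]
        assert errs == sorted(errs)


class TestTransfer:
    def test_same_maps_give_same_embedding(self, trained_tiny_model,
                                           two_state_maps):
        emb, frac = transfer_project(trained_tiny_model, two_state_maps)
        direct = encode(trained_tiny_model, two_state_maps)
        assert np.array_equal(emb.mu, direct.mu)
        assert 0.0 <= frac <= 1.0

    def test_independent_trajectory_on_par(self, trained_tiny_model,
                                           two_state_config, two_state_maps,
                                           two_state_split):
        from foldcvae.cvae import misprediction_of
        _, traj_b = generate_paired_trajectories(two_state_config, seed2=1001)
        maps_b = pad_maps(compute_contact_maps(traj_b.frames),
                          two_state_maps.size)
        _, frac_b = transfer_project(trained_tiny_model, maps_b)
        held_out = misprediction_of(trained_tiny_model, two_state_maps,
                                    two_state_split.test_idx)
        assert frac_b <= 1.5 * held_out

    def test_wrong_residue_count_rejected(self, trained_tiny_model):
        from foldcvae.synthetic import preset_config, generate_folding_trajectory
        cfg = preset_config("bba28", n_frames=12, seed=0)
        maps = pad_maps(compute_contact_maps(
            generate_folding_trajectory(cfg).frames))
        with pytest.raises(DataError):
            transfer_project(trained_tiny_model, maps)
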