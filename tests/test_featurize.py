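"""Contact-map featurization: brute-force oracles, rigid-motion
invariance, padding round trips, and dataset splitting."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from foldcvae.errors import ConfigurationError, DataError
from foldcvae.featurize import (
    ContactMapSeries,
    TrajectoryFrames,
    compute_contact_maps,
    default_padded_size,
    load_maps,
    load_trajectory,
    pad_maps,
    save_maps,
    split_dataset,
    unpad_maps,
)
from foldcvae.synthetic import generate_folding_trajectory, preset_config, write_trajectory


def brute_force_maps(coords, cutoff):
    """Independent O(N^2) scalar-loop oracle."""
    f, n = coords.shape[:2]
    out = np.zeros((f, n, n), dtype=np.uint8)
    for t in range(f):
        for i in range(n):
            for j in range(n):
                d = np.sqrt(((coords[t, i] - coords[t, j]) ** 2).sum())
                out[t, i, j] = 1 if d < cutoff else 0
    return out


class TestContactMaps:
    def test_matches_brute_force_on_random_frames(self, rng):
        coords = rng.uniform(-15, 15, size=(100, 21, 3))
        frames = TrajectoryFrames(coords=coords)
        maps = compute_contact_maps(frames, cutoff=8.0)
        assert np.array_equal(maps.maps, brute_force_maps(coords, 8.0))

    def test_rigid_motion_invariance_bitwise(self, rng):
        coords = rng.uniform(-15, 15, size=(100, 21, 3))
        base = compute_contact_maps(TrajectoryFrames(coords=coords))
        rots = Rotation.random(100, rng=np.random.default_rng(9))
        shifts = rng.uniform(-50, 50, size=(100, 1, 3))
        moved = np.einsum("fij,fnj->fni", rots.as_matrix(), coords) + shifts
        out = compute_contact_maps(TrajectoryFrames(coords=moved))
        assert np.array_equal(base.maps, out.maps)

    def test_cutoff_is_strict_less_than(self):
        # pair at 7.99 in contact, pair at exactly 8.00 not
        coords = np.array([[[0, 0, 0], [7.99, 0, 0], [7.99 + 8.0, 0, 0]]])
        maps = compute_contact_maps(TrajectoryFrames(coords=coords)).maps[0]
        assert maps[0, 1] == 1 and maps[1, 0] == 1
        assert maps[1, 2] == 0 and maps[2, 1] == 0

    def test_collinear_spaced_atoms_give_identity(self):
        coords = np.array([[[0, 0, 0], [10, 0, 0], [20, 0, 0]]], dtype=float)
        maps = compute_contact_maps(TrajectoryFrames(coords=coords)).maps[0]
        assert np.array_equal(maps, np.eye(3, dtype=np.uint8))

    def test_symmetric_unit_diagonal(self, rng):
        coords = rng.uniform(-10, 10, size=(5, 12, 3))
        maps = compute_contact_maps(TrajectoryFrames(coords=coords)).maps
        assert np.array_equal(maps, maps.transpose(0, 2, 1))
        assert (maps[:, np.arange(12), np.arange(12)] == 1).all()

    def test_rejects_bad_inputs(self, rng):
        frames = TrajectoryFrames(coords=rng.random((2, 5, 3)))
        with pytest.raises(ConfigurationError):
            compute_contact_maps(frames, cutoff=0.0)
        with pytest.raises(DataError):
            TrajectoryFrames(coords=np.full((1, 5, 3), np.nan))


class TestPadding:
    def test_pad_preserves_block_and_zeroes_border(self, rng):
        coords = rng.uniform(-10, 10, size=(4, 21, 3))
        maps = compute_contact_maps(TrajectoryFrames(coords=coords))
        padded = pad_maps(maps, 24)
        assert padded.size == 24 and padded.pad == 3
        assert np.array_equal(padded.maps[:, :21, :21], maps.maps)
        assert padded.maps[:, 21:, :].sum() == 0
        assert padded.maps[:, :, 21:].sum() == 0

    def test_pad_to_own_size_is_identity(self, rng):
        coords = rng.uniform(-10, 10, size=(3, 24, 3))
        maps = compute_contact_maps(TrajectoryFrames(coords=coords))
        assert np.array_equal(pad_maps(maps, 24).maps, maps.maps)

    def test_unpad_round_trip(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 30))
            raw = (rng.random((2, n, n)) > 0.5).astype(np.uint8)
            raw |= raw.transpose(0, 2, 1)
            raw[:, np.arange(n), np.arange(n)] = 1
            series = ContactMapSeries(maps=raw, n_residues=n, cutoff=8.0)
            target = default_padded_size(n)
            assert np.array_equal(unpad_maps(pad_maps(series, target)).maps, raw)

    def test_default_target_is_multiple_of_four(self):
        assert default_padded_size(21) == 24
        assert default_padded_size(28) == 28
        assert default_padded_size(35) == 36

    def test_pad_below_n_rejected(self, rng):
        coords = rng.uniform(-10, 10, size=(1, 21, 3))
        maps = compute_contact_maps(TrajectoryFrames(coords=coords))
        with pytest.raises(ConfigurationError):
            pad_maps(maps, 20)


class TestSplit:
    def test_default_sizes_80_10_10(self):
        split = split_dataset(10)
        assert (len(split.train_idx), len(split.test_idx),
                len(split.val_idx)) == (8, 1, 1)

    def test_partition_property_random_mode(self):
        a = split_dataset(1000, mode="random", seed=4)
        b = split_dataset(1000, mode="random", seed=4)
        for x, y in zip((a.train_idx, a.test_idx, a.val_idx),
                        (b.train_idx, b.test_idx, b.val_idx)):
            assert np.array_equal(x, y)
        union = np.sort(np.concatenate([a.train_idx, a.test_idx, a.val_idx]))
        assert np.array_equal(union, np.arange(1000))

    def test_contiguous_blocks(self):
        s = split_dataset(100, mode="contiguous")
        assert np.array_equal(s.train_idx, np.arange(80))
        assert np.array_equal(s.test_idx, np.arange(80, 90))
        assert np.array_equal(s.val_idx, np.arange(90, 100))

    @pytest.mark.parametrize("fractions", [(1.0, 0.0, 0.0), (0.5, 0.5, 0.1),
                                           (0.8, -0.1, 0.3)])
    def test_degenerate_fractions_rejected(self, fractions):
        with pytest.raises(ConfigurationError):
            split_dataset(10, fractions=fractions)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ConfigurationError):
            split_dataset(9)


class TestIO:
    def test_hdf5_cache_round_trip(self, two_state_maps, tmp_path):
        path = tmp_path / "maps.h5"
        save_maps(two_state_maps, path)
        back = load_maps(path)
        assert np.array_equal(back.maps, two_state_maps.maps)
        assert back.cutoff == two_state_maps.cutoff
        assert back.pad == two_state_maps.pad

    def test_pdb_dcd_round_trip(self, tmp_path):
        cfg = preset_config("fs21", n_frames=25, seed=8)
        traj = generate_folding_trajectory(cfg)
        paths = write_trajectory(traj, tmp_path / "sim")
        back = load_trajectory(paths["topology"], paths["trajectory"])
        assert back.n_frames == 25 and back.n_atoms == 21
        # DCD stores float32; PDB coordinates have 1e-3 precision
        assert np.abs(back.coords - traj.frames.coords).max() < 1e-2

    def test_single_frame_pdb(self, tmp_path):
        cfg = preset_config("fs21", n_frames=1, seed=8)
        traj = generate_folding_trajectory(cfg)
        paths = write_trajectory(traj, tmp_path / "sim")
        frames = load_trajectory(paths["native"])
        assert frames.n_frames == 1 and frames.n_atoms == 21

    def test_empty_selection_rejected(self, tmp_path):
        cfg = preset_config("fs21", n_frames=1, seed=8)
        paths = write_trajectory(generate_folding_trajectory(cfg), tmp_path / "s")
        with pytest.raises(ConfigurationError):
            load_trajectory(paths["native"], selection="name ZZ")

    def test_missing_file_rejected(self):
        with pytest.raises(FileNotFoundError):
            load_trajectory("/nonexistent/top.pdb")
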