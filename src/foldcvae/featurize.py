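"""Contact-map featurization of Cα trajectories.

A trajectory is reduced to per-frame Cα coordinates, converted to
symmetric binary contact maps (two atoms are in contact when their
Euclidean distance is strictly below a cutoff, 8 Å by default), padded to
a convolution-friendly square size, and partitioned into
train/test/validation index sets.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np

from .errors import ConfigurationError, DataError, FormatError

DEFAULT_CUTOFF = 8.0  # Å, strict "<"
DEFAULT_FRACTIONS = (0.8, 0.1, 0.1)

__all__ = [
    "TrajectoryFrames",
    "ContactMapSeries",
    "DatasetSplit",
    "load_trajectory",
    "compute_contact_maps",
    "pad_maps",
    "unpad_maps",
    "split_dataset",
    "default_padded_size",
    "save_maps",
    "load_maps",
]


@dataclass
class TrajectoryFrames:
    """Per-frame Cα positions in Å, shape (frames, N, 3)."""

    coords: np.ndarray
    frame_interval: float = 1.0
    source_id: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise DataError(f"coords must be (frames, N, 3), got {self.coords.shape}")
        if self.coords.shape[1] < 2:
            raise DataError("need at least 2 atoms per frame")
        if not np.isfinite(self.coords).all():
            raise DataError("non-finite coordinates in trajectory")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass
class ContactMapSeries:
    """Stack of symmetric binary contact maps, shape (frames, M, M).

    The top-left ``n_residues``×``n_residues`` block holds the real
    contacts (diagonal all 1); the remaining ``pad`` rows/columns are 0.
    """

    maps: np.ndarray
    n_residues: int
    cutoff: float
    pad: int = 0

    def __post_init__(self):
        self.maps = np.asarray(self.maps)
        if self.maps.ndim != 3 or self.maps.shape[1] != self.maps.shape[2]:
            raise DataError(f"maps must be (frames, M, M), got {self.maps.shape}")
        if self.maps.shape[1] != self.n_residues + self.pad:
            raise DataError("map size inconsistent with n_residues + pad")

    @property
    def n_frames(self) -> int:
        return self.maps.shape[0]

    @property
    def size(self) -> int:
        return self.maps.shape[1]

    def as_float(self, dtype=np.float32) -> np.ndarray:
        """Maps as continuous values in [0,1] for the model."""
        return self.maps.astype(dtype)


@dataclass
class DatasetSplit:
    train_idx: np.ndarray
    test_idx: np.ndarray
    val_idx: np.ndarray
    fractions: tuple = DEFAULT_FRACTIONS

    def __post_init__(self):
        self.train_idx = np.asarray(self.train_idx, dtype=np.int64)
        self.test_idx = np.asarray(self.test_idx, dtype=np.int64)
        self.val_idx = np.asarray(self.val_idx, dtype=np.int64)
        all_idx = np.concatenate([self.train_idx, self.test_idx, self.val_idx])
        if len(np.unique(all_idx)) != len(all_idx):
            raise DataError("split index sets overlap")

    @property
    def n_frames(self) -> int:
        return len(self.train_idx) + len(self.test_idx) + len(self.val_idx)


def load_trajectory(topology_path, coordinate_path=None,
                    selection: str = "name CA") -> TrajectoryFrames:
    """Read Cα coordinates (Å) from a topology (+ optional coordinate) file.

    Thin wrapper around MDAnalysis: any format it supports (PDB topology
    with DCD/XTC coordinates, or a multi-model PDB alone) works here.
    """
    import MDAnalysis as mda

    for path in filter(None, (topology_path, coordinate_path)):
        if not os.path.exists(path):
            raise FileNotFoundError(path)
    try:
        if coordinate_path is None:
            u = mda.Universe(str(topology_path))
        else:
            u = mda.Universe(str(topology_path), str(coordinate_path))
    except Exception as exc:  # noqa: BLE001 - normalise reader failures
        raise FormatError(f"could not read trajectory: {exc}") from exc
    atoms = u.select_atoms(selection)
    if atoms.n_atoms == 0:
        raise ConfigurationError(
            f"selection {selection!r} matches no atoms in {topology_path}")
    if atoms.n_atoms < 2:
        raise ConfigurationError("selection must resolve to at least 2 atoms")
    coords = np.array([atoms.positions.copy() for _ in u.trajectory],
                      dtype=np.float64)
    return TrajectoryFrames(coords=coords,
                            source_id=os.path.basename(str(topology_path)))


def compute_contact_maps(frames: TrajectoryFrames,
                         cutoff: float = DEFAULT_CUTOFF) -> ContactMapSeries:
    """Binary Cα–Cα contact maps: entry (i,j)=1 iff dist(i,j) < cutoff.

    Strict inequality at the cutoff; the diagonal is always 1 (self
    distance 0). Maps are invariant under rigid motion of each frame.
    """
    if cutoff <= 0:
        raise ConfigurationError(f"cutoff must be positive, got {cutoff}")
    x = frames.coords
    if not np.isfinite(x).all():
        raise DataError("non-finite coordinates")
    n_frames, n = x.shape[:2]
    maps = np.empty((n_frames, n, n), dtype=np.uint8)
    # chunked so the (chunk, N, N, 3) broadcast stays small
    chunk = max(1, int(2e7 // max(n * n, 1)))
    for s in range(0, n_frames, chunk):
        block = x[s:s + chunk]
        d2 = np.sum((block[:, :, None, :] - block[:, None, :, :]) ** 2, axis=-1)
        maps[s:s + chunk] = d2 < cutoff * cutoff
    return ContactMapSeries(maps=maps, n_residues=n, cutoff=cutoff, pad=0)


def default_padded_size(n_residues: int) -> int:
    """Smallest multiple of 4 that fits the protein (even, and divisible by
    the encoder's total downsampling factor of 4)."""
    return -(-n_residues // 4) * 4


def pad_maps(series: ContactMapSeries, target: int | None = None) -> ContactMapSeries:
    """Zero-pad maps on the bottom/right to ``target``×``target``."""
    n = series.n_residues
    if series.pad != 0:
        series = unpad_maps(series)
    if target is None:
        target = default_padded_size(n)
    if target < n:
        raise ConfigurationError(f"pad target {target} < n_residues {n}")
    if target == series.size:
        return series
    pad = target - n
    maps = np.zeros((series.n_frames, target, target), dtype=series.maps.dtype)
    maps[:, :n, :n] = series.maps
    return ContactMapSeries(maps=maps, n_residues=n, cutoff=series.cutoff, pad=pad)


def unpad_maps(series: ContactMapSeries) -> ContactMapSeries:
    n = series.n_residues
    return ContactMapSeries(maps=np.ascontiguousarray(series.maps[:, :n, :n]),
                            n_residues=n, cutoff=series.cutoff, pad=0)


def split_dataset(n_frames: int, fractions=DEFAULT_FRACTIONS,
                  mode: str = "contiguous", seed: int | None = None) -> DatasetSplit:
    """Partition frame indices into train/test/validation sets.

    ``|train| = floor(f_train * n)``; the remainder is split between test
    and validation proportionally to their fractions (for the default
    80/10/10 this is as even as possible, test taking any odd frame).
    Contiguous mode keeps temporal blocks together (less leakage between
    partitions); random mode shuffles frames first.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3:
        raise ConfigurationError("fractions must have 3 entries")
    if any(f <= 0 for f in fractions):
        raise ConfigurationError(f"fractions must all be positive, got {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError(f"fractions must sum to 1, got {fractions}")
    if mode not in ("contiguous", "random"):
        raise ConfigurationError(f"unknown split mode {mode!r}")
    if n_frames < 10:
        raise ConfigurationError(f"need at least 10 frames to split, got {n_frames}")

    n_train = int(np.floor(fractions[0] * n_frames))
    rem = n_frames - n_train
    n_test = int(np.ceil(rem * fractions[1] / (fractions[1] + fractions[2])))
    n_val = rem - n_test
    if min(n_train, n_test, n_val) < 1:
        raise ConfigurationError(
            f"split of {n_frames} frames with fractions {fractions} leaves an empty set")

    idx = np.arange(n_frames)
    if mode == "random":
        idx = np.random.default_rng(seed).permutation(n_frames)
    return DatasetSplit(train_idx=idx[:n_train],
                        test_idx=idx[n_train:n_train + n_test],
                        val_idx=idx[n_train + n_test:],
                        fractions=fractions)


def save_maps(series: ContactMapSeries, path) -> None:
    """Write a chunked HDF5 contact-map cache (/maps uint8 + metadata)."""
    with h5py.File(path, "w") as f:
        chunk = (min(256, max(1, series.n_frames)), series.size, series.size)
        dset = f.create_dataset("maps", data=series.maps.astype(np.uint8),
                                chunks=chunk, compression="gzip", shuffle=True)
        dset.attrs["cutoff"] = series.cutoff
        dset.attrs["n_residues"] = series.n_residues
        dset.attrs["pad"] = series.pad


def load_maps(path) -> ContactMapSeries:
    with h5py.File(path, "r") as f:
        if "maps" not in f:
            raise FormatError(f"{path} has no /maps dataset")
        dset = f["maps"]
        return ContactMapSeries(maps=dset[...],
                                n_residues=int(dset.attrs["n_residues"]),
                                cutoff=float(dset.attrs["cutoff"]),
                                pad=int(dset.attrs["pad"]))
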