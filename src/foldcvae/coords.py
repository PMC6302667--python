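"""Folding reaction coordinates: RMSD to the native state and the
fraction of native contacts Q.

RMSD uses the Kabsch procedure (centroid removal, optimal rotation from
an SVD with a determinant sign correction so only proper rotations are
allowed). Native contacts follow the ensemble definition: a Cα pair
(sequence separation ≥ ``min_separation``) is native when it is within
8 Å in at least 75% of the frames that lie within 1.1 Å RMSD of the
native structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .featurize import DEFAULT_CUTOFF, TrajectoryFrames

DEFAULT_RMSD_CUTOFF = 1.1     # Å, native-ensemble membership
DEFAULT_ENSEMBLE_FRACTION = 0.75
DEFAULT_MIN_SEPARATION = 3    # |i-j| >= 3: skip pairs in contact in any chain

__all__ = [
    "NativeReference",
    "ReactionCoordinates",
    "rmsd_to_native",
    "build_native_reference",
    "fraction_native_contacts",
    "compute_reaction_coordinates",
]


@dataclass
class NativeReference:
    """Native Cα coordinates plus the set of native contact pairs."""

    coords: np.ndarray                      # (N, 3) Å
    native_contacts: np.ndarray             # (P, 2) residue pairs, i < j
    rmsd_cutoff: float = DEFAULT_RMSD_CUTOFF
    ensemble_fraction: float = DEFAULT_ENSEMBLE_FRACTION
    contact_cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.native_contacts = np.asarray(self.native_contacts, dtype=np.int64)
        if self.native_contacts.size:
            if self.native_contacts.ndim != 2 or self.native_contacts.shape[1] != 2:
                raise DataError("native_contacts must be (P, 2)")
            n = self.coords.shape[0]
            if self.native_contacts.max() >= n or self.native_contacts.min() < 0:
                raise DataError("native contact index out of range")
        else:
            self.native_contacts = self.native_contacts.reshape(0, 2)

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]


@dataclass
class ReactionCoordinates:
    rmsd: np.ndarray   # per-frame Å
    q: np.ndarray      # per-frame fraction of native contacts, in [0, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(len(self.rmsd)),
                             "rmsd_A": self.rmsd, "q_native": self.q})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _as_coords(obj) -> np.ndarray:
    if isinstance(obj, TrajectoryFrames):
        return obj.coords
    if isinstance(obj, NativeReference):
        return obj.coords
    return np.asarray(obj, dtype=np.float64)


def rmsd_to_native(frames, native) -> np.ndarray:
    """Minimal Cα RMSD (Å) of each frame to the native structure.

    Both structures are centred at their centroids; the optimal rotation
    comes from the SVD of the cross-covariance with the usual det=+1
    correction, so reflections are never applied (a mirrored structure
    keeps a nonzero RMSD).
    """
    x = _as_coords(frames)
    y = _as_coords(native)
    single = x.ndim == 2
    if single:
        x = x[None]
    if y.ndim == 3:
        y = y[0]
    if x.shape[1:] != y.shape:
        raise DataError(f"atom-count mismatch: frames {x.shape[1]} vs native {y.shape[0]}")
    n = y.shape[0]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=0)
    if np.allclose(xc, 0) and np.allclose(yc, 0):
        warnings.warn("all-coincident coordinates; RMSD defined as 0", stacklevel=2)
        out = np.zeros(x.shape[0])
        return out[0] if single else out
    # Kabsch: E_min = sum|x|^2 + sum|y|^2 - 2*(s1 + s2 + d*s3), d = sign(det)
    h = np.einsum("fni,nj->fij", xc, yc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(np.einsum("fij,fjk->fik", u, vt)))
    s[:, -1] *= d
    e0 = (xc ** 2).sum(axis=(1, 2)) + (yc ** 2).sum()
    msd = np.maximum(e0 - 2.0 * s.sum(axis=1), 0.0) / n
    out = np.sqrt(msd)
    return float(out[0]) if single else out


def _contact_pairs_mask(n: int, min_separation: int) -> np.ndarray:
    """Candidate (i, j) pairs with j - i >= min_separation."""
    i, j = np.triu_indices(n, k=max(min_separation, 1))
    return np.stack([i, j], axis=1)


def build_native_reference(native_frame, ensemble: TrajectoryFrames | None = None,
                           rmsd_cutoff: float = DEFAULT_RMSD_CUTOFF,
                           ensemble_fraction: float = DEFAULT_ENSEMBLE_FRACTION,
                           contact_cutoff: float = DEFAULT_CUTOFF,
                           min_separation: int = DEFAULT_MIN_SEPARATION,
                           ) -> NativeReference:
    """Derive the native-contact set from an ensemble of conformations.

    Frames within ``rmsd_cutoff`` of the native structure form the native
    ensemble; a pair is a native contact when it satisfies the (strict)
    ``contact_cutoff`` rule in at least ``ensemble_fraction`` of those
    frames. With no ensemble — or one containing no near-native frame —
    the contacts of the native structure itself are used (with a warning
    in the degenerate-ensemble case). Pairs closer in sequence than
    ``min_separation`` are excluded: they are in contact in essentially
    any chain conformation and carry no folding signal.
    """
    native_xyz = _as_coords(native_frame)
    if native_xyz.ndim != 2:
        raise DataError("native_frame must be a single (N, 3) structure")
    n = native_xyz.shape[0]
    pairs = _contact_pairs_mask(n, min_separation)

    def contacts_of(frames_xyz: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(frames_xyz[:, pairs[:, 0]] - frames_xyz[:, pairs[:, 1]],
                           axis=-1)
        return d < contact_cutoff

    if ensemble is None:
        members = native_xyz[None]
    else:
        r = rmsd_to_native(ensemble, native_xyz)
        keep = r <= rmsd_cutoff
        if not keep.any():
            warnings.warn(
                "no ensemble frame within the RMSD cutoff of the native "
                "structure; falling back to the native frame's own contacts",
                stacklevel=2)
            members = native_xyz[None]
        else:
            members = ensemble.coords[keep]
    freq = contacts_of(members).mean(axis=0)
    native_pairs = pairs[freq >= ensemble_fraction]
    return NativeReference(coords=native_xyz, native_contacts=native_pairs,
                           rmsd_cutoff=rmsd_cutoff,
                           ensemble_fraction=ensemble_fraction,
                           contact_cutoff=contact_cutoff)


def fraction_native_contacts(frames, native: NativeReference) -> np.ndarray:
    """Per-frame Q = (native pairs in contact) / (total native pairs)."""
    if native.native_contacts.shape[0] == 0:
        raise ConfigurationError("native contact set is empty")
    x = _as_coords(frames)
    single = x.ndim == 2
    if single:
        x = x[None]
    if x.shape[1] != native.n_residues:
        raise DataError("atom-count mismatch between frames and native reference")
    i, j = native.native_contacts[:, 0], native.native_contacts[:, 1]
    d = np.linalg.norm(x[:, i] - x[:, j], axis=-1)
    q = (d < native.contact_cutoff).mean(axis=1)
    return float(q[0]) if single else q


def compute_reaction_coordinates(frames: TrajectoryFrames,
                                 native: NativeReference) -> ReactionCoordinates:
    return ReactionCoordinates(rmsd=rmsd_to_native(frames, native),
                               q=fraction_native_contacts(frames, native))
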