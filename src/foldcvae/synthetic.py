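"""Seeded synthetic folding trajectories with ground-truth state labels.

This is a statistical stand-in for real folding simulations, not a
physical model: there is no force field or integrator. The native state
is an ideal Cα α-helix (rise 1.5 Å, 100° per residue, radius 2.3 Å).
Each metastable state is one deterministic deformation of that helix:

* partially/fully unfolded states progressively extend the chain from
  the C-terminus (3.8 Å virtual bonds along a straight direction), so
  contacts are lost gradually from one end — the "gradual contact
  formation" pattern of real folding trajectories;
* misfolded states break the helix at a hinge and pack the two helical
  halves side by side: most native (local, helical) contacts survive,
  non-native inter-segment contacts appear, and the RMSD to the native
  state stays high — high Q together with high RMSD, the signature used
  to flag misfolded conformers.

Frames hop between states as a Markov chain whose stationary
distribution matches the configured occupancy weights; isotropic
Gaussian jitter models thermal fluctuation. Everything is reproducible
from the single config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .coords import DEFAULT_MIN_SEPARATION, _contact_pairs_mask
from .errors import ConfigurationError
from .featurize import DEFAULT_CUTOFF, TrajectoryFrames

HELIX_RISE = 1.5       # Å per residue along the axis
HELIX_TWIST = 100.0    # degrees per residue
HELIX_RADIUS = 2.3     # Å
CA_BOND = 3.8          # Å consecutive-Cα distance in the extended chain
Q_MATCH_TOL = 0.15     # achievable-q* tolerance before erroring

__all__ = [
    "StateSpec",
    "SyntheticConfig",
    "SyntheticTrajectory",
    "ideal_helix",
    "generate_folding_trajectory",
    "generate_paired_trajectories",
    "write_trajectory",
    "PRESETS",
    "preset_config",
]


@dataclass(frozen=True)
class StateSpec:
    """One metastable state: name, target fraction of native contacts q*,
    stationary occupancy weight, and whether it is a misfolded topology."""

    name: str
    q_star: float
    weight: float = 1.0
    is_misfolded: bool = False


@dataclass
class SyntheticConfig:
    n_residues: int = 21
    n_frames: int = 2000
    states: tuple = (
        StateSpec("folded", 0.95, 0.3),
        StateSpec("partial1", 0.7, 0.25),
        StateSpec("partial2", 0.4, 0.25),
        StateSpec("unfolded", 0.1, 0.2),
    )
    noise_sd: float = 0.3      # Å isotropic per-atom jitter
    switch_prob: float = 0.1   # per-frame probability of redrawing the state
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 8:
            raise ConfigurationError("n_residues must be at least 8")
        if self.n_frames < 0:
            raise ConfigurationError("n_frames must be nonnegative")
        if len(self.states) < 1:
            raise ConfigurationError("need at least one state")
        for s in self.states:
            if not (0.0 <= s.q_star <= 1.0):
                raise ConfigurationError(f"q* must be in [0,1], got {s.q_star}")
            if s.weight <= 0:
                raise ConfigurationError("occupancy weights must be positive")
        if not (0.0 <= self.switch_prob <= 1.0):
            raise ConfigurationError("switch_prob must be in [0,1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")


@dataclass
class SyntheticTrajectory:
    frames: TrajectoryFrames
    labels: np.ndarray            # per-frame state name
    native: np.ndarray            # (N, 3) native Cα coordinates
    state_coords: dict            # state name -> ideal (noise-free) coords
    config: SyntheticConfig


def ideal_helix(n_residues: int) -> np.ndarray:
    """Ideal α-helical Cα trace."""
    t = np.arange(n_residues)
    theta = np.deg2rad(HELIX_TWIST) * t
    return np.stack([HELIX_RADIUS * np.cos(theta),
                     HELIX_RADIUS * np.sin(theta),
                     HELIX_RISE * t], axis=1)


def _native_pair_set(native: np.ndarray,
                     min_separation: int = DEFAULT_MIN_SEPARATION) -> np.ndarray:
    pairs = _contact_pairs_mask(native.shape[0], min_separation)
    d = np.linalg.norm(native[pairs[:, 0]] - native[pairs[:, 1]], axis=-1)
    return pairs[d < DEFAULT_CUTOFF]


def _q_of(coords: np.ndarray, pairs: np.ndarray) -> float:
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=-1)
    return float((d < DEFAULT_CUTOFF).mean())


def _unfold_from_terminus(native: np.ndarray, first_unfolded: int) -> np.ndarray:
    """Keep residues [0, u) helical; extend the rest along +z with 3.8 Å steps."""
    n = native.shape[0]
    u = int(np.clip(first_unfolded, 1, n))
    out = native.copy()
    if u >= n:
        return out
    anchor = native[u - 1]
    steps = np.arange(1, n - u + 1)
    out[u:] = anchor + np.outer(steps * CA_BOND, np.array([0.0, 0.0, 1.0]))
    return out


def _misfold_hairpin(native: np.ndarray, hinge: int) -> np.ndarray:
    """Break the helix at ``hinge`` and pack the C-terminal half as an
    antiparallel helix alongside the N-terminal half."""
    n = native.shape[0]
    m = int(np.clip(hinge, 4, n - 4))
    out = native.copy()
    t = np.arange(n - m)
    theta = np.deg2rad(HELIX_TWIST) * t + np.pi
    z_top = native[m - 1, 2]
    out[m:] = np.stack([
        8.6 + HELIX_RADIUS * np.cos(theta),
        HELIX_RADIUS * np.sin(theta),
        z_top - HELIX_RISE * (t + 1),
    ], axis=1)
    return out


def _state_conformation(native: np.ndarray, spec: StateSpec,
                        pairs: np.ndarray) -> np.ndarray:
    """Deterministic conformation whose Q best matches the state's q*."""
    n = native.shape[0]
    if spec.is_misfolded:
        candidates = [_misfold_hairpin(native, m) for m in range(4, n - 3)]
    else:
        candidates = [_unfold_from_terminus(native, u) for u in range(1, n + 1)]
    qs = np.array([_q_of(c, pairs) for c in candidates])
    best = int(np.argmin(np.abs(qs - spec.q_star)))
    if abs(qs[best] - spec.q_star) > Q_MATCH_TOL:
        raise ConfigurationError(
            f"state {spec.name!r}: target q*={spec.q_star} unachievable for "
            f"{n} residues (closest attainable {qs[best]:.2f})")
    return candidates[best]


def generate_folding_trajectory(cfg: SyntheticConfig) -> SyntheticTrajectory:
    """Generate a seeded trajectory over the configured state repertoire."""
    rng = np.random.default_rng(cfg.seed)
    native = ideal_helix(cfg.n_residues)
    pairs = _native_pair_set(native)
    state_coords = {s.name: _state_conformation(native, s, pairs)
                    for s in cfg.states}
    names = [s.name for s in cfg.states]
    weights = np.array([s.weight for s in cfg.states], dtype=float)
    weights /= weights.sum()

    n = cfg.n_frames
    state_idx = np.zeros(n, dtype=np.int64)
    if n > 0:
        state_idx[0] = rng.choice(len(names), p=weights)
        switches = rng.random(n) < cfg.switch_prob
        draws = rng.choice(len(names), size=n, p=weights)
        for t in range(1, n):
            state_idx[t] = draws[t] if switches[t] else state_idx[t - 1]
    coords = np.empty((n, cfg.n_residues, 3))
    for k, name in enumerate(names):
        sel = state_idx == k
        coords[sel] = state_coords[name]
    coords += rng.normal(0.0, cfg.noise_sd, size=coords.shape)
    labels = np.array([names[k] for k in state_idx], dtype=object)
    frames = TrajectoryFrames(coords=coords, source_id=f"synthetic-seed{cfg.seed}")
    return SyntheticTrajectory(frames=frames, labels=labels, native=native,
                               state_coords=state_coords, config=cfg)


def generate_paired_trajectories(cfg: SyntheticConfig, seed2: int):
    """Two independent trajectories over the same states and native."""
    traj_a = generate_folding_trajectory(cfg)
    traj_b = generate_folding_trajectory(replace(cfg, seed=seed2))
    return traj_a, traj_b


PRESETS = {
    # residue counts mirror the three study systems: a 21-residue all-α
    # peptide, a 28-residue miniprotein, a 35-residue headpiece fragment
    "fs21": dict(n_residues=21),
    "bba28": dict(n_residues=28),
    "vhp35": dict(n_residues=35),
    "fs21-misfolded": dict(
        n_residues=21,
        states=(
            StateSpec("folded", 0.95, 0.3),
            StateSpec("partial", 0.55, 0.25),
            StateSpec("unfolded", 0.1, 0.2),
            StateSpec("misfolded", 0.8, 0.25, is_misfolded=True),
        ),
    ),
}


def preset_config(name: str, **overrides) -> SyntheticConfig:
    if name not in PRESETS:
        raise ConfigurationError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


def write_trajectory(traj: SyntheticTrajectory, outdir) -> dict:
    """Write native.pdb, traj.pdb (topology), traj.dcd and labels.csv so
    the file-based loading path can be exercised end to end."""
    import os

    import MDAnalysis as mda
    import pandas as pd

    os.makedirs(outdir, exist_ok=True)
    n = traj.native.shape[0]

    def _universe(positions):
        u = mda.Universe.empty(n_atoms=n, n_residues=n,
                               atom_resindex=np.arange(n),
                               residue_segindex=np.zeros(n, dtype=int),
                               trajectory=True)
        u.add_TopologyAttr("name", ["CA"] * n)
        u.add_TopologyAttr("type", ["C"] * n)
        u.add_TopologyAttr("element", ["C"] * n)
        u.add_TopologyAttr("resname", ["ALA"] * n)
        u.add_TopologyAttr("resid", np.arange(1, n + 1))
        u.add_TopologyAttr("occupancy", np.ones(n))
        u.add_TopologyAttr("tempfactor", np.zeros(n))
        u.atoms.positions = positions
        return u

    paths = {
        "native": os.path.join(outdir, "native.pdb"),
        "topology": os.path.join(outdir, "traj.pdb"),
        "trajectory": os.path.join(outdir, "traj.dcd"),
        "labels": os.path.join(outdir, "labels.csv"),
    }
    import warnings

    with warnings.catch_warnings():
        # benign writer notices about absent unit cells / optional PDB fields
        warnings.simplefilter("ignore", UserWarning)
        _universe(traj.native).atoms.write(paths["native"])
        first = traj.frames.coords[0] if traj.frames.n_frames else traj.native
        _universe(first).atoms.write(paths["topology"])
        u = _universe(first)
        with mda.Writer(paths["trajectory"], n_atoms=n) as w:
            for xyz in traj.frames.coords:
                u.atoms.positions = xyz
                w.write(u.atoms)
    pd.DataFrame({"frame": np.arange(traj.frames.n_frames),
                  "state": traj.labels}).to_csv(paths["labels"], index=False)
    return paths
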