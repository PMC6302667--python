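"""Latent-space diagnostics and conformational-state characterization.

Covers the post-training analysis: per-pixel reconstruction differences
and the misprediction fraction, t-SNE projection of the latent means, a
−log-histogram estimate of the free-energy surface over the projection,
and seeded k-means state assignment with per-state reaction-coordinate
summaries (including the high-Q/high-RMSD "misfolded candidate" flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, StateError
from .featurize import ContactMapSeries

DEFAULT_MISPREDICTION_THRESHOLD = 0.1  # absolute, on the [0,1] contact scale
DEFAULT_PERPLEXITY = 30.0
DEFAULT_FES_BINS = 64

__all__ = [
    "ReconstructionDiff",
    "StateMap",
    "reconstruction_difference",
    "misprediction_fraction",
    "tsne_project",
    "fes_histogram",
    "assign_states",
    "characterize",
    "save_fes",
    "plot_fes",
]


@dataclass
class ReconstructionDiff:
    """Per-pixel (reconstructed − original) over the unpadded block."""

    diffs: np.ndarray                        # (frames, N, N) in [-1, 1]
    threshold: float = DEFAULT_MISPREDICTION_THRESHOLD

    def __post_init__(self):
        self.diffs = np.asarray(self.diffs, dtype=np.float64)
        if self.diffs.size and (self.diffs.min() < -1 or self.diffs.max() > 1):
            raise DataError("reconstruction differences must lie in [-1, 1]")
        if not (0 < self.threshold < 1):
            raise ConfigurationError("threshold must be in (0, 1)")


@dataclass
class StateMap:
    """t-SNE coordinates, FES grid, and per-frame state labels (1..k)."""

    tsne_xy: np.ndarray
    fes: np.ma.MaskedArray
    labels: np.ndarray
    n_states: int
    summaries: pd.DataFrame | None = None


def reconstruction_difference(model, maps: ContactMapSeries,
                              subset=None,
                              threshold: float = DEFAULT_MISPREDICTION_THRESHOLD,
                              ) -> ReconstructionDiff:
    """decode(mu) − original contact map, restricted to the real N×N block.

    Uses the deterministic latent mean, not a sampled z, so the
    diagnostic is reproducible without a seed.
    """
    from .cvae import decode, encode

    if getattr(model, "trained_epochs", 1) == 0:
        raise StateError("model has not been trained; diagnostics would "
                         "reflect random weights")
    if subset is None:
        subset = np.arange(maps.n_frames)
    subset = np.asarray(subset, dtype=np.int64)
    if subset.size == 0:
        raise ConfigurationError("subset must be non-empty")
    n = maps.n_residues
    x = maps.as_float(np.float64)[subset]
    emb = encode(model, x.astype(np.float32))
    f = decode(model, emb.mu)
    return ReconstructionDiff(diffs=f[:, :n, :n] - x[:, :n, :n],
                              threshold=threshold)


def misprediction_fraction(diff: ReconstructionDiff,
                           threshold: float | None = None) -> float:
    """Fraction of pixels with |reconstructed − original| strictly above
    the threshold; pixels exactly at the threshold count as correct."""
    thr = diff.threshold if threshold is None else threshold
    if not (0 < thr < 1):
        raise ConfigurationError("threshold must be in (0, 1)")
    if diff.diffs.size == 0:
        return 0.0
    return float((np.abs(diff.diffs) > thr).mean())


def tsne_project(mu: np.ndarray, perplexity: float = DEFAULT_PERPLEXITY,
                 seed: int = 0) -> np.ndarray:
    """2-D t-SNE of the latent means; deterministic for a fixed seed.

    Degenerate input with no variance (all frames identical) maps to the
    origin rather than erroring.
    """
    from sklearn.manifold import TSNE

    mu = np.asarray(mu, dtype=np.float64)
    if mu.ndim != 2:
        raise DataError("mu must be (frames, d)")
    n = mu.shape[0]
    if n <= 3 * perplexity:
        raise ConfigurationError(
            f"t-SNE needs more than 3×perplexity={3 * perplexity:.0f} frames, "
            f"got {n}")
    if np.ptp(mu, axis=0).max() == 0:
        return np.zeros((n, 2))
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="pca")
    return tsne.fit_transform(mu).astype(np.float64)


def fes_histogram(tsne_xy: np.ndarray, bins: int = DEFAULT_FES_BINS):
    """−log occupancy histogram over the 2-D projection.

    F(bin) = −ln(count / count_max) for occupied bins (so the modal bin
    has F = 0); empty bins are masked. Returns (F, x_edges, y_edges).
    """
    xy = np.asarray(tsne_xy, dtype=np.float64)
    if np.isscalar(bins):
        bins = int(bins)
        if bins < 2:
            raise ConfigurationError("need at least 2 bins per axis")
    counts, xe, ye = np.histogram2d(xy[:, 0], xy[:, 1], bins=bins)
    occupied = counts > 0
    fes = np.ma.masked_array(np.zeros_like(counts), mask=~occupied)
    fes[occupied] = -np.log(counts[occupied] / counts.max())
    return fes, xe, ye


def assign_states(features: np.ndarray, k: int, seed: int = 0,
                  rmsd: np.ndarray | None = None,
                  q: np.ndarray | None = None,
                  q_hi: float = 0.8, rmsd_hi: float | None = None):
    """Seeded k-means state assignment with per-state summaries.

    ``features`` is the t-SNE projection or the latent means. Labels run
    1..k. If per-frame RMSD and Q are supplied, the summary table gains
    their per-state means plus a ``misfolded_candidate`` flag for states
    with mean Q ≥ ``q_hi`` and mean RMSD ≥ ``rmsd_hi`` simultaneously
    (the signature of a compact but non-native topology).
    """
    from sklearn.cluster import KMeans

    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2:
        raise DataError("features must be (frames, dims)")
    n = features.shape[0]
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if k > n:
        raise ConfigurationError(f"k={k} exceeds the number of frames {n}")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(features) + 1

    rows = []
    for state in range(1, k + 1):
        sel = labels == state
        row = {"state": state, "population": int(sel.sum())}
        if rmsd is not None:
            row["mean_rmsd"] = float(np.mean(np.asarray(rmsd)[sel]))
        if q is not None:
            row["mean_q"] = float(np.mean(np.asarray(q)[sel]))
        if rmsd is not None and q is not None and rmsd_hi is not None:
            row["misfolded_candidate"] = bool(
                row["mean_q"] >= q_hi and row["mean_rmsd"] >= rmsd_hi)
        rows.append(row)
    return labels, pd.DataFrame(rows)


def save_fes(fes: np.ma.MaskedArray, x_edges, y_edges, path) -> None:
    """Persist the FES grid to HDF5 (/fes with NaN for empty bins,
    /x_edges, /y_edges)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("fes", data=fes.filled(np.nan))
        f.create_dataset("x_edges", data=np.asarray(x_edges))
        f.create_dataset("y_edges", data=np.asarray(y_edges))


def plot_fes(fes: np.ma.MaskedArray, x_edges, y_edges, path,
             title: str = "free-energy surface (-log occupancy)") -> None:
    """Render the landscape to a PNG (masked bins left blank)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    mesh = ax.pcolormesh(x_edges, y_edges, fes.T, cmap="viridis")
    fig.colorbar(mesh, ax=ax, label="-ln(count / count_max)")
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def characterize(mu: np.ndarray, k: int, seed: int = 0,
                 perplexity: float = DEFAULT_PERPLEXITY,
                 bins: int = DEFAULT_FES_BINS,
                 rmsd: np.ndarray | None = None,
                 q: np.ndarray | None = None,
                 q_hi: float = 0.8, rmsd_hi: float | None = None) -> StateMap:
    """Full landscape characterization: t-SNE → FES → state assignment."""
    xy = tsne_project(mu, perplexity=perplexity, seed=seed)
    fes, _, _ = fes_histogram(xy, bins=bins)
    labels, summaries = assign_states(xy, k, seed=seed, rmsd=rmsd, q=q,
                                      q_hi=q_hi, rmsd_hi=rmsd_hi)
    return StateMap(tsne_xy=xy, fes=fes, labels=labels, n_states=k,
                    summaries=summaries)
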