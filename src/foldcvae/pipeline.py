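"""End-to-end pipeline: simulate → featurize → train → analyze → transfer.

A single ``RunConfig`` drives every stage; each stage's seed is derived
deterministically from the master seed, stage outputs are cached behind
a content-hash manifest (rerunning with an unchanged config skips the
stage), and the machine-readable summary lands in ``report.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import zlib
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, ValidationError

from . import coords as coords_mod
from . import cvae as cvae_mod
from . import featurize as feat_mod
from . import landscape as land_mod
from . import synthetic as syn_mod
from .errors import ConfigurationError

log = logging.getLogger("foldcvae")

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]


class FeaturizeParams(BaseModel):
    cutoff: float = feat_mod.DEFAULT_CUTOFF
    pad: Optional[int] = None
    split_mode: str = "contiguous"
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)


class ModelParams(BaseModel):
    n_conv_layers: int = 4
    n_filters: int = 100
    kernel: int = 5
    n_dense: int = 64
    latent_dim: int = 3
    optimizer: str = "rmsprop"
    epochs: int = 150
    learning_rate: float = 1e-3
    early_stop_patience: Optional[int] = None
    early_stop_tol: float = 1e-3


class AnalysisParams(BaseModel):
    k: int = 4
    perplexity: float = 30.0
    bins: int = 64
    misprediction_threshold: float = 0.1
    q_hi: float = 0.8
    rmsd_hi: Optional[float] = 4.0
    max_tsne_frames: int = 3000


class SimulateParams(BaseModel):
    preset: str = "fs21"
    n_frames: int = 2000
    noise_sd: float = 0.3
    transfer_frames: int = 0   # >0: generate an independent second trajectory


class RunConfig(BaseModel):
    """Validated configuration for one pipeline run."""

    out_dir: str
    seed: int = 0
    # either synthetic generation ...
    simulate: Optional[SimulateParams] = None
    # ... or user-supplied files
    topology: Optional[str] = None
    trajectory: Optional[str] = None
    native: Optional[str] = None
    transfer_topology: Optional[str] = None
    transfer_trajectory: Optional[str] = None
    featurize: FeaturizeParams = Field(default_factory=FeaturizeParams)
    model: ModelParams = Field(default_factory=ModelParams)
    analysis: AnalysisParams = Field(default_factory=AnalysisParams)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        try:
            return cls(**data)
        except ValidationError as exc:
            keys = ", ".join(".".join(str(p) for p in e["loc"])
                             for e in exc.errors())
            raise ConfigurationError(
                f"invalid run configuration (offending keys: {keys})") from exc

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out from the master seed."""
    return zlib.crc32(f"{master_seed}:{stage}".encode()) & 0x7FFFFFFF


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, path):
        self.path = path
        self.data = {}
        if os.path.exists(path):
            with open(path) as fh:
                self.data = json.load(fh)

    def fresh(self, stage: str, key: str, outputs: list[str]) -> bool:
        rec = self.data.get(stage)
        return (rec is not None and rec["key"] == key
                and all(os.path.exists(p) for p in rec["outputs"])
                and rec["outputs"] == outputs)

    def record(self, stage: str, key: str, outputs: list[str], cached: bool):
        self.data[stage] = {"key": key, "outputs": outputs, "cached": cached}
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)


def run_pipeline(config: RunConfig | dict) -> dict:
    """Execute the configured stages; returns the report dictionary.

    Artifacts written under ``config.out_dir``: maps.h5, model.ckpt.npz,
    embeddings.csv, coords.csv, loss_trace.csv, report.json, manifest.json
    (plus the synthetic PDB/DCD files when simulation is enabled).
    """
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    if config.simulate is None and (config.topology is None or config.native is None):
        raise ConfigurationError(
            "config needs either a 'simulate' block or topology+native paths")
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    manifest = _Manifest(os.path.join(out, "manifest.json"))
    report: dict = {"seed": config.seed, "stages": {}}

    # --- stage: simulate (or ingest user files) -------------------------

    if config.simulate is not None:
        sim = config.simulate
        key = _hash_obj(["simulate", sim.model_dump(), config.seed])
        sim_dir = os.path.join(out, "sim")
        outputs = [os.path.join(sim_dir, f) for f in
                   ("native.pdb", "traj.pdb", "traj.dcd", "labels.csv")]
        cached = manifest.fresh("simulate", key, outputs)
        cfg = syn_mod.preset_config(sim.preset, n_frames=sim.n_frames,
                                    noise_sd=sim.noise_sd,
                                    seed=stage_seed(config.seed, "simulate"))
        traj = syn_mod.generate_folding_trajectory(cfg)
        if not cached:
            log.info("simulate: %d frames of preset %s", sim.n_frames, sim.preset)
            syn_mod.write_trajectory(traj, sim_dir)
        manifest.record("simulate", key, outputs, cached)
        report["stages"]["simulate"] = "cached" if cached else "ran"
        frames, native_xyz, labels = traj.frames, traj.native, traj.labels
        transfer_frames = None
        if sim.transfer_frames > 0:
            cfg_b = syn_mod.preset_config(
                sim.preset, n_frames=sim.transfer_frames, noise_sd=sim.noise_sd,
                seed=stage_seed(config.seed, "simulate-transfer"))
            transfer_frames = syn_mod.generate_folding_trajectory(cfg_b).frames
    else:
        frames = feat_mod.load_trajectory(config.topology, config.trajectory)
        native_xyz = feat_mod.load_trajectory(config.native).coords[0]
        labels = None
        transfer_frames = None
        if config.transfer_topology:
            transfer_frames = feat_mod.load_trajectory(
                config.transfer_topology, config.transfer_trajectory)
        report["stages"]["simulate"] = "skipped"

    # --- stage: featurize ----------------------------------------------
    fz = config.featurize
    key = _hash_obj(["featurize", fz.model_dump(), config.seed,
                     frames.n_frames, frames.n_atoms])
    maps_path = os.path.join(out, "maps.h5")
    cached = manifest.fresh("featurize", key, [maps_path])
    if cached:
        maps = feat_mod.load_maps(maps_path)
    else:
        log.info("featurize: %d frames, cutoff %.1f Å", frames.n_frames, fz.cutoff)
        maps = feat_mod.pad_maps(
            feat_mod.compute_contact_maps(frames, cutoff=fz.cutoff), fz.pad)
        feat_mod.save_maps(maps, maps_path)
    manifest.record("featurize", key, [maps_path], cached)
    report["stages"]["featurize"] = "cached" if cached else "ran"
    split = feat_mod.split_dataset(maps.n_frames, fractions=fz.fractions,
                                   mode=fz.split_mode,
                                   seed=stage_seed(config.seed, "split"))

    # --- stage: train ----------------------------------------------------
    mp = config.model
    hp = cvae_mod.CVAEHyperparams(
        n_conv_layers=mp.n_conv_layers, n_filters=mp.n_filters,
        kernel=mp.kernel, n_dense=mp.n_dense, latent_dim=mp.latent_dim,
        optimizer=mp.optimizer, epochs=mp.epochs,
        learning_rate=mp.learning_rate)
    key = _hash_obj(["train", mp.model_dump(), config.seed, maps.n_frames,
                     maps.size, fz.model_dump()])
    ckpt = os.path.join(out, "model.ckpt.npz")
    trace_path = os.path.join(out, "loss_trace.csv")
    cached = manifest.fresh("train", key, [ckpt, trace_path])
    if cached:
        model = cvae_mod.load_model(ckpt)
    else:
        model = cvae_mod.build_model(hp, (maps.size, maps.size),
                                     seed=stage_seed(config.seed, "init"))
        def _log_epoch(ep, tr, vl):
            log.info("train: epoch %d train L=%.3f val L=%.3f", ep, tr[0], vl[0])
        cvae_mod.train(model, maps, split,
                       seed=stage_seed(config.seed, "train"),
                       early_stop_patience=mp.early_stop_patience,
                       early_stop_tol=mp.early_stop_tol, callback=_log_epoch)
        cvae_mod.save_model(model, ckpt)
        model.loss_trace.to_frame().to_csv(trace_path, index=False)
    manifest.record("train", key, [ckpt, trace_path], cached)
    report["stages"]["train"] = "cached" if cached else "ran"
    report["trained_epochs"] = model.trained_epochs
    report["loss_trace_path"] = trace_path
    if len(model.loss_trace):
        report["final_train_loss"] = model.loss_trace.train_total[-1]
        report["final_val_loss"] = model.loss_trace.val_total[-1]

    # --- stage: analyze --------------------------------------------------
    ap = config.analysis
    analyze_key = _hash_obj(["analyze", ap.model_dump(), key])
    emb_path = os.path.join(out, "embeddings.csv")
    coords_path = os.path.join(out, "coords.csv")
    report_path = os.path.join(out, "report.json")
    analyze_outputs = [emb_path, coords_path, report_path]
    if manifest.fresh("analyze", analyze_key, analyze_outputs):
        with open(report_path) as fh:
            old = json.load(fh)
        for field_name in ("misprediction_fraction", "state_summaries",
                           "transfer_misprediction_fraction"):
            if field_name in old:
                report[field_name] = old[field_name]
        report["stages"]["analyze"] = "cached"
        if "transfer" in old.get("stages", {}):
            report["stages"]["transfer"] = "cached"
        manifest.record("analyze", analyze_key, analyze_outputs, True)
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        return report

    emb = cvae_mod.encode(model, maps, seed=stage_seed(config.seed, "encode"))
    mispred = {
        name: cvae_mod.misprediction_of(model, maps, idx,
                                        threshold=ap.misprediction_threshold)
        for name, idx in (("train", split.train_idx), ("test", split.test_idx),
                          ("val", split.val_idx))}
    report["misprediction_fraction"] = mispred

    native_ref = coords_mod.build_native_reference(native_xyz, frames)
    rc = coords_mod.compute_reaction_coordinates(frames, native_ref)
    rc.to_csv(coords_path)

    n_frames = maps.n_frames
    sub = np.arange(n_frames)
    if n_frames > ap.max_tsne_frames:  # t-SNE cost is superlinear; subsample
        sub = np.random.default_rng(
            stage_seed(config.seed, "tsne-subsample")).choice(
                n_frames, ap.max_tsne_frames, replace=False)
        sub.sort()
    xy = land_mod.tsne_project(emb.mu[sub], perplexity=ap.perplexity,
                               seed=stage_seed(config.seed, "analyze"))
    fes, xe, ye = land_mod.fes_histogram(xy, bins=ap.bins)
    land_mod.save_fes(fes, xe, ye, os.path.join(out, "fes.h5"))
    land_mod.plot_fes(fes, xe, ye, os.path.join(out, "fes.png"))
    state_labels, summaries = land_mod.assign_states(
        xy, ap.k, seed=stage_seed(config.seed, "analyze"),
        rmsd=rc.rmsd[sub], q=rc.q[sub], q_hi=ap.q_hi, rmsd_hi=ap.rmsd_hi)
    state_map = land_mod.StateMap(tsne_xy=xy, fes=fes, labels=state_labels,
                                  n_states=ap.k, summaries=summaries)
    import pandas as pd
    df = pd.DataFrame(emb.mu[sub], columns=[f"z{i+1}" for i in
                                            range(emb.latent_dim)])
    df.insert(0, "frame", sub)
    df["tsne1"], df["tsne2"] = state_map.tsne_xy.T
    df["state"] = state_map.labels
    df["rmsd_A"] = rc.rmsd[sub]
    df["q_native"] = rc.q[sub]
    if labels is not None:
        df["true_state"] = np.asarray(labels)[sub]
    df.to_csv(emb_path, index=False)
    report["stages"]["analyze"] = "ran"
    report["state_summaries"] = state_map.summaries.to_dict(orient="records")

    # --- stage: transfer -------------------------------------------------
    if transfer_frames is not None:
        tmaps = feat_mod.pad_maps(
            feat_mod.compute_contact_maps(transfer_frames, cutoff=fz.cutoff),
            maps.size)
        _, frac = cvae_mod.transfer_project(
            model, tmaps, seed=stage_seed(config.seed, "transfer"))
        report["transfer_misprediction_fraction"] = frac
        report["stages"]["transfer"] = "ran"

    manifest.record("analyze", analyze_key, analyze_outputs, False)
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
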