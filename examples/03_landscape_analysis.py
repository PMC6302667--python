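"""Characterize the latent landscape of a system with a misfolded state.

Runs the full analysis: encode → t-SNE → −log-histogram free-energy
surface → k-means states, then cross-references each state with the two
physical reaction coordinates (RMSD to native, fraction of native
contacts Q). The misfolded state is the one with high Q *and* high RMSD.
"""

import numpy as np

from foldcvae import (
    CVAEHyperparams,
    build_model,
    build_native_reference,
    characterize,
    compute_contact_maps,
    compute_reaction_coordinates,
    encode,
    generate_folding_trajectory,
    pad_maps,
    preset_config,
    split_dataset,
    train,
)

cfg = preset_config("fs21-misfolded", n_frames=1200, noise_sd=0.3, seed=3)
traj = generate_folding_trajectory(cfg)
maps = pad_maps(compute_contact_maps(traj.frames))
split = split_dataset(maps.n_frames, mode="contiguous")

hp = CVAEHyperparams(n_conv_layers=2, n_filters=16, kernel=3, n_dense=32)
model = build_model(hp, (maps.size, maps.size), seed=5)
train(model, maps, split, seed=5, epochs=8)

ref = build_native_reference(traj.native, traj.frames)
rc = compute_reaction_coordinates(traj.frames, ref)
emb = encode(model, maps)

sm = characterize(emb.mu, k=4, seed=0, perplexity=25, bins=32,
                  rmsd=rc.rmsd, q=rc.q, q_hi=0.7, rmsd_hi=3.0)
print(sm.summaries.to_string(index=False))
print("\nFES grid: depth range 0 ..", f"{sm.fes.max():.2f}",
      "(−ln of relative bin occupancy; 0 = most populated basin)")
print("States with misfolded_candidate=True combine native-like contact "
      "counts with a large RMSD — compact but wrongly packed.")
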