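# Methods

## Problem and approach

Long protein-folding simulations produce millions of conformations that
must be grouped into a small number of metastable states before they can
be interpreted. `foldcvae` does this without labels: each frame is
reduced to a binary Cα–Cα contact map, a convolutional variational
autoencoder (CVAE) compresses the maps into a low-dimensional Gaussian
latent space, and conformational substates are read off that space with
t-SNE, a −log-occupancy landscape, and seeded k-means. Two physical
reaction coordinates — RMSD to the native structure and the fraction of
native contacts Q — are computed independently of the model and used
only to interpret and validate the discovered states.

## Featurization

Two Cα atoms are in contact when their Euclidean distance is strictly
below 8 Å. The strict inequality is a convention; distances exactly at
the cutoff have measure zero for simulation data, but tests pin the
behaviour so it cannot drift. The full N×N symmetric map is kept,
including the diagonal (always 1) and near-diagonal trivial contacts;
maps are stored as {0,1} and presented to the model as floats in [0,1].

Maps are zero-padded (bottom/right) to the smallest multiple of 4 that
fits the chain, because the encoder downsamples by a total factor of 4.
Padded pixels are excluded from all reconstruction-quality statistics.

Splits default to contiguous 80/10/10 train/test/validation blocks,
which limits temporal leakage between partitions in an autocorrelated
trajectory; a seeded random mode is available where per-frame shuffling
is wanted.

## Model

Encoder: `n_conv_layers` 'same'-padded convolutions with ReLU
activations (the first two at stride 2, the remainder at stride 1),
then a dense layer, then linear heads for the latent mean μ and
log-variance log σ². Decoder: the mirror image built from transposed
convolutions (exact linear adjoints of the encoder convolutions), ending
in a sigmoid pixel layer. Defaults: 4 conv layers, 100 filters, 5×5
kernels, 64 dense units, latent dimension 3.

Placing the two stride-2 reductions in the *first* layers rather than
after the last one is a deliberate efficiency choice: it cuts the
dominant convolution cost by roughly an order of magnitude at these
input sizes while leaving the receptive fields and parameter counts in
the same regime, which matters for a pure-NumPy engine on one CPU core.
The engine (im2col convolutions lowered to BLAS matmuls, explicit
backpropagation, RMSprop/Adam/Adamax/Adagrad) is part of the package and
is verified end to end by a finite-difference gradient check in float64.

### Loss

    L   = E_r + E_l
    E_r = mean over batch of  −Σ_pixels [ X log f(z) + (1−X) log(1−f(z)) ]
    E_l = mean over batch of  −½ Σ_j ( 1 + log σ_j² − μ_j² − σ_j² )

E_r is the full binary cross entropy (both terms; a contact-only term
would never penalize hallucinated contacts). E_l is the closed-form KL
divergence to N(0, I). E_r is summed over pixels and averaged over the
batch; E_l is averaged over the batch — so L is a per-conformation
quantity. Probabilities are clipped to [1e−7, 1−1e−7] before logs.

### Training

Reparameterized sampling z = μ + exp(log σ²/2)·ε during training;
deterministic μ at inference. Batch size is ceil(|train|/100) (small
batches keep the latent space from collapsing on long trajectories).
Default optimizer RMSprop at learning rate 1e−3 (all four optimizers are
selectable and tested). An optional early stop triggers after a
configurable number of epochs (default patience 10, tolerance 1e−3)
without validation-loss improvement. All randomness — initialization,
shuffling, ε draws — flows from explicit seeds, so traces are
bit-reproducible on one machine.

Reconstruction percentages are reported for both the test and the
validation partition (the pipeline report carries train/test/val), since
conventions differ on which held-out partition such figures quote.

## Reaction coordinates

RMSD uses the Kabsch procedure: centre both structures, take the SVD of
the cross-covariance, and flip the sign of the smallest singular value
when the rotation determinant would be −1, so only proper rotations are
allowed (a mirror-image helix keeps a large RMSD — load-bearing for the
misfolded synthetic state).

Native contacts follow the ensemble definition: the native ensemble is
every frame within 1.1 Å RMSD of the native structure, and a pair is a
native contact when it is within 8 Å in at least 75% of that ensemble.
If no frame qualifies, the native structure's own contacts are used,
with a warning. Pairs separated by fewer than 3 residues are excluded
from the native-contact *set* (|i−j| ≤ 2 Cα pairs are within 8 Å in any
chain conformation — 3.8 Å virtual bonds and the triangle inequality —
so they carry no folding signal and would floor Q near 0.5 for short
helical proteins); the contact *maps* keep every pair. Q is then the
realized fraction of native pairs, in [0,1].

## Diagnostics and landscape

The reconstruction difference is decode(μ) − original over the unpadded
block, in [−1, 1]. A pixel is mispredicted when |difference| > 0.1; the
threshold is absolute on the [0,1] contact scale (a relative reading of
"10% of the original value" is ill-defined at 0-valued pixels and would
count every nonzero reconstruction of an absent contact as an error).
Pixels exactly at 0.1 count as correct; the convention is pinned by a
test.

t-SNE runs on μ (sampled z would add jitter that reflects nothing in
the data), seeded, with perplexity 30 by default. The landscape is
F(bin) = −ln(count/count_max) over a 64×64 histogram of the projection:
0 at the modal bin, masked where empty — a qualitative free-energy
estimate, not a thermodynamic one. States are assigned by seeded k-means
with user-chosen k (the published analyses identify states visually; a
seeded clustering is the reproducible substitute), and each state is
summarized by population, mean RMSD and mean Q. A state is flagged a
misfolded candidate when mean Q ≥ 0.8 and mean RMSD ≥ a per-system
threshold simultaneously. The per-system "essentially folded" RMSD
threshold (e.g. 5 Å for a hot headpiece trajectory) is a configuration
value, not a constant.

## Synthetic systems

The generator is a statistical stand-in for folding trajectories, not a
physical simulation. The native state is an ideal Cα α-helix (rise
1.5 Å, 100°/residue, radius 2.3 Å). Each metastable state is one
deterministic deformation: unfolded/partial states extend the chain from
the C-terminus with 3.8 Å steps (contacts vanish progressively, so a
state ladder with target q* values of roughly 0.95/0.7/0.4/0.1 emulates
folded / two partial / unfolded); misfolded states break the helix at a
hinge and pack the halves antiparallel, preserving most native (local)
contacts while adding non-native inter-segment contacts and a large
RMSD. The deformation parameter is chosen to match the state's target
q* (configuration error if unreachable within 0.15). Frames follow a
Markov chain whose stationary distribution equals the occupancy weights
(default switch probability 0.1 per frame), plus isotropic Gaussian
jitter of 0.3 Å per atom — small against the 8 Å cutoff, so state
contact maps are nearly deterministic, and within-state RMSD spread
(~0.5 Å) stays below the 1.1 Å native-ensemble cutoff.

What passing on these systems shows: the pipeline recovers discrete,
well-separated states whose contact signatures differ, end to end and
reproducibly. What it does not show: performance under continuous
conformational exchange, rugged intra-state heterogeneity, or
non-helical topologies — real trajectories are harder in all three
ways, and the headline percentages here should be read as evidence the
machinery works, not as a forecast for any particular protein. Presets
cover 21-, 28- and 35-residue systems so size scaling is exercised.

## Problem sizes for the reported numbers

The reconstruction-quality figures recomputed by `scripts/acceptance.py`
use the default model on: (t1) the 21-residue 4-state system, 10,000
frames, 5 epochs; (t2) the 21/28/35-residue presets, 5,000 frames and 3
epochs each. On these synthetic systems the training loss flattens
within the first few epochs (the trace is recorded per epoch and the
identity L = E_r + E_l is asserted at 1e−6 relative), so these short
schedules sit past the knee of the loss curve; the ≤150-epoch ceiling
with early stopping is the general-purpose default.

## Numerical choices and edge cases

- Probabilities clipped at 1e−7 before logs; decode output is float64 so
  the clip is representable.
- All-coincident coordinates: RMSD defined as 0 with a warning.
- Degenerate all-identical latent means: t-SNE shortcut returns zeros
  rather than erroring.
- Pixels exactly at the misprediction threshold count as correct
  (strict >).
- Remainder frames in a split go to test before validation.
- Hyperparameter search: integer box from the allowed bounds
  (conv layers 1–4, filters 16–125, kernel 2–7, dense 32–100, latent
  2–16); random search by default, or a Gaussian-process
  expected-improvement loop (Matérn 5/2, candidate-pool maximization)
  — both seeded, both ranking by validation E_r with reduced-epoch
  trainings, with an optional wall-clock cap that returns partial
  results with a warning.

## Known limitations

- The NumPy engine is single-core and untuned for large proteins;
  beyond ~100 residues per-epoch cost grows quickly.
- Per-frame modelling only: temporal correlations are ignored by the
  model (the contiguous split is the only place time enters).
- Binary maps discard distance information below/above the cutoff.
- The landscape is an occupancy histogram of a nonlinear projection;
  basin depths are not free energies.
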