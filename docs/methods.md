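# Methods

## Reduced representation and distance tensors

Each nucleotide is pinned by five atoms — P and C4′ for the backbone,
plus three base atoms that differ between purines (C2, C6, N9) and
pyrimidines (C2, C4, N1). Because the base C2 occupies a different
ring position in the two families, the five atoms live in an 8-slot
layout whose first two slots are shared; missing atoms (typically the
leading phosphate) leave a zeroed slot with mask 0. A chain of length
*L* becomes an *L*×*L*×64 tensor: channel 8*p*+*q* holds the distance
between slot *p* of residue *i* and slot *q* of residue *j*, and the
mask tensor is the reshaped outer product of the per-residue masks.

**Symmetrisation.** Entries (i, j, 8p+q) and (j, i, 8q+p) describe the
same atom pair, and the package enforces exactly that exchange
symmetry (averaging the two; a no-op on tensors computed from
coordinates, a genuine projection for decoder outputs). The
alternative — forcing per-channel symmetry D[i,j,k] = D[j,i,k] by
transpose-averaging — collapses the two *different* distances
d(p_i, q_j) and d(p_j, q_i) into one value and destroys the
invertibility of the encoding; with the exchange rule the tensor
remains an exact, rigid-motion-invariant encoding, which the
round-trip test verifies at 10⁻³ Å. Per-pixel symmetry of the
*discrete* class maps, which the downstream models rely on, is
guaranteed separately by symmetrising the VQ-VAE embedding
(½(e + eᵀ)) before quantisation. Channels with p = q (e.g. the
phosphate–phosphate distance between first and last residue) are
symmetric under both conventions.

**Coordinate recovery.** Decoded distance tensors are mapped back to
coordinates by classical multidimensional scaling on the valid-atom
submatrix followed by L-BFGS minimisation of the raw stress
Σ(|xᵢ−xⱼ|−dᵢⱼ)²; the line search makes the recorded stress history
monotone. The result is defined up to rigid motion and reflection
(distance information cannot distinguish a mirror image), so
comparisons use a superposition RMSD that allows reflection.

## Neural networks

No deep-learning framework is a dependency: the three networks are
small residual CNNs implemented in `rnadistgen.nn` — stride-1
same-padded convolutions (im2col + matmul, exact transpose-convolution
backward), batch normalisation, ReLU/ELU, dense layers and Adam with
decoupled weight decay. Gradient correctness is enforced by
finite-difference tests. All arrays are float32, NHWC.

* **VQ-VAE encoder**: 7×7×32 convolution, one residual block
  [5×5,16]/[3×3,8], four blocks [5×5,8]/[3×3,8]; each block is
  2×[BatchNorm, ReLU, Conv] with a skip (1×1 projection when channel
  counts change). Output: 8-dimensional embedding per pixel.
* **VQ-VAE decoder**: four residual groups of four blocks with
  feature-map doubling 8→16→32→64 between groups (5×5 kernels, 3×3 in
  the last group), final ReLU so reconstructions are nonnegative.
* **Generator**: 3×3×26 convolution, then 8 blocks of
  2×[BN, ELU, 3×3 conv] + [BN, ELU, 3×3 conv] + [BN, ELU, dilated 3×3
  conv (rate 2)] with skips after the first two and across the last
  two sublayers; 1×1 convolution to K classes, softmax, and
  transpose-averaging of the probabilities so output maps are
  symmetric.
* **Score model**: 3×3×5 convolution, 4 residual blocks [3×3,5] with a
  dilated second half, then 1×1 convolutions to 100 and 1 channels;
  the scalar score f is the sum of the logit map.

**VQ straight-through.** The decoder consumes hard one-hot class
maps (that is what the generator later produces), which breaks the
classic straight-through path through quantised codebook vectors.
Gradients reach the encoder through a soft nearest-codebook assignment
softmax(−‖e−c_k‖²/τ): the decoder input is treated as
onehot + p − stop_grad(p). The temperature τ is set adaptively to the
batch median of the squared codebook distances — with a fixed unit
temperature the softmax saturates once embeddings drift away from the
codebook, the encoder stops receiving gradient, and the class
assignment stays frozen at whatever the initialisation happened to
produce. The codebook itself follows EMA updates
(decay 0.99) with k-means++ initialisation on the first batch and
dead-code revival (a code unused in the current batch whose EMA count
has decayed below 1% of the mean jumps to a random batch embedding);
without revival, K = 3 codebooks collapse to a single used class on
small fixture sets. Commitment cost β = 0.25. The reconstruction loss
is mask-weighted squared error, so padded and missing-atom entries
carry no gradient.

## Masked generation

The generator input stacks 14 channels: 8 for the directional sequence
bit pattern (one-hot of residue i ‖ one-hot of residue j, order
G, C, A, U; N = 0.25 everywhere; padding −1), 3 for the revealed class
map (masked = (0,0,0); class c = +1 at channel c, −1 elsewhere), 2
coordinate frames (identity diagonal; border box of side L; padding
−1) and 1 self-attention map. The attention head collapses the 50-row
homolog one-hot with a Dense(4→1), stacks the SHAPE column, and uses
two Dense(51→64) maps as query and key with 1/√64 scaling — a single
head, trained end-to-end with the trunk. With no homologs the 50 rows
are filled with the query sequence; with no SHAPE the column is zero,
which reduces the model to sequence-only prediction.

Training reveals the quantised target map except for a
truncated-normal number of pixels (mean L²/2, sd L²/4, clipped to
[0, L²]) masked in symmetric pairs; contact-flagged pixel pairs are
never masked. The loss is cross-entropy over all valid pixels:
revealed pixels act as easy anchors, and restricting the sum to
masked pixels changes nothing qualitatively. Optimiser: Adam (β₂ = 0.997) with decoupled weight
decay, linear warmup and cosine decay; optional early stopping on a
validation set. Full-scale defaults (batch 500, lr 10⁻³, weight decay
0.01, 10⁵ warmup steps, 5·10⁶-step cap, 100-nt crops) are kept as the
configuration defaults; the tests and the acceptance script override
batch, step count and maximum length to desk scale.

## Tree search

Actions assign a class to a masked off-diagonal pixel (applied
symmetrically); the diagonal is pre-set to the "nearest" class — the
class whose mean decoded distance over a reference set is smallest.
Selection maximises Q + c_p·√(Σ_a N)/(1+N) — the standard
prior-free PUCT exploration term for visit-count tree search. Expansion samples |S_R| masked
pixels (default 4), proposes each pixel's argmax class (sampled
classes are available as a config switch and matter for discovering
alternative conformations), and keeps actions whose one-step lookahead
reduces total predictive entropy by **more than** λ·ln K (λ = 1) — the
threshold direction is chosen so that "no qualifying action" is a
sharpness terminal. Values are fractional entropy reduction per
action, v = (H(s₀)−H(s))/(H(s₀)·depth) — a per-action rate, so values
are comparable across depths — with v = 0 when H(s₀) = 0. Backups add |S_H| to the visit counts along the path and
move Q convexly toward the best new child value (winner-takes-all);
terminal visits add N_expl to the counts and leave Q unchanged.
Terminal states are completed in parallel by argmax and deduplicated
by their finalized map; the ensemble size cap counts unique maps.

**Scale of c_p.** Entropy-reduction rates are small (≈1/(0.3·N) for a
length-L problem), so useful exploration constants are small too; the
default c_p = 10⁻⁴ with |S_R| = 4 reliably drives the search to
sharpness terminals, while discovering genuinely distinct alternative
conformations (bimodal targets) needs a stronger push — larger c_p
(~3·10⁻³), sampled candidate classes and a large terminal bonus
(N_expl of order 10²), which is exactly the role the terminal bonus
plays in the algorithm. The bimodal acceptance test runs under those
settings.

## Score model

Input is the one-hot class map stacked with the 8-channel sequence bit
pattern (11 channels): the pairwise comparison D(s, s′; x) is
sequence-conditioned, so the network sees x rather than judging maps
in isolation. Both objective terms, log D(true, false) and
log(1 − D(false, true)), equal log σ(f_true − f_false) analytically —
the implementation computes them through separate numerical routes and
a test asserts their identity. Negatives per structure: encoded drift
variants, 10 symmetric pixel-flip copies with corruption fractions
drawn uniformly from 5–35% (varied strengths generalise better than
one fixed fraction, which the tiny net can memorise; a flip floor of
one pixel pair keeps the degenerate 0% case distinct from the
positive), and generator argmax predictions at reveal fractions
0/5/10/15/20%.
Optimiser: Adam, weight decay 10⁻⁴, exponential LR decay 0.9988.

## Data engineering

Curation keeps RNA-only X-ray/NMR entries (resolution < 4 Å when
metadata is present; synthetic fixtures carry none and pass), standard
A/C/G/U residues, chains ≥ 14 nt (≥ 7 nt in multi-chain entries),
unique chain sequences for ≥ 3 chains. Sequence similarity is a global
alignment (match +1, mismatch −1, gap open −1, gap extension 0)
normalised by the longer length; note that with free gap extension the
optimum for a fully mismatching equal-length pair is two opened gaps
(normalised −0.5), not the −1.0 of an ungapped reading. Complete-
linkage clustering at 0.7 guarantees within-cluster minimum similarity
≥ 0.7; whole clusters go to one split, anchors force test, and a
leakage audit (no cross-split pair ≥ 0.7) runs on every generated
dataset. Long/multichain structures: length-proportional chain choice,
random 100-nt window, contact flags at < 3.3 Å minimum distance over
any represented-atom pair (measured on the reduced atom set), crops kept only below 5% contact
fraction. Sampling weights are uniform over clusters and
length-proportional within. Simulated SHAPE is the mean per-residue
positional deviation between a structure and its rigid-body-aligned
drift variants; experimental SHAPE is quantile-mapped onto the
simulated distribution (rank-based, hence invariant to monotone
transforms of the input). Homolog rows need E < 0.01, no insertion
columns, and ≥ 1 non-deletion mutation; gaps become 'N' and the array
is filled to 50 rows with the query.

## Synthetic fixtures

The fixture generator emulates the statistical structure the pipeline
assumes, not thermodynamics. Secondary structures are sampled as
hairpins (stem 3–6 bp, loop ≥ 3, optional tails), sequences designed
Watson–Crick-complementary with a 70% GC bias in stems, then refolded
(ViennaRNA MFE when available, with a Nussinov fallback) so the
sequence→structure mapping is deterministic and learnable. The C4′
backbone trace minimises a spring energy — bonds 5.9 Å, base pairs
10.5 Å, soft i,i+2 stiffness at 9.5 Å and a 13 Å excluded-volume floor
for distant non-paired residues — from a seeded open-circle
initialisation; P and base atoms are placed in local backbone frames
with bases pointing at their pairing partner (stems) or outward
(loops). Paired residues therefore sit closer than unpaired distant
ones, and all 8-slot mask invariants hold by construction.

Drift variants replace coarse-grained MD: chain-smoothed Gaussian
displacements (σ = 2 residues), optionally weighted by per-residue
flexibility (loops 2.0, stems 0.4), rescaled to the exact target RMSD.
Presets mirror the two augmentation regimes (5 variants at 3 Å;
100 variants at 1/3/5/10 Å). What the drift stand-in does **not**
model: energy-landscape realism, correlated domain motions beyond
chain smoothing, or base-pair breaking — so passing tests demonstrate
the pipeline's mechanics and statistical behaviour, not predictive
accuracy on experimental RNA. Homolog alignments apply point
substitutions (≥ 1 enforced) and deletions, never insertions, with
synthetic E-values below the acceptance threshold. Fixture datasets
are clustered, split and audited with the same machinery as real data.

## Problem sizes

All training in the test suite and the acceptance script is desk
scale, chosen so the whole pipeline trains CPU-only in minutes:
fixtures of 10–16 nt, 10–60 training structures, 120–350 optimiser
steps (batch 5–8, Adam lr 10⁻³) for the codecs and generator, 150
steps for the score model, tree-search budgets of 60–400 simulations
(20 000 for bimodal discovery). Paper-scale settings remain the
defaults of the corresponding config objects and are exercised as
configuration only. Reported quantities (held-out reconstruction
RMSEs, cross-entropy improvements, recovery and ranking rates) are
measured at these sizes; absolute values are not comparable to
full-scale training on experimental structures, but ordering trends
(reconstruction error falling with K, loops drifting more than stems)
are scale-robust.

## Numerical choices and degenerate inputs

Quantisation ties break to the lowest class index; argmax completion
inherits numpy's first-maximum rule. Selection ties break by lowest
pixel index then class. H(s₀) = 0 defines v = 0. A search that
exhausts its budget without a terminal finalizes the best-Q leaf and
flags it. Empty datasets, empty ensembles, all-masked tensors,
mismatched masks and out-of-range classes raise ValueError; NaN losses
abort training. Entropies are natural-log throughout. Determinism:
every stochastic component takes a seed or Generator; identical seeds
give bit-identical codebooks and ensembles (single-threaded BLAS).

## Known limitations

No mmCIF parsing, non-standard residues, or NMR multi-model handling
beyond one structure per model; sequence length is capped by the
configured max_len (100 by default, as in cropping); the refinement
module only emits the external engine's protocol and ranks its
outputs, it never runs molecular dynamics; the hand-rolled conv-net
stack is CPU-bound and makes no attempt at large-scale performance.
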