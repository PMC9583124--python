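# Methods

## The encoding scheme

A dictionary of `n ≤ 2^b − 1` characters is mapped to the non-zero `b`-bit
binary words in list order (the all-zero word seeds no cells and is never
assigned).  Each bit corresponds to one circular inoculation spot in a small
centered grid ("braille-like" array); a 1-bit seeds cells in its spot.  The
spot grid is near-square and row-major (1 bit → 1×1, 2 → 1×2, 4 → 2×2,
5–6 → 2×3, 7 → 2×4); `spacing` is the center-to-center distance.  Seeded
pixels draw intensities i.i.d. from a Gaussian with mean 0.5 truncated to
[0, 1] by rejection sampling (uneven cell seeding; default deviation 0.15).
A message is therefore a one-to-many object: every encoding of a character
is a different random field with the same spot support.

## Growth model

The colonization field `N ∈ [0, 1]` evolves on a pixel grid inside a growth
domain by discrete-time kernel convolution:

    K(d) = b·2^−(d/d1)^h1 − 2^−(d/d2)^h2
    raw_t = [ K ⊛ N_t  +  w·( (I/k)·N_t ⊛ 1_supp ) ]_+      (rectified)
    N_{t+1} = raw_t / (h + raw_t)                            (saturation)

with `b = 6.5`, `d1/d2 = 0.4`, `h1 = 1000`, `h2 = 2000` (the sharp-exponent
limit makes the kernel an expansion core of magnitude `b−1` out to `d1` and
an inhibition ring of depth −1 out to `d2`; it is truncated at
`cutoff = 1.25·d2`).  The saturating response with half-effect constant
`h = 2.0` (in kernel-mass units) is this package's bounded reading of the
otherwise unbounded linear update: it keeps `N` an occupancy in [0, 1),
makes a fully colonized neighborhood self-sustaining, and leaves the
expansion/inhibition sign structure intact.  Alternatives we rejected after
measurement: dividing the convolution by the kernel's positive mass (per-step
gain ≈ 0.19, every colony dies), dividing by the total mass (gain exactly 1;
marginal dynamics whose phase behavior inverts with `b`), and hard clamping
(binary front decisions amplify noise chaotically and the within-class /
between-class distance ratio collapses to 1).

At the defaults the model produces branching/labyrinthine colonies;
`classify_morphology` labels a final pattern `disk` when the colonized
fraction of the domain exceeds 0.85, `trivial` when the IoU between the
binarized pattern and seeding exceeds 0.5 (growth arrest), and `branching`
otherwise.  Raising `b` and `d1/d2` (e.g. b = 10, d1/d2 = 0.55) fills the
domain; collapsing the expansion range (d2 = 1.5 px) arrests the colony at
its seeds.

**Growth noise.**  The kernel is perturbed afresh at every time step by one
multiplicative scalar: `K_t = K·(1 + z_t/snr)`, `z_t ~ N(0, 1)`, `snr` the
linear signal-to-noise ratio.  The pooled element-wise standard deviation of
`K_t − K` over the truncated support equals `RMS(K)/snr` exactly.  We chose
the multiplicative (growth-rate) form after measuring the alternative of
i.i.d. per-element white noise: at snr 3.5 that injects per-step
perturbations of the growth potential comparable to the signal itself and
erases all class information (within-class pairwise distance equals
between-class at every horizon); the multiplicative form preserves the
convergent property the scheme depends on while still degrading it
monotonically (measured between/within ratios ≈ 1.10 at snr 3.5, ≈ 1.01 at
snr 2).  The default regime is seeding noise without growth noise.

**Termination.**  The simulation stops when the mean absolute per-step
change of `N` stays below `stop_tol = 1e-4` for `stop_patience = 5`
consecutive steps ("the colony has stopped growing"), or at `max_steps`
(recorded as unconverged in the metadata, not an error — noisy runs
typically end this way since the noise floor exceeds `stop_tol`).

**Plate influence.**  The boundary exerts `I(d) = −k·2^−(ε·d/R)` with
`k = 1000`, `d` the Euclidean distance to the boundary (exact distance
transform of the domain mask) and `R` its maximum over the domain (the
highest contour).  Following the update integral, `I` is added to the kernel
term by term, which amounts to shifting the local expansion/repulsion
balance in proportion to the colonized mass in the kernel window (the
`w·(I/k)·N ⊛ 1_supp` term above).  `influence_weight w = 0.25` was
calibrated once so that the far-reaching decay `ε = 1` (the encryption
setting) biases growth visibly without extinguishing it, while the default
`ε = 2000` confines the influence to the immediate boundary rim.  Domains of
four shapes (circle, diamond, square, equilateral triangle) are sized by an
`area_fraction` of the inscribed circle's area so that compared shapes are
area-matched; shapes that cannot fit the grid at the requested area are
rejected rather than silently clipped.

**Output.**  The final field is quantized round-half-up to an 8-bit
grayscale PNG (451×451 at full scale) with provenance (bits, parameter
digest, step count, convergence flag) in a PNG text chunk; internal state is
real-valued throughout.

## Scales

The library defaults are the full-scale setup: 451 px plates, `d2 = 10`,
`d1 = 4`, spot spacing 15 and radius 5.  All tests, examples and the
acceptance script run the desk-scale twin (`profiles.reduced`): 128 px
plates with every length in the same proportion to the kernel (`d2 = 4`,
spacing `1.5·d2 = 6`, radius `0.5·d2 = 2`, `max_steps = 120`).  One reduced
simulation takes ~0.1 s, which is what makes the statistical suites below
possible; the branching regime and spot-to-kernel geometry are preserved.

## Datasets and decoder

Balanced datasets hold the same number of replicates per character; item
`(class c, replicate r)` uses the generator seeded with
`(base_seed, c, r)`, so any item regenerates exactly and test splits are
disjoint by a replicate-index offset (10^6) rather than bookkeeping.
Patterns are rescaled to 80×80 (anti-aliased bilinear; the interpolation
choice is ours) and scaled to [0, 1].

The decoder is a small CNN: two blocks of 3×3 valid convolution → 2×2 max
pooling → ReLU (default 32 and 64 filters), then a ReLU dense layer (128)
and a softmax output of the dictionary size; Glorot-normal initialization,
categorical cross-entropy, Adam (lr 1e-3, batch 32), early stopping on a
10% stratified validation split (patience 10, min-delta 1e-4) with
best-weight restoration.  The network is implemented directly on numpy
(forward/backward passes and Adam), which makes training bit-reproducible
from its seed — the determinism contract is exact, not tolerance-based.
The test-suite uses a narrower variant (8/16 filters, 32-dim dense) purely
for speed.  Evaluation (accuracy, per-class precision/recall, confusion,
one-vs-rest ROC and macro AUC) uses scikit-learn metrics.

## Ensembles and uncertainty

Stacking trains M base CNNs on the same data with different seeds,
concatenates their training-set probability vectors (length M·n_classes)
and fits a meta-classifier: softmax regression by default, optional ReLU
MLP; Glorot-uniform init, Adam lr 1e-4, early stopping patience 5 /
min-delta 1e-4.  Majority voting decodes several replicate patterns of one
character and takes the modal label; ties break by highest summed
probability, then lowest class index.  Uncertainty metrics over M points
and N classes: `nll = −(1/M)ΣΣ y_ij ln p_ij` (natural log, probabilities
floored at 1e-12), `mse = (1/(MN))ΣΣ (y_ij − p_ij)²`, and top-1/top-5 error
(rank by probability, ties toward the lower index).

## Text codec

`encode_text` simulates `frames_per_char` fresh patterns per character (the
ballots, default 5) in message order; `decode_frames` classifies every frame
and majority-votes within each group.  The container is a numbered frame
directory with a JSON sidecar — PNG for the lossless mode (bit-exact round
trip) or JPEG for the lossy mode; container video formats would need a codec
backend this package does not ship, and requesting one raises an explicit
error.

## Cellular-automaton analogue

Characters embed as blocks of 1-cells in a binary sequence (block width 4,
spacing 8, centered), each cell flips independently with `flip_prob`
(default 0.05), and an elementary rule (0–255; fixed-zero boundary by
default, periodic optional) runs for a fixed number of steps.  A dense
softmax network decodes final sequences.  The rule is a required
configuration choice; the default 54 is a placeholder from the weakly
chaotic class.  Vectorized evolution is tested against an 8-entry
rule-table oracle for all 256 rules.

## What the generator does and does not emulate

The simulator stands in for colony-growth experiments: it reproduces the
qualitative phenomenology (branching at the default parameters, disk and
arrest regimes, one-to-many encoding, convergent-but-noisy replicates,
noise/spacing/dictionary-size tradeoffs).  It does not model nutrients,
quorum signalling, continuous time, or any specific organism, and its noise
is a two-parameter caricature (truncated-Gaussian seeding + multiplicative
kernel noise) of biological variability.  Passing tests therefore show that
the encoding/decoding machinery behaves correctly on patterns with these
statistics — not that a wet-lab colony assay would reach the same accuracies.

## Known limitations

- **Domain-shape encryption is weak in this generator.**  The pipeline is
  implemented end to end (equal-area shaped domains, ε = 1 influence,
  center cropping, per-key decoders), and the shape visibly alters the
  pattern texture; but measured across influence formulations, weights,
  noise levels and dictionary sizes, a decoder trained on one shape decodes
  the other shape's patterns about equally well.  The same convergence that
  makes decoding reliable anchors the class-discriminative features to the
  seed neighbourhood, where the ε = 1 influence of equal-area circle and
  square domains is nearly identical; the key-induced image changes are
  close to orthogonal to the class features.  The corresponding acceptance
  test asserts diagonal dominance and currently fails; treat the encryption
  layer as exploratory.
- Long noiseless runs spontaneously break exact symmetries (floating-point
  roundoff is amplified by the patterning instability); equivariance is
  only testable over short horizons.
- Statistical trend tests (replicates, noise, spacing, ensemble gains) run
  at small sizes (3–8 classes, ≤ 16 replicates, 3 seeds) and assert ordering
  of means, not effect sizes.
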