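# Methods

## Model and procedure

The framework addresses long-tailed classification by reshaping the label
space rather than the sampling distribution.  Let a training set have C
classes with counts N_1 ≥ … ≥ N_C and imbalance factor β = N_max/N_min.  A
backbone φ(θ, ·) maps inputs to M-dimensional features; a linear layer maps
features to P = Σ_c N_s(c) subclass logits; a three-affine-layer fully
connected head ("mapper") maps the P logits to C class scores.

**EMA centroids.**  Each class keeps a running feature center.  The first
time a class appears in a batch its center is set to the batch-class mean;
afterwards μ ← α·y + (1−α)·μ with y the current batch-class mean.  As
written, α weights the *current* batch, so the default α = 0.99 tracks the
batch mean closely with a 1% memory of history.  The conventional
heavy-smoothing reading is available by setting α small (e.g. 0.01); the
update rule is implemented literally and the knob covers both readings.
Centroid state persists across epochs — an EMA across batches is only
meaningful if it is not reset — and a per-class update counter distinguishes
"never seen" from "seen" so zero-initialised rows are never used as centers.

**Subclass partition.**  Within a batch, each present class's members are
partitioned by Euclidean distance to the (just-updated) centroid:

* `equal_width` (default): the range [0, max distance] is cut into N_s
  equal-width intervals; sample i gets index min(⌊d_i/d_t⌋, N_s−1) with
  d_t = max(d)/N_s.  Intervals are half-open with the last closed so every
  sample is assigned.
* `equal_rank`: the stable ascending sort of distances is cut into N_s
  contiguous blocks whose sizes differ by at most one; the block number is
  the subclass index.  This mode guarantees the near-equal subclass
  occupancy that motivates the split; equal-width cannot.

A batch-class whose distances are all equal (to relative precision 1e-9)
carries no spread information and maps to subclass 0.  The tolerance is not
cosmetic: a class whose first centroid update comes from exactly two samples
places both mathematically equidistant from the centroid, and without the
tolerance their subclass membership would be decided by floating-point
noise.  Rank-mode ties are broken by input position, keeping assignments
deterministic.

**Pseudo-labels.**  Sample of class c in subclass k gets pseudo-label
s_c + k, with s_c = Σ_{j<c} N_s(j).  The per-class ranges partition [0, P)
exactly, so the true class is always recoverable by a range lookup
(`canonical_projection` provides the lookup and the P×C 0/1 summation
matrix used as a test oracle for the learned mapper).

**Subclass counts.**  The tail class is the unit: N_s(c) =
max(1, round(N_c/N_min)) (half-up rounding), optionally clipped by a cap,
or a hand-tuned per-class vector supplied in the config.  All-equal counts
give N_s ≡ 1 and the framework degenerates to plain cross-entropy training.

**Two-phase alternation.**  Per batch (default; per-epoch available):
phase 1 computes subclass logits, assigns pseudo-labels, and takes one
SGD-with-momentum step on the pseudo-label cross-entropy (Loss1) through
classifier and backbone only; phase 2 feeds the *detached* logits of the
same batch to the mapper and steps on the true-label cross-entropy (Loss2)
through the mapper only.  The freeze contracts (phase 1 leaves the mapper
bit-identical and vice versa) are asserted in tests by parameter checksums.
At inference the clustering module is absent: backbone → classifier →
mapper → argmax.

**Rebalancing baselines.**  `none`, `resample` (per-sample draw probability
∝ 1/E_c) and `reweight` (per-class loss weight ∝ 1/E_c, normalised to sum
to C) with E_c = (1−b^{N_c})/(1−b) the effective number of samples
(default b = 0.999; as b→1, weights approach inverse class frequency).
Under `reweight`, each pseudo-class inherits its parent class's weight, and
the weights apply in both phases.

**Model selection.**  When a validation split is supplied, the returned
model carries the parameters of the epoch with the best validation top-1
(computed from true labels only; pseudo-labels are never produced outside
training steps).  This matters for the subclass runs: the pseudo-label
targets move with the centroids, so the raw end-of-run parameters fluctuate
while the best-epoch model is stable.

## Numerical and implementation choices

Networks are dense stacks (Linear/ReLU) with explicit backpropagation over
float64 numpy arrays; the optimiser is SGD with classical momentum
(v ← m·v + g, p ← p − lr·v).  Hidden layers use He-normal initialisation;
classifier and mapper output layers use a deliberately small scale
(std 0.01/√fan_in) so a fresh network starts at the uniform cross-entropy
ln K — the first-batch sanity band asserted in tests.  The default backbone
is an MLP (images are flattened first); an identity backbone exposes raw
features to the classifier directly.  The backbone is a contract, not a
fixed architecture: anything implementing forward/backward/params plugs in.
Full-scale optimizer defaults (lr 1e-4, 200 epochs, batch 32, momentum 0.9)
are kept in `TrainConfig`; desk-scale experiments override lr and epochs.

All randomness flows from one seed through named `SeedSequence` children
(model init / mapper init / batch order), so a run is bit-reproducible and
the one-subclass configuration reproduces a plain cross-entropy trainer's
parameter trajectory exactly, checksum for checksum — the strongest
correctness check on the training loop.

Non-finite activations or losses abort training with the offending epoch
and batch in the exception.

## Synthetic data: what it emulates and what it does not

`generate_gaussian_longtail` draws class centers at distance D from the
origin in random directions (feature dimension 8 by default) and, for
multimodal classes, subcluster centers at distance D from the class center;
samples are isotropic Gaussian (σ = `cluster_spread`) around subcluster
centers.  Defaults D = 2.5, σ = 1.0 give moderately overlapping classes —
separable but with genuine confusion, which is the regime where imbalance
hurts.  The generator encodes the method's structural premise: head classes
occupy broad regions with internal substructure while tail classes are
unimodal.  Subcluster identity is recorded as hidden ground truth.  What it
does not emulate: feature distributions induced by a *jointly trained* deep
backbone (whose geometry co-evolves with the clustering), label noise, and
the heavy non-Gaussian structure of real images; passing tests show the
algorithmic machinery behaves as designed, not that the method's gains
transfer to any particular real dataset.  `generate_blob_images` renders
one shape family per class with pose/scale as the intra-class nuisance so
the full image path (flatten → MLP) can run end to end.

The long-tail builder ranks classes by available count (ties by index) and
keeps round(N_max·β^(−r/(C−1))) samples for rank r under the `exponential`
profile — the standard geometric interpolation between the endpoints, which
only the endpoints pin down — or trims only the smallest class under
`endpoints_only`.  Subsets are drawn without replacement from a seeded
generator; test splits are never subsetted.

## The recovery experiment

`dicc.experiments.run_recovery_experiment` is the package's operational
check that head-class splitting helps the tail: four classes with training
counts 400/200/100/20 (β = 20), bimodal heads, balanced validation (50 per
class, drives best-epoch selection) and test (100 per class) splits from
the same mixture; MLP backbone (32, 16), lr 0.05, batch 32, 30 epochs, five
seeds; derived plan (20, 10, 5, 1), i.e. P = 36, versus the N_s ≡ 1
baseline under identical seeds and schedules.  Reported: mean tail-class
recall and top-1 on the test split for both arms.  Problem sizes were
chosen so the full five-seed, two-arm experiment completes in seconds on a
single CPU while leaving the tail class genuinely hard (≈60–70% recall).
The observed advantage of the subclass arm is consistent but small (a few
recall points); at this scale the mechanism — balancing per-(sub)class
gradient mass — is present, but the variance across seeds is substantial,
which is why the experiment compares means over five seeds rather than
single runs.

## Known limitations

* No convolutional backbone: without an autodiff framework the backbone
  family is dense-only, so image experiments flatten pixels.  The backbone
  contract accepts external implementations.
* Per-batch pseudo-labels are noisy for classes whose per-batch membership
  is smaller than their subclass count; equal-rank mode then assigns nearly
  one subclass per sample.  This is inherent to batch-local partitioning.
* The equal-width and rank-block partitions are both legitimate readings of
  the method's partitioning step; they disagree on unevenly dispersed
  batches, which is why both are exposed and tested.
* PR curves are computed one-vs-rest from mapped class scores; no AUROC,
  calibration, or cross-run significance testing.
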