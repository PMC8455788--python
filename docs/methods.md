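# Methods

## Problem and representation

Cysts in advanced polycystic kidneys are numerous (hundreds to thousands per
exam), near-spherical, and densely clustered: adjacent cysts abut with flat
contact faces and, at typical coronal T2 resolutions (in-plane ≈ 0.8–1.9 mm,
slices 3–9 mm), frequently merge through the slice axis.  `cystseg`
represents an instance segmentation as a 3-class *edge-core* semantic map —
{0 background, 1 edge, 2 core} — so that a slice-wise classifier only has to
learn three classes while the decoder recovers arbitrarily many instances
from the geometry of the core class.  All volumes are arrays indexed
(x, y, z) with z the slice axis; intensities are float32 (MR dynamic range
needs no more); NIFTI-1 is the interchange format and integer label maps are
written with an on-disk integer type wide enough for the largest label.

## The two codecs

**Dilation codec** (`encode_dilation`, first generation).  Core = the
instance itself; edge = its one-voxel 3D dilation shell (6-connected cross).
By default a voxel that is core of any instance stays core even inside
another instance's shell.  The historical behaviour — painting instances
sequentially so a later shell overwrites earlier cores at contact faces — is
available as `sequential=True`; it is what loses cyst volume on clustered
kidneys (measured below) and motivated the second codec.  Decoding is plain
6-connected component labelling of the core class (`decode_initial`), which
additionally fuses any cysts whose cores touch through thick slices.

**Erosion codec** (`encode_erosion`, production).  On the up-sampled working
grid, each instance is first *opened* with the 6-connected 3×3×3 cross
(`open_instances`); instances that vanish under erosion are removed there,
and `encode_erosion` refuses un-opened inputs rather than dropping instances
silently.  Core = 3D erosion of the instance; edge = the 3D inner edge
(instance − core) plus a per-slice 2D 4-connected outer dilation ring, the
latter computed per instance and unioned.  Class precedence on overlap is
core > edge > background.  Two properties make this codec exactly
invertible on opened instances: dilation ∘ erosion = opening = identity, and
every eroded core voxel has its full 6-neighbourhood inside its own
instance, so cores of distinct instances are never 6-adjacent.

## Working grid

`upsample_exam` brings an exam to in-plane `inplane_target` (512 for
clinical matrices; tests use smaller targets with the same integer scale
factors) and 3× the slice count, preserving physical extent (spacing is
rescaled).  Intensities are interpolated bicubically.  Labels are
interpolated *per label* as binary masks (order-1, threshold 0.5; where two
labels both pass threshold the larger value wins, ties to the smaller
label): interpolating label integers directly would invent intermediate
labels.  A cyst present on a single slice occupies ≥ 3 planes afterwards, so
it survives the erosion codec.  Grid-aligned sampling (`grid_mode`) places
up-sampled block centres on original voxel centres, so the down-sampling
step — nearest-neighbour sampling at block centres (`downsample_labels`) —
is an exact inverse of the label up-sampling for integer factors.  Nearest-
neighbour was chosen over re-thresholding for down-sampling because it
preserves small instances and introduces no new ambiguity.

## Decoding

`decode_final` = `split_cores` → `recover_lost_cores` → `dilate_instances`
→ `downsample_labels` → `filter_small(4)`.

- `split_cores`: Euclidean distance transform of the core mask, in voxel
  units (the working grid is near-isotropic after the 3× slice
  up-sampling); watershed of −EDT restricted to the mask with
  `watershed_line=True` (ridge voxels stay 0).  Seeds are the regional
  maxima of the *h-maxima suppression* of the EDT with h = 1 voxel,
  computed as the maxima plateaus of the morphological reconstruction of
  (EDT − 1) under EDT.  This merges maxima separated by saddles shallower
  than one voxel — the depth of digitization steps on thresholded
  up-sampled surfaces — while genuine two-cyst necks are deeper and keep
  separate seeds (a dumbbell of radius-4 spheres 6 voxels apart has saddle
  depth ≈ 1.35 and splits).  Plateau voxels are grouped into one seed with
  26-connectivity, because plateaus of digitized blobs fragment diagonally;
  the flood itself is 6-connected.
- `recover_lost_cores`: thin or few-voxel cores (EDT maximum ≤ 1) attract
  no seed, and ridge voxels are left unlabelled; their 6-connected
  components are appended with labels max+1, max+2, … so that every core
  voxel carries exactly one label (conservation is asserted in tests).
- `dilate_instances`: exactly one dilation round (the inner edge is one
  erosion deep).  A contested voxel goes to the 6-neighbour with the
  largest core EDT value — the instance whose body reaches deepest there —
  with remaining ties to the smallest label; the rule is order-independent
  and is verified against a per-voxel oracle.  Dilation is deliberately not
  constrained to the edge class: round-trip exactness requires claiming the
  inner edge wherever it lies.
- `filter_small`: instances below 4 voxels *on the acquisition grid* are
  removed (the MR noise floor used when building reference tracings);
  survivors are relabelled 1..K in ascending old-label order.

## Predictor contract, training, ensembling

A slice predictor is any callable mapping a 4-channel stack
[slice z−1, slice z, slice z+1, kidney mask at z] (out-of-range neighbours
are zero planes) to per-voxel probabilities over {background, edge, core}.
Intensities are normalised per volume to [0, 1] by the 1st–99th percentile
inside the kidney mask (field-strength invariance); the channel order is
fixed as above.

The bundled implementation is an inception U-Net written on a small numpy
layer kit with hand-written backprop (`cystseg._nn`): encoder stages are
inception blocks (parallel 1×1/3×3/5×5 convolutions, concatenated, ReLU)
followed by stride-2 convolutions and dropout; the decoder mirrors them with
nearest-neighbour up-sampling, skip concatenation and inception blocks; a
1×1 convolution and softmax end the network.  Branch width (`base`, default
8 ⇒ stage width 24) and `depth` (default 2) are configurable; gradients are
verified against finite differences to ~1e−6 relative error in float64.
Training (`train_reduced`) minimises 1 − J, J the soft Jaccard index
averaged over edge and core with smoothing ε = 1 (the index is maximal at a
perfect match, so 1 − J is the minimised loss), using Adam with the
production recipe as defaults: 200 epochs, batch size 6, learning rate
1e−3.  No extra class weighting is applied — the 2D outer edge dilation at
encode time is the class-imbalance mitigation.  Full-scale training is out
of scope; `train_reduced` exists to overfit small phantoms and prove the
optimisation plumbing (the suite checks a decreasing, seed-reproducible
loss trajectory).

`select_ensemble` ranks candidate predictors (e.g. four cross-validation
folds) by mean edge/core Jaccard on validation exams and keeps the top
three.  `majority_vote` picks the class with ≥ 2 of 3 votes per voxel; a
1-1-1 split is resolved by the largest summed probability, remaining ties by
the precedence core > edge > background; a tie between hard-label-only
members is an error rather than an arbitrary choice.  `predict_exam` runs
members slice-wise, votes, and forces voxels outside the kidney mask to
background.  `MockOraclePredictor` replays an encoded ground truth so the
whole pipeline is exercisable with no trained weights (CLI
`--mock-oracle`).

## Quantification and agreement

Similarity metrics binarize instance maps (label > 0): Dice, Jaccard,
precision, recall, and ARVC = |V_p − V_r| / V_r with the *reference* volume
as denominator (this convention reproduces the published reader-study ARVC
means; the reader-vs-reader cell of that table is better matched by a
pair-mean denominator, which we note but do not use).  Empty-vs-empty pairs
score all metrics perfect so cyst-free exams are well-defined.  TCV = Σ
labelled voxels × voxel volume (mL); cystic index = 100 · TCV / TKV.
Bland–Altman statistics use percent differences relative to the pair mean,
dᵢ = 100(aᵢ − bᵢ)/((aᵢ+bᵢ)/2), with bias = mean(d) and precision = sample
(n−1) standard deviation — the only convention that reproduces all three
published reader-study triples from the printed volumes ("precision" is
never defined algebraically in the source material; n−1 is inferred from
exact numeric agreement).  R² is the squared Pearson correlation from OLS.

## Phantom generator

`generate_phantom` emulates what the pipeline assumes about clinical exams,
not MR physics: two ellipsoidal kidneys; cysts as spheres digitized by
voxel-centre membership in physical mm (so thick slices yield flattened
voxel spheres and the z-axis pathology the decoder must handle); a
cluster_fraction of cysts placed against an existing cyst at 0.85–1.0 of
the sum of radii (touching or slightly overlapping — a flattened contact
face); later placements yield voxel-wise to earlier ones, and a placement
keeping < 70 % of its sphere is rejected (deep interpenetration is not a
physical configuration of distinct cysts).  Labels are 1..K in placement
order; every label is one 6-connected component fully inside the kidney.
Intensities: background 0.05, parenchyma 0.45, simple cysts 0.95,
"complicated" (hypointense) cysts 0.12 with probability
`hypointense_fraction` (default 0.1), an optional bright pelvis-like
ellipsoid (0.90) at each kidney's medial pole outside the cyst truth, plus
additive Gaussian noise (σ = 0.03 default).  Defaults: 96×96×24 voxels at
(1.41, 1.41, 4.0) mm — the target cohort's median acquisition — 30 cysts,
log-normal radii (median 4 mm, σ_log 0.35).  Deliberate omissions: Rician
noise, bias fields, partial-volume spectra, non-spherical cysts.  Passing
tests therefore demonstrate the geometric/decoding guarantees and pipeline
plumbing, not clinical segmentation accuracy.

## Measured guarantees (recomputed by `scripts/acceptance.py` and the suite)

On 20 seeded phantoms (64×64×24 at (1.5, 1.5, 3.0) mm — 3 mm is the initial
cohort's median slice thickness and gives the near-isotropic working grid
the production pipeline assumes — 15 cysts each, cluster fraction 0.5,
radius median 6.5 mm σ_log 0.15 so all cysts exceed 2 in-plane voxels in
radius): the erosion-codec round trip (encode the opened up-sampled truth →
`decode_final`) preserves the reference-standard TCV with bias ≈ −0.004 %
and precision ≈ 0.01 %, and preserves the per-exam instance count exactly;
the sequential dilation codec decoded the initial way loses ≈ 8 % TCV on
the same phantoms.  The reference standard here is the *opened* truth: the
opening is part of the reference-standard definition (it exists precisely
so the erosion→dilation round trip is exact), and costs a few percent of
raw truth volume on small digitized cysts.  The clinical similarity tables
and final-model agreement statistics of the source study require its
60-exam dataset and trained weights and are not reproduced; the end-to-end
oracle-ensemble test stands in for them at desk scale.

## Numerical and degenerate-input choices

Scan-order relabelling (first-encountered voxel in C order) fixes label
identity everywhere labels are assigned.  `jaccard_index` with smoothing 0
scores an empty-vs-empty pair 1 by convention.  `bland_altman` requires
strictly positive series (relative differences); `linreg_r2` rejects a
constant x.  `cyst_stats` raises on a cyst-bearing exam with an empty
kidney mask (undefined cystic index) but returns zeros when both are empty.
Phantom generation, training, and all CLI commands are bit-reproducible
given their seeds.
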