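# Methods

`nphkit` implements an automated pipeline for screening normal pressure
hydrocephalus (NPH) from CT-like brain volumes.  The pipeline has four
scientific components: (1) a probability-map-augmented 3-D UNet that
segments the volume into six classes, (2) a region-of-avoidance (ROA)
procedure that converts the ventricle segmentation into a filter over an
atlas streamline set, (3) graph coefficients of the resulting structural
connectome, and (4) a linear SVM that fuses volumetric and network
features into a binary NPH prediction.  A synthetic phantom generator
makes every stage testable without any imaging data.

## Segmentation model

The segmentation network is a 3-D UNet variant operating on grids whose
axes are divisible by 16.  The encoder has four downsampling blocks (two
3×3×3 convolutions and a rectifier each; the first three halve the grid
with a stride-2 first convolution, the fourth is preceded by 2×2×2 max
pooling), doubling feature channels at each level, so the bottleneck
sits four resolution levels below the input.  The decoder mirrors this
with four upsampling blocks (two conv+rectifier passes, 2×2×2
nearest-neighbour upsampling, a 1×1×1 convolution, group normalisation)
and skip concatenations from the matching encoder blocks.  Two auxiliary
taps after the first rectifier of decoder blocks 2 and 3 pass through
1×1×1 convolutions, are summed across scales, upsampled, and
concatenated into the last decoder block.  Every 3×3×3 convolution is
followed by group normalisation (default 4 groups, clamped to the
channel count).

The distinguishing input is a pair of spatial probability maps for the
two cerebrospinal-fluid classes that are hardest to separate on CT —
the lateral ventricles and the subarachnoid space.  The maps are the
voxelwise average of registered training annotations in a common
template space, carried into each subject's grid by the inverse of its
template registration (trilinear interpolation; the interpolation for
this step is this package's choice, as is the RAS/NIfTI convention
throughout).  A two-convolution branch ingests the 2-channel map stack
and joins the main stream at the last upsampling level.  When
cross-validating, maps must be rebuilt from each fold's training
annotations only; `build_probability_maps` takes an explicit annotation
list for exactly this reason.

### The six classes

The head emits a 6-channel softmax: background, ventricle, subarachnoid
space, gray-white matter, cerebellar CSF, cerebellar gray-white.  A
softmax needs a background class, so within a 6-channel budget the
cerebellar tissue is represented by two classes (its CSF spaces and its
parenchyma) and skull voxels train as background (`SKULL_LABEL`
collapses to 0 in `collapse_training_labels`).  Phantom label volumes
keep skull as a separate seventh label for intensity synthesis and for
the Evans'-index inner-skull reference.

### Training

Defaults follow the clinical-scale protocol: Adam at learning rate 1e-3,
weight decay 1e-4 (classic coupled L2), dropout 0.5 on the bottleneck
and decoder outputs, 300 epochs.  The loss is voxelwise cross-entropy;
"hard per-image" mode restricts each image's loss to its hardest
fraction of voxels (default 0.7, configurable back to plain CE).  The
hard-fraction reading of hard-example mining is one of two defensible
interpretations; both modes ship.  Input intensities are clipped to the
annotation viewing window [-980, 80] HU and min-max scaled; the bounds
are configurable because relative density information matters.

The network and its optimiser are implemented directly on numpy arrays
with an in-repo reverse-mode autodiff (`nphkit._nn`): convolution as a
tensordot over a strided sliding-window view, group-norm and max-pool
backward passes written out, Adam with bias correction.  Gradients are
verified against float64 finite-difference oracles in the test suite.
A full forward/backward pass on a 32³ volume at 4 base channels takes
about 0.13 s on one CPU core.

**Desk-scale overfit protocol.**  The repository's convergence check
overfits a single 32³ phantom at 4 base channels for 200 epochs and
requires ventricle Dice ≥ 0.90.  Because one volume yields one Adam
step per epoch, the total per-weight displacement of such a run is
bounded by roughly lr × epochs; at the clinical default of 1e-3 a
200-step run cannot reach confident logits regardless of architecture.
The desk protocol therefore uses lr 2e-2 with hard per-image CE
(fraction 0.7) and no dropout, which reaches ventricle Dice 1.0 across
initialisation seeds.  The clinical defaults are unchanged.

## Region of avoidance and connectome

Patient-specific diffusion data is not part of a CT workflow, so the
connectome is approximated by filtering a fixed atlas streamline set:
the predicted ventricle mask, carried to template space, acts as a
region of avoidance, and a streamline is discarded iff any point of its
dense resampling (step = half the minimum voxel spacing, vertices always
included; step configurable) falls in a mask voxel.  Enlarged ventricles
therefore knock out more fibers.  Surviving fibers are tallied into a
90×90 matrix by *endpoint-pair counting*: the parcel labels at the first
and last point form an edge; fibers with a background endpoint or both
endpoints in one parcel are dropped.  Endpoint counting (rather than
pass-through counting) is the simplest defensible edge definition and is
isolated behind `build_connectivity` so the alternative could be swapped
in.  The 90-region default matches the classic cerebral parcel count of
AAL-style atlases; `n_regions` is a parameter.

## Network coefficients

Thirteen coefficient families are computed in binary and weighted
variants: density, mean local clustering, transitivity, characteristic
path length, small-worldness, global efficiency, diameter, radius,
degree assortativity, and rich-club at k ∈ {5, 10, 15, 20} — 26 values.
(The alternative reading in which density has no weighted variant is
available as `feature_mode="25"`; 26 is the default.)

Weighted conventions follow the Bullmore–Sporns / Rubinov–Sporns canon:
distances use edge length 1/w; clustering and transitivity first
normalise weights to a maximum of 1 and use geometric-mean triangle
intensity; the weighted rich-club divides within-club weight by the sum
of the equally many largest weights anywhere in the graph.  Density and
the path-based coefficients act on raw weights, so scaling all weights
by c scales weighted density by c and weighted path length by 1/c while
binary coefficients are unchanged — the scale behaviour the test suite
asserts.  Small-worldness is the path-length ratio only (characteristic
path length over the mean of 20 seeded G(n, m) null graphs with the same
node and edge counts; weighted nulls permute the observed weight
multiset onto random edges); no clustering normalisation is applied, as
that is how the protocol defines it.

Path-based coefficients are evaluated on the largest connected component
when filtering disconnects the graph.  Degenerate cases (no edges, empty
rich club, zero degree variance) substitute 0 and set a per-feature
boolean flag instead of propagating NaNs, so a heavily filtered
connectome still yields a finite 26-vector.

## Volumetric features, Evans' index, prediction

Per-class volumes are voxel counts times voxel volume (mL).  The four
volumetric features are ventricle, subarachnoid, cerebral gray-white,
and total volume; "total" sums all intracranial tissue classes
(including cerebellar ones, excluding skull) — the inclusive reading of
an ambiguous definition.

Evans' index is A/B: A is the maximal left-right span of the ventricle
mask over axial slices, restricted to the anterior half of the brain
bounding box (the operationalisation of "frontal horns" here); B is the
maximal inner-skull span.  Spans are measured centre-to-centre, so
quantisation error is at most one voxel per width.  The threshold rule
classifies index ≥ 0.3 as NPH.

Prediction standardises the fused 30-feature vector (z-score per
training fold; the protocol is silent on scaling, standardisation is
this package's choice) and fits a linear SVM with L2 penalty (C = 1.0,
configurable).  Evaluation repeats reshuffled stratified 5-fold
cross-validation (default 100 iterations) and pools train/test precision
and recall over all folds, reported as mean ± sd in percent with NPH as
the positive class.  A shallow fully-connected fusion head is described
in one place in the source protocol while the reported tables use the
SVM; the SVM path is primary here and the FC variant is not implemented
beyond the configuration seam.

## Synthetic phantoms

`make_phantom` builds nested-ellipsoid heads: a skull shell, a CSF-
filled cavity, a cerebral gray-white bulk, paired lateral-ventricle
lobes with explicit prism-shaped frontal horns, and an inferior
cerebellar compartment with a CSF rim.  Geometry is written in
canonical millimetres for a 128 mm field and scales with the actual
grid, so any shape divisible by 16 works.  Frontal horns span ±15 mm
and the inner skull ±50 mm by default, i.e. a built Evans' index of
0.30 at dilation 1.0; the ventricle dilation factor scales the
ventricular system and drives every downstream contrast.  Intensities
are class means (CSF 8, gray-white 30, skull 1000, background −1000 —
Hounsfield-flavoured) plus Gaussian noise (sd 5 by default).  Every
generator is a pure function of its seed.

Cohorts draw NPH subjects' dilation uniformly from (1.5, 1.9) by
default and keep controls at 1.0, which makes the groups linearly
separable on ventricle volume — deliberately: the end-to-end test asks
whether the pipeline *recovers* a contrast that is present by
construction.  What passing tests therefore show is that the machinery
(segmentation plumbing, ROA filtering, coefficient computation, CV
protocol) is correct; they do not show that real NPH cohorts are this
separable, that CT texture, partial-volume effects, scanner variation
or anatomical variability are handled, or that the clinical accuracy
figures transfer.  No diffusion physics is simulated; streamlines are
smooth splines between random parcel pairs.

## Problem sizes and numerical choices

The shipped tests run the pipeline at desk scale as the package's own
evaluation protocol: 32³–64³ grids, 4–8 base channels, 500–2000 atlas
streamlines, 90 parcels, 20-subject cohorts, 20 CV iterations.
Clinical-scale runs (256×256×128 grids, 50 000 streamlines, 100
iterations) use the same code paths with larger parameters.

Other numerical decisions: out-of-field voxels fill with 0 (labels,
probabilities) or −1000 (intensity); label resampling is
nearest-neighbour only; argmax ties break to the lowest class index;
Dice of two empty masks is 1; all randomness flows from explicit seeds
(cohort and pipeline seeds expand via `SeedSequence`); file writes are
atomic (temp file + rename).

## Known limitations

Registration is consumed, never estimated — transforms arrive as
FLIRT-style 4×4 matrices.  The phantom has no CT texture or artifacts.
The autodiff engine supports exactly the operator set this network
needs and trains one volume per step (no batching, no GPU).  The
weighted assortativity uses strength correlation over edges, one of
several conventions in use.  Rich-club coefficients are not normalised
against degree-preserving null models (the protocol's feature is the
raw fraction).
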