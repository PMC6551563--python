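# Methods

## Problem and model

`ventparc` labels every voxel of a skull-stripped, rigidly aligned,
inhomogeneity-corrected T1-weighted brain volume with one of five classes:
background, right lateral ventricle (RLV), left lateral ventricle (LLV),
third ventricle, fourth ventricle.  The target population spans normal
anatomy to severe ventriculomegaly (e.g. normal pressure hydrocephalus),
where atlas-registration-based parcellation tends to fail because the
ventricles are grossly enlarged and distorted.

The segmentation model is a residual 3D U-Net:

* **Contracting path.**  `depth` encoder blocks.  Each block is
  `conv3x3x3 -> activation -> conv3x3x3 -> activation` with a short residual
  skip: the output of the first conv+activation stage is added element-wise
  to the output of the second stage.  The first block runs at stride 1 (full
  resolution); every later block's first convolution has stride 2, so level
  *k* lives at 1/2^k of the input grid.  Inputs must therefore be divisible
  by 2^(depth-1).
* **Activation layers** are instance normalization followed by a leaky ReLU
  (negative slope 0.1).  Instance normalization standardizes each channel
  over space per sample, which makes the features — and hence the
  segmentation — invariant to positive affine rescalings of the input
  intensities, so no intensity normalization of the inputs is required.
* **Expanding path.**  One decoder block per level below the coarsest:
  `conv1x1x1 (channel halving) -> activation -> repeat-upsampling (x2) ->
  conv3x3x3 -> activation -> concatenation with the matching encoder output
  (long skip) -> dropout (rate 0.2) -> conv3x3x3 -> activation`.
* **Classification head.**  Every decoder output is projected to L=5
  channels by a 1x1x1 convolution; starting from the coarsest projection the
  maps are repeat-upsampled and summed level by level, and the finest sum
  passes through a channel softmax.  A switch disables the fusion (only the
  finest projection feeds the softmax) for ablation.

### Loss and optimization

Training minimizes one minus the mean soft Dice coefficient over all L
labels, background included:

    Loss = 1 - (1/L) * sum_l (eps + 2 sum_i P_il T_il)
                             / (eps + sum_i P_il + sum_i T_il)

with eps = 1e-3 guarding empty labels (their term tends to 1).  Optimization
is Adam with step size 0.001, beta1 0.9, beta2 0.999, eps 1e-7, batch size
one.  Each epoch regenerates the augmented training list: the N originals,
their left-right flips (with RLV/LLV labels exchanged — a mirrored right
ventricle is a left ventricle), and two fresh rotate+deform variants of each
of those, 6N items in a deterministic shuffled order.

### Numerical and design choices

The network, its gradients and Adam are implemented directly on numpy
(float32, im2col convolutions with zero "same" padding; instance-norm
statistics accumulated in float64).  Choices that the architecture
description leaves open, fixed here:

* **Residual summation point.**  The short skip adds the first-stage
  activations to the *activated* output of the second convolution
  (`out = h + act(conv(h))`), so zeroing the second convolution makes the
  block an exact pass-through of the first stage.
* **Input standardization.**  In instance-norm mode the input channel itself
  is instance-normalized before the first convolution.  With zero padding a
  shifted input (`a*x + b`) is not an exact per-channel affine image of the
  features at the volume borders, so post-conv normalization alone leaves a
  border-dependent residue; normalizing the input makes the linear-intensity
  invariance exact rather than approximate.
* **Batch-norm ablation.**  Batch normalization (batch size one) keeps
  running statistics with momentum 0.1; training normalizes with the current
  sample's moments, inference with the running estimates — which is exactly
  what breaks intensity invariance at test time.
* **Classifier initialization.**  Conv weights use variance scaling for
  leaky ReLU (seeded); the final projection biases start at the
  background-dominated label prior (foreground logits -4, split evenly
  across fused levels).  With uniform initial probabilities the mean-Dice
  loss over-predicts foreground everywhere early on and cleans this up very
  slowly (the spurious-voxel gradient scales with the small overlap term);
  prior-aware initialization removes that transient.
* **Decoder opening conv** halves the channel count (configurable).
* **Argmax decoding** breaks ties toward the lowest label index.
* **Cropping.**  Volumes are cropped symmetrically around the brain-mask
  bounding box to a target shape; odd slack puts the extra voxel on the
  high-index side, and a window that would leave the volume is shifted
  minimally to fit.  Crop offsets are kept so predictions are evaluated in
  the original frame.

## Evaluation metrics

Per compartment and for the whole ventricular system (union of labels 1-4):

* **DSC** `2|S∩T| / (|S|+|T|)`; defined as 1 when both masks are empty,
  0 when exactly one is.
* **HD95**: boundary voxels are mask voxels with at least one 6-neighbour
  outside the mask (grid edges count as outside); distances are Euclidean in
  mm via the voxel spacing; the 95th percentile (linear interpolation
  between order statistics) is taken within each directed distance set and
  the two directions combined with a max.  Undefined (an error) for empty
  masks.  Several incompatible HD95 conventions exist; this one is frozen
  and cross-checked against a brute-force all-pairs oracle in the tests.
* **AVD** `|V_S - V_T| / V_T * 100` (%), with volumes = voxel count x voxel
  volume.  Structures absent from both volumes are reported not-applicable
  rather than given fabricated numbers.

## Synthetic ventriculomegaly phantoms

Real cohorts with manual ventricle delineations are not redistributable, so
all desk-scale experiments run on generated phantoms: a single ellipsoidal
"brain" (tissue intensity 0.8) containing four disjoint CSF-dark
(intensity 0.2) compartments — two curved, tapered para-sagittal tubes
(lateral ventricles), a thin mid-sagittal slab (third) and a small inferior-
posterior midline ellipsoid (fourth) — plus multiplicative smooth bias
(default peak 10%), additive Gaussian noise inside the brain (default 10% of
the CSF/tissue contrast; the skull-stripped background stays exactly zero)
and small rigid pose jitter per subject.  A scalar `enlargement` dilates all
compartments (strongest on the laterals, as in hydrocephalus); ventricular
voxel volume is monotone in it at fixed seed, and an enlargement that would
push a ventricle through the brain mask raises an error instead of clipping.
The default 4 mm voxels put phantom ventricular volumes in the
tens-to-hundreds of millilitres, the range seen from healthy controls to
severe NPH; this millilitre calibration is a convenience, not a claim of
anatomical realism.

What the phantom deliberately does not model: cortical folding, partial
volume effects, white-matter hyperintensities, multi-contrast appearance.
Tests passing on phantoms therefore demonstrate that the pipeline's
mechanics and optimization work — not clinical-grade accuracy on real MRI.

## Desk-scale study conditions

The shipped `desk` preset, used by the tests and the results script, was
chosen once as a configuration that exercises every component on one CPU:

* phantoms: 32x32x32 voxels at 4 mm spacing; training cohort of 12 subjects
  with enlargement evenly spanning [0, 3]; 2 validation subjects; 4 held-out
  test subjects spanning the same range (all from disjoint seed streams);
* network: depth 3, channels (8, 16, 32), ~81k parameters;
* training: 20 epochs of the full augmentation protocol (72 items/epoch),
  Adam as above; elastic deformation uses 16 mm smoothing and at most 4 mm
  (one voxel) displacement, rotation up to 10 degrees per axis;
* the convergence-speed comparison between the fusion and no-fusion heads
  uses a smaller setting (20^3 phantoms, 6 training subjects with
  enlargement in [0, 2] and milder pose jitter, 12 epochs, validation-loss
  threshold 0.35) since only the epoch *ordering* of the two variants is of
  interest.

The `paper_scale` preset records the full-scale configuration
(192x256x192 inputs, depth 4, channels 32-256, 150 epochs); it is provided
as configuration only and requires accelerator-class hardware.

## Known limitations

* Single-channel T1-w input only; no DICOM, no preprocessing (N4, rigid MNI
  registration, skull-stripping are upstream tools).
* The numpy engine is single-threaded and desk-scale; it favours exact
  reproducibility (bit-identical reruns for a fixed config seed) over speed.
* Phantom realism as above; per-structure volume distributions are not
  calibrated to any cohort.
* HD95/percentile and boundary conventions are one defensible choice among
  several; comparisons against other implementations should align these.
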