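# Methods

## Problem setting

Quantitative CT analysis (CT-qa) of the lung decomposes every voxel inside
a lung mask into gas and tissue using the linearity of the Hounsfield
scale between air (−1000 HU) and water (0 HU):

    gas fraction   = −HU / 1000            (HU ≤ 0)
    tissue density = (HU + 1000) / 1000    [g/ml]

so gas fraction + density ≡ 1 on [−1000, 0]. Multiplying by the voxel
volume and summing over the mask gives total gas volume (ml) and total
tissue mass (g, the "lung weight"). Voxels are further classified into the
four standard aeration compartments over closed integer HU ranges:
non-aerated (+100…−100), poorly aerated (−101…−500), normally aerated
(−501…−900), hyper-inflated (−901…−1000). Recruitability between a low and
a high airway pressure is the fraction of non-aerated tissue mass at the
low pressure that regains aeration at the high pressure.

The expensive step is producing the lung mask. The package trains an
encoder-decoder network to predict it from a preprocessed slice.

## Conventions and numerical choices

* **Slice order**: index 0 is the most cranial slice. DICOM patient z
  increases toward the head, so series are sorted by descending
  z-position. This fixes the direction of cranio-caudal profiles.
* **HU arithmetic** is floating point; raw stored values stay integer.
* **CT-qa clamping**: HU is clamped to [−1000, +100] before the gas/tissue
  formulas and classification, so values below −1000 count as pure gas and
  gas volume is never negative. Float HU is rounded half away from zero to
  an integer before classification, because the compartment bounds are
  closed integer ranges. CT-qa always operates on original HU, never on
  the 8-bit preprocessed image, whose quantization (step ≈ 4.4 HU) would
  bias the mass estimates.
* **Rasterization** of ROI polygons: a pixel belongs to the mask iff its
  center lies inside or on any polygon, even-odd rule, boundary counted as
  inside. This is deterministic and is verified against an exhaustive
  geometric oracle.
* **Prone correction** is a 180° in-plane rotation keyed on Patient
  Position ∈ {HFP, FFP} (or an explicit flag); unknown position codes pass
  through with a logged warning.
* **Quantization** to 8 bits maps −1024 → 0 and +100 → 255 linearly and
  rounds half away from zero; the absolute quantization error is bounded
  by half a step, 1124/255/2 ≈ 2.204 HU. Normalization to the network
  range is (p − 128)/128, giving [−1.0, 0.9921875]; these constants are
  fixed, not configurable.
* **Thorax mask**: pixels at or above 8-bit value 119 (≈ −500 HU, a robust
  air/soft-tissue separation point), connected components below 0.5% of
  the slice area discarded, internal holes filled. The threshold and the
  particle fraction are exposed in `PreprocessParams` because no canonical
  values exist; the defaults are package choices.
* Background pixels removed by the thorax mask carry 8-bit value 0 and
  normalize to −1.0, i.e. they are indistinguishable from air — intended,
  since the mask exists to delete irrelevant anatomy.

## The network

A 2-D U-Net parameterized by `(input_size_px, base_channels, depth)`. The
shape law is: contraction level k operates at `input/2^k` pixels with
`base·2^k` channels. Each level applies two 3×3 convolutions (SAME
padding), each followed by batch normalization and LReLU (α = 0.1);
downsampling is a 3×3 convolution with stride 2 that halves the spatial
size and doubles the channels (replacing max pooling); the bottleneck has
two such conv blocks with a dropout layer (p = 0.4) strictly between them.
The expansion path upsamples by nearest-neighbour value duplication (×2),
applies an up-convolution halving the channels, concatenates the skip
feature map, and filters twice. The output layer is a 1×1 convolution with
a single filter and no activation. All weights are Xavier
(Glorot-uniform, fan-average) initialized; the variant name is recorded in
model metadata. At full scale (512, 32, 5) the bottleneck is 16×16 with
1024 channels and the graph contains 8,993 convolution kernels.

The implementation is plain numpy with hand-written backpropagation
(im2col-free shift-and-accumulate convolutions, standard batch-norm
gradients, inverted dropout). Convolutions use the flipped-kernel
orientation of the discrete-convolution definition, which lets a naive
quadruple-loop implementation serve as an independent oracle; since
kernels are learned, the orientation is irrelevant to the model class.
Gradients are verified against central finite differences in the tests.

Design points that were genuinely open:

* *Upsampling* is value duplication followed by a 3×3 convolution, not a
  learned transposed convolution of the resize step itself.
* *Binarization*: targets are {−1, +1} under MSE, so the raw output is
  thresholded at 0, the symmetric decision boundary (configurable).
* *Batch-norm placement* is conv → BN → LReLU.
* *No post-processing* (e.g. largest-component filtering) is applied to
  predicted masks by default, so evaluation reflects raw network output.

## Training

One iteration = sample a minibatch (size 12, uniform with replacement;
an epoch-shuffling mode exists behind a flag) → forward → MSE loss →
backpropagation → SGD update. Learning rate 0.01 and momentum 0.9 are
conventional defaults — no published regime dictates them — and both are
mandatory config keys recorded in the checkpoint. Weight decay defaults to
0. There is no early stopping; the iteration count is configuration. NaN
loss aborts with a diagnostic. Train/test splits are drawn at patient
granularity so no subject leaks across sets.

## The phantom generator

Each synthetic subject is a thorax ellipse of body soft tissue (+40 HU) in
air (−1024 HU) containing two lung ellipses whose semi-axes taper toward
apex and base (elliptical taper with a floor of ~0.35 so end slices keep a
visible lung). Aeration profiles:

* `normal`: homogeneous −800 HU lung;
* `ards_gradient`: HU linear in the ventral→dorsal pixel coordinate
  (default −950 → +50), crossing all four compartments — a minimal model
  of the gravitational density distribution of ARDS; optionally a dorsal
  pleural-effusion-like crescent (+10 HU) outside the lungs.

Ground truth (mask, gas volume, tissue mass, per-compartment masses) is
computed from the noiseless integer-HU field by exact integer accumulation
(masses are integer multiples of `V_voxel`/1000 g) *before* Gaussian HU
noise (default SD 10 HU, truncated to [−1024, +100]) is added. CT-qa on a
noiseless phantom therefore reproduces the truth to machine precision, and
on a noisy ≥10⁴-voxel lung to well under 1% (zero-mean noise averages
out).

**Paired pressures.** Within a fixed voxel grid, gas fraction and density
sum to 1, so a voxel cannot gain gas and keep its tissue mass — a lung
gaining gas at constant mass must occupy more voxels. The paired-pressure
construction therefore: (i) keeps all non-recruited voxels bit-identical;
(ii) converts the ventral-most non-aerated voxels to normally aerated
(−700 HU) until the target mass fraction `1 − low/high` is reached (voxel
granular; the achieved fraction is recorded in the truth object); and
(iii) moves the displaced tissue mass, in exact integer units, into an
aerated expansion shell grown around the lungs inside the thorax. Total
tissue mass is conserved exactly while gas volume rises, which is what the
cross-pressure lung-weight consistency audit assumes of a perfect
segmentation.

The default corpus mixes cohorts in proportion normal : ARDS : COVID-19 =
15 : 100 : 20, with per-subject geometry jitter; COVID-19 subjects use a
milder, ground-glass-like dorsal gradient. The desk-scale study conditions
are 24 subjects × 10 slices at 64×64 px (4×4×5 mm voxels), 80/20
patient-level split, 600 iterations — sized so the whole experiment runs
in a few minutes on one CPU while leaving the full-scale configuration
available unchanged.

**What the phantoms do not emulate**: airways, vessels, lobar anatomy,
scanner kernels, beam hardening, motion. Passing the phantom experiments
demonstrates that the pipeline's mechanics (preprocessing, training loop,
shape laws, quantification, statistics) are correct; it does not certify
segmentation accuracy on clinical CT, where anatomy and pathology are far
harder.

## Agreement statistics

IoU is computed per slice and per stacked volume; the per-volume value is
voxel-level by design (a slice-mean variant exists behind a flag), since
that is the standard volumetric reading. Two empty masks have IoU 1
(agreement on absence) but such slices are excluded from cranio-caudal
profile bins, which describe lung-bearing slices; each subject's slice
axis is normalized to [0, 1] and binned (20 bins by default).
Bland-Altman limits use the 1.96 multiplier on the sample SD (ddof = 1).
The paired test is Student's t when Shapiro-Wilk does not reject
normality of the differences at α = 0.05, otherwise Wilcoxon signed-rank;
two-tailed throughout.

The well-aerated form of recruitability is reported as the change in
normally-aerated tissue mass divided by the total tissue mass at the low
pressure; the denominator is not canonical, so it is stated in the result
metadata.

## Known limitations

* The numpy network is CPU-bound; full-scale training (512 px, tens of
  thousands of iterations) is out of practical reach — the full-scale
  configuration is built and audited for its shape laws and kernel count,
  not trained here.
* SGD with momentum is the only optimizer, MSE the only loss.
* Single-frame axial DICOM only; no multi-frame/enhanced objects, gantry
  tilt, or DICOM-RT structure sets.
* Batch-norm running statistics are updated with a fixed momentum (0.1);
  very short training runs may leave them close to their initialization.
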