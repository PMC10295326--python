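# Methods

`trabeculagen` implements a complete desk-scale pipeline for studying
whether clinical-resolution CT of vertebral trabecular bone can support
micro-CT-grade morphometry after unpaired image-to-image translation. Real
cadaver scans are replaced by synthetic phantoms with exactly known ground
truth, so every downstream claim is checkable. This note records the models,
the parameters that matter, the numerical choices, and what the synthetic
setting does and does not demonstrate.

## Phantoms

**Microstructure model.** Cancellous bone is modelled as the excursion set
of a band-limited Gaussian random field: an iid Gaussian voxel field is
low-pass filtered with an isotropic (optionally anisotropy-weighted)
Gaussian kernel and thresholded inside the cancellous compartment. The
threshold is the order statistic that selects exactly
`round(BV/TV_target x n_cancellous)` voxels, so the achieved bone volume
fraction equals the target to within one voxel *by construction* — this
exactness is what makes BV/TV recovery a sharp test. The vertebral
cross-section is an ellipse with a posterior circular canal notch, wrapped
in a cortical shell of configurable thickness (default 0.4 mm); soft tissue
surrounds the body.

**Thickness control.** No closed form links the field's correlation length
to the local thickness of the thresholded phase, so the mapping (filter
sigma, in voxels) -> (mean Tb.Th, in voxels) is measured once per volume
fraction on a 96^3 calibration field with a fixed internal seed, fitted
linearly, inverted, and cached for the process lifetime. Across the default
cohort the oracle-measured Tb.Th lands within a few percent of the target.

**What is not controllable.** At fixed BV/TV and Tb.Th the separation of a
thresholded Gaussian field is emergent: the defaults (BV/TV 0.18, Tb.Th
0.218 mm) yield Tb.Sp ~= 0.52 mm, not the ~0.93 mm typical of elderly
lumbar specimens measured by the same metrics. Real trabecular networks are
more rod-like and more anisotropic than a Gaussian excursion set at this
volume fraction. `target_tbsp_mm` is retained in the interface for
documentation, and the achieved value is stored in the ground truth record.
Conclusions about Tb.Sp recovery therefore apply to the phantom texture,
not to real bone.

**Rendering.** The binary microstructure is relabelled to 8-bit intensities
(bone 200, marrow 50, soft tissue 80 by default; the mapping is a
convention, not a fit to any scanner) and rendered twice:

* *micro-CT-like*: native isotropic 52 µm grid, Gaussian PSF of sigma
  0.026 mm (half a voxel), additive Gaussian noise (default sd 8).
* *MDCT-like*: separable Gaussian PSF with FWHM 0.4 mm in-plane and 0.6 mm
  axially (within the 200–500 µm clinical resolution range), resampled to
  0.195 mm in-plane (a 512 matrix over a 100 mm field of view) with axial
  spacing twice the micro-CT spacing — so an MDCT stack always has
  `ceil(n_micro / 2)` slices, reproducing the 2:1 slice-count ratio that
  the pairing stage exploits — then quantized with noise (default sd 4).

Cohorts (`make_study_set`) jitter BV/TV (sd 0.016) and Tb.Th (sd 0.015 mm)
per vertebra, matching typical inter-specimen scatter, and derive all
randomness from one master seed; identical seeds give bit-identical
volumes.

## Morphometry

**Binarization** uses the IsoData (iterative intermeans) threshold on the
8-bit histogram of the VOI: starting from the region mean, iterate
`t <- (mean(values <= t) + mean(values > t)) / 2` to a fixed point. One
global threshold per VOI is the default; per-slice thresholding sits behind
a flag. Voxels strictly above the threshold are bone.

**BV/TV** is an exact integer ratio (foreground voxels in the VOI / VOI
voxels) and is invariant under any monotone intensity remapping that
preserves each voxel's side of the threshold.

**Local thickness** follows the largest-inscribed-sphere definition: the
thickness at a voxel is the diameter of the largest sphere containing it
that fits in the phase. The implementation computes the exact Euclidean
distance transform, reduces the centre set to a distance ridge, and paints
spheres in decreasing radius order. Two numerical choices matter:

* All cover tests use *integer squared* radii: a centre with squared
  distance value R2 covers lattice points with squared offset `<= R2 - 1`
  (the strict inequality `|v - c| < r` without floating-point ties), and
  the assigned diameter is `2 sqrt(R2) - 1` voxels, so a slab t voxels
  thick maps to exactly t and an isolated voxel to 1.
* The ridge test prunes a centre only when its *digital* sphere (the
  lattice point set) is contained in a 26-neighbour's, decided by
  precomputed containment templates indexed by squared radius and offset
  class. Digital containment is weaker than the Euclidean bound, prunes
  1–2 orders of magnitude more centres on curved phases, and is exactly
  lossless: the painted map is identical to brute force, which the test
  suite verifies voxel-for-voxel against an independent pairwise-distance
  oracle.

Tb.Th is the mean map value over bone voxels in the VOI, Tb.Sp the same for
the marrow phase (so `tbth(B) = tbsp(~B)` exactly); the sd is taken over
voxels, not over trabeculae. Thickness is only defined on isotropic grids;
`measure_stack` resamples anisotropic stacks (e.g. MDCT) to the finest
pitch by linear interpolation first. Region-limited measurement crops to
the VOI bounding box plus an adaptive margin (three times the largest
observed sphere radius), pads cut borders with background so truncation can
only shrink spheres, and discards phase components that do not touch the
VOI (a sphere containing a VOI voxel cannot leave its connected component).
Volume borders behave as if the phase continued; metrics are 3-D over the
VOI, not per-slice averages.

**VOI placement.** The standard cylinder is 15 mm diameter x 5 mm height.
The anatomical construction (centreline of the short axis of the axial
body section; tangent point 5 mm interior to the anterior edge; two
cylinders 5 mm above/below the cranio-caudal midline) is implemented and
flags `clipped=True` with a warning when the body cannot contain the
cylinder. Phantom studies default to a centred VOI because the desk-scale
bodies (~24 mm) cannot honour the anterior-margin construction at full VOI
size.

## Slice pairing

MDCT and micro-CT stacks of one specimen are aligned along the slice axis
by appearance: MDCT slices are bicubically upsampled to the micro-CT
in-plane grid (keypoint coordinate distances are only comparable on one
grid); SIFT keypoints are matched across modalities with a Lowe ratio of
0.75 plus mutual-nearest-neighbour filtering; a slice pair's distance is
the mean Euclidean distance between matched coordinates, with pairs holding
fewer than three matches assigned a sentinel of (largest finite distance in
the matrix + 1) so the alignment stays total. Dynamic time warping with
steps {(1,0), (0,1), (1,1)} (ties broken diagonal-first for determinism)
yields the optimal monotone path — verified against exhaustive path
enumeration on small matrices — and each micro-CT slice is then paired with
the first MDCT slice the path assigns it, replicating MDCT slices ~2x. On
phantom stacks, where truth is micro slice 2i <-> MDCT slice i by
construction, >= 90% of recovered pairs fall within one slice of truth at
default noise.

## Translation model

The generator is an encoder–decoder conditioned on a class code: a content
encoder (convolutions with instance normalization and ReLU, three stride-2
stages: a 64x64 slice gives an 8x8 spatial code) extracts layout; a class
encoder (convolutions without normalization, globally pooled, averaged over
the K target images; K = 1 here) extracts texture; the decoder applies two
AdaIN residual blocks — features instance-normalized, then scaled and
shifted per channel by two fully connected heads reading the class code,
with the scale kept positive through a softplus — followed by three
nearest-neighbour x2 upsampling stages. The discriminator is a patch
network: one convolution, ten residual blocks without normalization under
Leaky ReLU, four 2x2 average poolings, and a final convolution with one
channel per class (two classes), giving a 4x4 logit map at 64x64.

Training alternates discriminator ascent and generator descent on

    L_GAN + lambda_R L_R + lambda_F L_F,
    L_GAN = E[log D^cx(x)] + E[log(1 - D^cy(G(x, y)))],

with L_R the L1 identity reconstruction |x - G(x, x)| and L_F the L1
distance between discriminator features of the translation and of the
target. Each iteration draws a random *ordered* pair of distinct classes,
so the discriminator sees real examples of both classes over time. The
generator minimizes the non-saturating surrogate `-log D^cy(x_bar)` by
default; the literal `log(1 - D)` form (same optimum, prone to stalling
early) is available behind a flag. Probabilities are clamped to
[1e-7, 1 - 1e-7] inside logarithms; training aborts with a checkpoint if
any loss goes non-finite.

Defaults: lambda_R = 0.1, lambda_F = 1.0, RMSProp at lr 1e-4, batch 1,
64x64 single-channel slices, base width 6 (a desk-scale fraction of the
published architecture family's width; the layer topology is fixed, widths
are configuration). One master seed drives weight initialization and batch
sampling; checkpoints embed config, weights, optimizer state and RNG state,
and reload bit-identically. The stack is pure NumPy with a purpose-built
reverse-mode autodiff (im2col convolutions); float64 inputs are propagated
unchanged, which the test suite uses to verify every operator's gradient
against high-precision finite differences.

## Evaluation

**SSIM** uses the standard 11x11 Gaussian window (sigma 1.5), C1 = (0.01
L)^2, C2 = (0.03 L)^2, L = 255, computed on registered pairs (ground-truth
pairing for phantoms, DTW pairing otherwise).

**FID** is the Fréchet distance between Gaussian fits to image embeddings,
with the matrix square root taken symmetrically by eigendecomposition and
eigenvalues clipped at -1e-8. The canonical embedding is a pretrained
Inception network; this package ships a *seed-frozen random convolutional
projector* instead (three stride-2 convolutions with fixed Gaussian
weights, ReLU, mean+sd pooling) and accepts any user extractor. Random
projections preserve low-order texture statistics well enough to rank
blurry-versus-sharp reconstructions, but absolute values are not comparable
to Inception-based FID; every report header states the extractor.

**Statistics.** K-S normality and Levene homogeneity pre-checks; Friedman
across >= 3 related groups (defined as 0 when all groups are identical,
where the rank statistic is degenerate); Mann-Whitney U and paired t
against the reference; OLS with R^2 and F = R^2 (n-2)/(1 - R^2); Fisher-z
comparison of two correlations; ICC(2,1) (two-way random effects, absolute
agreement, single measures — the form is a choice, stated in the output)
with F-based 95% CI. Two-sided tests, alpha 0.05. Note that absolute-
agreement ICC is sensitive to a common rescaling of both columns; no
invariance is assumed.

## Problem sizes

Default study conditions keep every stage tractable on one CPU core:
phantoms of 26 x 26 x 7 mm at 52 µm (500 x 500 x 135 voxels) for
morphometry, 10 mm phantoms for translation datasets, 64x64 training
slices, ~2000 training iterations, ground-truth thickness measured on a
central 13 x 13 x 5 mm cancellous region. These sizes are the package's
desk-scale defaults; everything scales up by configuration.

## What passing tests show — and what they do not

The synthetic phantoms share with real vertebral specimens the geometry
(body, shell, canal), the two-resolution imaging physics (partial volume,
noise, 2:1 slice ratio) and the morphometric regime (BV/TV ~ 0.18, Tb.Th
~ 4 voxels at 52 µm). They do not reproduce plate-rod mixtures,
anisotropic fabric, marrow heterogeneity, beam hardening, fixation
artefacts, or scanner-specific intensity scales — the intensity mapping is
three flat levels. Parameter recovery and training gains on phantoms
therefore validate the *machinery* (thresholding, sphere fitting, pairing,
losses, statistics) and the end-to-end plumbing, not clinical performance
on cadaver or in-vivo scans.
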