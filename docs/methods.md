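# Methods

This note documents the models, numerical choices and limitations of
`canalseg`. It states no empirical result the test suite or the
acceptance script does not itself compute.

## Phantom model

The phantom is the package's stated world: a CT-like volume
(128×128×160 voxels at 0.5×0.5×1.0 mm by default, x = left→right,
y = posterior→anterior, z = inferior→superior) containing

* **vertebral bodies** — elliptical cylinders (semi-axes 16×13 mm,
  +700 HU) stacked along the spinal axis, 18 mm high, separated by
  8-mm disc spaces; six bodies, five disc levels (L1-L2 … L5-S1);
* **a curved spinal axis** — lateral deviation `A·sin(πz/L)` and AP
  deviation `0.3A·sin(2πz/L)` with amplitude A = 8 mm by default
  (cohort sampling draws 0.6–1.0 × A per patient), giving tangent tilts
  up to ~8°;
* **the dural sac** — an elliptical tube (minor/major ratio 0.7,
  +15 HU) centred on the axis. Its cross-sectional area *perpendicular
  to the axis* equals a per-level target at each disc centre and widens
  back to a 170-mm² baseline over ±5 mm with a squared-cosine taper
  `A(d) = A_c + (A_0 − A_c)·[(1 − cos(πd/5))/2]²`. The squared form is
  flat near the centre, so sub-voxel misalignment of a measurement
  plane barely perturbs the narrowest-slice area while the disc-centre
  slice remains the narrowest by construction;
* **disc posterior margin and ligamentum flavum** — 4-mm soft-tissue
  bands immediately anterior (+60 HU) and posterior (+80 HU) to the
  sac within each disc space, the structures whose hypertrophy
  produces stenosis and whose contrast behaviour differs between
  acquisition modes.

Attenuation is a fixed pseudo-HU palette; only relative contrasts
matter for segmentation learning. Oblique cross-sections are drawn
per axial slice as the perpendicular ellipse stretched by 1/cos θ
along the local tilt direction, which makes the perpendicular area
exact by construction; the vertebra layer set is inclusive and
symmetric about each body centre and the stack is phase-shifted so
disc centres coincide with voxel-layer centres (otherwise the
narrowest slice is never rendered and voxelized areas bias high).
Per-patient cohort sampling draws level DSAs uniformly from
45–160 mm², straddling both clinical thresholds.

**Acquisition modes.** Lumbar mode keeps native 1-mm slices with no
contrast. Abdominal mode adds +40 HU to disc and ligament tissue
(contrast enhancement) and linearly resamples z to 2-mm slices,
keeping the first slice position fixed. Gaussian intensity noise
(sd 5 HU by default) is seeded and applied in both modes.

**Ground-truth DSA** (`true_dsa`) resamples the label volume on an
arbitrary plane and returns dural-sac pixel count × pixel area. Each
pixel is rasterised by majority coverage over 4×4 nearest-neighbour
subsamples, with exact-half ties counted one half each; plain
one-sample-per-pixel lookup shows a +5–8 % moiré bias on oblique
planes at 0.5-mm pixels, the antialiased rasteriser stays within ~2 %.

**What the phantom does not emulate:** bone texture, osteophytes,
facet joints, scanner noise spectra, partial-volume blur at tissue
boundaries, and anatomical variability of sac shape (always an
ellipse). A green test therefore establishes that the measurement
chain is correct on high-contrast geometry, not that the network
segments clinical CT.

## Geometry

Centroids are found by thresholding at 300 HU, 3-D connected
components (≥ 500 mm³) and per-component centre of mass — sufficient
for phantoms; robust vertebra localisation on real scans is a separate
upstream problem and out of scope. The virtual spinal curve is a
cubic spline through the centroids in a chord-length parameter,
re-parameterised by numeric arc length (4096-point trapezoidal
integration, monotone PCHIP inverse; arc-length accuracy well under
0.1 mm). Disc centres sit at arc-length midpoints between adjacent
centroids.

Reformation samples 11 planes at arc offsets −5…+5 mm, each normal to
the curve tangent. In-plane frames are rotation-minimising: the first
axis is the projection of world x, subsequent frames re-project the
previous axis onto the new plane, avoiding frame flips. Intensities
are interpolated trilinearly, labels nearest-neighbour, on identical
frames. Field of view and pixel size are configurable (no protocol
value exists for them); the pipeline uses canal-centred 32-mm windows
at 0.5 mm. Because the canal runs posterior to the body centroids, a
plane *anchored* on the body-centroid curve meets the canal 1–2 mm
away from the disc centre when the axis tilts in AP; the pipeline
therefore anchors its planes on the canal axis (the centroid curve
translated by the known 20-mm offset). On real anatomy this
translation would come from the canal's position in the localisation
step.

## Segmentation model and training

Single-encoder, dual-decoder U-Net: per stage two conv(3×3)–batchnorm–
ReLU blocks and 2×2 max pooling; depth 4, base 16 channels doubling
per stage (defaults chosen for CPU-scale training; the source
architecture's widths are unpublished). Both decoders consume the
same skip connections by concatenation and differ only in how they
grow feature maps — decoder A uses 2×2-stride-2 transposed
convolutions, decoder B nearest-neighbour upsampling followed by a
3×3 convolution. Inference uses decoder A (the choice is arbitrary
and configurable). Inputs are normalised to zero mean / unit variance
per slice.

The engine is NumPy: channels-last tensors, convolution as k² shifted
GEMMs, hand-written backward passes verified against float64 central
differences (tests), He initialisation from a seeded generator, Adam
(β = 0.9/0.999, ε = 1e-8). Everything is float32 in production; a
module-level dtype switch exists for gradient verification.

Losses: pixel-averaged cross-entropy per decoder (probabilities
clamped at 1e-7), summed over decoders on labelled batches; the
consistency term is the mean squared difference between the two
decoders' soft probability maps, averaged over **all** elements
(batch, pixels, channels) — two one-hot maps that disagree everywhere
score 1.0. The consistency weight λ defaults to 1.0 (no published
value exists); applying it to soft maps rather than hard argmax labels
follows directly from the stated L2 form. Each optimisation step sees
one labelled batch and, when unlabelled data exist and λ > 0, one
unlabelled batch of equal size, so both terms stay active; with λ = 0
training is provably invariant to the unlabelled set. No LR decay, no
early stopping — the reference schedule is 50 epochs at lr 0.001 and
nothing more.

Augmentation (identical spatial transform for image and mask, nearest
neighbour for the mask; photometric transforms image-only): elastic
deformation (α = 10 px, σ = 4 px), scaling 0.9–1.1, rotation ±15°,
Gaussian blur σ ≤ 1 px, Gaussian noise sd 0.05 of the intensity range,
each applied with probability 0.5/0.5/0.3/0.3. The named transforms
are prescribed; all magnitudes are this package's choices.

## Stenosis rules and evaluation

DSA = positive-pixel count × pixel area on the predicted mask
(probability threshold 0.5; no connected-component filtering by
default, as none is described for the source method). Dichotomous
rule: normal iff DSA ≥ 100 mm²; severe rule: normal iff ≥ 75 mm².
A disc level is represented by the minimum DSA over its 11 slices and
classified from that minimum.

Evaluation: Dice with the both-empty convention = 1; ICC(2,1)
(two-way random effects, absolute agreement, single measure — the
standard form for method-agreement studies) with its F-based 95 % CI,
computed via pingouin and unit-tested against an independent ANOVA
mean-squares oracle; accuracy/sensitivity/specificity as percentages
with exact Clopper–Pearson 95 % CIs (this method reproduces the
reference worked examples exactly, e.g. 281/391 → 71.9 % (67.1–76.3));
the CI method is named in every report. Percentages are rounded to
one decimal, DSC/ICC to two. The narrowest-slice comparison labels a
level `equal` when |algorithm minimum − reader DSA| ≤ 1 mm² (a tie
tolerance the source protocol leaves unspecified), `algorithm_narrower`
when the algorithm's minimum is smaller, else `reader_narrower`;
"narrower = better at finding the narrowest slice" is the implemented
reading of an operationally under-specified criterion. ICC strata are
computed at slice level.

## Reproducibility and scale

Every run flows from one root seed split per stage
(`np.random.SeedSequence`); identical (config, seed) reproduce the
evaluation tables byte for byte, which the test suite asserts. The
semi-supervised recovery experiment in the suite runs scaled down
(64×64 canal-centred windows, 20 labelled + 40 unlabelled slices, 15
epochs, 3 seeds) to fit a single-CPU budget; `dsc_recovery_experiment`
exposes the full-size setting (160×160, 40 + 160, 50 epochs)
unchanged. The success thresholds (held-out DSC ≥ 0.80; λ = 1 within
0.02 of λ = 0) are the same at both scales.

## Known limitations

* The phantom's stenosis morphology is generic canal indentation; it
  does not distinguish disc-bulge from ligament-hypertrophy patterns.
* The centroid finder assumes isolated high-attenuation bodies.
* Headline clinical figures from patient cohorts (DSC ≈ 0.85,
  ICC ≈ 0.8, accuracy ≈ 84 %) are not reproducible here — the data are
  private; phantom results characterise the measurement chain only.
* The NumPy engine trains desk-scale models; it is not a general deep
  learning framework (no strides ≠ 1, no dilation, 2-D only).
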