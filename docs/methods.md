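# Methods

## Model and assumptions

`cpseg` treats choroid plexus (CP) segmentation as one-dimensional intensity
clustering restricted to an anatomically plausible region. The inputs are a
T2-FLAIR volume and an aseg-style integer parcellation that are already
bias-corrected and coregistered onto one voxel grid; the package validates
grid agreement (shape exactly, spacing/affine within 1e-4 mm) but performs
no registration, bias correction or resampling of its own.

Within each hemisphere's eroded LV + CP region the normalized intensities
are modelled as a 3-component Gaussian mixture: suppressed ventricular fluid
(dark), a partial-volume shell where fluid mixes with wall tissue
(intermediate), and plexus (bright). The model is intensity-only; spatial
structure enters solely through the prior region, not through the mixture.
Hemispheres are defined by label identity, not by a midline plane, so the
method is robust to head tilt; fitting the sides separately keeps left/right
CP size differences from biasing a single fit.

## Pipeline steps and parameters

| step | parameter | default | unit | rationale |
|---|---|---|---|---|
| prior | `labels.{left,right}.{lv,cp}` | 4/31, 43/63 | label id | FreeSurfer colour-table convention |
| erosion | `erosion.radius_voxels` | 1 | voxel | strip one partial-volume rim; radius-1 Euclidean ball = centre + 6 face neighbours, the only sphere of radius one voxel |
| smoothing | `smooth.sigma_voxels` | 0.5 | voxel | light denoising at ~1 mm isotropic resolution that keeps the thin plexus |
| smoothing | `smooth.masked` | true | — | renormalized kernel inside the region so dark extra-regional tissue cannot leak into boundary voxels |
| mixture | `gmm.means` | 0.15, 1.5, 4 | normalized intensity | empirical starting point for mean-normalized FLAIR |
| mixture | `gmm.sds` | 0.02, 0.1, 1.5 | normalized intensity | ditto |
| mixture | `gmm.weights` | 0.45, 0.5, 0.05 | — | ditto; CP is a small fraction of the region |
| EM | `gmm.tol` | 1e-6 | relative Δ log-likelihood | standard tight tolerance |
| EM | `gmm.max_iter` | 500 | iterations | ample for 1-D mixtures |
| EM | `gmm.variance_floor` | 1e-4 | normalized intensity | prevents component collapse onto duplicated samples |

The kernel for erosion is defined in voxel space and ignores anisotropic
spacing: "one voxel" is a grid notion. Out-of-grid voxels count as
background during erosion and as "outside" for boundary extraction, so
regions touching the volume border behave as if the volume were padded with
background.

Normalization divides by the mean of the *strictly positive* intensities in
the eroded region; zeros can only arise from masked-out background and would
otherwise dilute the scale. The same smoothed, normalized values are used
for fitting and for the final voxel assignment.

EM details: responsibilities are computed in the log domain
(log-sum-exp), so extreme outliers produce well-defined posteriors rather
than 0/0. There are no random restarts — a single deterministic run from the
configured initialization — hence reruns are bit-identical and results are
invariant to sample order. The CP role goes to the highest *fitted* mean
(component identities may swap during EM); an exact mean tie is broken
toward the larger weight, then the higher index. If EM hits `max_iter`
without converging the last iterate is used and `converged=false` is
recorded. Voxels removed by the erosion are never reinstated; this is the
source of the method's small, systematic volume underestimation and is
accepted deliberately, since the eroded rim is exactly where partial-volume
voxels would otherwise create false positives.

## Evaluation metrics

* DSC = 2|A∩B|/(|A|+|B|); two empty masks score 1.0 by convention (perfect
  agreement), one empty mask scores 0.
* HD95 is the symmetric variant: the larger of the two directed 95th
  percentiles of nearest-neighbour distances between boundary voxel centres,
  in physical mm. Boundaries use 6-connectivity; percentiles use linear
  interpolation over the sorted directed distances. HD95 of two identical
  masks is 0; it is undefined (an error) if either mask is empty.
* VD% is reported signed and in magnitude, since both conventions are in
  use; it is undefined for an empty reference.

## The phantom generator

`synthetic_data` renders, per hemisphere, an ellipsoidal ventricle (semi-axes
10.5 × 13.5 × 8.5 voxels on a 64³, 1 mm grid) whose deep interior is dark
fluid (55 ± 8 scanner units), bounded by a 3-voxel partial-volume shell
(480 ± 100), with bright CP blobs (1400 ± 90) attached to the wall from
inside; everything sits in a dim background (40 ± 10) with additive
acquisition noise (sd 25, Gaussian by default, Rician optional) and clipping
at zero. With this geometry the region fractions are roughly 0.5 fluid /
0.42 shell / 0.08 plexus, so the region-normalized class means land near
0.2 / 1.3 / 3.5 — the regime the published initialization expects.

Two imperfections are built in deliberately. The emitted CP label is an
eroded subset of the truth blobs, so the prior under-covers the structure it
is meant to flag and the mixture — not the prior — must find the CP extent.
And because each blob's surface touches the ventricle wall, the pipeline's
one-voxel erosion removes a thin rim of true plexus: the phantom reproduces
the method's characteristic slight underestimation structurally (mean signed
VD% ≈ −8 over repeated phantoms) rather than by a tuned constant.

What the phantom does *not* emulate: real ventricular shape (ellipsoids, not
anatomy), bias fields, flow artefacts, partial-volume gradients at class
interfaces (classes are piecewise-constant plus noise; smoothing introduces
mixing only at the filter scale), or FreeSurfer's actual failure modes
beyond simple label dilation/erosion. Passing phantom tests therefore
demonstrates that the algorithmic chain is correct under its own model
assumptions, not that accuracy on clinical data will match phantom numbers.

Presets: `default` (reference regime, seed 7), `noisy` (class sds
15/160/250 and noise sd 150, seed 11), `small_cp` (two blobs of radius
2.2–2.6 voxels, seed 13), `one_sided` (right ventricle and labels absent,
seed 17). Problem sizes (64³ grids, ~8 000 region samples per side, 30 000
EM recovery samples) keep every check comfortably fast on a single CPU.

## Design choices on genuinely open points

* Masked vs whole-image smoothing: both are implemented; masked is the
  default because unmasked filtering drags dark extra-regional tissue into
  the region's boundary voxels.
* Normalization scope: region-restricted (not whole-image), consistent with
  every other step operating inside the prior region.
* HD95 construction: symmetric, voxel-centre based. A directed or
  surface-mesh variant would differ in the third decimal at phantom scale.
* Erosion connectivity: the radius-1 ball (6-neighbour cross) is the
  literal "sphere of one voxel"; a larger radius is configurable.

## Known limitations

* Blobs (or real plexus) thinner than ~2 voxels after smoothing lose their
  bright intensity mode and cannot be separated by the mixture — the
  `small_cp` preset stays just above this regime, and the failure is abrupt
  below it.
* The intensity-only model cannot distinguish bright non-plexus tissue that
  the prior region erroneously includes; quality of the LV labels bounds
  quality of the output. The per-side region voxel count is logged for
  screening.
* One-voxel erosion plus no re-growing means the reported volumes are
  biased low by design; comparisons should use consistently processed
  cohorts rather than absolute volumes.
* Soft/fuzzy assignment and spatially regularized mixtures are out of
  scope.
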