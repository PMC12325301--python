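# cpseg — region-informed One-GMM choroid plexus segmentation

The choroid plexus (CP) is the CSF-producing tissue inside the brain's
ventricles. On T2-FLAIR MRI the free fluid of the lateral ventricles (LV) is
suppressed (dark) while the plexus stays bright, but the structure is small,
irregular and hugs the ventricle wall, so general-purpose parcellations
segment it poorly. `cpseg` implements a one-stage, region-informed approach
for researchers who already run a FreeSurfer-style anatomical pipeline and
want reliable CP masks and volumes from coregistered FLAIR images.

## Method

For each hemisphere:

1. **Anatomical prior** — merge the LV and CP labels of an aseg-style
   parcellation (defaults 4/31 left, 43/63 right) into one region, then
   erode it by one voxel with a spherical kernel (the radius-1 Euclidean
   ball) to strip the partial-volume rim.
2. **Conditioning** — smooth the FLAIR inside the eroded region with a
   masked 3-D Gaussian filter (σ = 0.5 voxel) and divide by the mean of the
   region's non-zero intensities, giving dimensionless values x with
   non-zero mean 1.
3. **Mixture model** — fit a 3-component univariate Gaussian mixture
   p(x) = Σₖ πₖ 𝒩(x; μₖ, σₖ²) by EM from the fixed empirical start
   μ = [0.15, 1.5, 4], σ = [0.02, 0.1, 1.5], π = [0.45, 0.5, 0.05]
   (dark fluid / partial-volume shell / bright plexus).
4. **Hard assignment** — each voxel goes to its maximum-posterior
   component; the component with the highest *fitted* mean is the CP.

The hemispheric masks are unioned and volumes are reported in ml. Accuracy
against a reference mask is measured with the Dice similarity coefficient
DSC = 2TP/(2TP + FP + FN), the symmetric 95th-percentile boundary Hausdorff
distance (HD95, mm), and the volume difference VD% = 100(V_pred − V_true)/V_true.

Because nothing outside the eroded prior is ever a candidate, the prediction
cannot leak into surrounding tissue; the price is a slight systematic volume
underestimation where the plexus touches the ventricle wall.

## Worked example

No patient data ships with the package; the built-in phantom generator
produces a FLAIR-like volume, an imperfect prior label map, and the exact
truth mask:

```
$ cpseg simulate --preset default --out-dir demo
wrote phantom (default, seed 7) to demo; truth CP volume 0.610 ml

$ cpseg segment --flair demo/flair.nii.gz --labels demo/aseg.nii.gz \
                --out demo/cp_mask.nii.gz --report demo/report.json
bilateral CP volume: 0.563 ml (left 0.325, right 0.238)

$ cpseg evaluate --pred demo/cp_mask.nii.gz --truth demo/truth_cp.nii.gz
DSC 0.9582  HD95 1.00 mm  VD% -7.70 (|7.70|)  pred 0.563 ml / true 0.610 ml
```

The segmentation recovers 96% overlap with the planted truth, boundary
disagreement within one voxel, and the expected small negative volume bias
(the eroded wall rim). `demo/report.json` records the fitted mixtures — for
this phantom the left-side EM converges in 41 iterations to means
≈ [0.23, 1.21, 3.38] with weights ≈ [0.40, 0.52, 0.08], i.e. the three
planted intensity classes.

The same pipeline is available from Python:

```python
from cpseg import segment, run_report, generate, preset

flair, aseg, truth = generate(preset("default"))
result = segment(flair, aseg)
print(run_report(result, truth)["metrics"])
```

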