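# cmfseg

Automatic, unsupervised segmentation of enhancing breast lesions in dynamic
contrast-enhanced MRI (DCE-MRI), built for researchers who need a
reproducible classical baseline: no training data, deterministic output,
every stage testable in isolation.

A lesion enhances after contrast injection while normal tissue mostly does
not, so the pipeline works on the registered subtraction image
`I_sub = max(I_reg − I_pre, 0)` and proceeds in three stages:

1. **Pre-processing** — the post-contrast volume is registered onto the
   pre-contrast one with an in-plane affine transform
   (Translation·Rotation·Shear·Scale, MSE metric, multiresolution, bicubic
   resampling) and subtracted.
2. **Lesion detection** — the subtraction image is denoised by a
   phase-preserving log-Gabor wavelet shrinkage: per band the amplitude
   `A = √(Re²+Im²)` is soft-thresholded against a Rayleigh noise threshold
   `τ = σ(√(π/2) + c·√((4−π)/2))`, with σ estimated from the median band
   amplitude (`median = σ√(2 ln 2)`), while the phase `φ = atan2(Im, Re)` —
   where edges live — is untouched. After adaptive Wiener and bilateral
   smoothing, each slice is segmented by continuous max-flow (CMF): the
   convex dual `min_{u∈[0,1]} Σ(1−u)·Cs + u·Ct + Σ C|∇u|` solved by an
   augmented-Lagrangian scheme (an n-label Potts relaxation is included).
3. **Post-processing** — disc dilation (radius 5 px), largest connected
   component, intersection with the original mask: speckle is removed,
   lesion pixels are never invented.

Evaluation ships with the nine standard pixel metrics (Acc, Se, Sp, P, ER,
Vs, DSC, JC, AUC) plus PSNR, and a synthetic phantom generator (Rician
noise, known ellipsoidal lesion, injected misalignment) makes the whole
chain verifiable without clinical data.

## Worked example

```python
from cmfseg import PhantomSpec, generate_case, segment_case

pre, post, gt = generate_case(PhantomSpec(seed=1))   # synthetic DCE-MRI pair
result = segment_case(pre, post, gt=gt)

print(f"recovered shift: tx={result.transform.tx:+.2f} px "
      f"ty={result.transform.ty:+.2f} px theta={result.transform.theta:+.4f} rad")
for k, v in result.metrics.as_dict().items():
    print(f"{k:>4}: {v:.4f}")
```

prints

```
recovered shift: tx=-2.50 px ty=+1.50 px theta=-0.0029 rad
 Acc: 0.9999
  Se: 0.9929
  Sp: 1.0000
   P: 1.0000
  ER: 0.0001
  Vs: 0.9964
 DSC: 99.6425
  JC: 99.2876
 AUC: 0.9971
```

The phantom injected a (+2.5 px, −1.5 px, +0.01 rad) misalignment between
the frames; the recovered translation is its inverse to two decimals and
the rotation is recovered to within a hundredth of a radian on this noisy
pair (noise-free recovery is exact to ~1e-4 rad). DSC and
JC are overlap percentages against the known lesion mask; Se/Sp/P are the
pixel-level sensitivity, specificity and precision; Vs compares the two
volumes; AUC summarizes the soft CMF label map against the ground truth.

The same pipeline is scriptable from the shell:

```bash
cmfseg phantom --seed 1 --out-dir case/
cmfseg segment --pre case/pre.nii.gz --post case/post.nii.gz \
               --gt case/gt.nii.gz --out mask.nii.gz
cmfseg evaluate --seg mask.nii.gz --gt case/gt.nii.gz --report report.json
cmfseg batch --manifest manifest.csv --out-dir results/   # Table-style CSV
```

NIfTI, DICOM series (read-only) and TIFF stacks are supported; every config
key (`cmf.lambda_tv`, `denoise.c`, `post.se_radius`, ...) can be set in a
YAML file or overridden with `--set key=value`.

## Documentation

`docs/methods.md` describes the models, defaults, numerical choices and
known limitations in detail.
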