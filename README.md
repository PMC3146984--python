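# icseg

Automatic delineation of pigmented skin lesions in dermoscopic images by
iterative seeded classification.

Accurate lesion borders are the first step of any computer-aided melanoma
workup, but hand-drawn contours are slow and vary between dermatologists.
`icseg` segments a single dermoscopic frame with no user input by exploiting
two acquisition priors: the lesion sits near the center of the circular
imaged field, and the surrounding skin is lighter.  It is written for
researchers working on dermoscopic image analysis who need a reproducible,
parameter-transparent baseline segmenter plus the standard border-evaluation
metrics, and it ships a synthetic dermoscope-frame generator so everything
runs end to end without clinical data.

## Method

All processing happens in the CIE L\*u\*v\* space of the median-filtered
(5×5) frame.  Distances are specified in millimetres and converted through
the acquisition geometry (field diameter in mm, pixels per mm), so every
parameter transfers across cameras.

1. **Seed selection.**  Inside the annulus d₂ = {5 mm < r ≤ ℓ} each
   axis-aligned quadrant contributes the 1-mm box with maximal mean
   luminance; the box most dissimilar from the merged other three is
   discarded (three-vs-one test).  Inside the central disk d₁ = {r ≤ 5 mm}
   the 1.5-mm box whose mean luminance is farthest from the skin mean
   becomes the lesion seed.
2. **Hybrid classification.**  Disjoint halves of the seed pixels train a
   linear (pooled-covariance) and a quadratic Gaussian discriminant.  Their
   posteriors are fused per pixel,

       p_k(y | x) = λ_k · p_QDA(y | x) + (1 − λ_k) · p_LDA(y | x),

   with λ_k chosen on a 0.01 grid to maximize the *worse* of the two
   per-class accuracies on the pooled seed samples; ties go to the smallest
   λ, privileging the simpler linear model.
3. **Iterative update.**  Pixels with posterior > 0.98 are harvested as new
   training samples (lesion candidates restricted to the opened region that
   encloses the lesion seed — a safeguard that never restricts the
   segmentation itself), capped at the original seed size per class, and
   the loop repeats until the high-confidence lesion count m_k satisfies
   |1 − m_{k+1}/m_k| < 0.01, or 30 iterations.
4. **Postprocessing.**  Erosion (0.12 mm disk), dilation (0.3 mm) ANDed
   with the raw mask, Gaussian connect filter (threshold 0.1), then each
   region scored by n_i = Σ exp(−[(u−u₀)² + (v−v₀)²] / 2σ²) with σ = 2.5 mm
   about the field center; the best region is kept, holes filled, and its
   border traced at half-pixel precision.

Evaluation follows the field's standard scores: sensitivity/specificity,
the symmetric Hausdorff distance d_H between contour point sets (in mm),
and the tolerance ratio e(τ) — the fraction of contour points of both
curves within τ (default 0.5 mm) of the other curve.

## Worked example

Generate three synthetic frames (contrast 40, 20 and 9 L\* units) and
segment the first:

```bash
$ icseg simulate --n 3 --contrast 40,20,9 --seed 1 --out frames
wrote 3 frames to .../frames
$ icseg segment frames/frame_000.png --out results
converged=True iterations=2 lesion_px=6504
```

The run converged after 2 iterations and found a lesion of 6504 px.  The
iteration log shows the mixing weight λ_k, the high-confidence lesion count
m_k and the training-set sizes per iteration:

```
$ cat results/frame_000_iterations.csv
k,lambda_k,m_k,n_train_skin,n_train_lesion,converged
1,0.0,6097,675,484,False
2,0.0,6045,1350,968,True
```

λ stayed at 0 (the seed classes were separable, so the linear model was
kept), m_k moved from 6097 to 6045 — a relative change of 0.9%, under the
1% stop rule — and each class's training set doubled once with harvested
high-confidence pixels.  Comparing the written mask against the generator's
ground truth:

```python
>>> import imageio.v3 as iio
>>> from icseg import dice_coefficient
>>> mask  = iio.imread("results/frame_000_mask.png") > 127
>>> truth = iio.imread("frames/frame_000_mask.png") > 127
>>> dice_coefficient(mask, truth)
0.973
```

`results/` also contains the contour as CSV (px and mm), a border overlay
PNG and a JSON run summary.  The same pipeline is available from Python via
`icseg.run_pipeline` / `icseg.run_ics`, and `icseg evaluate manifest.csv`
scores batches of candidate/reference mask pairs.

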