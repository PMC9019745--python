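# temposeg

Pixel-level segmentation of grayscale movies by **temporal similarity**:
unsupervised pseudo-labels from a discounted k-means, supervised refinement
with a linear classifier, and a mask-specific median filter.

## The problem

Fluorescence movies of electrically active tissue — e.g. optical-mapping
recordings of a whole heart loaded with a voltage-sensitive dye — must be
segmented into *object* (tissue) and *background* pixels before any
statistics are computed, otherwise means, medians and standard deviations
are contaminated by background noise. Thresholding a single frame fails
whenever contrast is low (during diastole there may be no visible object
at all), and supervised segmentation networks need labeled masks nobody
has.

`temposeg` segments at the pixel level using each pixel's **time series**
instead of any single frame. After per-pixel min–max normalization over
time, background pixels become full-range amplified noise while tissue
pixels show a stereotyped action-potential (AP) waveform — two well
separated classes in the n-dimensional space of n-frame windows, even
during diastole.

## The method

Each pixel contributes one point x ∈ [0,1]ⁿ (its normalized n-frame
window; a 100×100 frame gives 10,000 points).

1. **Discounted k-means** (2 clusters). Standard Lloyd iteration, except
   that during assignment the distance D₁ to one designated centroid is
   multiplied by a discount factor γ ∈ (0,1]: a point joins cluster 1 iff
   γ·D₁ ≤ D₂. With γ = 1 this is exactly plain k-means; as γ shrinks the
   discounted cluster swallows everything. Points that *still* cling to
   the rival cluster (D₂ < γ·D₁) are **stubborn points** — so deep inside
   their cluster that they resist the pull. Running this twice (once
   discounting each side) yields high-confidence tissue and background
   pixels with border zones excluded — automatic training data.
2. **Linear classifier.** A linear SVM (or logistic regression
   f(x) = σ(w·x + b) thresholded at 0.5) is trained on the pseudo-labels
   and classifies all pixels of any window; the 10,000 decisions reshape
   to a 100×100 binary mask.
3. **Mask median filter.** A pixel keeps its value only if more than
   `threshold` (default 3) of its 3×3 neighbors share it; otherwise it
   flips. Either value can be protected (`remove_heart=False` leaves all
   1-pixels intact).

Sliding the window (small n, e.g. 32 frames) with per-window re-harvest
tracks moving boundaries; γ can be auto-tuned by bisection to hit a target
amount of training data.

A full synthetic-movie generator (AP-like waveform, conduction delay,
optional rotation/shrinking, ground-truth masks) makes every stage
testable end to end.

## Worked example

```python
import numpy as np
from temposeg import (SyntheticSpec, generate, combined_segment,
                      kmeans_only_segment, evaluate_masks)

sm = generate(SyntheticSpec(seed=0))          # 1024-frame, 100x100 movie
res = combined_segment(sm.movie, n=256, frames=[1], method="svm",
                       gammas=(0.8, 0.8), seed=0)
metrics = evaluate_masks(res.masks, sm.truth_masks[:1])
km = kmeans_only_segment(sm.movie, n=256, frame=1, seed=0)

print(res.log)
print(f"heart ratio r        : {res.heart_ratio_per_frame[0]:.4f}")
print(f"true object fraction : {sm.truth_masks[0].object_ratio:.4f}")
print(f"pixel accuracy       : {metrics['mean_accuracy']:.4f}")
```

prints

```
combined_segment: method=svm n=256 gammas=(0.8,0.8) seed=0 frames=[1] reharvest=False normalization=movie
window 1: harvested 2828 object / 7172 background pixels
heart ratio r        : 0.2828
true object fraction : 0.2828
pixel accuracy       : 1.0000
```

The harvest found exactly the 2,828 disk pixels (the heart ratio r —
object pixels over total pixels — matches the true fraction), and the SVM
mask reproduces the ground truth pixel for pixel at this noise level.

The same pipeline is available from the shell:

```bash
temposeg synth --out movie.tif --truth-dir truth/ --seed 0
temposeg segment --input movie.tif --method combined --n 256 --seed 0 --out masks/
temposeg eval --pred masks/ --truth truth/
```

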