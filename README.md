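# tsrseg

Tissue segmentation and tumor–stroma-ratio (TSR) scoring for H&E-stained
colorectal cancer sections, with a full human-vs-automated agreement
analysis.

The TSR — the tumor area divided by the combined tumor + stroma area within
a region of interest — is a prognostic factor in colorectal and other
cancers, but human "eyeballing" of the ratio is noisy and biased. This
package implements an automated pipeline for pathologists and imaging
researchers:

* **Five-class tissue segmentation** (tumor, stroma, necrosis, mucus,
  background; a sixth *artifact* label marks ignored regions) with two
  models sharing one truncated MobileNetV2-style encoder (output stride 16):
  * **BPN (Basic Prototype Network)** — few-shot segmentation. Each class
    is a *prototype* p_c: masked average pooling of support-image features
    over the class annotation, averaged across supports. A query feature x
    is scored with s_c(x) = −½‖x − p_c‖² and labeled by its nearest
    prototype; per-class score maps are bilinearly upsampled to native
    resolution before the argmax. Adapting to new data needs only new
    supports, no retraining. Trained episodically with a pixel-wise
    cross-entropy over prototype similarities plus a prototype-attraction
    term weighted by γ.
  * **U-Net baseline** — the same encoder plus a 4-block expansive decoder
    with skip connections, trained with pixel-wise cross-entropy.
* **Overlap-tile inference** for ROIs larger than the 512×512 patch size:
  tiling A (stride = patch size, later patches overwrite edge overlaps) and
  tiling B (a 96 px boundary of each patch is discarded; active areas of
  320×320 px, ≈39 % of the patch, tile the image exactly once).
* **TSR scoring**: TSR = 100·tumor/(tumor+stroma) %, necrosis/mucus/
  background excluded; stroma-low / stroma-high categorization at 50 % or
  65 % cutoffs.
* **Agreement statistics**: two-way absolute-agreement single-measure ICC
  with F-based 95 % CIs, Cohen's kappa on categorized TSR, deviation
  summaries filtered by segmentation-quality grade, and the A–D
  quality-vs-deviation categorization.
* **Synthetic data**: seeded generator of H&E-like scenes (warped Voronoi
  regions, class-distinct textures) with exact ground truth, and a
  simulator of biased, noisy human TSR raters — so the entire pipeline is
  testable without any image downloads.

The networks run on a compact NumPy reverse-mode autodiff core
(`tsrseg.nn`); no GPU or deep-learning framework is required.

## Worked example

```bash
python examples/rater_agreement.py
```

```
inter-observer ICC(A,1) = 0.934 (95% CI 0.90-0.96)
Cohen's kappa (model vs obs01, 50% cutoff) = 0.569
mean model-minus-observer deviation over 30 well-segmented ROIs = -10.8 pp (configured observer bias: +11 pp)
ROI 1 vs obs01: deviation -12.5 pp, quality 9.5 -> category C
```

Ten simulated observers overestimate the TSR by +11 pp; they agree well
with each other (ICC 0.93), yet the unbiased automated score sits ≈11 pp
below them — inter-rater agreement alone does not certify unbiased
estimates. The other examples cover scene generation
(`generate_scene.py`), few-shot training (`few_shot_segmentation.py`,
held-out pixel accuracy 0.80 with a frozen random encoder → 0.97 after 200
episodes), and tiled inference with TSR scoring (`tiling_and_tsr.py`).

A thin CLI wraps the same library:

```bash
tsrseg generate --out data --n 12 --seed 1
tsrseg train --data data --model bpn --out ckpt/bpn.npz --episodes 200
tsrseg segment --image roi.png --checkpoint ckpt/bpn.npz --tiling B --out mask.png
tsrseg agree --raters raters.csv --ai ai.csv --quality quality.csv --out report
```

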