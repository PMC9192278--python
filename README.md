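# strokeseg

Low-dose brain-CT processing for ischemic stroke, end to end on synthetic
data: head phantoms with known lesions and perfusion truth, BM3D and
residual-CNN denoising, residual-SE U-Net lesion segmentation, perfusion
mapping by SVD deconvolution, and clinical-style evaluation reports.

The package is aimed at people prototyping or teaching CT image-analysis
pipelines who need every stage testable against ground truth without any
patient data: every input is generated, seeded, and carries its truth
(lesion masks, noise sigma, CBF/CBV/MTT fields).

## What it computes

**Denoising.** A low-dose scan is modeled as χ = φ(y): the clean image y
plus noise (Gaussian of known σ in HU by default). Two denoisers are
provided: a from-scratch two-stage BM3D (block grouping → collaborative
DCT+Haar filtering with hard threshold → Wiener refinement on the stage-1
pilot) and residual CNNs — DnCNN, which predicts the noise map and
subtracts it, F(χ) ≈ φ⁻¹(χ), trained by min ‖F(χ) − y‖²; and a cascade
whose later blocks consume (previous estimate, original input). The CNNs
run on a small NumPy autodiff engine included in the package, so there is
no deep-learning framework dependency.

**Segmentation.** RISEU-Net: a U-Net whose blocks are residual
(out = X + F(X)) and gated by squeeze-excitation channel attention,
trained under Dice-family losses. Plain Dice is 2|E∩F|/(|E|+|F|) for
prediction E and truth F; the New-Dice variant subtracts false negatives
and false positives in the numerator, 2(|E∩F| − |¬E∩F| − |E∩¬F|), giving
it range [−2, 1].

**Perfusion.** Voxelwise contrast curves C(t) = F_s·(AIF ⊛ R)(t) are
inverted by truncated-SVD deconvolution of the AIF Toeplitz system to
recover CBF (residue peak), CBV (area ratio), MTT = 60·CBV/CBF and TTP.

**Reporting.** PSNR/RMSE/SSIM quality tables, lesion-level
sensitivity with voxel-level specificity/accuracy, Welch t and 2×2 χ²
group comparisons, texture moments, and the bias–variance decomposition
mse = bias² + variance.

## Worked example

```sh
python examples/05_perfusion_maps.py
```

builds a 64×64 phantom with one hypodense lesion, simulates a 20-frame /
45 s contrast series (normal tissue CBF 60 mL/100 g/min, MTT 4 s; lesion
CBF 20, MTT 8), deconvolves it and prints:

```
normal tissue:
  CBF   60.0 mL/100g/min (truth 60)
  CBV   4.00 mL/100g (truth 4.00)
  MTT    4.0 s (truth 4)
  TTP    9.5 s
ischemic lesion:
  CBF   20.0 mL/100g/min (truth 20)
  CBV   2.65 mL/100g (truth 2.67)
  MTT    7.9 s (truth 8)
  TTP   11.8 s
```

The recovered maps reproduce the assigned truth, and the lesion shows the
ischemic signature clinicians read: low flow, prolonged transit, delayed
peak. The other scripts in `examples/` walk the remaining stages (phantom
and noise statistics, BM3D quality tables, DnCNN training gains,
segmentation efficacy tables, the full pipeline with its manifest), each
printing the numbers it computes and a line on what they mean.

A command-line interface mirrors the pipeline stages:

```sh
strokeseg phantom --out run/ --seed 7 --shape 128 128
strokeseg denoise run/lowdose.nii.gz run/denoised.nii.gz --method bm3d --sigma 25
strokeseg run --out run_full/ --seed 7     # full pipeline + manifest
```

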