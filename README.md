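# breastasym

Computer-aided detection (CAD) pipelines for early breast-cancer screening
from **infrared thermograms** and **mammogram texture patches**, built around
bilateral asymmetry analysis.

Tumour angiogenesis raises local skin temperature, so in a healthy subject
the temperature patterns of the two breasts are closely mirror-symmetric
while a one-sided lesion breaks that symmetry. The thermogram pipeline
quantifies this with oriented band-pass texture features:

1. **Segmentation** — Otsu thresholding keeps the warm body against the cool
   background, morphological opening/closing and largest-component selection
   clean the mask, and horizontal (Sobel) edge projection locates the
   inframammary fold before the mask is split into left/right breast ROIs.
2. **Gabor texture energies** — a bank of 20 real Gabor filters
   (Gaussian envelope × cosine carrier) at radial frequencies
   F ∈ {0.25, 0.176, 0.125, 0.088} cycles/pixel and orientations
   O ∈ {0°, 36°, 72°, 108°, 144°}, with −6 dB envelope spreads
   σ<sub>x</sub> = √(ln 2)(2<sup>B</sup>+1) / (√2 π f (2<sup>B</sup>−1)) at
   B = 1 octave (circular: σ<sub>y</sub> = σ<sub>x</sub>). Each ROI yields the
   per-filter energy E<sub>k</sub> = Σ<sub>x,y</sub> |(I ∗ g<sub>k</sub>)(x,y)| / N over its mask.
3. **Asymmetry signature** — the 20-vector |E<sub>k</sub>(left) − E<sub>k</sub>(right)|, near
   zero for symmetric breasts, is classified by an RBF-SVM (C = 2, γ = 2).

The mammogram pipeline classifies pre-segmented ROIs by difference-of-
Gaussians denoising, gray-level co-occurrence matrices (GLCM) and the 13
classic Haralick statistics, fused by an ensemble of bootstrap RBF-SVMs
under nine combination rules (majority vote, max, sum, min, average,
product, naive Bayes, decision templates, Dempster–Shafer).

A shared metrics engine reports sensitivity, specificity, accuracy, error
rate, precision, MCC and F-score per train/test iteration, with
mean ± sample-SD/min/max aggregation. A synthetic-scene generator produces
mirror-symmetric bilateral thermal fields with optional hot-spot lesions and
gray-level texture patches with controllable GLCM statistics, so the whole
system is testable without clinical data.

## Worked example

```python
import numpy as np
from breastasym.synthetic import ThermoSceneParams, generate_thermogram
from breastasym.pipelines import thermo_signature

normal = generate_thermogram(ThermoSceneParams(noise_sd=0.2, seed=1))
lesioned = generate_thermogram(ThermoSceneParams(
    noise_sd=0.2, seed=1, lesion_side="left", lesion_amplitude=2.0,
    lesion_sigma=8.0, micro_texture=True))

for name, scene in [("normal", normal), ("lesioned", lesioned)]:
    sig = thermo_signature(scene.grid)
    print(f"{name:9s} label={scene.label:9s} |signature| = "
          f"{np.linalg.norm(list(sig.values())):.4f}")

from breastasym.synthetic import default_separable_dataset
from breastasym.pipelines import scenes_to_feature_table, PipelineConfig, run_task_experiment

scenes, _ = default_separable_dataset(n_per_class=20, seed=1)
features = scenes_to_feature_table(scenes)
reports, agg = run_task_experiment(features, PipelineConfig())
print(f"mean accuracy {agg.mean['accuracy']:.2f}% +- {agg.sd['accuracy']:.4f} "
      f"(sensitivity {agg.mean['sensitivity']:.2f}, specificity {agg.mean['specificity']:.2f})")
```

prints

```
normal    label=normal    |signature| = 0.0042
lesioned  label=malignant |signature| = 0.0684
mean accuracy 90.28% +- 11.0763 (sensitivity 0.81, specificity 1.00)
```

The asymmetry signature of the lesioned scene is ~16× larger than the
noise-driven asymmetry of the healthy one, and six stratified 70/30
train/test iterations of the RBF-SVM on 40 such scenes already reach 90%
mean accuracy (100% at the standard 80-scene benchmark size).

The same workflow is available from the shell:

```sh
breastasym simulate --out data/ --n-normal 20 --n-benign 10 --n-malignant 10 --seed 7
breastasym run --config cfg.yaml --manifest data/manifest.csv --out results/
```

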