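# cervia

Quantitative analysis of **visual inspection with acetic acid (VIA)** — the
low-cost cervical-cancer screening method in which 3–5% acetic acid turns
abnormal (CIN2+) squamous epithelium densely white while normal tissue stays
light pink. `cervia` implements the full image-analysis pipeline for *paired*
cervicograms taken before and after acetic-acid application:

1. **Preprocessing** — specular highlights are detected at 60% of the 8-bit
   intensity range (per-pixel channel maximum) and inpainted from their
   neighbourhood; the ectocervix region of interest (ROI) is segmented from
   the two most significant bit-planes of the red channel (red ≥ 64) with
   morphological cleanup, and the pre/post ROI masks are intersected.
2. **Registration and clock slicing** — each image carries three manual
   fiducials (cervix centre, two cervical-os endpoints); images are rigidly
   rotated so the os line is horizontal and translated to a common centre,
   then the ROI is partitioned into 12 clock-position sectors matching how
   excised tissue is sectioned for histopathology.
3. **Feature extraction** — five predictors per sector:
   - *D*<sub>ave</sub> = ½(*D*<sub>G/R</sub> + *D*<sub>B/R</sub>), where
     *D* = *I*<sub>post</sub>(mode) − *I*<sub>pre</sub>(mode) is the shift of
     the channel-ratio histogram mode (256 bins over [0, 2]);
   - post-acetic green and blue channel standard deviations;
   - mean CIE-Lab *a\** of the post-acetic sector;
   - Haralick correlation of the grey-level co-occurrence matrix (GLCM) of
     the HSV saturation difference image, summed over offsets at
     0°/45°/90°/135° with inter-pixel distance 5 and 8 grey levels.
4. **Classification** — KNN (k = 5, Euclidean), polynomial-kernel SVM
   (degree 4, cost 3, gamma 2.2) and a Gini decision tree (≤ 20 nodes) are
   compared under the holdout + 10-fold cross-validation protocol with
   per-fold z-score standardization, ROC/AUC, and grid search.
5. **Evaluation** — confusion matrices, sensitivity/specificity/accuracy,
   Cohen's κ with significance, reader pooling, the one-positive-sector
   patient rule, and the clock-annulus visualization of predictions
   against per-sector histopathology.

Clinical cervicograms of this kind are not publicly deposited, so the
package ships a first-class **synthetic scene generator** that emulates the
relevant statistics (pink elliptical ectocervix, vaginal-wall clutter,
os-slit fiducials, saturated specular spots, and sector-confined
aceto-whitening with elevated G/B, reduced *a\**, and coherent texture),
with per-sector ground truth, so the entire pipeline is testable end to end.

## Worked example

```python
from cervia.workbench import RunConfig, run_pipeline

result = run_pipeline(RunConfig(out_dir="scratch/demo"))
print(result.comparison)
print(f"sector accuracy {result.sector_accuracy:.1f}%")
```

prints (default 20-patient cohort, seeds 0/1/2):

```
  family  accuracy  sensitivity  specificity  kappa  auc
0    KNN     100.0        100.0        100.0    1.0  1.0
1    SVM     100.0        100.0        100.0    1.0  1.0
2     DT     100.0        100.0        100.0    1.0  1.0
sector accuracy 100.0%
```

i.e. on the default synthetic world every classifier separates abnormal from
normal sectors perfectly in cross-validation, and the best model recovers
all held-out per-sector ground truth. (Real cervicograms are far harder; the
generator's role is to verify mechanics and feature directions, not to
emulate clinical difficulty — see `docs/methods.md`.)

The same pipeline is available from the shell:

```bash
cervia simulate --n-patients 20 --seed 0 --out scratch/cohort
cervia extract --manifest scratch/cohort/cohort.csv --out scratch/features.csv
cervia run --out scratch/run
```

Reader-study arithmetic works directly from printed rates:

```python
from cervia.evaluate import confusion_from_rates, cohen_kappa

cm = confusion_from_rates(75.0, 100.0, n_pos=12, n_neg=8)  # -> tp=9 fn=3 fp=0 tn=8
print(round(cohen_kappa(cm).kappa, 3))                     # 0.706
```

## Acceptance script

`scripts/acceptance.py` reconstructs each reader's 2×2 confusion matrix from
the printed sensitivity/specificity of a 20-case reader study (12 abnormal,
8 normal), recomputes Cohen's κ per reader, and pools the four matrices
cellwise before recomputing the overall κ:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
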