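# ctacollat

Automated collateral-status classification for CT angiography (CTA)
maximum-intensity-projection (MIP) slices in acute ischemic stroke, built
from three pieces:

1. **Rule-based segmentation** — brain extraction from 8-bit windowed
   (0–450 HU) slices via cranium binarization at gray value 255,
   flood-fill interior recovery, XOR, three Sobel boundary-peeling passes,
   and morphological opening when a calvarial defect lets the brain leak
   into the background; followed by vessel segmentation with a
   normalized-histogram **triangle threshold**
   (`NH_i = H_i · (255 − g_peak) / H_peak`, threshold = the gray level
   farthest from the line joining the histogram peak to the top level).
2. **A parameterized CNN family** — 2–5 convolutional blocks with
   per-block filter doubling, swept over a 192-point grid of kernel size
   K ∈ {3,5,7}, first-layer filters F ∈ {8,16}, depth N_conv ∈ {2..5},
   fully connected width ∈ {64,128} and batch size ∈ {8,16,32,64}.
   Inputs are the binarized vessel masks of two anatomical levels
   (ganglionic + supraganglionic) stacked as a 128×128×2 tensor.
3. **An evaluation framework** — stratified patient-level five-fold
   cross-validation with a 3:1 train/validation split, tenfold
   augmentation of training images only, early stopping monitored on
   validation AUC, probabilities pooled across test folds, and metrics

   * Youden index `J = sensitivity + specificity − 1`, maximized over
     ROC cut-offs,
   * overall performance `= (J* + AUC) / 2`,
   * orientation `= sensitivity − specificity` (positive =
     sensitivity-oriented model).

Because clinical CTA cannot be redistributed, the package ships a
**phantom generator**: synthetic head slices with a 255-valued skull
ring, a noisy mid-intensity brain disc, curvilinear random-walk vessel
strokes whose density differs between good- and poor-collateral classes,
optional calvarial defects, and exact ground-truth masks. Every stage of
the pipeline is tested end-to-end against these phantoms.

The intended audience is researchers reproducing or extending
hyperparameter-orientation analyses of collateral classifiers, and
anyone needing a dependency-light (NumPy/SciPy) reference implementation
of the triangle-threshold vessel segmentation pipeline.

## Worked example

```bash
# 3-patient phantom cohort (BMPs + manifest.csv)
ctacollat phantom --n-good 2 --n-poor 1 --seed 3 --outdir cohort

# brain mask, then triangle-threshold vessel mask
ctacollat segment brain cohort/P0000_gang.bmp -o brain.bmp
ctacollat segment vessels cohort/P0000_gang.bmp --brain-mask brain.bmp \
    -o vessels.bmp --dump-histogram hist.csv
```

prints

```
wrote 3 patients to cohort/manifest.csv
brain mask: 31497 px -> brain.bmp
threshold 111; vessel px 3204 -> vessels.bmp
```

The brain mask covers the ~31.5k-pixel disc enclosed by the skull ring;
the adaptive threshold lands at gray 111, just above the parenchyma
histogram (range 70–110), so the 3204 returned pixels are the bright
vessel strokes. `hist.csv` holds the per-gray-level counts, normalized
values and perpendicular distances behind the threshold choice.

The same objects are available as a library:

```python
from ctacollat import phantom, preprocess, vesselseg

ph = phantom.generate_phantom(phantom.PhantomSpec(seed=3), "good")
brain = preprocess.extract_brain_region(ph.image)
vessels = vesselseg.segment_vessels(ph.image, brain)
```

A scaled-down grid sweep (one configuration here; drop `--scale` for the
full 192):

```bash
ctacollat sweep run --n-good 4 --n-poor 4 --scale 0.006 \
    --max-epochs 1 --patience 1 --seed 2 --outdir sweepout
ctacollat evaluate sweepout/predictions.csv
# model af678a305c42: AUC=0.562 cutoff=0.576 sens=50.00% spec=100.00%
#   acc=75.00% J=0.500 overall=0.531
```

`sweep filter` (AUC ≥ 0.7 subset), `sweep rank` (top models by overall
performance) and `sweep compare` (paired t / independent t /
Mann–Whitney U between hyperparameter levels) operate on the summaries
CSV.

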