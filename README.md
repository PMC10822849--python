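# qusresponse

Quantitative-ultrasound (QUS) parametric imaging and transfer-learning-style
classification for predicting breast-tumour response to neoadjuvant
chemotherapy from pre-treatment radiofrequency (RF) ultrasound.

Clinical studies of locally advanced breast cancer report that spectral
properties of calibrated ultrasound backscatter — measured before any
treatment — carry information about whether a tumour will respond to
chemotherapy. Because patient RF data cannot be redistributed, this package
pairs the full analysis pipeline with a point-scatterer RF simulator so that
every stage can be exercised, calibrated and tested against known ground
truth.

## The pipeline

1. **RF frames** (`synthetic_rf`): raw echo signals on a scan-line grid,
   6 MHz centre frequency, 3–8 MHz (−6 dB) band, 40 MHz sampling, from
   two-class cohorts (37 nonresponders vs 137 responders, 4–7 image planes
   per patient) whose tumour cores differ in scatterer radius and number
   density.
2. **Spectral estimation** (`qus_spectral`): per-block Hann-gated averaged
   periodograms, normalized against a reference phantom of known attenuation
   (0.576 dB/MHz·cm) and sound speed (1488 m/s):

   `NPS(f) = S(f) − R(f) + 4 (α_s − α_r) f d`  (dB; f in MHz, depth d in cm).

   A line fit on the band gives the spectral slope SS (dB/MHz), 0-MHz
   intercept SI (dB) and midband fit MBF = SI + SS·f_c (dB). The backscatter
   coefficient BSC(f) = BSC_ref(f)·10^(NPS/10) is fitted with a spherical
   Gaussian form factor, BSC(f) = C·f⁴·exp(−0.827 k² a_eff²), yielding the
   average scatterer diameter ASD = 2·a_eff (µm) and average acoustic
   concentration AAC = 10·log10(C/ASD⁶) (relative dB).
3. **Parametric maps** (`parametric_maps`): a 2.2 mm sliding window (94%
   overlap by default) over the tumour core + 5 mm margin produces five
   co-registered maps; each is cropped, min–max scaled and bilinearly
   resized to 224×224.
4. **Features** (`deep_features`): a frozen convolutional backbone maps each
   image to a 7×7×2048 activation (100,352-vector); per-patient vectors are
   averaged over the tumour's image planes. The default backbone is a
   seeded, fixed-weight random-projection CNN honouring the same output
   contract; any network with a `forward (224,224,3) -> (7,7,2048)` can be
   injected.
5. **Selection + balancing** (`selection_balancing`): keep features nonzero
   in ≥90% of training patients, select the k = round(√n) = 13 best by
   ANOVA F-test, then rebalance the training classes with SMOTE.
6. **Classification** (`classify_eval`): stratified 20% unseen holdout,
   fivefold cross-validation on the rest, linear SVM (C = 1), per-class
   precision/recall/F1 and balanced accuracy with nonresponder as the
   positive class.

## Worked example

The numbered drivers under `analysis/` run a 20-patient demonstration:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_build_parametric_maps.py
python analysis/03_extract_features.py
python analysis/04_classify_and_evaluate.py
```

prints, among other things:

```
P000 (NR): 191 blocks, 122 valid | median SS -0.421 dB/MHz | median ASD 56.1 um (truth 70.7 um in-core)
P005 (RR): 202 blocks, 131 valid | median SS -0.161 dB/MHz | median ASD 39.1 um (truth 40.9 um in-core)
...
confusion [[NR->NR, NR->RR], [RR->NR, RR->RR]]: [[1, 0], [0, 3]]
  balanced accuracy 100%
```

The nonresponder's larger core scatterers steepen the spectral slope
(−0.42 vs −0.16 dB/MHz) and enlarge the estimated scatterer diameter
(56 vs 39 µm, medians over core *and* margin blocks, hence below the
core-only truth), and the classifier separates the demonstration classes
perfectly. `analysis/05_calibration_studies.py` adds the estimator-recovery
and null-calibration checks (use `--full` for the 174-patient end-to-end
run).

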