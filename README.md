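# busfeat

Breast-ultrasound (BUS) tumor classification from combined deep and
handcrafted features.

Reading BUS images is operator-dependent, and computer-aided diagnosis
pipelines aim to give radiologists an objective second opinion on
whether an outlined tumor is benign or malignant. `busfeat` implements
such a pipeline end-to-end for grayscale ultrasound images paired with
binary tumor masks (or contour polygons):

1. **ROI definition** — the tight tumor bounding box expanded by 30 px
   per side (clipped to the image), so the classifier also sees the
   surrounding tissue.
2. **Deep features** — each convolutional layer CL of size W×H×N of a
   backbone network is summarized per channel k into
   CLmax(k) = max CL(·,·,k) and CLavg(k) = (1/WH) Σ CL(·,·,k),
   giving a 2N vector per layer. Six extraction levels assemble these
   (and the fc activations) with l2-normalization at every step: per
   layer (CF1), per block (CF2), all blocks (CF3 — the CONV set), per
   fc layer (FCF1), both fc layers (FCF2), and everything combined
   (CF_FCF). For VGG19 these levels contain 128–1024, 256–4096,
   11,008, 4096, 8,192 and 19,200 features respectively.
3. **Handcrafted features** — 800 gray-level co-occurrence (GLCM)
   texture statistics (10 distances × 4 orientations × 20
   Haralick/Soh/Clausi statistics) from the ROI, and 18 morphological
   features from the tumor outline (area, perimeter, form factor
   4πA/P², roundness, aspect ratio, convexity, solidity, extent,
   undulation, compactness, NRL entropy/variance, and six best-fit
   ellipse descriptors).
4. **Feature selection** — mRMR (MID criterion, three-state
   discretization at mean ± stdev) ranks all M features; the nested
   top-m groups are scored by cross-validated SVM MCC and the smallest
   argmax becomes the candidate group; backward elimination then removes
   features while the MCC does not drop.
5. **Classification** — a binary RBF-SVM (malignant = positive class),
   tuned by exhaustive grid search over C ∈ {2⁻⁵…2¹⁵} and
   σ ∈ {2⁻¹⁵…2³} (399 pairs, γ = 1/(2σ²)) maximizing the MCC pooled
   over stratified 10-fold cross-validation. Reports accuracy,
   sensitivity, specificity, MCC, PPV, NPV (mean ± stdev across folds),
   ROC/AUC, and paired t-tests between competing configurations.

Because clinical BUS datasets with expert outlines are generally not
redistributable, the package ships a seeded **phantom generator**:
speckle-textured images with hypoechoic, star-convex lesions whose
boundary irregularity is class-dependent (smooth ≈ benign, spiculated ≈
malignant), with exact masks. The full pipeline is exercised and tested
on these phantoms; see `docs/methods.md` for what that does and does
not demonstrate about clinical data.

## Worked example

```sh
busfeat synth --out demo --n-benign 30 --n-malignant 30 --seed 5
busfeat cv demo/manifest.csv --recipe morphology --seed 5 --out demo_cv
```

prints

```
selected: morph (1)
    accuracy: 100.0 +/-  0.0 %
 sensitivity: 100.0 +/-  0.0 %
 specificity: 100.0 +/-  0.0 %
         mcc: 100.0 +/-  0.0 %
         ppv: 100.0 +/-  0.0 %
         npv: 100.0 +/-  0.0 %
         auc: 1.000
```

`selected: morph (1)` is the provenance line: the two-phase selection
reduced the 18 morphology features to a single one that alone separates
these (deliberately easy) phantoms perfectly in 10-fold CV; the six
metrics are fold means ± standard deviations in percent. Other recipes
combine families, e.g. `--recipe deep:CF3+morphology` or
`--recipe texture+morphology` (818 features); `--no-selection` feeds
the full vector to the SVM; `busfeat generalize train.csv test.csv`
trains on one manifest and evaluates once on a disjoint one.

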