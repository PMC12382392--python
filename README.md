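# nitroscan

Smartphone-scale plant phenotyping for leafy vegetables: estimate **leaf
nitrogen** (total reduced nitrogen TRN and nitrate NO3, mg N/g DW) and
**shoot dry-weight biomass** (DW, g) from top-view RGB imagery and colored
LiDAR point clouds, and locate the **nitrogen dosage that maximizes growth**
from dose-response curves.

The package is aimed at phenotyping and precision-agriculture researchers
who want a tested, fully seeded reference implementation of this pipeline:

1. **Spectral features** — raw digital numbers are calibrated to reflectance
   with a dark frame and a 99.9 % white reference
   (`refl = (DN − mean(dark)) / (mean(white) − mean(dark))`), leaves are
   segmented (ExG + Otsu, or any externally supplied mask), and 15 RGB
   vegetation indices (ExG, GLI, NGRDI, MGRVI, VARI, TGI, ExR, NDYI, NRI,
   NGI, NBI, GMRI, GRRI, EGMERI, RGBVI) are averaged per plant.
2. **Structural features** — point clouds are denoised by voxel point
   density (1 cm voxels, cells of ≤ 4 points dropped), split into plant and
   background by 2-class K-means on the RGB attributes, and summarized by 9
   traits: height HT, crown width CW (exact planar diameter), crown volume
   CV (convex or alpha-shape hull), point count PC, density PD = PC/CV,
   per-voxel count variance CR, and counts above 75/50/25 % of plant height.
3. **Trait regression** — SVR, random forest and Lasso on spectral-only,
   structural-only and combined feature sets, scored by ME, MAE, RMSE,
   rRMSE = RMSE/mean(obs) and R² on a stratified 70/30 split, plus feature
   relevance from normalized linear-SVR weights averaged over 100 random
   splits.
4. **Dose response** — each feature y is fit by OLS as
   `y = a·u² + b·u + c, u = √dose`; concave fits with an interior vertex
   give a peak dose `(−b/2a)²`. Peaks are averaged within the spectral and
   structural groups and across groups to give the optimal dosage.
5. **Baselines** — DGCI-based nitrogen estimation and Otsu leaf-area-based
   dry-weight estimation for comparison.

Because no public dataset accompanies this design, a first-class
**synthetic-experiment generator** emulates the study conditions: 84 plants
in 8 dose groups (20–800 ppm), traits following concave quadratics in
√dose peaking at 150 ppm, leaf greenness coupled to TRN, canopy size coupled
to DW, and clouds carrying a dark background plane plus isolated noise
points that the denoiser provably removes exactly.

## Worked example

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_extract_features.py --seed 1
python analysis/05_dose_response.py
```

prints, among other output,

```
Leaf segmentation mean IoU vs generator truth: 1.000
Polynomial order comparison on DW (corrected AIC, lower is better):
{1: 362.3, 2: 196.1, 3: 193.4}
Group peak dosages: spectral 134.4 ppm, structural 172.1 ppm
Optimal nitrogen dosage: 153.2 ppm (generator truth: trait curves peak at 150 ppm)
```

meaning: the classical segmenter recovers the generated leaf masks
essentially perfectly; a quadratic in √dose fits dry weight far better than
a line (the cubic adds nothing substantive); and averaging the interior
dose-response peaks of the chlorophyll indices (ExR, VARI, GMRI) and the
canopy metrics (HT, CV) localizes the optimum within a few ppm of the
configured 150 ppm truth. `analysis/03_train_models.py`,
`04_feature_relevance.py` and `06_baseline_comparison.py` continue the
narrative: spectral features carry the nitrogen signal, structural features
the biomass signal, the combined set is competitive with the better single
modality, and both single-feature baselines trail the random forests.

The same stages are available as a CLI (`nitroscan simulate`,
`extract-spectral`, `extract-structural`, `train`, `relevance`,
`optimize-dose`, `run-all`) and as one call, `nitroscan.run_all(RunConfig())`,
which is byte-reproducible under a fixed seed.

## Layout

```
src/nitroscan/     library: synthetic, spectral, structural, regression,
                   doseresp, baselines, pipeline, io, cli
analysis/          numbered narrative drivers writing results/
tests/             pytest suite (unit, property, end-to-end acceptance)
docs/methods.md    model, parameter and design documentation
```
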