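# organoid3d

3D segmentation and quantification of organoids and their nuclei in
high-content screening plates, plus the downstream analytics such screens
need: imaged-area-normalized cell densities, live/dead filtering from a
dead-cell dye, IC50 dose–response curves, clone co-localization
statistics, and nuclear-morphology classifiers.  A ground-truthed
synthetic plate generator exercises every stage, so the whole pipeline is
testable on a laptop with no imaging data.

It is written for groups running 3D organoid cultures (e.g. patient-derived
tumour models with fluorescently labelled subclones) on confocal
high-content systems that export per-field, per-plane, per-channel TIFFs.

## The pipeline

1. **Assembly** (`plate_io`): per-field z-stack tiles are stitched into one
   `(channel, z, y, x)` volume per well and stored as a chunked Zarr array.
2. **Organoid segmentation** (`organoid_segmentation`): per-field cleaning
   (binarize / open / dilate on the 2D max projection), anisotropic
   Gaussian smoothing, triangle histogram thresholding, stitch-then-label
   3D connected components, small-object removal, and a per-organoid
   feature table (volumes, axes, solidity, Euler number, intensities).
3. **Nucleus segmentation** (`nuclei_segmentation`): each organoid is
   cropped by its 3D bbox, percentile-normalized per channel, and
   segmented per fluorescence channel by a pluggable backend (default: an
   anisotropy-aware seeded watershed; adapter slot for star-convex CNNs).
4. **Quantification** (`well_quantification`): organoid-occupied imaged
   area in mm², dead-nucleus flagging from the dye channel
   (bbox mean > 0.1 after per-organoid normalization), live counts,
   densities, clone ratios.
5. **Analytics**: `dose_response` fits 4/5-parameter logistic curves
   (`f(x) = B + (T−B)/(1+10^{b(x_mid−x)})^s` on x = log10 dose) with
   bootstrap IC50 confidence intervals; `spatial_stats` computes the clone
   localization score `Lo = mean(X_n / (K·R_x))` over K-nearest-neighbour
   windows, its radial-neighbourhood variant and permutation p-values;
   `morphology_classifier` trains logistic regressions separating treated
   from untreated nuclei and reports held-out ROC AUC.
6. **Simulation** (`synthetic_data`): renders wells of ellipsoidal
   organoids packed with flat-top nucleus blobs in two clone channels plus
   a dead-dye channel, with tunable clone mixing, spatial affinity, dose
   effects, debris and noise — together with exact truth tables.

See `docs/methods.md` for the model details and numerical choices.

## Worked example

```python
from organoid3d import SimulationConfig, generate_well_volume
from organoid3d.organoid_segmentation import SegmentationParams
from organoid3d.nuclei_segmentation import BackendConfig
from organoid3d.pipeline import segment_well_organoids, segment_well_nuclei
from organoid3d.spatial_stats import CellPointSet, localization_score

cfg = SimulationConfig(seed=1, clone_fraction=0.5, affinity=1.0)
vol, truth = generate_well_volume(cfg)          # ~20 organoids, ~1500 nuclei

labels, organoids = segment_well_organoids(vol, SegmentationParams())
nuclei = segment_well_nuclei(vol, organoids, BackendConfig(), dead_channel="draq7")
print(len(organoids), "organoids,", len(nuclei), "nuclei")

biggest = organoids.sort_values("volume").iloc[-1]["label"]
ps = CellPointSet.from_nuclei(nuclei, vol.voxel_size_um, organoid_label=biggest)
print("Lo(K=5) =", round(localization_score(ps, "mcherry", 5).score, 2))
```

Output:

```
20 organoids, 1523 nuclei
Lo(K=5) = 1.62
```

The well was generated with 20 organoids and 1,485 true nuclei, so both
counts are recovered to within a few percent.  `Lo(K=5) = 1.62` means a
mCherry cell's five nearest neighbours are 62% more enriched for mCherry
cells than the organoid-wide fraction would predict — the expected
signature of the fully blocked clone arrangement (`affinity=1`); under
random mixing the score sits at 1.

The same flow is available from the shell:

```bash
organoid3d simulate --out plate/ --seed 1 --wells 2
organoid3d run --input plate/ --output results/ --dead-channel draq7 --workers 2
organoid3d ic50 --summary results/wells_summary.csv --response-col density_egfp --seed 1
```

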