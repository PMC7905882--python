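# stedclust

Nanocluster localization and spatial statistics for STED
super-resolution microscopy images.

Membrane receptors such as the immune checkpoint PD-1 organize into
nanoclusters — aggregations below the diffraction limit that appear as
localized intensity peaks in STED images (~30–50 nm lateral
resolution, 20–25 nm pixels). Whether a ligand geometry reorganizes
those clusters is a question about spatial point patterns: do clusters
pack more densely, sit closer together, or grow larger under one
condition than another? `stedclust` implements the full desk side of
such a study, from raw image to per-condition significance calls, plus
a synthetic STED-image generator with known ground truth so every
stage is testable without microscope data.

## The pipeline

**Localization.** Each raw image is binarized into a cell mask (Otsu
on a log-transformed, lightly smoothed copy), multiplied by the mask,
band-passed with a difference of Gaussians (σ₁ = 0, σ₂ = 100 nm),
clipped at zero, smoothed (σ = 15 nm), and standardized by dividing by
(mean + std) of the in-cell pixels. Local maxima above a global,
batch-calibrated threshold become cluster localizations; maxima in
adjacent pixels are merged at their intensity-weighted centroid.

**Three per-cell statistics.**

- *Local density*: a 2D Gaussian KDE map of the localizations
  (bandwidth 200 nm) with unit-peak kernels, so the value at a pixel
  reads as the kernel-weighted number of clusters around it; the
  intensities of its local maxima form the density-peak distribution.
- *Nearest neighbours*: for each cluster, the distances to its k = 4
  nearest neighbours (self excluded), pooled per cell.
- *Cluster size*: four 400 nm line profiles (0°/45°/90°/135°) through
  each localization, each fitted with a Lorentzian
  `offset + A / (1 + ((x − x₀)/γ)²)`; among profiles with R² > 0.9 the
  minimum FWHM (= 2γ) is the cluster size.

**Statistics across cells.** The cell is the statistical unit. Each
cell's sample becomes a probability-density curve (Gaussian KDE);
curves are averaged per condition with a pointwise 83.4% Student-t
confidence band of the mean. Non-overlap of two bands marks a
significant difference at ≈ the 5% two-sided t-test level; maximal
non-overlap intervals, crossover points (peak of the running integral
of the curve difference) and one-sided two-sample Kolmogorov–Smirnov
tests on the pooled values are reported per pairwise comparison.

**Simulator.** Cell-shaped support regions, cluster positions from
CSR / Thomas (aggregated) / fixed-pair / coincident point processes,
per-cluster apparent sizes, 2D Lorentzian (or Gaussian) spot profiles,
in/out-of-cell background and Poisson photon noise — all reproducible
from a single master seed, with ground truth saved beside every image.

## Worked example

Simulate the default study — three conditions (a CSR control and two
Thomas-aggregated patterns) with 24 cells each — and run the whole
analysis:

```python
from stedclust import (PreprocessParams, PipelineConfig,
                       run_full_pipeline, generate_dataset)
from stedclust.pipeline import default_experiment, calibrate_threshold_from_render

conditions, render = default_experiment(n_cells=24)
dataset = generate_dataset(conditions, 24, render, (256, 256), master_seed=7)
threshold = calibrate_threshold_from_render(render, (256, 256), None, seed=7)
print(f"calibrated peak threshold: {threshold:.3f}")

config = PipelineConfig(preprocess=PreprocessParams(peak_threshold=threshold),
                        outdir="study_out", master_seed=7)
report = run_full_pipeline(config, dataset=dataset)

nn = report["analyses"]["nn_distance"]
for comp in nn["comparisons"]:
    a, b = comp["pair"]
    iv = ", ".join(f"{lo:.0f}-{hi:.0f}" for lo, hi in comp["significant_intervals"][:2])
    print(f"{a} vs {b}: significant at {iv} nm; "
          f"crossover {comp['crossover_point']:.0f} nm; "
          f"KS p ({a} distances larger) = {comp['ks_a_bigger_than_b']['p']:.2e}")
```

prints

```
calibrated peak threshold: 0.624
control vs loose: significant at 0-394, 461-1141 nm; crossover 428 nm; KS p (control distances larger) = 4.17e-149
control vs tight: significant at 0-328, 366-927 nm; crossover 347 nm; KS p (control distances larger) = 3.94e-218
loose vs tight: significant at 0-185, 290-642 nm; crossover 242 nm; KS p (loose distances larger) = 5.14e-44
```

Reading it: both aggregated conditions shift nearest-neighbour
distances toward shorter values than the CSR control — the confidence
bands separate below ~330–390 nm (where the aggregated conditions have
more probability mass) and again at larger distances (where the
control has more, a direct consequence of the fixed k), with the
crossover point marking where the cumulative difference peaks. The
tiny KS p-values confirm the pooled distributions are stochastically
ordered in the same direction. `study_out/` holds per-cell
localization CSVs, the distributions table, per-analysis statistics
JSONs, publication-style curve plots and a run log echoing every
parameter and seed.

The same pipeline is scriptable from the shell:

```bash
stedclust run-all --outdir study_out --n-cells 24 --seed 7
stedclust localize image.tif --pixel-size-nm 20 --threshold 0.62 --out locs.csv
```

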