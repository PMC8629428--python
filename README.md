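# memcrowd

Quantification of membrane protein **cluster and crowd organization** in
super-resolution (STED-scale) and epifluorescence images of plasma-membrane
sheets — built for the syntaxin 1A / SNAP25 question: do tight syntaxin
clusters reorganize the diffuse SNAP25 crowds around them?

The package implements the full measurement chain:

- **Spot detection** by topographic prominence (ImageJ "Find Maxima"
  semantics, persistence/union-find implementation) with plateau-centroid
  tie-breaking;
- **Spot sizing** by dual-orientation 31 × 3 px linescan Gaussian fits,
  FWHM = 2√(2 ln 2)·σ, with R² ≥ 0.8 and middle-third centring QC;
- **Clustering degree** rSDM = SD/mean of background-corrected ROI pixels;
- **Colocalization** by Pearson correlation (PCC) with the 180°-rotated
  ("flipped") chance-overlap control;
- **Point-pattern statistics** — nearest-neighbour distributions, radial
  cross-counts, pair distribution g(r) — against the ideal-gas/CSR null
  p(r) = 2πλr·e^(−πλr²), with minus-sampling border correction and seeded
  Monte-Carlo envelopes;
- **Membrane-sheet segmentation** (blur σ = 3 + Otsu + area filter) and the
  plasma-membrane fraction arithmetic;
- **Regression models**: per-sheet intensity–intensity OLS with a Welch
  slope test, the exponential decay y = (a − b)e^(−d·x) + b of clustering
  degree vs staining intensity, and copy-number ratio propagation;
- a **synthetic-scene generator** (Thomas cluster process, tunable crowd
  recruitment coupling, 65 nm FWHM Gaussian PSF, Poisson + read noise,
  optional self-quenching and epitope-shielding distortions) providing
  ground truth for every stage.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import numpy as np
from memcrowd import (SceneSpec, simulate_scene, RegionOfInterest,
                      find_maxima, maxima_size, maxima_density,
                      roi_mean_intensity, pcc, pcc_flipped_control,
                      nn_distances)

scene = simulate_scene(SceneSpec(window_um=(5, 5), coupling_p=1.0, seed=42))
roi = RegionOfInterest.full(scene.image_clusters)

clusters = find_maxima(scene.image_clusters)                      # sharp channel
crowds = find_maxima(scene.image_crowds, presmooth_sigma_px=0.5)  # noisy channel

size_nm, _ = maxima_size(scene.image_clusters, clusters)
print(f"cluster density {maxima_density(clusters, roi):.1f} /um^2, "
      f"size {size_nm:.0f} nm")
stats = roi_mean_intensity(scene.image_crowds, roi, background=5.0)
print(f"crowd rSDM {stats.rsdm:.2f}")
print(f"PCC {pcc(scene.image_clusters, scene.image_crowds, roi):.2f} "
      f"(flipped {pcc_flipped_control(scene.image_clusters, scene.image_crowds, roi):.2f})")
print(f"median crowd-to-cluster distance "
      f"{np.median(nn_distances(crowds, clusters, 200.0)):.0f} nm")
```

prints (seed 42):

```
cluster density 10.1 /um^2, size 89 nm
crowd rSDM 1.65
PCC 0.54 (flipped 0.01)
median crowd-to-cluster distance 35 nm
```

With full recruitment (`coupling_p=1`) the crowd channel is strongly
clustered (high rSDM), correlates with the cluster channel far above its
flipped control, and crowd maxima sit ~35 nm from the nearest cluster —
versus ~140 nm (ideal-gas-like) at `coupling_p=0`.

## Analysis scripts

Numbered drivers under `analysis/` rebuild the study narrative on synthetic
conditions and write tables to `results/`:

1. `01_simulate_scenes.py` — render control / overexpression-like /
   SNARE-deleted-like conditions (images under `scratch/`);
2. `02_cluster_metrics.py` — densities, sizes, rSDM, PCC per condition,
   percent-of-control comparisons;
3. `03_spatial_statistics.py` — cross-type distances and g(r) vs CSR
   envelopes;
4. `04_model_fits.py` — shielding-vs-slope regression, rSDM-vs-intensity
   exponential fit, and the printed ratio arithmetic.

The command line mirrors the library: `memcrowd simulate|analyze|compare|report`.

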