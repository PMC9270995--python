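# bmoquant

Quantitative 3D image analysis for **bone marrow organoids (BMOs)** —
self-aggregated co-cultures of mesenchymal stromal cells (MSCs) and
endothelial cells (ECs) grown one-per-microwell in hydrogel arrays, used to
study the homing of hematopoietic stem/progenitor cells (HSPCs) into a
vascularized niche *in vitro*.

The package turns multi-channel confocal z-stacks (nuclear/mesenchymal,
CD31, CD45/CFSE channels) and brightfield plate images into per-organoid
quantities:

- **Segmentation** — organoid surface from the smoothed nuclear/mesenchymal
  channel; endothelial network from CD31 restricted to the organoid; homed
  cells (CD45⁺ or CFSE⁺) by scale-matched Laplacian-of-Gaussian blob
  detection, "homed" meaning the centroid lies inside the organoid mask.
- **Network architecture** — 3D skeletonization of the vessel mask to a
  centerline graph; volume, branch count, junction count, total length.
- **Distance statistics with a null model** — distance channels whose voxel
  values are the Euclidean distance (µm) to the organoid surface or network
  surface; per-cell distances D_o and D_n as the mean of those channels over
  the cell volume; the *expected* distance of a uniformly placed cell as the
  channel mean over the organoid volume (for D_o) or the network-cleared
  organoid volume (for D_n); and the fraction of cells strictly closer than
  that expectation. For a ball of radius R the uniform baseline is exact:
  E[D_o] = R/4 and P(D_o < E[D_o]) = 1 − (3/4)³ = 37/64 ≈ 0.578.
- **Growth and volume** — per-microwell aggregate areas from brightfield
  images of the 11×11 array (121 microwells of 400 µm per well), and the
  ellipse-fit volume estimator Vol = 4/3·π·R_major·R_minor² from the
  z-projection of the organoid mask.
- **Time courses** — homed-cell counts normalized to the number seeded,
  descriptive summaries across organoids, and CFSE-dilution tracking
  (intensity halves per division; generation k = round(log₂(I₀/I))).
- **Synthetic ground truth** — a seeded generator for all of the above:
  organoid bodies, capsule-tree vessel networks with a true centerline
  graph, cells placed by uniform / perivascular / depth-biased laws with
  true distances, confocal-like rendering (PSF blur, Gaussian+Poisson
  noise), and brightfield plates — so the whole pipeline is testable without
  external data.

## Worked example

The null model, straight from the library (see `examples/02_null_model_distances.py`):

```python
import numpy as np
from bmoquant import (ShapeSpec, PlacementLaw, make_organoid_mask,
                      place_cells, distance_channel, expected_distance)

ball = make_organoid_mask(ShapeSpec("ball", (100.0,)), (1, 1, 1), (211, 211, 211))
exp_o = expected_distance(distance_channel(ball, ball))
cells = place_cells(ball, None, 2000, PlacementLaw("uniform"), seed=0)
d_o = np.array([c.d_o_um for c in cells])
```

prints

```
expected D_o (volume mean): 24.30 µm   [closed form R/4 = 25]
sample mean D_o (n=2000):   24.17 µm
fraction below expected:    0.580   [closed form 37/64 = 0.578]
```

The expected distance sits ~0.7 µm below the continuous closed form because
the digital surface is the shell of boundary *voxels*; the fraction-below
statistic lands on 37/64, the signature that a uniform cloud is compared to
the volume mean rather than the median. With perivascular placement
(attraction scale 10 µm) the same statistic computed against the *network*
distance rises above 0.90 — the pattern expected when homed cells
preferentially sit near vessels.

An end-to-end run (`examples/06_full_pipeline.py`) simulates a 75/25-like
organoid, segments it back, and prints the per-organoid record:

```
organoid demo-0 (75/25):
  ellipse-fit volume:   1.43e+06 µm³ (R_major 70, R_minor 70 µm)
  network:              3.76e+04 µm³, 13 branches, 5 junctions
  homed cells:          40 (100.0% of seeded)
  expected D_o / D_n:   16.8 / 20.9 µm
  fraction below D_o:   0.68 (uniform placement sits near 0.58, not 0.5)
  fraction below D_n:   0.47
```

Each script in `examples/` exercises one capability and explains its output.
The same stages are available from the shell:

```bash
bmoquant simulate --out scene/ --seed 1
bmoquant segment scene/stack.ome.tif --out masks/
bmoquant network masks/network_mask.tif --out net/
bmoquant run-all --config cfg.yaml --seed 1 --out results/
```

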