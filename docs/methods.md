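# Methods

This note documents the models, conventions and numerical choices behind
`bmoquant`, in the order a stack flows through the pipeline. Nothing here
states an empirical result the test suite or `scripts/acceptance.py` does
not itself compute.

## Coordinate and unit conventions

Arrays are `(z, y, x)` (channel-first when multi-channel); voxel `(i, j, k)`
has physical center `(i·dz, j·dy, k·dx)` in µm. All lengths, areas and
volumes are physical. Anisotropic spacing is first-class: smoothing sigmas
are given in µm and converted per axis, distance transforms use the spacing
as the sampling metric, and skeleton path lengths sum anisotropic steps.
Typical confocal geometry (0.71 µm in-plane, 0.5 µm z-step) is exercised in
dedicated tests; most fixtures use 1 µm isotropic grids for clarity.

## Synthetic scenes: what they emulate and what they do not

The generator produces the statistical structure the analysis assumes, with
known ground truth:

- **Organoid body**: a voxelized ball or axis-aligned ellipsoid,
  ~200–400 µm across. Real organoids are rounded but not exactly
  ellipsoidal; surface roughness, internal intensity texture and nuclear
  granularity are not modeled. Consequence: segmentation scores on synthetic
  data bound the easy part of the problem (geometry recovery), not
  stain-quality variation.
- **Vessel network**: a random capsule tree. Root segments start on a shell
  at 0.6–0.9 of the organoid radius with headings blended toward the local
  tangent plane by `outer_bias` (0–1) — this encodes the observation that
  endothelial structures arrange preferentially toward the organoid
  periphery, and `outer_bias = 1` gives purely shell-hugging vessels. Branch
  events split a growing tip into two daughters rotated 30–55° off the
  parent heading, with all pairwise angles at a node ≥ 45°. A clearance
  constraint (default 4.5 vessel radii between non-adjacent segments;
  relax via `min_clearance_um` for denser networks) keeps the rasterized
  mask's skeleton topologically identical to the true graph, which is what
  makes exact branch/junction oracle tests possible. Segments that would
  exit the safe interior margin have their outward radial component
  reflected inward; branch events with no admissible placement are dropped
  and logged, and the truth graph records what was actually placed. No
  anastomosis (the true graph is a forest), no radius tapering, no lumen.
- **Cell placement laws**: `uniform` draws voxels independently and
  uniformly from the organoid-minus-network volume — exactly the null model
  the distance statistics assume. `perivascular` applies rejection sampling
  with acceptance weight exp(−D_n/scale): single parameter, monotone in
  distance, and recovering the uniform law as scale → ∞.
  `depth_biased` weights by exp((D_o − max D_o)/scale), attracting cells to
  the core. True D_o/D_n per cell are read from distance channels computed
  on the *true* masks, so downstream errors measure the pipeline, not the
  truth definition. An optional hard-core separation (`min_separation_um`)
  thins draws until all pairwise distances clear the limit — cells are
  ~8 µm bodies, not points — and is used in detection round-trip fixtures
  (10 µm) so that "detected = planted" is a well-posed claim; the
  null-model statistics always use the pure independent-draw law.
- **Rendering**: organoid mask → flat nuclear/mesenchymal channel, network
  mask → flat CD31 channel, each cell → Gaussian blob (σ = cell radius / 2)
  with peak I₀/2^k for CFSE generation k, composited by voxelwise maximum so
  planted peaks are exact before degradation. Then per-channel Gaussian PSF
  blur, constant background, optional Poisson shot noise (scaled) and
  Gaussian read noise, clipped to the bit depth. This is a phenomenological
  acquisition model: no depth-dependent attenuation, scattering, bleaching
  or spectral bleed-through. A universal "no voxel exceeds background + 3σ"
  bound cannot hold for Gaussian noise over millions of voxels; the
  background-only guarantee is exact at zero noise and a tail-fraction bound
  (≤ 0.5 % above 3σ) otherwise.
- **Brightfield plates**: flat dark disks centered in an 11×11 grid of
  400 µm microwells on a brighter background with mild Gaussian noise — no
  meniscus shading, debris or illumination gradients.

Every stochastic operation is a pure function of (inputs, seed).

## Segmentation

Organoid: Gaussian smoothing at σ = 2 µm (physical units) on the
nuclear/mesenchymal channel, global threshold (Otsu by default; a fixed
threshold is available for cross-run comparability), interior hole filling,
largest 26-connected component. The 2 µm default matches the scale of the
structure being smoothed over (cell-scale texture); σ = 1 µm for CD31
preserves 3–8 µm vessels. The network threshold is computed from voxels
inside the organoid only, and objects below 100 µm³ (≈ a 6 µm ball) are
removed as speckle. An empty network is a valid outcome (pure-MSC organoids)
and is flagged in logs, never fatal.

Cell detection: Laplacian-of-Gaussian scale stack spanning the expected
diameter range (default 6–14 µm; r = σ√3 in 3D), per-axis sigmas for
anisotropy. Candidates are validated against a robust background floor —
median + 7·MAD of a copy smoothed at the minimum cell scale — which removes
the white-noise false positives that survive the LoG threshold in
multi-million-voxel stacks (the 7σ level is set by that multiple-comparison
burden). Surviving peaks undergo greedy non-maximum suppression at the
minimum diameter (two spots closer than the resolution limit merge,
brightest wins), then a local half-peak segmentation yields the cell's
voxels, intensity-weighted centroid, volume and per-channel means, plus the
peak intensity. Only cells whose centroid lies strictly inside the organoid
mask are returned — the operational definition of a homed cell; boundary
cases the imaging literature leaves undefined are thereby resolved
conservatively.

## Skeleton analysis

`skimage.morphology.skeletonize` thins the vessel mask to a one-voxel
centerline; the graph is assembled with 26-connectivity. Junction voxels
(≥ 3 skeleton neighbors) are clustered (adjacent junction voxels → one node
at their centroid); endpoints have exactly one neighbor; branches are
maximal chains between nodes with anisotropy-aware path lengths.

Thinning thick junctions is the main artifact source: one true junction can
split into 2–3 junction clusters joined by micro-branches (including
triangles and chains that re-enter the same cluster as short self-loops).
Cleanup is mask-informed rather than constant-tuned: using the mask's
interior distance transform, junction–junction branches, terminal spurs and
self-loops shorter than 3× the local half-thickness are contracted/removed —
two real junctions of tubes that thick could not be resolved at that
separation anyway. Junctions left with degree 2 dissolve into pass-through
branches; degree-1 junctions reclassify as endpoints. A junction-free closed
loop is kept as one self-edge branch (node kind `"cycle"`). The default
terminal-spur floor is two voxel diagonals. With these rules, skeleton
branch/junction counts equal the generator's truth graph exactly on seeded
capsule trees (asserted in the tests), and metrics are reported both
globally and per connected component.

## Distance quantification

The surface of a mask is its set of voxels with a 6-connected background
neighbor; array-border voxels count as surface. Distance channels are exact
Euclidean distance transforms (scipy EDT with the voxel spacing as sampling)
to that surface set, defined on a domain mask and NaN elsewhere — outside
the domain the distance is *undefined*, never zero. Surface voxels are at
distance 0.

Per-cell D_o/D_n = mean of the channel over the cell's segmented voxels
restricted to the domain; cells entirely outside the domain are flagged
excluded. Expected distances average the channel over the whole organoid
volume (D_o) or the organoid volume minus the network (D_n) — the volume a
uniformly placed cell can occupy. The fraction-below-expected statistic uses
strict inequality; ties count as not below. Because the comparison is to the
mean, the uniform baseline for a ball is 37/64 ≈ 0.578, not 0.5 — the
package's key control, verified against the closed form and Monte-Carlo
sampling. Digitization biases the ball expectation ~3 % below R/4 (surface
voxel centers sit inside the continuous sphere); tolerances account for
this. Across organoids, expected distances are summarized as mean ± SD over
organoids (the per-voxel SD within one organoid is a different, larger
quantity and is not reported).

Histograms use half-open bins [k·w, (k+1)·w) with a 5 µm default width;
relative mode normalizes to unit mass.

## Growth and volume

Brightfield analysis inverse-thresholds the plate image (aggregates are
darker), labels particles, and assigns each to the microwell whose ROI
circle (radius = pitch/2) contains its centroid. Particles below
5×10³ µm² are debris; above 2×10⁵ µm² they are flagged `merged`; particles
touching the image border flag `edge`; several particles in one microwell
keep the largest and flag `multi`; empty microwells yield a record with
area 0 and flag `empty` — one record per microwell, always.

The volume estimator projects the mask along z (the optical axis), fits the
equivalent ellipse of the projection by second-order moments, and applies
Vol = 4/3·π·R_major·R_minor². The formula is exact for spheres and for
prolate shapes whose long axis lies in the imaging plane; for oblate shapes
flattened along z it overestimates by ≈ the in-plane/axial radius ratio
(a 100×100×40 µm organoid comes out 2.5× too large). The bias is
characterized in the tests rather than corrected, because the estimator's
definition — not a better volume — is the quantity of record.

## Time courses and CFSE dilution

Counts are descriptive: per organoid and time, n_cells and
pct_homed = 100·n/n_seeded; condition summaries report mean/SD across
organoids. No inferential statistics are computed. CFSE generation
assignment uses the cell's **peak** intensity (max over its segmented
voxels): with the blob rendering model the peak equals the planted I₀/2^k
exactly at zero blur/noise, whereas the mean depends on the segmentation
support; k = round(log₂(I₀/I)) clipped to [0, 8], NaN for non-positive
intensities. When I₀ is not supplied it should be estimated as the median
intensity of the labeled input suspension at t = 0. The dilution check
reports per-time median intensities and flags an interval when the median
drops ≥ 40 % — the halving pattern expected from division; the 40 % level is
this package's convention (no numeric criterion exists in the literature for
"constant" CFSE) and is labeled as such in the output.

## Pipeline and reproducibility

`RunConfig` (pydantic, unknown keys rejected) carries every stage parameter
with defaults, round-trips losslessly to YAML/JSON, and hashes to a short config
digest written into every output file together with the seed. Identical
config + seed reproduce byte-identical CSV/JSON outputs. Stage failures
abort with the failing stage named. Warnings (no network, excluded cells,
dropped branch events) are logged, never silently swallowed.

## Problem sizes and known limitations

Tests run at 96–211 voxel grids; the full round-trip check runs once at
256³ with a 30-segment network and 100 cells. Limitations worth restating:
synthetic stains are flat (no texture), the vessel generator makes forests
(no loops unless constructed explicitly), the acquisition model is
phenomenological, detection assumes quasi-spherical cells in the 2–30 µm
diameter window, and passing round-trip tests on synthetic data bounds
algorithmic correctness — not performance on real stacks with uneven
staining, optical attenuation or touching cells.
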