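# Methods

`canopyrecon` reconstructs a 3-D point cloud of a crop row from a
consumer RGB-D camera carried over the canopy by a moving platform, and
measures per-plant phenotypic traits (height, leaf area, projected canopy
area) from the result. This note documents the models, the parameters
that matter, the synthetic test bed, and the numerical choices.

## Acquisition model

The sensor looks straight down from 1.1 m above the ground and records
colour and depth at 30 Hz while the platform translates along the row at
0.2–0.6 m/s. The sensor's x axis opposes the platform motion and its z
axis points at the ground, so in camera coordinates the row extends along
x and scene content drifts toward +u as the platform advances. Depth is
stored as 16-bit integers in millimetres (depth value 0 = no
measurement); the usable depth window is the sensor's working range,
0.11–1.5 m.

Depth and colour cameras are related by a rigid extrinsic transform
`P_rgb = R·P_ir + T`. A colour pixel with candidate depth maps to a depth
pixel by back-projection, inverse extrinsics and re-projection; the
candidate comes from the depth image resampled by forward projection
(standard align-depth-to-colour with a z-buffer), and the mapping is
iterated once with the depth actually read back. Fractional mapped pixels
resolve by nearest-neighbour rounding — bilinear depth interpolation is
deliberately avoided because depth discontinuities at leaf edges would
fabricate intermediate depths. Fused clouds carry one point per colour
pixel with valid in-range depth.

## Frame selection by visual displacement

At 30 Hz consecutive frames are nearly redundant; reconstruction uses
frames a fixed metric distance apart. The displacement between a frame
and the last *selected* frame (cumulative measurement — matching against
the immediately preceding frame would accumulate drift) is estimated
visually:

1. scale-invariant keypoints with 128-dimensional descriptors on both
   colour images (scikit-image's SIFT, `upsampling=1`; descriptors
   unit-normalised so the match threshold is scale-meaningful);
2. one-to-one nearest-descriptor matches kept below Euclidean distance
   0.3;
3. matches restricted to depths within ±10% of the calibration depth, so
   one pixel-to-metre conversion coefficient `I` (from a photographed
   scale plate: `I = physical length / pixel span`, equal to `Z/f` for a
   pinhole) applies to all of them;
4. displacement = component-wise median of pixel offsets times `I`
   (median rather than mean for robustness to residual mismatches).

A frame is selected when the along-track distance reaches the configured
range, default [0.05, 0.07] m — chosen for ≥60% image overlap at 1.1 m
height; field rigs will need to set it for their own geometry. A frame that jumps straight past the upper bound is still
selected but flagged as an overshoot. Note that with a fixed metric
range the *number* of selected frames per metre of row is speed-invariant
by construction; what halves when the platform speed doubles is the
number of raw frames consumed per selection (stride 8 at 0.2 m/s versus
4 at 0.4 m/s at 30 fps).

## Registration

Each selected frame enters with the coarse pure-translation matrix

    S = [[1,0,0,-dx],[0,1,0,-dy],[0,0,1,0],[0,0,0,1]]

built from its estimated displacement, and is refined by colored ICP
(Park, Zhou & Koltun 2017) against the accumulated row cloud, cropped to
the incoming frame's neighbourhood (±0.05 m) so each pairwise
registration stays O(frame size). The joint objective

    E(T) = (1-δ)·E_color(T) + δ·E_geometric(T),   δ = 0.968

combines point-to-plane residuals over correspondences within
`max_corr_dist` (default 0.01 m) with photometric residuals between
source intensity and the target's intensity linearised on the local
tangent plane. The photometric term is essential here: the soil is nearly
planar, so point-to-plane alone leaves in-plane sliding unconstrained —
that, plus repetitive canopy texture, is exactly why a good coarse
initialisation is required at all. δ = 0.968 is the published default of
the cited algorithm.

Numerical choices, each of which proved load-bearing on synthetic
fixtures:

* **Pyramid**: coarse-to-fine voxel levels at 4×, 2×, 1×, 0.5× of
  `max_corr_dist`, correspondence radius equal to the voxel. The finest
  (5 mm) level is what brings translation recovery from ~2 mm down to
  ~0.5 mm: it is the first level that cleanly resolves the 2 cm soil
  texture.
* **Photometric gating**: the colour term is active only at levels whose
  voxel is ≤ `max_corr_dist`. Coarser levels sample the texture beyond
  its Nyquist limit; their aliased gradients can walk a near-perfect
  initialisation to a false texture period.
* **Damped Gauss-Newton**: the 6×6 normal equations are solved through an
  eigendecomposition with Tikhonov damping at 1e-4 of the largest
  eigenvalue, and translation steps are clamped to the correspondence
  radius. Both guards exist because weakly constrained directions
  (in-plane slide on planar ground) otherwise random-walk on residual
  noise.
* **Normals** by PCA over 30 nearest neighbours, oriented toward the
  camera; intensity gradients by constrained least squares over 15
  neighbours projected to the tangent plane.
* Convergence when the parameter-update norm falls below 1e-6.

The merged row cloud is the concatenation of all transformed frame
clouds; no point is dropped at this stage.

## Cleaning

Fixed chain: statistical
outlier removal (k = 20 neighbours, cutoff mean + 2.0 std of the mean-kNN
distances; both values are the conventional defaults), then a radius filter (default ≥12 neighbours within 0.002 m,
implemented as "the 12th nearest neighbour lies within r", which is
equivalent and much cheaper than ball counting), then voxel averaging on
a 0.001 m grid anchored at the coordinate origin (so crops of the same
cloud bucket identically). The radius and voxel defaults assume the
full-resolution sensor footprint (~0.9 mm at 1.1 m); at reduced test
resolutions the radius filter must be scaled with the footprint or it
deletes everything.

## Segmentation

RANSAC (1000 draws of 3 points, inliers within 0.005 m, least-squares
refit, seeded RNG) fits the dominant plane; the cloud is rotated so the
plane normal becomes +z and shifted so the plane is z = 0, then flipped
if needed so the canopy sits above the plane.

Vegetation and soil separate on the excess-green index 2G − B − R with an
Otsu threshold (256 bins over [min, max]; ties — which genuinely occur,
because every split inside an empty histogram gap has equal between-class
variance — break toward the lower edge). Colour runs *before* clustering
so soil cannot bridge adjacent plants.

Individual plants come from density clustering (DBSCAN, ≥40 points within
0.04 m) on a 0.005 m voxel-downsampled copy of the vegetation cloud.
Over-segmented clusters merge by the row-axis interval rule: while any
cluster's row-axis midpoint lies inside another cluster's row-axis
interval, it is absorbed (bounds and members unioned) into the containing
cluster with the largest extent; processing order (ascending interval
minimum) makes the fixpoint deterministic, and each absorption removes
one cluster so at most n−1 occur. The cluster "centre" is the
row-axis midpoint (Ymin+Ymax)/2 — the only definition under which
"centre lies between the maximum and minimum of the other cluster" is
meaningful. The merge axis is configurable
because the row direction depends on platform geometry; in camera/row
coordinates produced by the synthetic rig the row runs along x.

Each merged cluster's bounds, expanded by 0.002 m on all six faces, crop
one plant out of the *original* full-resolution vegetation cloud (closed
lower / open upper bounds so abutting boxes partition space). Cropping
the original rather than the cleaned cloud matters quantitatively: the
1 mm voxel filter caps density at ~1 point/mm², which would dominate the
projected-area error budget.

## Traits

* **Height**: maximum signed distance from plant points to the soil
  plane, which is re-fitted by RANSAC on the soil-coloured partition
  (not assumed to be z = 0) so residual levelling error does not bias
  heights.
* **Leaf area** ("faceting"): project the leaf cloud to its PCA best-fit
  plane, Delaunay-triangulate in 2-D, drop triangles whose longest 3-D
  edge exceeds 0.01 m (they bridge outline concavities), sum the 3-D
  triangle areas. Summing in 3-D (not in projection) is intentional: a
  curved leaf's area exceeds its footprint. Leaf clouds are inputs
  (clipped manually in practice; sampled from leaf meshes in the
  synthetic studies).
* **Projected canopy area**: drop z, bucket (x, y) into an
  origin-anchored grid (0.001 m cells at full sensor resolution), area =
  occupied cells × cell².

## Synthetic test bed

`synthetic` builds triangle-mesh scenes with construction-time ground
truth: a soil plane at z = 0 textured as 2 cm speckled cells, and plants
made of a thin vertical stem prism plus parametric curved leaves
(bilinear-patch meshes whose analytic areas come from fine subdivision;
coarse render mesh and fine reference agree to ~0.1%). Speckle is
luminance-dominant (channel-correlated) with a small chroma term —
albedo texture varies in brightness far more than in hue, and this is
what keeps the excess-green index bimodal between soil and vegetation; a
fully chromatic speckle would defeat the colour model that the real
method relies on. Rendering is a deterministic software rasteriser:
pinhole projection, z-buffer, flat per-face colours, Gaussian depth noise
(default σ = 1 mm), per-pixel colour jitter (default 2/255, sensor noise,
deliberately distinct from the viewpoint-stable face speckle). Identical
spec + seed reproduce scenes and frames bit for bit.

What the generator does **not** emulate: wind motion, specular leaves,
depth-sensor systematic biases (edge bleeding, multipath), rolling
shutter, lens distortion (the real sensor's SDK rectifies), occlusion by
neighbouring rows, and the long-tailed outlier structure of real stereo
depth. Passing the synthetic studies therefore demonstrates the
correctness and internal consistency of the algorithms at field-realistic
geometry and noise scales — not field accuracy, which only manual
measurements of real plants can establish.

## Study conditions and problem sizes

The packaged studies (`canopyrecon.evaluation`, rerun by
`scripts/acceptance.py`) use these sizes, chosen as the package's own
desk-scale working points:

* **Pose recovery**: 20 rendered frame pairs at 424×240, camera offsets
  up to 0.07 m, depth noise σ = 1 mm. Typical recovery ≤0.5 mm and
  ≤0.05°.
* **Frame selection**: sweeps at 0.2/0.4/0.6 m/s, 30 fps, 424×240, over
  a 0.34 m track.
* **End-to-end trait recovery**: five plants spaced 0.18 m (stems
  0.10–0.20 m, 3–5 leaves of 0.03–0.05 m), rendered at 848×480 — a
  native sensor mode whose ground footprint (~1.1 mm) matches the
  full-resolution regime, so the full-resolution radius-filter
  scale (0.0025 m/12) applies and the projected-area grid statistics carry
  over. The projected-area cell is 0.002 m, scaled from the
  full-resolution 0.001 m cell to preserve points-per-cell (which sets
  the boundary-cell occupancy bias of the occupied-cell estimator — at
  too-low density the estimator systematically undercounts any
  fixed-cell ground truth, a property worth remembering when comparing
  projected areas across sensors).
* **Leaf faceting**: ten isolated parametric leaves sampled at
  4×10⁵ points/m², compared to analytic areas.

## Known limitations

* Pure-translation coarse model: platform rotation between frames is not
  estimated (the fine stage can absorb ~2°, no more).
* Single linear sweep; no loop closure or pose-graph optimisation.
* The cluster-merge rule is one-dimensional along the row; plants
  overlapping *across* the row would need the configurable axis or a 2-D
  rule.
* Otsu on excess green assumes soil/vegetation bimodality; heavily
  green-mossed soil or chlorotic plants would break the split.
* Heights are biased high by a few millimetres under depth noise (a max
  statistic over noisy points); at σ = 1 mm the bias is ~3 mm.
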