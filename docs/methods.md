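# Methods

This note documents the model, the numerical choices, and the limits of what
the synthetic verification shows. Angles are in degrees throughout; the sign
convention is fixed package-wide: **positive = shallower toward the right of
the screen** (row index decreases as column index grows). Under the default
geometry the fascicle inclines positively and the aponeurosis is near
horizontal (slightly negative), so `PA = |θ_fas − θ_apo|` equals the sum of
the two structures' inclinations away from each other.

## Image model and preprocessing

Frames are 8-bit grayscale grids (rows = depth, columns = lateral). Color
input is collapsed by BT.601 luminance; deeper bit depths are max-normalized
so the brightest pixel maps to 255. One `RoiSpec` (per trial, not per frame)
splits each frame into the fascicle ("top") and aponeurosis ("bottom")
sub-images; crops carry their (row, col) offset so detections map back to
full-frame coordinates.

Denoising keeps pixels with intensity **≥** the threshold (equality
survives; pixels strictly below it are removed). The default threshold of
100 sits roughly 4σ above the default synthetic background (mean 20,
speckle σ ≤ 20) while structures render near 200–220, so structure pixels
survive at full speckle and background crossings are isolated stragglers
that DBSCAN discards as noise.

Augmentation multiplies intensities inside a user-placed ellipse
(center/semi-axes/rotation parameterization; focus/vertex forms are
interconvertible) by a gain ≥ 1, clipped at 255. It is an optional rescue
for dim/shadowed fascicles: a filter that brightens the true fascicle above
the denoise threshold restores detection, and filters that do not help are
voted down by the fusion weights (below).

## Clustering

Clustering runs on (col, row) coordinates only — intensity has already been
consumed by the threshold and re-enters through the value function. DBSCAN
(default, `eps = 2.0`, `min_pts = 5`) is implemented directly: a pixel is a
core point when ≥ `min_pts` pixels (itself included) lie within `eps`;
clusters are density-connected sets; the rest is noise. Determinism is
pinned by processing pixels in row-major scan order, and a border point
reachable from several clusters is claimed by the first-discovered cluster
under that order. An O(N²) literal implementation of the same definition
(`brute_force_components`) is part of the package and serves as the test
oracle; the KD-tree implementation must reproduce its partitions exactly.

K-means (scikit-learn, seeded, `n_init = 4`) and single-linkage HAC
(connected components of the strict `< threshold` pair graph) are provided
for method comparison. When no `k` is given, K-means uses the DBSCAN cluster
count found on the same input. With `eps = 2.0` and 4–6 px thick tubular
structures, DBSCAN bridges small anti-aliasing gaps but keeps structures
separated by ≥ 3 px apart; `min_pts = 5` suppresses isolated speckle
crossings. These defaults were chosen on synthetic scenes and are exposed in
the config.

## Orientation of a cluster

The four corner pixels are the members extremizing col±row (LU/RD minimize/
maximize col+row; RU/LD extremize col−row), with ties broken toward smaller
col then smaller row. The cluster's orientation, however, is *not* taken
from lines through those integer corner pixels: on rasterized rectangles the
±0.5–1 px corner quantization propagates to up to ~3° of angle error at
40 px length, which would swamp sub-degree PA tracking. Instead the cluster
is fit with an oriented box: the intensity-weighted principal axis of the
member pixels gives the direction θ, the extreme projections give
half-length h and half-thickness t, and the two box diagonals make angles
α₁ = θ − atan(t/h), α₂ = θ + atan(t/h) with the horizontal, so
ᾱ = (α₁+α₂)/2 = θ exactly. Intensity weighting lets the anti-aliased edge
pixels contribute fractionally; on rendered strips the orientation is
recovered to ≲ 0.02°, and to ≤ 0.5° in the worst rasterization case tested.
The integer corners remain available for drawing and diagnostics.

Degenerate clusters (single pixel, zero extent) report angle 0 with a
`degenerate` flag.

## Merging and plausibility

Fragmented fascicles (shadow gaps, local dropouts) appear as several
collinear clusters. A pair merges when (i) one cluster lies strictly right
of the other with lateral gap ≤ `max_gap_px` (default 40 — the merge rule
alone would join arbitrarily distant collinear clusters), (ii) their angles
agree within `angle_tol_deg` (default 5), and (iii) the connection line
agrees with their mean angle within `connect_tol_deg` (default 5). The
connection line joins the *fitted-axis endpoints* (centroid ± h·u) rather
than integer corner pixels: over an 8 px gap a 1–2 px corner offset would
swing the connection angle by ~15° and veto valid merges; the axis endpoints
sit on the centerline and keep it within tolerance. Merging repeats until no
pair qualifies (a fixpoint; pixel-conserving and idempotent). Clusters
smaller than `min_cluster_px` (default 15) are dropped before orientation —
corner geometry on single-digit clusters is meaningless.

Plausibility encodes muscle geometry: in the top ROI the fascicle endpoints
must slope in the configured direction (`fascicle_rises_right`, default
True; the opposite setting expresses the same anatomical rule under a
mirrored probe orientation), and in the bottom ROI the aponeurosis must be
near-horizontal (|angle| ≤ 15° by default).

## Value function and selection

`V = w·L/L₀ + (1−w)·B/B₀` with `L` the Euclidean endpoint distance, `B` the
summed member intensity, `w = 0.6`, and norms `L₀ = ROI width`,
`B₀ = 255 × ROI width`. The published description of the method lists the
ingredients of its cluster value (pixel count/brightness, endpoints, a
weight) but not a legible closed form; this convex combination is the
package's reconstruction — the simplest form monotone in both ingredients —
and is the module's main assumption. Ties break toward the larger pixel
count, then the smaller cluster id. The selected cluster's fitted-axis
orientation is reported as the structure's angle (the endpoint line that an
investigator would draw is available from the corners and is what
`pennatrack plot` overlays).

## Temporal viscosity

The weight is a skew-normal bump normalized to its mode:
`λ(d) = A · SN(d; ξ, ω, α) / SN(mode; ξ, ω, α)`, `A ∈ (0, 1]`. The mode is
located numerically (bounded scalar minimization of −pdf within ξ ± ω;
closed forms exist only for α = 0). Defaults when uncalibrated: ξ = 0,
ω = 2°, α = 0, A = 1 — at 20 Hz and slow isometric contraction the
frame-to-frame PA increment is a fraction of a degree, so ω = 2° passes
normal increments at near-full weight while a 20°+ outlier lands ~10σ out.

Within a frame, per-filter angles fuse as `θ* = Σ λₙθₙ / (Σ λₙ + ε)` with
λₙ evaluated against the previous final PA; ε = 10⁻⁶ only guards the
division, at the cost of a relative bias ≤ ε/Σλₙ. When every λₙ falls below
`λ_floor = 10⁻³` the frame is declared unusable and the previous final PA
is held (status `fallback`); the same holds when nothing is detected at all.
Across frames, `θ_final = λθ* + (1−λ)θ_pred` with `θ_pred` either the
previous final angle (default — safest at 20 Hz) or a linear extrapolation
from the last two (switchable; the stream runs fusion first, then the
across-frame blend). The first frame passes through unsmoothed; smoothing
applies to the PA directly (configurable in principle to per-structure
angles, but PA is what downstream consumers use).

Calibration fits (ξ, ω, α) to observed increment samples by the method of
moments and then multiplies ω by `span_factor` (default 2) so the viscosity
span strictly exceeds the empirical spread — the weight must suppress only
outliers. Two numerical guards: sample skewness below twice its standard
error √(6/n) is treated as zero (the skewness→shape inversion amplifies
small-sample noise into spurious shape and inflated scale), and degenerate
(constant) samples return a 0.5° scale floor with a warning. Moment
calibration replaces kernel-density matching; with ≥ a few hundred samples
the two agree in span and the moments are parameter-free.

## Synthetic scenes

The generator renders what the pipeline consumes: an anti-aliased
(coverage-weighted, then 8-bit quantized) fascicle strip at a known angle in
the top ROI — optionally split into collinear fragments with gaps — a
near-horizontal aponeurosis band in the bottom ROI, additive Gaussian
speckle clipped to [0, 255], optional bright distractor blobs placed off the
fascicle line, an optional column-band shadow (multiplicative attenuation),
and a corrupted mode: fascicle at 10% intensity plus a bright decoy streak
offset +25°, so a corrupted frame yields a *wrong* detection rather than a
missing one — the failure mode temporal smoothing exists to absorb.
Sequences realize a PA trajectory by varying the fascicle angle against a
fixed aponeurosis; all randomness flows from one integer seed and frames are
bit-reproducible. Ground truth comes from the scene parameters alone.

Simplifications, hence limits of what passing tests show: speckle is
additive Gaussian, not multiplicative log-compressed speckle — only the
contrast statistics seen by the threshold are emulated; fascicles are
straight (no curvature), exactly one fascicle is rendered per frame, and
tissue texture, probe pressure artifacts and out-of-plane motion are absent.
Recovery numbers on these scenes bound discretization and noise-threshold
errors of the algorithm, not performance on clinical images.

## Verification problem sizes

The acceptance script uses: 54 random pixel sets of ≤ 500 pixels across six
(eps, min_pts) settings for the clustering oracle; 156 rotated rectangles
(13 angles × 3 lengths × 4 thicknesses); 36 fragmented-fascicle cases
(2 gap widths × 6 angles × 3 fragment counts); 15 clean and 100 noisy
single frames end to end; one 20-frame corrupted sequence; 500 calibration
samples; and two repeated 10-frame runs for determinism. These sizes keep
the full recomputation within seconds while covering every stage.

## Known limitations

- Fascicle length, thickness and curvature are out of scope; only
  orientations and the PA are estimated.
- One fascicle and one aponeurosis are tracked per frame (the
  highest-value cluster in each ROI).
- The value-function form is a reconstruction (see above); `w` and the
  norms may need retuning on real data.
- Parameter sensitivity: extreme denoise thresholds remove structure or
  keep noise; the defaults assume the synthetic contrast regime and should
  be set per acquisition setup.
- Processing is CPU-bound Python/NumPy, suitable for offline analysis of
  20 Hz streams rather than hard real-time control loops.
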