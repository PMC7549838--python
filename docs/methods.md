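# Methods

## Model

A flower is a deterministic function of 16 parameters. The ovary is a
cylinder (radius r_b, the length unit; height h_b) with its base at Z = 0.
Each of the n organs is a rigid planar ellipse whose semi-axes follow the
two-piece linear rules given in the README; negative values are clamped to
zero, and a clamped organ is kept in the sequence (its position and angles
are still defined) but skipped when meshing or rasterizing — lengths are
physical and an organ of zero size has simply vanished.

Identity is an index rule: organ i is a tepal iff i < N_t with
N_t = round(n·max(t_x, t_y)). The two size rules may switch at different
organs (t_x ≠ t_y produces the thin- or round-tepal morphs); identity and
the elevation ramp follow the *later* switch, so the organ that ends the
ramp is the last one still tepal-like on either axis.

The elevation ramp's printed increment divides by "t_max − 4"; taken as a
fraction this is dimensionally inconsistent, so the denominator is
interpreted in organ counts, (N_t − 4). This gives the stated endpoints:
organs 0–3 at o_min, organ N_t − 1 exactly at o_max (asserted to 1e-9 in
the tests). Flowers with N_t ≤ 4 keep all tepals at o_min.

The height rule h_{i+1} = h_i + e^{p·φ_i} leaves the unit of φ open; the
default evaluates the exponent with φ in degrees, which with the default
pitch p = −0.01 produces smoothly tightening intervals over a 100-organ
spiral (the radian convention is available via `angle_unit="radians"`).
The exponent is capped at ±700 so extreme positive pitches saturate instead
of overflowing. The default p is negative although the sweep range for p is
positive; both signs are accepted everywhere.

## Geometry and placement

The renders that motivated the model show organs attached to the ovary wall
but give no placement equations, so placement is a package design choice:
the organ plane is spanned by the tangential direction t̂ = (−sinφ, cosφ, 0)
and the tilted direction d̂ = cos(o)·r̂ + sin(o)·ẑ, and the ellipse touches
the ovary at the basal end of its longitudinal axis (center = attachment +
y·d̂). A `anchor="center"` option places the ellipse center on the wall
instead. Organs are rigid and flat: no bending, curling or surface texture,
which is why strongly recurved or wavy cultivars are outside the model's
reach. Meshes triangulate each ellipse as a 64-vertex fan plus a closed
cylinder for the ovary; inner organs are not clipped against the ovary top.

## Silhouettes and indices

Projection is orthographic; the silhouette is the union of all projected
organ ellipses plus the ovary footprint (disc in top view, rectangle in
side view), with no hidden-surface removal. Rasterization uses scanline
polygon fill at a default 256 px per ovary radius (128 px in grid sweeps);
each polygon is also outlined so edge-on organs (o = 90° in top view, which
project to segments) still register. When the union is disconnected the
largest connected component is scored.

The outer contour is extracted by marching squares at the 0.5 level and
simplified by Douglas–Peucker at 1 px tolerance before measuring its
length: raw pixel-chain contours overestimate perimeters of smooth or
obliquely oriented edges by ~5%, and the simplification restores analytic
values (circle, rotated square and 5-pointed star agree with closed-form
solidity and convexity to well under 2% at these resolutions — the
tolerance the test suite asserts). Areas use the component's pixel count
(A_t) and the convex hull of the contour (A_c, L_c via `scipy.spatial.ConvexHull`).

## Morphospace sweeps

Grids are inclusive of both endpoints. The four presets are: openness
(o_max × o_min, 0–90° in 15° steps), thresholds (t_x × t_y, 0–1 in 0.2
steps), shortening rates (s_x1 0–1.00 step 0.04 × s_y1 0–3.50 step 0.14,
26 × 26) and initial lengths (x_0, y_0 each 0.50–9.00 step 0.50). The
openness and threshold grid spacings are package choices (no printed
resolution exists for them); the other two use the printed resolutions.
Outside the swept axes every cell keeps t_x = t_y = 0.20 and
o_max = o_min = 45°. Cells are independent and evaluation is deterministic;
re-running a sweep reproduces bit-identical matrices. The full 26 × 26
shortening sweep at 128 px/radius (both views) is the largest routine
computation, about two minutes on one core.

On that grid the package reproduces the qualitative gradients of the
original silhouette analysis: top-view solidity falls steeply with s_x1 and
weakly in aggregate with s_y1 (the s_y1 trend is non-monotone locally — it
rises slightly at small s_y1 before falling — so only the aggregate rank
correlation is asserted); side-view solidity is governed by s_y1 and almost
independent of s_x1; and the minimum convexity in both views sits at the
(s_x1 = 1, s_y1 = 0) corner.

## Measurement and estimation

Organ sheets are binarized with Otsu's global threshold (fixed-threshold
override available), components under 100 px² discarded, and each component
reduced to its moment-equivalent ellipse (scikit-image regionprops); the
major axis is the longitudinal full length, the minor the transverse.
Components are ordered row-major by centroid — bands are split where
consecutive centroids differ by more than half the median component height
— and border-touching components are flagged rather than dropped. The
mm-per-pixel scale is an explicit input; no in-image calibration target is
assumed. The ovary radius is likewise supplied externally per flower.

Estimation regresses standardized organ length on l_i = i/n over the tepal
range (the first `tepal_count` organs when given, else the whole table).
The printed estimation formulas halve the intercepts (x_0 = b/2) but not
the slopes (s = a), which cannot both hold for a single full-length
regression; the default (`convention="semi"`) therefore regresses
semi-axis values, so x_0 is the intercept and s_x1 the slope magnitude, and
the estimator is exactly inverse to the generative model — noiseless
round trips recover parameters to 1e-6 relative error, the property the
suite asserts. `convention="full"` reproduces the literal printed formulas
(its shortening rates are exactly twice the semi-axis ones). Shortening
rates are reported as positive magnitudes. Exact round trips are defined
only in the linear regime — if a shortening rate is steep enough to clamp
an organ in the fitted range to zero size, the measured sequence leaves the
line and the estimator returns a best linear fit, not the generating
parameters.

With 20 tepals spanning only l ∈ [0, 0.19], the slope has little leverage:
at 5% measurement noise, single-flower s_y1 estimates scatter with a
standard deviation of roughly 0.5. The estimator is unbiased (the
Monte-Carlo suite checks bias < 2 SE over 200 replicates) but individual
recovered rates are imprecise, which is worth remembering when reading
per-flower estimates from real scans too.

## Synthetic fixtures

The generators exist so the whole measure → estimate → summarize chain runs
and validates with zero external inputs; no raw specimen data is shipped.
Measurement noise is multiplicative Gaussian on full lengths (error scaling
with organ size, plausible for scanned outlines); the default sigma_rel =
0.05 represents a 5% measurement error. Cohorts draw (x_0, y_0, s_x1,
s_y1) per shape class from independent Gaussians truncated at zero, seeded
with the class-wise means and standard deviations of the published
100-specimen summary (stellate, cup-like, other, unknown, with 20/34/8/38
flowers); all other parameters stay at the defaults, so each flower has 100
organs and 20 tepals. The synthetic default ovary radius is 10 mm. All
randomness flows from a single integer seed.

What the fixtures do *not* emulate: inter-parameter correlations (real
parameters correlate below 0.8 but not at zero; injection is off by
default), organ overlap or tearing on sheets, shadows and uneven
illumination, and any real noise structure of flat-bed scans — so passing
recovery tests demonstrate correctness of the pipeline under the stated
noise model, not measurement accuracy on real scans.

## Numerical choices and limitations

- Angles are stored in degrees throughout; radians appear only inside
  trigonometric evaluation.
- Grid coordinates are generated as lo + step·k with a rounded count, so
  inclusive endpoints survive floating-point stepping.
- `round(n·t)` uses floor(x + 0.5) to avoid banker's rounding surprises at
  exact halves.
- Diurnal opening/closing is outside the model: elevation angles are fixed
  per flower.
- Summary statistics use sample (ddof = 1) standard deviations; a
  single-flower class reports std = 0 and degenerate correlations are NaN.
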