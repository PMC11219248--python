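# Methods

## Measurement model

All quantities are defined in a per-femur anatomical frame constructed from
the bone surface alone:

* **Anatomical axis** — the line through the midpoints of the femoral width
  at two shaft levels, by default 100 mm and 150 mm proximal to the distal
  joint line.  "Width midpoint" is interpreted as the mean of the most
  medial and most lateral surface points of a slice of thickness ±2 mm cut
  perpendicular to the current working axis; this matches the radiographic
  construction the measurement emulates, which the source material does not
  define more precisely.
* **Mechanical axis** — the anatomical axis rotated by a fixed valgus angle
  (default 6°, the conventional template value) about the anteroposterior
  direction, the proximal end tilting medially (toward the femoral head).
  The rotation axis is orthogonalised against the anatomical direction so
  the angle between the two axes equals the valgus angle exactly.
* **Axial plane** — perpendicular to the mechanical axis.
* **Clinical transepicondylar axis (c-TEA)** — the line through the medial
  and lateral epicondylar *prominences* (the apex, not the sulcus, which is
  harder to identify on CT and intra-operatively).
* **Coronal plane** — through the ME, spanned by the c-TEA direction and
  the mechanical-axis direction.  The phrase "contains the horizontal plane
  of the mechanical axis" admits more than one reading; the
  spanning-directions interpretation is adopted.

Five distances are measured per knee: `me_fj`/`le_fj`, the perpendiculars
dropped in the axial plane from the prominences onto the posterior condylar
line (the tangent through the posterior-most point of each condyle — the
joint line in flexion); `me_ej`/`le_ej`, the perpendiculars dropped in the
coronal plane onto the distal articular line (tangent through the
distal-most condylar points — the joint line in extension); and `ml`, the
3-D chord between the prominences (the axial plane only *locates* the
prominences; the width itself is not an in-plane projection).  Distances
are unsigned: on anatomically valid femora the prominences always lie
proximal/anterior to the joint-line tangents, so a sign carries no
information.  Each of the four epicondyle distances divided by `ml` gives a
dimensionless ratio; the prediction for a new femur is `offset = ml ×
ratio`, rounded half-up to integer millimetres (so 67 × 0.33 = 22.11 → 22).

## Frame construction

The definitions are circular: the anatomical axis is referenced to the
distal joint line, which needs the mechanical axis, which needs the
anatomical axis.  `build_frame` resolves this by fixed-point iteration:
bootstrap directions from the vertex cloud (principal axis, oriented
proximally by comparing near-maximal radial extents of the two ends; the
in-plane principal direction of the distal fifth seeds the
transepicondylar direction; the posterior bulge of the condylar mass
relative to the shaft axis orients anteroposterior, and the side label
fixes the medial sign), then repeat: condylar extremes → distal joint-line
level → anatomical axis → mechanical axis → epicondyles → planes, until no
landmark moves by more than 0.1 mm (default; at most 25 passes).

Numerical choices that matter:

* **Landmark detection** is an argmax over surface vertices along a frame
  direction (exhaustively checkable).  Inside `build_frame` each argmax
  seed is refined by local quadratic regression: a paraboloid is fitted to
  the surface patch within 4 mm of the seed and its apex taken, re-centred
  and repeated up to three times.  This removes the outward extreme-value
  bias a raw argmax over jittered vertices carries (several tenths of a
  millimetre at 0.2 mm vertex noise) and makes the result independent of
  which of several near-tied vertices seeded it.  Slice-width extremes are
  refined with the 1-D analogue along the slice ring, restricted to the
  near-apex patch (the far cortex has similar in-slice offsets).  The
  public `detect_*` functions keep pure argmax semantics; refinement is a
  `FrameConfig` flag, on by default.
* **Damping** — the transepicondylar and working proximal directions are
  under-relaxed (averaged with their previous value) between passes, which
  suppresses two-cycles caused by discrete seed flips; the *reported* frame
  always uses the exact, undamped constructions.  A period-2 cycle whose
  two states agree within the convergence tolerance is accepted as
  converged.
* **Search regions** — epicondyles are sought within a ±20 mm axial band
  centred on the condylar mass; condylar extremes within 35 mm of the
  distal-most vertex (so a slightly tilted working direction cannot promote
  a shaft vertex); ties in an argmax resolve to the vertex nearest the band
  midline.
* **Tolerances** — 1e-9 absolute for normalised quantities, 1e-6 mm for
  lengths; angles are degrees at every public interface.

## Synthetic femora

The generator provides ground truth at two fidelities.

**Landmark level.**  In a canonical frame (mechanical axis = +z,
transepicondylar direction = x with medial = +x on the right, posterior =
−y) the prominences sit at (±ML/2, 0, 0) and the condylar support points on
tangent lines tilted by `sin θ = (d_med − d_lat)/ML` at offset
`−(d_med + d_lat)/2`, which makes the perpendicular distances from the
prominences equal the generating spec *exactly*; measuring the landmarks in
the canonical frame round-trips all five distances to machine precision.
This exactness is what lets the statistical layer be validated separately
from geometry processing.

**Mesh level.**  The surface is a union of overlapping shells (no detection
requires watertightness): a shaft tube of radius 16 mm and length 200 mm
along the anatomical axis, with vertex rings every edge-length so the
shaft slices are populated (the default length comfortably contains the
100/150 mm levels); two condylar ellipsoids whose centres and semi-axes are
solved so their posterior-most and distal-most surface points are the exact
landmarks; and two epicondylar spheres (radius 6 mm) whose apices are the
prominences.  The condyle centres sit at ±25 % of ML with fixed
anteroposterior/axial centre offsets (−8 mm, −10 mm), values chosen once to
give a plausible distal femur.  The vertex nearest each exact landmark is
snapped onto it, so on the noise-free mesh the argmax detections are exact
by construction.  Optional Gaussian vertex jitter (`surface_noise_sd`)
emulates segmentation noise; ground truth records the pre-noise landmarks.

**Cohorts** are drawn from a single-factor model: `ML ~ N(μ, σ)` and each
distance `D = μ_D + ρ σ_D/σ_ML (ML − μ_ML) + ε` with
`ε ~ N(0, σ_D √(1−ρ²))`, so every marginal mean, marginal SD and
distance-vs-width correlation matches the configuration; only the
distance-width correlations are specified, so the distance–distance
correlations follow from the shared factor (the natural minimal model when
only width correlations are known).  Defaults are the reference cohort of
127 osteoarthritic knees: ML 75.1 ± 4.2, ME-FJ 29.4 ± 2.2, LE-FJ 21.2 ±
2.3, ME-EJ 25.1 ± 2.8, LE-EJ 21.3 ± 2.5 mm; correlations with ML 0.623,
0.396, 0.393, 0.445.  Draws violating positivity or `ML > ME-FJ` are
resampled (a continuous-normal tail can otherwise produce unconstructable
anatomy).  A root seed drives cohort sampling, per-knee jitter and pose,
so runs are bit-reproducible.

What the generator does *not* emulate: real condylar surface shape
(ellipsoids stand in for cartilage-free subchondral bone), the trochlea,
osteophytes, segmentation artefacts correlated along the surface, or
anatomically varying valgus angle.  Passing tests therefore demonstrate
correctness of the *measurement chain* under controlled geometry and noise,
not clinical accuracy on patient CT.

## Statistics

* `summarize` — sample mean, SD (n−1) and the Student-t 95 % CI of the
  mean.  Display rounding is half-away-from-zero to one decimal.
* `pearson` — product-moment r with the two-sided p-value from
  `t = r√((n−2)/(1−r²))` on n−2 df.
* `icc_absolute_agreement` — ICC(2,1), two-way random effects, absolute
  agreement, single rater, from the ANOVA mean squares
  `(MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n)`.  The form is not stated
  by the source material; ICC(2,1) is the standard choice for
  intra-/inter-observer landmark reliability.  Since the raters/repeats
  protocol is also unstated, the reliability reproduction is a regime
  check (two simulated observers with 0.3 mm independent landmark noise),
  not an exact one.
* `correlation_power` — power of the zero-correlation test.  The default
  `exact` method integrates Hotelling's exact sampling density of r under a
  bivariate-normal population beyond the critical r of the t-test
  (evaluated in log space with a Gaussian-hypergeometric factor, quadrature
  via `scipy.integrate.quad`).  `fisher_z` is the `atanh` normal
  approximation; `nct` is the point-biserial-style noncentral-t
  approximation used by some power software (noncentrality
  `ρ√n/√(1−ρ²)`).  At ρ = 0.3, α = 0.05, n = 127 these give 0.933, 0.931
  and 0.940 respectively; the exact value is confirmed by Monte-Carlo
  rejection rates in the test suite, and the spread between methods is the
  reason all three are exposed.

## Problem sizes used in validation

The test battery uses cohorts of n = 127 (the study size) at landmark
fidelity, 200 replicate cohorts for coverage of the recovery bands, 30
mesh-fidelity femora at 1 mm resolution (noise-free and 0.2 mm jitter)
under random rigid poses, and 50,000 Monte-Carlo draws for the power
oracle.  These sizes keep the full suite under a minute of compute while
leaving the sampling error of each check an order of magnitude below its
tolerance.

## Known limitations

* The parametric surface is convex around every landmark; detection on
  real bone (sulcus/prominence ambiguity, osteophytes) is harder.
* Cartilage is absent, as in CT-based measurement; distances refer to the
  bony surface.
* The fixed 6° valgus is a template convention applied to every femur; the
  per-patient hip-centre construction is out of scope.
* The 2-D/3-D radiograph-to-CT registration of the original workflow is
  not modelled; meshes are assumed already segmented, in millimetres.
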