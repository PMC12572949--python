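# Methods

## Measurement model

A segmented cartilage cross-section is a simple polygon bounded below by
the cartilage–bone interface polyline and above by the synovial–cartilage
polyline, both ordered lateral → medial in mm coordinates with the image
y-axis pointing down (raster convention; the probe is at small y).  Mask
inputs use 0-based pixel indices with pixel centres at
(i + 0.5)·spacing.

Zones are vertical slabs in the image x-axis — not arc-length intervals
along the bone — because the protocol defines the intercondylar zone as a
fraction of the *image width* centred on the notch.  Two conventions are
implemented:

* `absolute_mm` (default): bounds at notch_x ± 4.8 mm.  This is the
  default because the absolute span is the only unambiguous statement of
  the protocol; at the nominal 38.4 mm field of view it coincides with the
  25 % convention.
* `fraction_of_extent`: bounds at notch_x ± fraction·extent/2 with
  fraction = 0.25 of the imaged cartilage width.

If the notch sits closer than the half-span to an edge, the zone is
truncated at the extent and flagged rather than rejected: truncation is a
data-quality signal, not an error.  A span wider than the section is an
error.

Per zone, area is the polygon clipped to the slab (shapely, with vertices
interpolated at the exact bound abscissae) and interface length is the
bone polyline's arc length clipped to the same slab, segments split at
bound crossings.  Thickness = area / interface length.  The interface
length is taken on the bone side — not the synovial side, not a midline —
matching the definition of the metric.  Zone areas must sum to the total
polygon area and zone lengths to the total bone arc length within 1e-9
relative; this conservation identity is asserted on every call, so a
violation is a bug, never a warning.  Thickness is reported to 3 decimals
in outputs (the precision of the normative tables) and kept at full
precision internally.

The notch is always supplied by the caller, mirroring its manual
identification in the protocol; `suggest_notch` (deepest synovial point)
exists as a convenience but is never used silently.

Mask tracing keeps the largest connected component (equal-size ties are an
error), fills interior holes, and emits per-column outer pixel edges, so a
solid w×h-pixel block yields boundaries exactly w·spacing long and
h·spacing apart, and traced boundaries lie within half a pixel of the true
ones.

## Phantoms

Phantoms offset a bone baseline by a thickness profile t(x):

* **Flat baseline** with arbitrary strictly positive profiles (constant,
  piecewise-constant, or any callable).  Profile steps are represented
  exactly by duplicate abscissae carrying the left-limit value, so
  piecewise phantoms are measured to floating precision, not to the
  polyline sampling density.
* **Circular-arc baseline** with constant profiles.  Positive radius means
  the arc is convex toward the probe and the cartilage is offset outward
  (away from the arc centre): the full-band area/length ratio is then the
  annular-sector value t·(1 + t/(2R)), which is the closed form the tests
  assert.  Negative radius (concave) offsets toward the centre and
  requires t < |R|; violations are rejected with the offending x-range.
  Varying profiles over a curved baseline are not supported: their ground
  truth under vertical-slab clipping has no tractable quadrature, and no
  validation scenario needs them.

Ground-truth zone thickness is computed from the *continuous* geometry by
quadrature — profile integrals for flat baselines, a polar-coordinate
area integral with slab-dependent radial limits for arcs — independently
of the polygon measurement path, so phantom tests compare two genuinely
different computations.

Rasterisation marks a pixel foreground iff its centre lies inside the
band.  Phantoms emulate segmentation *geometry* only: no speckle,
attenuation, or probe physics, so passing tests validate the measurement
pipeline downstream of segmentation, not segmentation of real B-mode
images.

## Synthetic cohorts

Readings follow a two-way additive model: reading r of subject i at site s
is group_mean(s) + b_i + e_ir with b ~ N(0, σ_b²) shared across sites and
e ~ N(0, σ_w²) i.i.d.  Homoscedastic normal errors are assumed because
that is the model under which ICC(3,1) and SEM are defined; real
within-subject error may scale with thickness or drift across repeat
probe placements, which this generator does not emulate.  The planned ICC
is σ_b²/(σ_b² + σ_w²).

Defaults: group means and sizes from the normative tables (232 subjects,
56/70/47/59 per age band, 132 female / 100 male); k = 3 readings;
σ_b = 0.30 mm, typical of the published per-group SDs (0.24–0.46 mm);
σ_w is calibrated from a target SEM% via σ_w = SEM%/100 × grand mean,
because the study reports SEM% (1.3–2.3 %) rather than a raw reading SD —
the mid-band default SEM% of 1.8 gives σ_w ≈ 0.057 mm.

The exact-moments mode recentres and rescales each group's draw so the
sample mean and SD (ddof = 1) equal the request exactly; summary-statistics
and raw-data engines then agree to floating precision, which is what makes
the twin-engine equivalence testable bit-for-bit.

## Reliability statistics

From the complete n×k matrix (incomplete subjects are dropped and
counted; the study states no missing-data rule):

* Two-way decomposition: BMS (df n−1), reading-occasion RMS (df k−1),
  residual EMS and SSE (df (n−1)(k−1)).  An SSE below 1e-12 of the total
  sum of squares is snapped to zero — it is subtraction round-off, and
  letting it through would report a spurious ICC marginally below 1.
* ICC(3,1) = (BMS − EMS)/(BMS + (k−1)·EMS): single-measure *consistency*
  ICC — the occasion mean square is excluded from the denominator,
  matching a fixed-rater, consistency-of-agreement design.  CIs come from
  the F = BMS/EMS pivot; the one-sided 95 % lower bound is compared with
  the 0.70 acceptability threshold.  EMS = 0 yields ICC 1 with CI [1, 1]
  and a degeneracy flag rather than NaN.
* SEM = √EMS; SEM% = 100·SEM/grand mean, CI from the chi-square interval
  on SSE.  Acceptable below 10 %.
* CV% (log method): the same decomposition on log readings gives the
  within-subject log-variance s²; CV% = 100·√(exp(s²) − 1), the standard
  log-normal within-subject CV, which reduces to 100·s for small s.  The
  variant 100·(exp(s) − 1) is available by flag since log-method variants
  differ across the literature.  CI maps the chi-square interval of s²
  through the same transform.

## Group comparisons

* t test: pooled-variance Student by default (consistent with the
  published p values; Welch by flag); works from (n, mean, SD) alone.
* One-way ANOVA from summaries: SSB = Σ nᵢ(x̄ᵢ−grand)², SSW = Σ (nᵢ−1)sᵢ²;
  identical to raw-data ANOVA given the sufficient statistics.
* Tukey–Kramer: q = |x̄ᵢ−x̄ⱼ|/√(MSW/2·(1/nᵢ+1/nⱼ)), p from the
  studentized-range distribution with (k, N−k); handles unequal n.
  Significance is reported at two tiers (0.05, 0.001) with direction
  labels ("4 > 2") whose orientation always matches the sign of the mean
  difference.
* Gate: Brown–Forsythe (median-centred Levene) at α = 0.05 routes
  ANOVA+Tukey vs Kruskal–Wallis+Dunn; the mean-centred variant is a flag.
  When a site fails the gate the report keeps both paths — the parametric
  F remains informative and published reports have mixed the two.
* Kruskal–Wallis with tie correction; Dunn pairwise z on mean ranks,
  Bonferroni over all pairs (the correction named by the protocol, with
  Dunn as the standard rank post hoc it corrects).
* Mann–Whitney U: exact enumeration when both n ≤ 10 without ties,
  tie-corrected normal approximation otherwise.
* Shapiro–Wilk (3 ≤ n ≤ 5000) routes t vs Mann–Whitney and
  mean ± SD vs median (IQR) reporting.
* Fisher's exact for r×2 tables (Freeman–Halton): full vectorised
  enumeration over the r−1 free cells when the table count is below
  2·10⁶, otherwise Monte-Carlo with the replicate count and seed recorded
  in the result.  p sums all tables with probability ≤ the observed
  (within 1e-9 log-tolerance for ties).

Rollups average site means, not subjects: knee = mean of its three site
means, region = mean of the region's two sides, overall = mean of all six
site means.

## Problem sizes and tolerances in the validation suite

Deterministic recomputations use the published moments directly.
Stochastic checks use: 200 reliability replicates of 232×3 matrices
spanning the SEM% 1.3–2.3 band; 500 cohorts of 100×3 for ICC CI coverage
(93–97 % band); 2000 null ANOVA simulations at group sizes 56/70/47/59
(4–6 % rejection band); 10⁵ Monte-Carlo draws for the studentized-range
oracle.  Phantom suites run at 0.05 mm/px and ~2000 polyline points, where
constant-thickness recovery is exact to the reported precision, the
annulus closed form holds to 1e-4 mm, and mask- and polyline-derived
thickness agree within one pixel spacing.

## Known limitations

* No segmentation of raw B-mode images; inputs are masks or polylines.
* Exclusion of images with an irregular cartilage rim is an analyst
  decision upstream of this package.
* The cohort generator does not model site-to-site error correlation
  beyond the shared subject effect, nor age/sex-dependent measurement
  error.
* Single-rater designs only: ICC(2,1)/ICC(1,1) and inter-rater analyses
  are out of scope.
* The published tables carry 3-decimal rounding; statistics recomputed
  from them inherit an irreducible uncertainty of a few units in the
  second decimal of F.
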