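# Methods

## Problem and approach

`aquaniche` supports siting decisions in freshwater aquaculture by estimating
the *realised abiotic niche* of candidate species from occurrence records and
gridded environmental layers, then asking two questions: does a given farming
environment fall inside a species' niche, and do several species share enough
abiotic space (a non-null niche intersection) to be candidates for
polyculture? The method is correlative: it characterizes where a species is
observed, not the full range of conditions it could physiologically tolerate,
and it says nothing about biotic or economic compatibility.

The pipeline is:

1. **Cleaning** — occurrence records pass a fixed sequence of rules
   (coordinate validity, (0,0) placeholders, exact lat==lon, country-code
   mismatch, sea points, spatial outliers). Each rejected record carries the
   name of the first rule it failed, so retained + flagged always partitions
   the input.
2. **Gridding** — records collapse to one presence per cell of a 10- or
   30-arcminute WGS84 grid anchored at (−180, −90), neutralizing uneven
   sampling effort. The working extent defaults to 56°S–60°N, 145°W–180°E
   (the joint coverage of the global layers the tool consumes).
3. **Environment matrix** — per presence cell, 16 raster variables are
   aggregated as the mean of source pixels whose centres fall in the cell
   (no area weighting), and 3 photoperiod summaries are computed at the cell
   centre latitude. Units are kept exactly as the layers deliver them
   (e.g. °C×10); standardization later removes scale.
4. **Reduction** — PCA on the correlation matrix of the pooled species
   matrices; components with eigenvalue > 1 are retained (Guttman-Kaiser).
   If the retained dimensionality still exceeds ln(number of presences) for
   a species, a warning is attached — boundary estimation becomes unreliable
   in that regime.
5. **Hypervolume** — a one-class SVM (RBF kernel) fitted per species on its
   scores delimits the niche; volume is estimated by rejection sampling.
6. **Applications** — inclusion tests for site queries, n-way intersection
   volumes, combination rankings, and per-variable density profiles.

## Coordinate conventions

Cells are half-open intervals `[b, b + res)` on both axes with boundaries at
integer multiples of the resolution from (−180, −90); for a 30′ grid every
centre has fractional part 0.25 or 0.75. Extent minima are inclusive, maxima
exclusive, except the global maxima (180°E, 90°N) which are inclusive.
Rectangular site queries snap via their centroid. These conventions uniquely
reproduce the published farm-site cell centres used as fixed checks
(e.g. (48.1203°N, 1.7925°W) → (48.25, −1.75)).

## Photoperiod

Day length uses the CBM closed-form model: with
θ = 0.2163108 + 2·atan(0.9671396·tan(0.00860·(J − 186))) and solar
declination φ = asin(0.39795·cos θ),

D(L, J) = 24 − (24/π)·acos[(sin(p·π/180) + sin(L·π/180)·sin φ) / (cos(L·π/180)·cos φ)],

with the daylength coefficient p = 0.8333° (apparent sunrise/sunset including
refraction, the default of the standard R implementation, against which the
tests cross-check to < 0.05 h). The arccos argument is clamped to [−1, 1],
which yields exactly 24 h / 0 h under polar day / night. Years are treated as
365 days; annual summaries (min, max, range) are insensitive to leap days at
the reported precision.

## Hypervolume estimation

The one-class SVM uses ν = 0.01 (expected training rejection rate) and
γ = 0.5, both configurable. Scores are standardized per axis (mean 0, sd 1,
ddof = 1) *inside* the fit, so γ acts on comparable scales whatever the
spread of the reduced scores — the same behaviour as the reference SVM
implementations in R, which scale by default. The decision function is
evaluated from the stored support vectors and dual coefficients, which makes
serialized hypervolumes (JSON header + full-precision CSV point cloud)
reproduce inclusion decisions bit-exactly after reload.

Volume is estimated by rejection sampling in the standardized bounding box of
the training scores expanded by `box_margin = 0.5` standardized units per
side: `volume = box_volume × acceptance_fraction`, mapped back to the shared
reduced space through the standardization Jacobian. Accepted samples are
retained as the point cloud with density `accepted / volume`. On a unit
square with 2000 training points this recovers volume ≈ 1 (median within 15%
over seeds); the SVM boundary is soft, so some bulge beyond the true support
is expected. If every sample is rejected (pathologically large γ), a
dedicated error suggests raising γ or the margin rather than returning a
silent zero.

Intersections of n ≥ 2 hypervolumes are estimated the same way over the
intersection of the members' sampling boxes, accepting a sample iff every
member's decision function admits it. An empty box or zero acceptances is the
*null intersection* verdict (volume 0, empty cloud): no shared abiotic space.
The binomial standard error of each estimate is reported; invariant checks
(intersection ≤ min member volume, monotone under adding members, order
invariance) hold to within 3 standard errors.

**Shared space requirement.** Hypervolumes that will be intersected are
always fitted in one PCA computed on the pooled, jointly standardized
matrices of the species under comparison — intersection is undefined across
different reduced spaces. Combination ranking therefore refits each subset in
its own pooled space; volumes are comparable within a subset size, and the
feasibility verdict (volume > 0) is the primary cross-subset signal.

**Site inclusion** for an intersection is the logical AND of the member-wise
decision-function tests, not a nearest-neighbour query against the MC cloud:
it is deterministic given the fits, and the cloud is retained for volume
estimation only.

## Numerical choices

- Kaiser retention always keeps at least the first component, so degenerate
  inputs still yield a usable 1-D space (logged).
- Variables whose sample standard deviation is below `1e-10 × max(|mean|, 1)`
  are dropped before standardization: mean-aggregating a constant raster can
  leave ~1-ulp jitter that must not be inflated into a fake axis.
- PCA component signs follow the convention that the largest-magnitude
  loading is positive; eigenvalues sum to the number of variables (tolerance
  1e-6) and loadings are orthonormal (1e-8).
- Density profiles use a Gaussian KDE with Silverman bandwidth per species
  per variable, evaluated on a shared grid spanning the pooled range expanded
  by max(10% of the span, 4 bandwidths) — the latter guarantees each curve
  integrates to ≈ 1 over its grid. Zero-variance samples are flagged
  degenerate and their point mass reported as the mode.
- Spatial outliers: for species with ≥ 7 records, a record is flagged when
  its mean great-circle distance (haversine, R = 6371 km) to conspecifics
  exceeds Q3 + 5 × IQR of those means; the multiplier is configurable.
- Taxon suggestions use restricted Damerau-Levenshtein distance
  (case-insensitive, threshold 2 edits) against a user-supplied checklist.
- One root seed drives everything; each stochastic operation derives a child
  seed from (seed, operation, species names) by hashing, so fits are
  reproducible and independent of execution order.
- The dimensionality warning threshold uses the natural logarithm.

## Synthetic data

The generator builds deterministic rasters (constants, longitude/latitude
gradients, sinusoids) plus a random land mask, and draws occurrence records
from explicit niches defined in raw variable units: boxes (uniform over
satisfying cells) or Gaussians (cells weighted by the product of
per-variable normal densities). Records are jittered uniformly within their
cell, so presence gridding recovers exactly the sampled cells. A
contamination option appends labelled (0,0) points, sea points, and one far
outlier per species for cleaning tests.

The canonical two-species test world uses a 20°×15° extent at 30′, with
temperature and precipitation increasing along longitude and elevation along
latitude; two box niches on temperature place the species in the longitude
bands [1°, 8°] and [6°, 13°], overlapping in [6°, 8°]. Test sites sit at the
overlap centre and far outside both bands. Species samples of 300 records
(~200–300 presence cells) are typical of a moderately well-recorded species
after gridding and keep a full pipeline run around a second.

What these fixtures do **not** emulate: spatial autocorrelation and sampling
bias of real occurrence databases, correlated multi-variable climate fields,
realistic coastlines, or niches with curved boundaries. Passing tests
demonstrate the estimator recovers known simple niches under clean
conditions; they do not certify accuracy on sparse or biased real data — the
dimensionality warning and the occurrence-count diagnostics exist precisely
because real datasets often are both.

## Known limitations

- Realised ≠ fundamental niche: absence of occurrences in suitable
  conditions (dispersal limits, competition) shrinks the estimated niche.
- The SVM boundary is soft; volumes carry both Monte-Carlo error and a
  systematic bulge/shrink controlled by ν and γ.
- Rankings refit PCA per subset; volumes are not directly comparable across
  subsets with different retained dimensionality.
- Non-WGS84 rasters are rejected, not reprojected; aggregation is
  pixel-centre membership, not area-weighted.
- The country-code rule is inert unless the caller supplies country
  polygons; no boundary dataset is bundled.
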