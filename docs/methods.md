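# Methods

## The model

`bcfuse` reconstructs a spatiotemporally complete black-carbon (BC) field
from two complementary, individually incomplete measurement systems:

* a **pollutant × location** system **X**ₘ ∈ ℝ^(p×l): time-averaged maps of
  p pollutants over l locations, produced by repeated mobile monitoring and
  aggregated per ~30 m road segment;
* a **location × time** system **X**_F ∈ ℝ^(s×t): temporally complete BC
  series from s fixed low-cost sensor sites at t time bins (15 min default).

Both matrices are factorized with non-negative matrix factorization:

    X_M ≈ W_P H_L        (k source signatures × pollutant-invariant spatial patterns)
    X_F ≈ W_S H_T        (q time-invariant spatial patterns × characteristic time signals)

The working assumption is that the same sources and meteorology shape both
sets of spatial patterns, so each time-invariant pattern (column of W_S) can
be expressed as a combination of the pollutant-invariant patterns (rows of
H_L) evaluated at the sensor sites.  With Φ ∈ {0,1}^(s×l) the binary
row-selection operator onto the sites, the reprojection coefficients are the
least-squares solution

    C = (Φ H_Lᵀ)⁺ W_S ∈ ℝ^(k×q),

computed with an SVD pseudoinverse (relative singular-value cutoff `rcond`,
default 1e-10).  The complete field is then

    X_BC = H_Lᵀ C H_T ∈ ℝ^(l×t),

i.e. the spatially dense patterns carrying the temporally complete signals.
Because C is refitted through a pseudoinverse, any positive per-factor
rescaling of H_L or W_S cancels exactly; the NMF normalization convention is
therefore immaterial to X_BC, a property the test suite verifies numerically
rather than assumes.

### Assumptions and when they break

* Spatial patterns are stable over the campaign (the mobile maps are
  time-averaged).  A transient roaming source violates this; the scene
  generator can inject one (`transient_source: true`) to stress-test.
* The latent spatial structure shared across pollutants spans the spatial
  structure of BC variability.  With fewer pollutants or collinear
  signatures the span degrades gracefully (sensitivity case on pollutant
  count).
* Concentrations are non-negative; reconstruction negatives (possible since the
  reconstruction product is unconstrained) are clipped to zero and counted.

## Pipeline stages and parameters that matter

| stage | parameter | default | why |
|---|---|---|---|
| mobile aggregation | `min_visits` | 15 passes | below ~15 repeat visits the median-of-pass-means is an unstable estimate of the time-averaged concentration |
| | `max_gap_s` | 60 s | a gap longer than a minute at urban speeds means the vehicle left and returned: a new pass |
| | `max_snap_dist` | 30 m | one segment length; beyond that a GPS fix is not on this road |
| sensor prep | `bin_width` | 15 min | balances instrument noise suppression against temporal resolution |
| | `min_coverage` | 0.5 | a bin mean from under half the expected raw samples is not trusted |
| | `min_observed` | 0.8 | sites with >20% missing bins are rejected rather than imputed |
| kriging | `variogram_kind` | exponential | generic monotone spatial decay; fitted per pollutant by pair-count-weighted least squares |
| factorization | `k`, `q` | 5, 16 (or `auto`) | campaign-standard ranks; `auto` picks the knee of the error-vs-rank curve |
| | `tol`, `max_iter` | 1e-6, 2000 | HALS stopping rule (relative objective change per sweep) |
| fusion | `rcond` | 1e-10 | relative SV cutoff of the pseudoinverse; effective-rank deficiencies are warned, not silently absorbed |

Gap imputation is linear in time per site for interior gaps and the site
median at the edges — the simplest scheme that cannot manufacture temporal
structure.  Clipping of noise-driven negatives happens after averaging
(bins) or after the median (segments), and every clip is counted and logged.

### NMF details

Both factorizations minimize the Frobenius loss with HALS coordinate
descent from an NNDSVD-style initialization (zeros filled with a small
fraction of the matrix mean so the updates cannot lock them).  The
initialization is deterministic, so a fit is a pure function of
(matrix, rank); the `seed` is recorded for provenance.  HALS updates are
exact per-column minimizers, hence the objective trace is monotone
non-increasing — asserted per sweep at 1e-10 in the tests.

Rank selection normalizes the relative-error-vs-rank curve to the unit
square and takes the point of maximum perpendicular distance from the chord
joining its endpoints.  A flat or perfectly linear curve has no interior
knee; that case is flagged rather than guessed.

### Sensor placement

Candidate sites are ranked by pivoted QR on the transpose of a spatial
basis (default: the leading 8 left singular vectors of the site × time
matrix).  QR column pivoting greedily maximizes a determinant surrogate of
basis observability, but its residuals all vanish once the basis rank is
exhausted, making pivot order beyond r numerically arbitrary.  For m > r
the selection therefore continues with a D-optimal greedy rule — add the
candidate with the largest leverage x M⁻¹ xᵀ, maximizing the determinant
gain of the information matrix — instead of padding the basis with trailing
singular vectors, which empirically makes the selection chase noise
components and lose to random placement at larger m.  `pad=True` restores
the padded-basis variant.

The optimal-vs-random benchmark scores every selection against the same
fixed evaluation set (reconstruction error at all non-sensor segments of a
synthetic scene); scoring each selection on its own complement would bias
the comparison, because QR deliberately leaves the least informative sites
out.

## The synthetic scene

The generator emulates the structure the model relies on — and nothing
more.  A square grid of streets cut into 30 m segments (default 400 over a
600 m domain), 60 sensor sites jittered within ~20 m of the roads, and a
small number of point sources, each with:

* a non-negative pollutant signature (Dirichlet-distributed; the
  `signature_alpha` concentration controls how chemically distinct sources
  are),
* an exponential spatial kernel exp(−d/L), L ∈ [120, 260] m by default,
* weekday/weekend diurnal profiles (smooth baselines plus Gaussian peaks)
  and lognormal day-to-day strengths (σ = 0.3).

The truth cube is the sum of these separable terms plus a flat background,
so its unfoldings have non-negative rank = sources (+1 with background) —
the property that makes exact-recovery and planted-rank experiments
meaningful.

Sampling:

* **Mobile**: two vehicles drive weekdays 09:00–16:00; each 15-min block a
  vehicle works one local neighborhood (a seed segment and its ~40 nearest
  neighbors) before moving on, emitting 1-Hz points with 10% multiplicative
  lognormal noise.  Spatial locality within a block matters: an earlier
  i.i.d.-teleporting sampler made every Lagrangian window average the whole
  domain, which erases the model-vs-areawide contrast that real drive data
  exhibit.  10% of segments get a 50× lower visit weight, so the ≥15-visit
  filter is genuinely exercised.
* **Fixed sites**: per-(site, bin) lognormal noise (10% CV — sensor noise
  acts at the averaging scale), an additive Gaussian noise floor of
  0.15 µg/m³ per raw sample (realistic for sub-minute low-cost optical BC;
  it produces the negative raw readings that exercise the clipping path),
  and 5% missing bins.

What the generator does **not** emulate: wind-driven plume anisotropy,
chemistry, long-range transport, instrument drift, GPS error.  Passing
tests on these scenes show the pipeline recovers structure *of the kind the
model assumes*; they do not certify performance on real data, where the
shared-pattern assumption itself is the main risk.

### Scales used in the experiments

The default scene (p=6, l=400+60, s=60, t=960, 4 sources + background) is a
deliberate desk-scale analogue of a dense urban campaign — small enough
that the full suite of experiments (50-iteration leave-site-out CV, a
70-fit placement benchmark repeated 10 times, 30 planted-rank trials) runs
in minutes on one core.  `SceneConfig.campaign_scale()` reproduces full
campaign shapes (10 pollutants, 4417 locations, 97 sites, 9600 bins) for
shape/bookkeeping checks.

The planted-rank (knee) experiment uses a dedicated construction: 10
pollutants, equal source strengths, sparse signatures (`signature_alpha
0.3`), 60–120 m kernels, no background, 1% noise.  Planted rank is only a
well-posed notion when sources are distinguishable in chemistry and space;
with generic overlapping sources, two of five can be near-collinear and a
4-factor solution is then legitimately the better description.

## Numerical choices

* Pseudoinverse cutoff 1e-10 (relative); effective rank below k triggers a
  warning and the minimum-norm solution.
* Kriging uses the semivariance form of the ordinary-kriging system with a
  Lagrange multiplier, one global solve per pollutant (no neighborhood
  truncation at these problem sizes); weights sum to 1 by construction and
  are asserted to 1e-8.  Sites within 1 m of a segment location copy its
  value directly.
* Variogram fits start from moment-based initial values and use bounded
  trust-region least squares; a failed fit raises with the empirical curve
  attached rather than returning defaults.
* Ties: point-to-segment snapping breaks distance ties lexicographically by
  segment id; QR pivoting and the leverage greedy break ties by index.
* Degenerate inputs error early and namedly: empty segment sets, sites with
  no samples, all-zero factor columns, coincident kriging training points.

## Known limitations

* The reprojection is unregularized least squares; with very few sites or
  nearly collinear patterns, C inherits their conditioning (warned, not
  fixed).  Ridge or non-negative variants are out of scope.
* No uncertainty quantification on X_BC.
* The imputation scheme is not seasonal/diurnal-aware; it is only meant to
  bridge short gaps ahead of factorization.
* `leave_sites_out_cv` reuses the pollutant-side factorization across
  iterations — legitimate because the mobile side never sees sensor data,
  but it means the CV does not propagate mobile-map sampling variability;
  the vehicle-holdout experiment covers that axis.
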