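# Methods

## The geometric model

The testis is idealized as a solid ellipsoid

    x²/(a·l)² + y²/(b·l)² + z²/(c·l)² = 1,

with the long axis along X. The dimensionless semi-axis ratios satisfy
`a ≥ b ≥ c ≥ 1` and `l > 0` (mm) is the width of one parenchymal slice,
so the physical semi-axes are `A = a·l`, `B = b·l`, `C = c·l`. A note on
convention: `A`, `B`, `C` are **semi**-axes, not full axis lengths —
this is forced by the implicit equation above and is what makes all the
section-area formulas below consistent. Anatomical planes follow the
testis frame: transverse sections are normal to X, sagittal to Y,
coronal to Z.

A microTESE procedure is modelled in two steps:

1. **Tunical incision** (longitudinal or transverse) through the
   capsule, which bivalves the testis like a book. A longitudinal
   incision opens it in the X–Y plane, exposing two faces of the
   central coronal ellipse (combined area `2πab·l²`); a transverse
   incision opens the Y–Z plane (`2πbc·l²`).
2. **Serial parenchymal slicing** in one anatomical plane, at every
   integer multiple of `l` strictly inside the ellipsoid. Slicing
   parallel to the bivalve exposure plane is infeasible — those slices
   would be detached from the tunica albuginea and fall apart — which
   excludes (longitudinal, coronal) and (transverse, transverse) and
   leaves four feasible methods, numbered 1–4.

Each cut at index `i` (|i| ≤ ratio − 1 along the cut normal; pole
planes have zero area and are never counted) contributes
`4·S_i` of searchable area: 2 bivalved halves × 2 faces per cut. The
half-section areas are

    S_x = π b c l² (a² − x²) / (2a²)      (transverse, and cyclically)

and the sums telescope, e.g. for transverse slicing

    Σ 4·S_x = 2 b c l² (2a+1)(2a−1)/(3a) · π .

The total searchable area of a method is the bivalve face area plus its
slice-face sum. Adjacent methods differ by

    total(1) − total(2) = 2c·l²(a² − b²)/(3ab)·π
    total(2) − total(3) = 2b·l²(a − c)·π
    total(3) − total(4) = 2a·l²(b² − c²)/(3bc)·π ,

all strictly positive when `a > b > c`. Hence the ranking theorem:
method 1 — longitudinal tunical incision with transverse slicing —
maximizes the searchable surface, for every strictly ordered integer
testis. The package verifies this exhaustively on the grid `a ≤ 12`
rather than trusting the algebra.

Only cut faces are counted as searchable: the outer convex surface of
each slice, and any occlusion of the faces near the tunical hinge, are
not modelled. Degenerate shapes are reported honestly: `a = b`
collapses the first difference to zero, `b = c` the last, and a sphere
makes all four totals equal; ties are broken by ascending method label
and flagged as ties.

## Numerical verification

Every closed form has an independent oracle:

* **Direct summation** evaluates `Σ 4·S_i` term by term; it must agree
  with the telescoped closed form to relative 1e-9 (double precision
  passes with orders of magnitude to spare).
* **Implicit-equation quadrature** (`plane_section_area_quadrature`)
  integrates a plane section using only the implicit ellipsoid
  equation: the section boundary is found by bisection (never by the
  ellipse-area formula), and the in-plane integral uses Gauss–Legendre
  nodes under a sine substitution that removes the square-root endpoint
  singularity. Tolerance: relative 1e-4 at 1024 nodes; observed
  agreement is near machine precision. A naive 2-D occupancy grid was
  rejected because its O(1/resolution) boundary error cannot meet that
  tolerance.
* **Continuum limit**: with physical axes fixed and `l = A/a → 0`, the
  slice-face sum times `l` converges to twice the ellipsoid volume
  (each slice exposes two faces); the refinement sequence
  `a ∈ {10, 20, 40, 80}` must show monotonically shrinking error. The
  error of the transverse sum is exactly `2πBC·l²/(3A)`, i.e. O(l²).

Strict mode (default) requires integer ratios, which the closed sums
need; generalized mode (`strict=False`) admits real ratios and sums
over the integer cut lattice directly, with the closed form refusing to
apply. The clinical front-end `recommend()` takes semi-axis lengths in
mm, divides by the slice width, rounds to the nearest integer ratios
and reports the rounding residual, keeping the closed forms applicable.

## Cohort statistics

The clinical component compares sperm retrieval rates (SRR) between a
56-patient historical cohort and a 102-patient cohort treated with the
area-maximizing method, overall and within etiology and histopathology
subgroups. Choices, in order of consequence:

* **Uncorrected Pearson chi-square** on each 2×2 table, df = 1, no
  Yates continuity correction, no exact-test fallback. This is the only
  variant consistent with the published subgroup p-values: for the
  maturation-arrest table (0/2 vs 8/9) the uncorrected statistic is
  6.52 (p = .011), where Fisher's exact test would give .055. The
  caveat is explicit: several subgroup tables have expected counts
  below 5, where the chi-square approximation is rough; the package
  reproduces the published analysis rather than improving on it.
* **Not-computable rows**: a subgroup with an empty cohort on one side,
  or a degenerate table (zero row/column margin, e.g. zero successes in
  both cohorts), gets `p = None` rather than a number.
* **Rounding**: SRRs are rounded half-up, 0 decimals for the overall
  row, 1 decimal for subgroups — matching the published precision. One
  known anomaly: 13/24 = 54.1667% rounds to 54.2% while the source
  table prints 54.1%; that single cell is excluded from the
  reproduction test and flagged here.
* **No multiple-testing correction**, matching the published per-row
  tests at α = .05.

Patient-level covariates (age, hormones) were never published, so the
record schema carries them as optional fields only and no continuous
comparisons are attempted.

### The reconstructed count table

The published tables give, per cohort, success counts by etiology and
separately by histopathology — not the joint assignment.
`datasets.reference_cohort()` builds a synthetic 158-patient record
list whose two margins both match the printed counts exactly, via a
northwest-corner transport applied separately to successes and
failures. Every marginal summary — which is all the comparison uses —
is therefore exact; the individual etiology×histopathology pairings
are an arbitrary feasible choice and should not be interpreted.

### The synthetic cohort generator

`synth_cohort` draws independent Bernoulli outcomes per patient within
each (cohort, subgroup) arm, with exact arm sizes and deterministic
output given a seed. Its default arm specification
(`datasets.reference_synth_arms()`) uses the published subgroup mix and
the observed subgroup SRRs as the true rates. It emulates the
between-patient independence and subgroup structure of the cohort; it
does **not** emulate patient covariates, within-surgeon learning
curves, temporal drift over the accrual periods, or any correlation
between etiology and histopathology. Passing tests on synthetic data
therefore validate the arithmetic and the test's calibration, not the
clinical effect itself — individual retrieval outcomes are not
reproducible from published information, only the count arithmetic is.

`power_sim` calibrates the uncorrected test by Monte-Carlo: at the
study's group sizes (56 vs 102) and a common rate of 0.29, the type-I
error over 10⁴ replicates must lie in [0.03, 0.07]. Degenerate
replicate tables are skipped and counted as non-rejections.

## Problem sizes and defaults

* Exhaustive geometry grids run to `a ≤ 12` (220 strict triples) for
  identities and ranking; the self-verification CLI defaults to depth
  10. These grids complete in seconds and already cover every
  clinically plausible ratio (a 2–3 mm slice against a ≤ 25 mm
  semi-axis gives ratios ≤ 12).
* Quadrature resolution defaults to 1024 nodes (floor 64); the
  verification suite samples sections at 256 nodes, where agreement is
  already ~1e-15.
* Slice width default in examples is 2.5 mm, the middle of the 2–3 mm
  range used clinically; all lengths are mm, areas mm², volumes mm³.
* Monte-Carlo calibration uses 10⁴ replicates; parameter-recovery
  checks use 10⁴ patients per arm with a 2% tolerance.

## Known limitations

* The ellipsoid is rigid: no tissue deformation, vasculature, or
  tubule-level structure; the blood-supply rationale for transverse
  slicing is qualitative and not computed.
* The ranking theorem is proved here by exhaustive evaluation on an
  integer grid, not symbolically for all real `a > b > c` (the
  algebraic differences make the general case evident, but the package
  asserts only what it computes).
* Small-expected-count chi-square p-values (several subgroup rows)
  carry the usual approximation caveat noted above.
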