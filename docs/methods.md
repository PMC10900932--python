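# Methods

## Scope and model overview

`spsd` implements a stochastic parametric approach to bone-marrow dosimetry
for incorporated ⁸⁹Sr and ⁹⁰Sr(+⁹⁰Y).  Hematopoietic bone sites are
decomposed into simple-shaped segments; each segment is a stylized solid
(box, elliptic cylinder, deformed cylinder, ellipsoid, triangular pyramid or
tube) whose interior spongiosa — a rod-like trabecular lattice immersed in
marrow — is bounded by a cortical shell on the surfaces where cortex exists
anatomically.  Dose factors DF(AM←TBV) and DF(AM←CBV) convert activity
concentration in trabecular or cortical bone (Bq/g of parent nuclide) into
dose rate in active marrow (Gy/s), carried throughout on the 10⁻¹¹ scale.

The package does **not** run electron–photon transport.  Phantoms can be
exported for transport codes, but dose factors inside the package come from
analytic surrogates fitted to transport results, valid for segments whose
spongiosa dimensions exceed two electron mean pathlengths (≈0.46 cm):

* mean pathlength (CSDA) in spongiosa: λ(Ē) = 0.112 + 0.099·e^(−1.526·BV/TV) cm;
  the maximum pathlength is ≈5λ and never exceeds 1.1 cm, which is what
  permits segment-by-segment modelling in the first place.
* DF(AM←TBV) = a·(1 − e^(−b·BV/TV)), (a, b) = (28, 0.897) for ⁹⁰Sr and
  (13.9, 1.06) for ⁸⁹Sr, defined on BV/TV ∈ [0.01, 0.52]; its residual
  relative uncertainty follows δ = 0.063 + 0.1·e^(−0.373·DF), i.e. from
  ~15% for the most porous spongiosa down to 6.5% at the densest.
* the cortical-to-trabecular energy-deposition ratio
  F꜀(Ct.Th) = a_F·e^(−b_F·Ct.Th), (a_F, b_F) = (0.435, 4.98) for ⁹⁰Sr and
  (0.431, 6.915) for ⁸⁹Sr, on Ct.Th ∈ [0.01, 0.41] cm, whence
  DF(AM←CBV) = DF(AM←TBV) · F꜀ · V_CBV/V_TBV.  The energy-ratio residual is
  taken as a fixed average 10% (its true spread is 4–20% over the fitted
  interval but no functional form is published); it combines with the TBV
  residual in quadrature.  The composition is used rather than the rounded
  closed-form coefficients (12.2, 6) to avoid double rounding; the rounded
  forms serve as cross-checks only.
* segments whose spongiosa surface area SS ≤ 6 cm² receive a crossfire
  multiplier (SS_ext/SS)^0.28, SS_ext being the surface after growing every
  linear dimension by 2λ, with a 5% relative uncertainty.  Outside their
  fitted intervals all surrogates extrapolate with a warning instead of
  failing; the shipped reference segments stay inside.

Eq.-of-record conventions: dimension lists follow a×b×H for elliptic
cylinders and a×b×c×d×H for deformed cylinders with a, c the **full** major
axes and b, d the full minor axes (the deformed cylinder interpolates
linearly between two parallel ellipses whose major axes lie in perpendicular
planes, so a truncated cone is the degenerate case); ellipsoids use full
axes l, m, n; tubes use inner/outer radius and height.  Converting a mean
absorbed energy per decay into a dose factor applies the MeV→J conversion
explicitly and the source/marrow mass ratio, which makes DF intensive in the
tissue masses.

## Individual-variability sampler

Macroscopic dimensions and cortical thickness vary between individuals with
normal marginals; Tb.Th and Tb.Sp with lognormal marginals.  Macro
parameters are positively correlated (default pairwise 0.5, the typical
inter-bone correlation of skeletal dimensions); Tb.Th and Tb.Sp negatively
(default −0.5: thinner trabeculae sit further apart).  Correlated draws use
a Gaussian copula — correlated standard normals mapped through the marginal
quantile functions — with componentwise truncation to the central 90%
probability mass (draws with any coordinate outside ±1.645 are treated as
outliers and redrawn).  Because symmetric truncation shrinks the standard
deviation by ≈0.79, the underlying scales are inflated by the reciprocal
factor so the *realized* population carries the stated CVs; the stated CVs
are thus interpreted as properties of the accepted draws, not of a
hypothetical untruncated parent.

Each micro draw implies a bone volume fraction through the rod-lattice
scaling BV/TV ∝ Tb.Th²/(Tb.Sp+Tb.Th)², anchored so the population-mean
(Tb.Th, Tb.Sp) maps exactly to the population-mean BV/TV.  Draws whose
implied BV/TV leaves the admissible (min, max) interval are resampled, up to
1000 attempts before a segment-named failure.  With the reference
variability set (micro CVs 4%, macro 16–17%, Ct.Th 42%) the realized BV/TV
CV is ≈12%; perfect Tb.Th–Tb.Sp anticorrelation would push it to ≈16%, so
the reported spread of the original generator suggests a stronger
anticorrelation than the −0.5 default.  The default is kept because only the
sign of the correlation is firmly established; the magnitude is exposed as a
parameter.

**Sample sizing.**  How many random phantoms does a segment need?  The
per-segment variability estimator is the relative RMSD of randomized dose
factors about the population-mean model's value (about the *true* value, not
the sample mean, so bias is not hidden).  Its stability is judged by the
relative variance of that estimator (VOV), computed by bootstrap resampling
at each candidate sample size; the minimum acceptable size is the smallest
n with VOV < 0.15.  For lognormal dose-factor populations with CV ≈ 0.25 —
the operating regime — a dozen random phantoms are comfortably sufficient
(VOV(12) ≈ 0.04–0.08 across seeds).

## Phantom geometry

Cortical shells are built by *shrinking* the outer solid: every covered
surface moves inward by its thickness, so the spongiosa is a same-kind solid
and shell volumes are exact for boxes (closed-form L³−(L−2t)³ for cubes) and
standard stylized-phantom offsets for curved shapes (the true offset of an
ellipse is not an ellipse; the error is second order in t/R and is absorbed
into the voxelization tolerance).  Per-surface thicknesses are supported for
the cortical-nonuniformity protocol: a random per-face list is rescaled so
its mean equals the target mean thickness.  Pyramid shells scale uniformly
about the incenter (per-face thicknesses on a tetrahedron are not needed by
any fixture and are rejected).

The trabecular lattice places cylindrical rods along all three axes on a
grid of period Tb.Sp+Tb.Th with Gaussian positional jitter (scale tb_sp_sd,
clipped at 45% of the period to preserve ordering) and per-rod lognormal
thickness (mean Tb.Th, SD tb_th_sd).  The rod-placement algorithm of the
original generator is unpublished, so the lattice is calibrated: a final
uniform thickness-scale factor is adjusted (BV/TV ≈ scale², a few fixed-point
iterations on a Monte Carlo estimate with ~10⁵ interior points) until the
realized bone fraction lands inside the admissible BV/TV interval, with a
bounded-retry failure otherwise.

Voxelization samples membership at voxel centers (matching the lattice-input
conventions of transport codes and exactly testable on aligned grids); label
counts conserve the grid by construction, and voxel volumes converge to the
closed forms at first order in resolution.  A resolution coarser than
0.75×Tb.Th triggers a warning — coarser grids bias dose factors — and a
configurable voxel budget (default 6×10⁷) guards against accidental
grid explosions.  Spongiosa surface areas from voxel grids are face counts
times the voxel face area; on curved surfaces this staircase estimate
overestimates by up to ~π/2, so analytic surfaces are preferred whenever the
partition is available.  Tube spongiosa surfaces count both the inner and
the outer lateral boundary.

## Size classes and the uncertainty budget

Segments are classified by circumscribed-box edges and spongiosa volume V_s:
four classes for the trabecular source (all edges >1.1 cm; V_s >1.1 cm³ with
one, or two, edges below 1.1 cm; V_s <1.1 cm³) and six for the cortical
source (edge cuts at 2.8/1.5/1.1 cm, volume cuts at 1.6/0.2 cm³).  The
volume rules dominate the edge rules — a segment with tiny spongiosa is
"small" no matter its envelope — which resolves the textual overlap of the
group definitions.

Budget components and their classification:

| component | δ | class | applies to |
|---|---|---|---|
| shape stylization | 15/13/7% (TBV2–4), 15/10/14/9/4% (CBV2–6) | shared | all but the largest classes, where it is negligible |
| voxelization | 1% | shared | everywhere (given the 0.75×Tb.Th rule) |
| model restriction | 5% | shared | segments with SS ≤ 6 cm² |
| cortical uniformity | 7% | shared | cortical source only |
| micro/macro variability | 20% default (true range ~5–60%), segment-specific when measured | unshared | everywhere |
| chemical composition | 4% | unshared | everywhere |
| bone density | 4% (large)/6% (small) TBV; 0 (large)/13% (small) CBV | unshared | by size |

Components combine in quadrature within each class; overall
δ = √(δ_shared² + δ_unshared²).  Where only a range is published for a
component the group-specific value is used, defaulting to the conservative
end when a single number is required.

## Skeletal aggregation

Site dose factors are marrow-mass-weighted means of segment dose factors;
the skeletal average weights sites by measured active-marrow fractions
(10 adult sites, normalized; average CV 0.39).  Because bone dimensions
correlate across the skeleton, site dose factors are treated as correlated
with ρ = 0.5 (configurable): with per-site σᵢ = DFᵢ·Wᵢ·√(δ_wᵢ² + δ_DFᵢ²),
the variance of the skeletal average is Σσᵢ² + ρ·ΣΣ_{i≠l}σᵢσₗ — verified
against the explicit covariance-matrix quadratic form to 10⁻¹⁰.  The
shared/unshared split runs this machinery twice: AM-fraction variability
enters only the unshared pass (it is individual anatomy), the introduced
components only the shared pass.  Sites without dose factors are dropped
with renormalization and a warning rather than an error.

Segment-level dose factors are treated as lognormal,
μ = ln(mean/√(cv²+1)), s = √ln(cv²+1), a parameterization that round-trips
mean and CV to 10⁻¹⁰ relative; pooling dose factors across segments whose
magnitudes differ by an order of magnitude uses the standardization
(DF̄−DF)/σ_var, whose pooled distribution is compared between a normal and a
3-parameter (shifted) lognormal fit by likelihood — the lognormal is fitted
in both skew orientations because the standardization mirrors the skew of
the underlying dose factors.

The **two-dimensional Monte Carlo** draws, per population realization, one
multiplicative shared perturbation ~ Normal(1, δ_shared) (truncated at zero;
the excluded mass is negligible for δ_shared ≤ 0.16), and per individual a
lognormal dose factor with mean scaled by the shared draw and CV =
δ_unshared.  The empirical CV of the product converges to
√((1+δ_s²)(1+δ_u²)−1) ≈ √(δ_s²+δ_u²), and the empirical 5th–95th percentile
interval reproduces the lognormal interval of the overall CV.

## Synthetic data and what the tests do (and do not) show

The per-segment morphometric appendix of the adult-male skeleton (47
segments over 12 sites) is not part of the shipped tables.  The
`synthetic_adult_skeleton` builder therefore assembles a stand-in: real site
identities and AM weights, with representative per-site BV/TV, Ct.Th and
sizes spanning the small/large classes, and analytic dose factors.  Tests
against it check *structural* claims — the shared component of the skeletal
average stays below 16%, unshared dominates shared, quadrature identities —
not the exact printed skeletal means, which depend on the unpublished
segment inventory.  Similarly, the regenerated-variability test checks that
per-segment dose-factor spreads fall inside the reported 0.05–0.62 band, a
range containment rather than an equality.  The six-phantom reference table
is reproduced exactly in its geometric columns (spongiosa and cortical
volumes to <5%), which is what validates the shell construction; its
printed dose factors arise from full transport and are used only as budget
constants.

## Numerical choices and problem sizes

Fixed seeds everywhere (`numpy.random.default_rng`; no global state).
Lattice calibration uses 1.2×10⁵ Monte Carlo points; membership-vs-volume
checks use 2×10⁵ points at a 1% tolerance; sampler moment tests use 10⁴
draws at 3-standard-error tolerances; bootstrap VOV uses 500 replicates; the
two-dimensional Monte Carlo examples use a few ×10⁵ realizations.  These
sizes make the statistical assertions sharp while keeping any single test in
the sub-second to few-second range.

## Known limitations

* No transport: surrogate validity is limited to spongiosa dimensions
  >0.46 cm; smaller segments need transport-based dose factors (the
  classification and budget machinery still applies to them).
* Sources are restricted to bone *volumes*; surface-deposited short-lived
  emitters and alpha emitters would need bone-surface source regions.
* Rod-like trabeculae only; no plate-like microstructure, no marrow
  cellularity subdivision (active vs total marrow is handled entirely by the
  mass-fraction weights), no photon cross-dose between bones.
* Child skeletons are supported by the schema (AM sites absent from the
  adult list receive the average 39% fraction CV) but no child segment
  tables are shipped.
* The residual law of the TBV fit was established for ⁹⁰Sr and is applied
  to ⁸⁹Sr unchanged, consistent with the two nuclides' near-identical
  relative variability.
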