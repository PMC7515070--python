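# Methods

## The estimator

A tachogram of N beats is truncated to its largest leading block of
b^m samples (b = 2 by default) and normalized to a probability measure
P. Padding is deliberately avoided: appended mass would create
artificial singularities at the series end, whereas truncation only
shortens the support, and the measure must partition exactly into b^n
boxes at every level for the box sums to be meaningful. At level n the
support is covered by b^n boxes of relative size L = b^(−n), each
holding b^(m−n) samples; valid levels are 1 … m−1 (at least b boxes,
at least b samples per box) and all of them enter the scaling fits by
default. The fits are ordinary least squares of

  S_f(n)  = Σ_i μ_i(q, L) ln μ_i(q, L)   and
  S_α(n)  = Σ_i μ_i(q, L) ln P_i(L)

against ln L, with μ_i(q, L) = P_i(L)^q / Σ_j P_j(L)^q. Natural
logarithms are used throughout; slopes against ln L are base-invariant.
Each q on the grid (default −10 … 10, step 0.1, 201 points) is fitted
independently; R² and slope standard errors are retained per point so
poor scaling is visible rather than silent. No weighting or scale
sub-selection is applied: for exact cascades every level lies on the
regression line, and for empirical series the diagnostics expose any
departure.

Numerics: the powers P^q are evaluated as exp(q ln P − max), i.e.
max-shifted in log space, so |q| = 10 on box masses of order 1e−6
neither overflows nor underflows; zero-mass boxes are excluded from the
sums (the 0·ln 0 → 0 convention), though RR-derived measures have none.

## Shape statistics

α_max and α_min are read at the q-grid endpoints (q_min and q_max
respectively); when α(q) is monotone — always, for exact cascades —
these coincide with the extrema over the grid. α₀ is the α of the grid
point maximizing f, ties within 1e−12 broken toward q = 0, the
theoretical maximizer. The symmetry ratio r = (α_max − α₀)/(α₀ − α_min)
is classified five ways with configurable cut points (0.5, 0.95, 1.05,
2.0): empirical usage calls r ≈ 0.4 "sharply" left-biased while r well
above 2 is sharply right-biased, and a narrow band around 1 is labelled
symmetric.

Curvature uses K = |y″| / (1 + y′²)^{3/2} on the (α, f) points. Two
finite-difference modes are provided because the spectrum's α values
are not uniformly spaced:

* `uniform` (default): successive difference quotients for the
  first derivative and the classical three-point second difference with
  h taken as the local mean spacing. This mirrors the uniform-step
  construction applied to a nearly uniform grid. It is exact for
  quadratics on uniform grids but formally inconsistent (O(1) error)
  when the spacing varies strongly between neighbors — acceptable near
  the spectrum vertex, where spacing varies slowly.
* `nonuniform`: the exact three-point formulas for unequal spacing,
  used by the geometry tests on irregular grids.

The slope in the denominator is always the central difference, which
makes K invariant to reversing the traversal direction of the curve.
A 201-point spectrum yields 200 first-derivative and 199 curvature
values; the first and last grid points are dropped and the center of
the 199-point profile (0-based index 99) sits at q = 0. Consecutive
points closer than 1e−9 in α are merged (f averaged) before
differentiation: otherwise near-duplicate abscissae, which arise for
near-monofractal series, produce division blow-ups that would dominate
K spuriously. A spectrum that collapses entirely (a uniform measure) is
flagged degenerate and its vertex curvature reported as +inf rather
than a large noise-determined number.

The per-subject summary K_max is the profile maximum over a window
|q| ≤ w (default: the whole grid, since K decays toward the tails for
well-behaved spectra; w can be narrowed to 1 for series whose tails
misbehave). Ties go to the smallest |q|.

## Group statistics

Cohorts are summarized by the pointwise mean curvature profile and its
maximum (mvac). The dispersion attached to mvac is the standard error
of the mean at the argmax index by default; the standard deviation is
retained alongside, and the choice is recorded in the output metadata,
since a "±" without definition is ambiguous. Skew counts partition each
cohort into r > 1, r < 1 and r = 1 exactly (the last is measure-zero in
practice but kept as its own bin).

Significance tests compare per-subject curvature maxima — the only
per-subject scalar consistent with group-level ± summaries — using
Welch's two-sided unequal-variance t-test at α = 0.05. Welch is chosen
because healthy and CHF groups have very different K variances. A
seeded permutation test (10 000 resamples by default) is provided for
small strata such as sparse NYHA classes. The degenerate case of two
zero-variance samples with equal means returns p = 1. NYHA
stratification orders classes I < II < III < III-IV < IV, omits empty
classes, and tests consecutive present classes pairwise.

The three-criterion health assessment — (a) wide spectrum, (b) right
lean, (c) small vertex curvature; two of three decide the label — takes
its thresholds from the caller. There is no universal cut point: the
reference values must come from cohorts analyzed with identical
settings (a midpoint-of-group-means constructor is provided). The
assessment is a research summary, not a diagnostic device.

## Synthetic data

Deterministic base-b multiplicative cascades are the estimator oracle.
With weights (p_1 … p_b), the box masses at every level are exact
weight products, the partition sums factorize, and the spectrum has the
closed form α(q) = Σ μ̃_i ln(1/p_i)/ln b, f(q) = Σ μ̃_i ln(1/μ̃_i)/ln b
with μ̃_i = p_i^q/Σ p_j^q — so the scaling plots are exactly straight
and the estimator must agree to near machine precision, which the tests
assert at 0.02 absolute over the full grid (and observe at ~1e−14).
Randomizing the weight assignment per node scrambles the ordering
while provably preserving the multiset of box masses at every level
(each node still splits its mass by the same weight multiset), hence
the spectrum — giving irregular-looking series with exactly known
spectra.

RR-like surrogates are randomized base-4 cascades (length 4^(m/2) =
2^m, so the dyadic analysis partition nests exactly in the generator's)
scaled by a constant to a mean interval of 0.8 s. Pure scaling is used
rather than any affine map with an offset: spectrum estimation
renormalizes, so scaling is exactly invariant, whereas adding an offset
would mix in a uniform background measure and destroy the singularity
structure. The amplitude distribution of the surrogates is therefore
not physiological (its coefficient of variation is far larger than real
RR series); only the multifractal structure is controlled, which is
what the estimator and the group statistics consume.

The `healthy_like` weight set (0.38, 0.32, 0.18, 0.12) was chosen from
the analytic oracle so that, on the standard q ∈ [−10, 10] grid, the
spectrum is broad (Δα ≈ 0.8), right-skewed (r ≈ 1.3), and
vertex-dominated in curvature. The last property constrains the weight
ratios: if any adjacent weight ratio is ≳ 2, α(q) saturates well inside
|q| ≤ 10, the α spacing between grid points collapses in the tails, and
finite-difference curvature blows up there instead of at the vertex.
Keeping the small-weight ratio at 1.5 (right tail explored, no
saturation) and the large-weight ratio at ~1.19 (left tail barely
explored) produces the broad right-skewed regime. The `chf_like`
profile interpolates the same weights toward the uniform split by
0.65 × severity: at severity 1 the spectrum is ≈ 3× narrower, which
raises vertex curvature ≈ 10× (compressing the α axis by s multiplies
the zero-slope vertex curvature by 1/s²) — the narrow, spiky,
roughly symmetric regime of heart-failure spectra. Severity 0
reproduces the healthy parameterization exactly. Per-subject diversity
comes from a 5% log-normal jitter on the weights, seeded per subject.
Surrogates carry synthetic asleep (first half) and awake (second half)
windows so the segment-extraction path is exercised end to end.

Passing tests on surrogates therefore demonstrate that the estimator
recovers known spectra and that the group statistics separate cohorts
whose spectra differ as healthy and CHF spectra do; they do not
demonstrate anything about real tachograms' noise, nonstationarity,
ectopy or sleep-stage structure, none of which the generator emulates.
Numeric agreement with published clinical tables is not a surrogate
goal and is not asserted anywhere.

## Problem sizes and defaults

Validation cascades use 16 levels (65 536 cells) for the binomial
oracle and 9 levels (19 683 cells) for the trinomial one. Surrogate
cohort simulations in the test suite and the acceptance script use
4 096-beat subjects (length_m = 12), 20 per group, 100 replications —
sizes at which the group discrimination is already saturated, so larger
series would only add runtime; the generator's default subject length
is 2^16 beats (≈ 14.6 h at 0.8 s/beat), enough to carve a 6 h segment.
Welch calibration uses 2 000 null replications of n = 20 vs 20
standard normals. Six-hour segments are the first qualifying prefix of
beats inside the first state window that spans the requested duration;
recordings without a continuous qualifying window raise an error, the
analogue of excluding such recordings from segment-level analyses.

Beat-artifact rejection is available (drop RR outside 0.2–4.0 s or
jumping > 20% from the previous beat, then renormalize) but is OFF by
default: the default pipeline analyzes the series as given.

## Known limitations

* The default uniform-step curvature mode is a faithful
  reconstruction of a finite-difference recipe, not a convergent
  estimator on non-uniform grids; use `nonuniform` when the α spacing
  varies rapidly.
* α_min/α_max are grid-endpoint values; for empirical series with
  non-monotone α(q) they may differ slightly from the extrema.
* K_max of a *single* near-monofractal subject is numerically fragile
  (curvature of a tiny arc); the degenerate flag and the window option
  are the guard rails, and group-level mvac is the robust quantity.
* WFDB binary/annotation parsing and sleep staging are out of scope;
  RR files and state windows are supplied as text.
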