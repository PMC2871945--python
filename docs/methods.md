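# Methods

## Scope and assumptions

`lepirisk` implements an 11-parameter exposure model for larvae of three
non-target Lepidoptera near Cry1Ab-expressing maize (MON810): the butterflies
*Inachis io* and *Vanessa atalanta* (first instar, on *Urtica dioica*) and
the moth *Plutella xylostella* (fourth instar, on Brassicaceae weeds).  The
model is deliberately worst-case at every open choice: a shallow
dose–response slope, maximal MON810 uptake outside Spain, and sublethality
treated as if all affected larvae die.  It does not model density
dependence, parasitism, life-table dynamics, anisotropic (wind-direction)
dispersal, or instars/host plants other than those named.

## Dose–response calibration

Bioassay LC50s against Bt176 pollen (186.8 grains cm⁻² for first-instar
*I. io*, 113.1 for fourth-instar *P. xylostella*) are rescaled by the ≈31-fold
lower Cry1Ab concentration of MON810 pollen; the published rounded values
**5800** and **3626** grains cm⁻² are used verbatim.  Note 113.1 × 31 =
3506.1 ≠ 3626; the exact fold behind the published moth constant is not
recoverable, so the published value is adopted and the rescaling operation
kept transparent (`rescale_lc50`), with the discrepancy asserted — not
reconciled — in the tests.

The response is logit-linear in log₁₀ dose.  The underlying probit slope
estimate is 1.095 per log₁₀-dose unit, but the published probit equations
are not recoverable from the source text, so the logit slope is obtained by
exact two-point calibration: the curve passes through (LC₅₀, 0.5) and
through the published crop-edge anchor *g*(0) = 0.0292 at 10^2.346 grains
cm⁻², giving **s ≈ 2.472**.  The independent within-crop anchor
(*h* = 0.0805 at 2.7 × 10^2.346) recovers the same slope to 0.08% relative —
the internal-consistency check the calibration rests on.  Fixed
probit→logit conversion constants (1.6–1.8) cannot reproduce both anchors
and are not used.  The classic logistic(x) ≈ Φ(x/1.702) equivalence is
retained as a property test (links agree to |Δp| < 0.01 over 10–1000 grains
cm⁻²).  The moth shares the calibrated slope, since the same probit slope
1.095 underlies all three species; its curve then gives *g*(0) ≈ 0.0159 and
*h* ≈ 0.0449.

Two published moth values are mutually inconsistent — the within-crop
mortality is printed both as 0.148 (parameter table) and, implicitly, as
0.194/4 = 0.0485 (sublethality section); the calibrated 0.0449 is consistent
with the latter and with the stated 1–2% adjusted within-crop rate, so the
package always computes *h* from the model and treats neither printed moth
value as an anchor.

A steep-slope sensitivity variant (`species_model(..., probit_slope=5.0)`,
probit link) reflects the much larger literature slope estimate, under which
within-crop mortality collapses below 10⁻⁶; it is an option, never the
default.

## Deposition

log₁₀ deposition declines linearly with distance at −0.145 per metre
(halving roughly every 2.08 m).  Slide-based deposition measurements
overestimate leaf retention ~3-fold; nettle leaves retain 2.85× more than
smooth leaves.  The leaf-level intercepts are fixed at 1.891 (Brassicaceae)
and 2.346 (*U. dioica*); the assignment with the nettle curve larger is the
only one that reproduces all three published anchors (*g*(0), μ(2), *h*),
and the 2.85 ratio at every distance is a test invariant.  Within-crop
deposition is 2.7× the edge value.  Distances are continuous, measured from
the crop edge.

## Margin average μ(D)

μ(D) = (1/D)∫₀ᴰ g(E) dE by adaptive quadrature (`scipy.integrate.quad`,
absolute tolerance 10⁻¹⁰), deterministic across runs at well below the
4-significant-figure reporting precision; a 1 mm trapezoid grid agrees to
10⁻⁶ (test invariant).  μ(2) evaluates to 0.02100 against the published
0.0209 (0.5% relative, within the rounding of the published constants).
D = 0 is rejected: margin-free fields enter through the population mixture,
not through a degenerate average.

## Temporal coincidence

Larval-instar entry/exit days and pollen-shed start/end days are each
summarised by a bivariate distribution, assumed bivariate normal (the
distributional family is not stated in the source; normality is what makes
the stated 95% regions ellipses).  The multiplier *a* is the fraction of the
larval 95% ellipse overlapped by the pollen-shed 95% ellipse, computed on a
deterministic 500×500 grid over the larval ellipse's bounding box and
checked against a 10⁶-point rejection-sampling oracle to 0.005.  Although
the source text verbally defines *a* via the *non*-overlapped proportion, it
multiplies mortality by *a* and labels it "temporal coincidence": only the
retained-overlap reading keeps perfect coincidence from nullifying
mortality, so that reading is implemented.  Regional *a* values may also be
supplied directly as scalars, which is the primary input path (published
regional values were expert-elicited).

## Population level

Fields are assumed square, host plants randomly placed.  A *C*-ha field
with a *D*-m margin holds 10000·*C·e* exposed host plants within the crop
and 400·*D·f*·√*C* in the margin; the plant-weighted mean of *h* and μ(*D*)
simplifies to (25*e h*√C + *f D* μ)/(25*e*√C + *f D*) (identity verified to
10⁻¹² on random scenarios).  Margin-free fields (probability *q*) contribute
*h* alone; the q-mixture is the only reading that keeps the proportion a
valid plant-weighted average at q = 1.  The result is scaled by *x·a*
(physical effects, temporal coincidence) and *y·z·v* (host-plant share of
arable habitat, maize share of arable fields, MON810 share of maize).
Sublethality = min(4 × mortality, 1); the cap is a validity guard, not a
published constant.  Multi-year decline is projected as 1 − (1 − m)ᵗ
(compounded; linear approximation available), with m combining
per-generation mortality over the ≤2 generations coincident with pollen
shed: 0.5%/yr compounds to 4.89% ≤ 5% over 10 years.

## Aggregated deposition

Spatial clumping of pollen is Normal(0, **0.175**) noise on log₁₀ deposition
(≈12-fold 99% variation), applied before exponentiation, never to the
probability.  Monte Carlo uses `numpy.random.default_rng` with a single
user-supplied seed per sweep; 1000 replicates is the default study size,
while tests and the acceptance script use ≥10⁵ replicates or the
Gauss–Hermite quadrature evaluation (order 120) to push Monte Carlo error
below reporting tolerance.  Amplification exceeds 1 wherever deterministic
mortality is in the convex region (Jensen), grows with distance, and
approaches exp(s²σ²/2) ≈ 1.707 in the small-mortality limit.  Computed
values: butterflies 1.559 (E = 0) and 1.670 (E = 4.5), consistent with the
published 1.53–1.63; the moth evaluates to 1.617 (E = 0) and 1.686
(E = 4.5) against published 1.71–1.79.  The published moth multipliers
exceed the theoretical small-mortality ceiling for the shared slope 2.472,
so they cannot be reproduced under this calibration at any Monte Carlo size;
they would require a moth-specific slope near 2.6.  The package reports the
model-consistent values and records the difference here rather than
re-tuning the slope to the multiplier.

## Scenarios and synthetic data

A scenario document binds regional parameters (x, a, z, v, y, e, f, C, D, q)
to a species.  The packaged 11-region fixture is flagged `illustrative:
true`: the published per-region parameter values were expert-elicited and
never released, so the fixture picks plausible values within the published
per-species ranges (e.g. z ∈ [0.024, 0.7], C ∈ [1.1, 58] ha, D ∈ [1, 4.5] m)
and is *not* a reproduction of the published regional results table; its
estimates land in the same 0–6.4×10⁻³ range, which is the only assertion
made of it.  The synthetic generator samples uniformly within those ranges,
fixes v = 0.8 (the worst-case uptake rule applied outside Spain), and since
no range was published for q, samples q ~ U[0, 0.5].  Spanish regions are
encoded with e = 0, trace margin density and (for the butterflies) y = 0,
driving mortality to zero through the multiplicative chain — matching the
field observation of essentially no host plants at pollination time.

Uniform sampling within ranges reproduces the *spread* of regional
conditions but not their empirical joint distribution (real regions
correlate e.g. field size with margin practice); passing tests therefore
show the machinery is correct across the plausible parameter box, not that
any particular region's published estimate is recovered.

## Reporting

Results CSV uses three-significant-figure scientific notation, column order
region, species, h, mu, adjusted crop/margin individual rates, population
mortality, sublethality.  Quadrature problem sizes used by the acceptance
script: 100-point margin-width sweeps over (0, 10] m and 2×10⁵ Monte Carlo
replicates per amplification factor.
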