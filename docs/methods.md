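# Methods

## Geometry and units

Raw measurements are two orthogonal opening diameters (transverse,
sagittal; mm) and a depth (mm) per spiracle. The opening area is the
ellipse on the two *full* diameters, A = π·d₁·d₂/4. The alternative
literal reading of "semi-axes = diameters" (A = π·d₁·d₂) inflates area
four-fold and fails the circle limit (d₁ = d₂ = 2r must give πr²); it
is kept behind `literal_semi_axes=True` strictly for sensitivity
analysis. All diffusive biophysics is done in cm (Krogh constants are
per-cm), advection in SI, with every conversion factor in
`spiroscale/units.py`.

Whole-animal capacities require all eight spiracles. A specimen with
missing labels is a hard error rather than a silent partial sum;
imputation by conspecific means is available but opt-in
(`impute_from=`). Per-spiracle regressions simply drop specimens
lacking that spiracle.

## Physical constants

All frozen at 25 °C (no temperature correction is applied):
D = 0.178 cm² s⁻¹ (O₂ diffusivity in air), β = 404 nmol cm⁻³ kPa⁻¹
(capacitance coefficient of O₂ in air), μ = 1.86 × 10⁻⁸ kPa s
(dynamic viscosity of air), 20.7 μJ nL⁻¹ O₂ (RQ 0.85),
24.5 nL nmol⁻¹ (molar volume at 25 °C). The energy/volume conversion
pair is sometimes quoted as "20.7 kJ/l and 24.5 mol/l", which is
dimensionally inconsistent (24.5 mol/l would be a liquid-like
concentration); the per-nL/per-nmol chain used here is the coherent
one and reproduces the standard conversion 1 μW = 1/(20.7·24.5)
nmol O₂ s⁻¹. Constants are overridable through `PhysicalConstants`
and the YAML config.

## Demand model and required gradient

Resting metabolic rate: log₁₀(MR μW) = 3.2 + 0.75 log₁₀(m g). A
scenario is (AS, EXP): demand = 10^(log₁₀ AS + 3.2 + EXP·log₁₀ m),
converted to nmol s⁻¹, divided by the summed-and-doubled diffusive
conductance to give the required ΔP_O2. At m = 1 g the flight/rest
ratio is exactly AS and EXP is inert — both are contract tests.
Defaults: rest (AS = 1, EXP = 0.75), flight (AS = 90 with EXP = 0.67
or 1.19, spanning the published range of insect flight scaling; 90 is
the median of reported beetle aerobic scopes 80/90/110).

ΔP_O2 curves over a mass grid (200 log-spaced points by default) are
evaluated from the fitted total-conductance regression line rather
than from individual specimens: curve endpoints are then statements
about the fitted allometry, not about whichever specimen happened to
sit at the extreme. Per-specimen values are available in the
capacities table. The mass where a scenario crosses the 21 kPa
atmospheric ceiling has a closed form,
m* = 10^((log₁₀21 − a)/(EXP − b)) with a, b derived from the demand
and conductance lines; it is infinite when conductance scales at
least as fast as demand.

## Scaling inference

Fits are ordinary least squares on log₁₀–log₁₀ axes, residual sd with
the n−2 denominator, specimen (not species mean) as the unit of
analysis. Isometric references follow the conventional rounded values
0.67 (area), 0.33 (depth and area/depth), 1.0 (area²/depth). Note a
small internal tension of that convention: 0.67 − 0.33 = 0.34 and
2·0.67 − 0.33 = 1.01, so a generator built on exponents 0.67/0.33
produces index slopes of 0.34/1.01, not 0.33/1.0. Tests therefore
check recovery of the generating exponents, and exact p = 1 behaviour
only where reference and truth coincide.

Uncertainty:

- **Bootstrap** — case resampling of (mass, value) pairs, B = 10,000
  by default, percentile intervals with linear interpolation between
  order statistics (numpy's `quantile(..., method="linear")`, fixed
  for reproducibility), seeded. Resamples in which every mass
  coincides leave OLS undefined; they are redrawn and the redraw count
  logged. p-values against a reference slope are two-sided:
  2·min(frac ≤ ref, frac ≥ ref), clipped to 1. The bootstrap interval
  is reported at 2.5–97.5%.
- **Bayesian** — normal likelihood with line mean; priors
  slope ~ N(0, 5), intercept ~ N(0, 5), σ ~ HalfNormal(1) on the
  log₁₀ scale (weakly informative; overridable). Sampling uses an
  affine-invariant ensemble (emcee): 24 walkers, 500 burn-in steps,
  ≥500 retained steps, thinned to the requested number of draws;
  seeded and exactly reproducible. Effective sample size per
  parameter is computed (arviz) and a minimum-ESS flag (default 100)
  marks non-convergence on the result rather than silencing it. HPD
  intervals are reported at 0.95 and, matching a common display
  convention, 0.94 (3rd–97th).
- **Relative variability** — residual sd divided by 10^intercept (the
  predicted trait at 1 g), reported as the point value plus the
  median and 2.5–97.5 percentile summary over bootstrap samples.

The fit report covers 8 spiracles × 4 metrics (depth, area,
area/depth, area²/depth) plus the two whole-animal totals: 34 rows.

## Phylogenetic comparative layer

Trees are newick (dendropy behind the module surface); branch lengths
can be forced to one, the standard fallback when true lengths are
unknown — and the default whenever the input carries none. The
shared-ancestry covariance over *specimens* has diagonal = tip depth
and off-diagonal(i,j) = λ·(shared root-to-MRCA branch length of the
two species); conspecific specimens share the full tip depth, so a
relative diagonal jitter (default 10⁻⁶) keeps the matrix invertible.
λ multiplies off-diagonals only (Pagel's transform). pGLS solves
(XᵀV⁻¹X)⁻¹XᵀV⁻¹y via Cholesky; a singular V raises with the condition
number. Polytomies are allowed and never resolved.

λ identifiability is profiled over a grid in [0, 1] with ML plug-ins
(β̂(λ), σ̂² = RSS/n). The declared identifiability threshold is a
profile range of 2 log-likelihood units, the χ²₁/2 95% cutoff: below
it no grid value of λ can be rejected against the best one. Two
subtleties:

- A perfectly constant response has zero residual variance at every
  λ; the profile is reported as exactly flat (zeros) with a
  `degenerate` flag instead of the formal +∞.
- With replicate conspecifics, the *specimen-level* profile is
  dominated by within-species disagreement: λ → 1 forces conspecifics
  to be near-identical, so any within-species scatter rejects it by
  tens of log-likelihood units regardless of ancestry. That steepness
  is real but answers the wrong question. `level="species"` collapses
  replicates to species geometric means first; at the default design
  (17 specimens, 10 species) that ancestry-level profile is flat in
  most simulated studies — the design cannot inform λ — which is why
  the pipeline's default is plain OLS/bootstrap/Bayes with the
  phylogenetic layer behind a flag.

A uniform-prior/grid-posterior overlap summary
(`lambda_prior_posterior_overlap`, 1 = posterior indistinguishable
from prior) gives the Bayesian reading of the same diagnostic, using
the profile likelihood as a plug-in marginal.

## Synthetic data generator

The generator emulates the structure of a small interspecific
morphometric study: 10 species, 1–2 specimens each (17 total), species
masses log-uniform on 0.097–18 g with a 0.05 log₁₀ within-species
jitter; per spiracle, log₁₀ dimension = intercept + exponent·log₁₀
mass + optional Brownian species deviation (simulated on the tree,
scaled by `lambda_signal`) + independent N(0, sd) noise. Diameters are
emitted with a fixed transverse/sagittal ratio of 2 (slit-like
openings) such that the ellipse formula recovers the target area
exactly. Defaults encode the study conditions: isometric truth (area
0.67, depth 0.33); area weights S:T:A1–A3:A4–A6 = 4:1:1:0.5 with the
absolute scale set so a 1 g animal's doubled summed area/depth is
≈0.25 cm — chosen so the resulting resting ΔP_O2 spans the realistic
~0.05–0.5 kPa over the mass range; area noise tightening anteriorly
(0.05 at S up to 0.25 at A6) and uniform depth noise (0.08). Trees
are uniform random pairwise joins with unit branch lengths.

What the generator does *not* emulate: measurement error correlated
across spiracles within a specimen, sexual dimorphism, non-power-law
(e.g. segmented) allometries, real scarab topologies, or meaningful
branch lengths. Passing tests therefore demonstrate correctness and
calibration of the machinery under the stated statistical structure,
not agreement with any real specimen.

## Problem sizes and numerical choices

Simulation-based checks use: 500 replicates for bootstrap-coverage
estimation (B = 2,000 inside each), 200 for Bayesian HPD calibration,
300 for generator parameter recovery, 40 for λ-flatness frequency —
sizes at which the binomial error of an estimated rate is ~1–2 points.
Bootstrap CI endpoints are order statistics and re-derivable from the
retained sample arrays; all samplers take explicit integer seeds and
the full pipeline is byte-identical across reruns with equal seeds.

## Known limitations

- The percentile bootstrap undercovers at this sample size: measured
  across 2,000 simulated studies (n = 17, log₁₀ noise 0.1), the
  nominal 95% slope interval covers the generating exponent 92.4 ±
  0.6% of the time. This is the familiar small-sample behaviour of
  percentile intervals, shared with the original-scale analysis it
  mirrors; treat 95% intervals at n = 17 as mildly optimistic. (The
  Bayesian HPD calibrates at ≈96% in the matching simulation.)
- The spiracle is modelled as a straight cylinder; valves, the
  bellows-shaped atrium and any interaction between neighbouring
  spiracles are out of scope, as is airflow simulation through the
  tracheal network.
- pGLS assumes the λ-scaled Brownian covariance is correct up to
  scale; no Ornstein–Uhlenbeck or measurement-error models are
  provided.
- The Bayesian sampler is a general-purpose ensemble method; for the
  3-parameter regression it converges comfortably (ESS flags guard
  the exceptions) but it is not a gradient-based sampler and very
  small noise scales may need more steps.
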