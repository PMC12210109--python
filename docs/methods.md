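# Methods notes

## Scope and data model

The package analyzes period-averaged daily intakes of animals (or
cages) restricted to fixed-formula diets. A diet is a point in mixture
space: mass fractions of protein, digestible carbohydrate, fat, and a
single noncaloric diluent class (cellulose, which also absorbs
minerals/vitamins/moisture when compositions are derived from
ingredient lists). All percent-energy quantities are derived on demand
from the mass fractions and the energy conversion factors; they are
never stored, so the two representations cannot drift apart. "Percent
protein" is deliberately ambiguous in the field — by energy in linear
intake models, by mass in the leverage power law — so the API exposes
`pct_energy_protein` and `frac_protein` as distinct named quantities
and no operation accepts a bare "percent protein".

## Energy conversion factors

Defaults are protein = carbohydrate = 16.7 kJ/g, fat = 37.7 kJ/g,
cellulose = 0 kJ/g. They are the unique solution of the linear system
formed by two worked diet densities (a 25/70/5 protein/carb/fat diet at
17.75 kJ/g; a 10/70/20 diet at 20.9 kJ/g), verified by an independent
`numpy.linalg.solve` in the test suite. Cellulose is treated as
nondigestible (0 kJ/g); a nonzero factor can be configured for
sensitivity analysis. Factors are validated to be nonnegative with
fat strictly denser than protein.

## Synthetic data generator

The generator is the test bed for every downstream stage; it emulates
the *geometry* of two published designs, not their exact recipes.

* `solonbiet25`: 10 energy-share triples on an even grid spanning
  protein 5–60%, carbohydrate 20–75% and fat 20–75% of energy, realized
  at 17 and 13 kJ/g (all ten) and 8 kJ/g (five of them) by cellulose
  dilution — 25 diets, the 17 kJ/g tier being the isocaloric subset.
  Units are cages of three same-sex animals; intakes are per-animal
  daily means.
* `hu29`: four series over 29 diets — series 1/2 span 5–30% protein
  energy at 60% or 20% fat energy; series 3 (10% protein) spans 10–80%
  fat energy in ten steps; series 4 (25% protein) spans 10–70% in seven
  (80% fat is unreachable at 25% protein since energy shares must sum
  to one). Every diet carries a 9% noncaloric residual by mass,
  representative of micronutrient premixes and fiber; with the default
  factors this places the six series-2 diets plus the five lowest-fat
  series-3/4 diets in the 15.9–18 kJ/g near-isocaloric band (11 diets).
  Units are single-housed animals.

Intake on a diet with protein mass fraction `p` has expectation
`P·p^L`. Noise is multiplicative lognormal with unit mean and
configurable coefficient of variation (intake is positive and
right-skewed). The default `noise_cv = 0.10` is a free choice — no
residual magnitude is available for either study design — and is
recorded in every simulation config. The fitting modules assume
additive Gaussian residuals; that mismatch is intentional and is part
of what the calibration tests probe (they confirm the leverage
estimator stays unbiased and its tests near-nominal under it).

A between-study elevation of `study_offset_kj` kJ/day is applied as an
*additive food-mass offset* `δ = offset / mean(energy density over the
design)`, so the mean energy-intake gap across the design equals the
configured value exactly, while regression slopes against protein
content are untouched on isocaloric designs. A multiplicative offset
was considered and rejected: it rescales the whole leverage curve and
would make slope-homogeneity across studies false by construction.

What the generator does **not** emulate: body-mass dynamics, sex or
strain effects (hooks exist via the labeled columns, defaults are
zero), within-animal time series, appetite breakpoints at extreme
protein dilution, and palatability phenomena. Passing tests therefore
show estimator and test behavior under the stated stochastic model,
not agreement with any real dataset.

## Leverage models

`fit_power_leverage` minimizes squared error of `P·p^L` via
Levenberg–Marquardt with starting values (median intake, log-log OLS
slope), relative tolerance 1e-8 and a 200-iteration budget;
non-convergence flags the result rather than raising mid-pipeline.
Standard errors come from the Jacobian at the optimum
(`σ²(JᵀJ)⁻¹`), and the test of `L = 0` is the asymptotic t statistic
with `n − 2` degrees of freedom. The log-log closed form doubles as an
independent oracle: on noiseless data both routes agree to 1e-6. The
predictor defaults to protein proportion by mass (the convention of
the substitution forecast); a by-energy switch exists, the code path
being identical since both live in (0, 1].

Linear fits and the between-study models are ordinary least squares
(statsmodels): elevation from `intake ~ study`, slope difference from
`intake ~ protein × study`, each Wald-tested. Observations enter
unweighted; cage-level means are single observations; p-values are
reported raw without multiplicity correction, and are labeled as such
in serialized output.

`fit_log_ratio` regresses intake on `ln(protein : diluent)` by mass
with cellulose or fat as diluent. Diets with a zero diluent fraction
are excluded and counted. The noncaloric-vs-caloric diluent contrast
separates protein-dilution feedback from energy-density effects: under
a pure leverage model, food-intake slopes match for the two diluents,
while only fat dilution raises energy intake.

## Response surfaces

No installed Python package provides penalized *bivariate* smooths, so
the smoother is implemented here as a thin-plate regression spline:

* radial basis `η(r) = r² log r` on standardized (x, z), knots at the
  distinct design points (thinned to at most `k = 25` by deterministic
  farthest-point sampling — designs project many diets onto the same
  (x, z) point, so the effective knot count is usually 11–29);
* unpenalized null space `[1, x, z]`; the bending-energy penalty is
  projected onto the constraint subspace and clipped to positive
  semidefinite;
* the smoothing parameter minimizes GCV `n·RSS/(n − edf)²` over a
  91-point log-spaced grid (descending, so ties resolve to the
  smoother fit), via a one-time simultaneous diagonalization that makes
  the whole path cost one eigendecomposition;
* `beta0` is the fitted value at the design's mean (x, z);
  `smooth_edf` is the trace of the hat matrix minus the 3 null-space
  dimensions, so a flat fit reports ≈ 0.

Significance of the smooth (`p_smooth`) is the exact OLS F-test of the
unpenalized spline basis against the intercept-only model. Approximate
edf-based tests on GCV-selected penalized fits are known to be
miscalibrated; the exact F-test is size-correct under Gaussian errors
by construction, and simulation under the lognormal noise model
confirms a rejection rate close to nominal. The reported surface,
`smooth_edf` and `σ²` still come from the penalized fit. On simulated
leverage data the fitted values track R mgcv's
`gam(y ~ s(x, z))` to within a few percent of the response SD
(cross-checked in the test suite; mgcv is an oracle there, never the
implementation).

Grids (default 40×40) are masked to the convex hull of the observed
design points. A lattice cell counts as inside when its center is
within half a cell diagonal of the hull, i.e. when the cell's *region*
touches sampled space; masking is therefore exact up to lattice
resolution, and no wholly-exterior cell ever carries a fitted value.
The axes-collinearity precondition (|r| ≥ 0.95 across design points)
refuses designs in which protein and nonprotein energy density cannot
be separated, naming the fat/energy-density confound that motivates
it. Grouped fits (strain, sex, study) are independent per group with
shared color-scale metadata; groups failing preconditions are skipped
with a logged reason. Sexes are pooled raw by default; the grouped fit
is the alternative.

## Substitution forecast

`forecast` evaluates `P·p^L` on a protein grid and converts to energy
under two substitution regimes: isocaloric (density pinned to a
reference, default 17 kJ/g) and gram-for-gram fat substitution
(carbohydrate fixed, fat absorbing the removed protein mass;
compositions leaving the simplex raise an error naming the grid
point). All arithmetic is full precision. `cumulative_difference`
multiplies the daily energy gap by the horizon (12 weeks = 84 days);
its `printed_precision` mode first rounds daily energies to 0.1 kJ,
reproducing published arithmetic chains that accumulate rounded daily
values (15.7 × 84 = 1318.8 rather than the full-precision 1322.1). The
default grid is 100 log-spaced points on [0.05, 0.60] (the sampled
protein range), truncated to [0.05, 0.30] in fat-substitution mode
where the reference composition caps the protein + fat budget.

## Pipeline

`run_reconciliation` executes the stages in a fixed order and aborts at
the first unmet precondition with a stage name and machine-readable
code. All randomness derives from one root seed through
`numpy.random.SeedSequence.spawn`; the resolved config, its hash, the
seed and the package version are written beside every output, and
rerunning with the same seed reproduces the manifest exactly. The
forecast stage uses the *fitted* (P̂, L̂) of the lead study, so the
end-to-end run demonstrates the whole chain from simulated raw intakes
to the cumulative-energy forecast.

## Problem sizes used in the checks

Calibration checks use 200 Monte-Carlo replicates at `n_per_diet = 20`
(leverage recovery, CI coverage, type-I error, study comparison) or
`n_per_diet = 5` (flat-surface null), sizes at which the whole suite
completes in well under a minute while Monte-Carlo error on a 5%
rejection rate is about ±1.5 percentage points — the acceptance bands
of [3%, 8%] reflect that. Surface-topography checks use
`n_per_diet = 20` over five seeds. The "low/high" argmax regions are
defined on hull-normalized coordinates: protein below 0.2 of its
observed range; nonprotein below 2/3 (food) or above 0.8 (energy) —
the asymmetry exists because low-protein cells of the solonbiet25 hull
geometrically exclude the very lowest and very highest nonprotein
values, and food intake under the generative model is flat along the
nonprotein axis, so its argmax position within the low-protein strip
is noise-determined within those bounds.

## Known limitations

* The leverage SEs are asymptotic; no profile or bootstrap intervals.
* No mixed-effects structure for cage clustering; cage means are
  independent observations, matching the unit of analysis convention.
* The smoother's F-test discards the penalization when testing, trading
  a little power for exact size; it also requires replicate
  observations (it is undefined when the basis saturates the data).
* Diet designs are generated on even grids; users wanting exact
  published recipes must supply them as CSVs.
* The two-axis surface cannot attribute effects separately to
  carbohydrate and fat; that is a property of the (x, z)
  parameterization, not of the smoother.
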