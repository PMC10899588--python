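# Methods

This note records the models implemented in `herbtox`, their assumptions,
the defaults and the numerical choices, in the order the pipeline runs.

## Single-substance dose-response (`herbtox.dose_response`)

Responses are inhibition fractions relative to the mean control response
(raw fluorescence F is converted upstream as 1 − F/F_control); values outside
[−0.1, 1.1] are rejected as data errors rather than clipped. Two families are
fitted on the log10 concentration scale:

* logistic  E(c) = θ/(1 + e^{−(α+β·log10 c)})
* weibull   E(c) = θ·(1 − e^{−e^{α+β·log10 c}})

with θ ∈ (0, 1] the maximal effect and β > 0. Both are strictly increasing
with E(0) = 0 taken explicitly as the log-scale limit. Zero-concentration
controls are excluded from the fit (they carry no information on the log
scale) and at least 4 distinct nonzero concentrations are required.

Sigmoid least-squares surfaces are multimodal, so the optimizer
(`scipy.optimize.least_squares`, bounds θ ∈ (0, 1], β > 0, tolerances 1e−14)
is seeded from the best point of a coarse grid over α ∈ [−6, 6] (25 points),
β ∈ {0.5, 1, 2, 4} and θ ∈ {0.6, 0.8, 1.0}. On noiseless model-generated
data the generating parameters are recovered to ~1e−10 relative error.
Datasets whose responses span ≤ 0.01 are flat — they carry no dose signal and
are reported as non-converged rather than fitted to an arbitrary curve.

Family selection is by AIC, computed as n·ln(RSS/n) + 2k with k = 4
(three curve parameters plus the error variance); RSS is floored at 1e−30 so
noiseless fits keep a finite criterion. Ties break toward the logistic
family. ECx uses the closed-form inversions of both families.

The fitted panel is persisted as a versioned YAML list of records
(family, θ, α, β, RSS, AIC per herbicide); a list rather than a mapping so
duplicate names are detectable on read, and floats round-trip at full
precision.

## Mixture toxicity and atrazine equivalents (`herbtox.mixture`)

Concentration addition is the only mixture model implemented — the assumed
shared mode of action of the triazine panel (photosystem II inhibition)
justifies it, and no interaction (synergy/antagonism) terms are considered.
The mixture effect x* solves Σ c_i/ECx_i(x) = 1. The toxic-unit sum is
strictly decreasing in x (every ECx is increasing), so the root is unique; it
is bracketed on (1e−8, min θ − 1e−8) and solved with Brent's method to an
x-tolerance of 1e−12, which keeps the toxic-unit residual below 1e−8.
Mixtures whose toxic units still exceed 1 at the top of the bracket act above
the smallest attainable maximum; they are flagged with a warning and returned
at the bracket top rather than extrapolated.

TEQ = ECx_ref(x*) with atrazine as reference. The fixed-ratio TEF shortcut
Σ c_i·EC50_ref/EC50_i is retained because it is common practice and exact for
parallel curves, but it is labelled approximate: the full CA solve is the
primary conversion. Below-LOQ concentrations enter as zero.

## Community curve and station mapping (`herbtox.impact`)

The community-level concentration-response relationship is *defined* as the
monotone shape-preserving interpolant (PCHIP) through the three calibration
anchors (5.1, 5%), (11.9, 10%), (35.2, 25%) in (log10 concentration, logit
inhibition-fraction) space. This representation is exact at every anchor in
both directions, strictly monotone, linear in the transformed space beyond
the outer anchors (using the interpolant's endpoint slopes), and clamped to
[0, 99.9]% — the logit transform guarantees predictions never reach 100%.
The headline exceedance statistics depend only on the anchors, not on the
interpolation between them. Inversion is by bracketed root finding in log10
concentration (xtol 1e−14, anchors reproduced to better than 1e−9).

Per-station inhibition is curve(TEQ(station)); stations with every herbicide
below the LOQ are retained with TEQ 0, so they dilute regional medians.
"Inhibited by more than x%" uses strict inequality.

Regional summaries use the linear-interpolation quartile convention
(`numpy.quantile` default, documented because conventions differ) and a
percentile bootstrap of the median (B = 2000 by default, seeded per region
from a fixed spawn key; single-station regions are flagged degenerate). The
chronological trend test is a one-way ANOVA across the stages 1990–2000,
2001–2011, 2012–2022, computed from explicit between/within sums of squares
with the p-value from the F distribution; regions lacking 2 stages with
≥ 2 stations are flagged, not raised. `scipy.stats.f_oneway` serves as an
independent oracle in the tests, never as the implementation.

The coastal carbon-loss arithmetic multiplies a productivity-decline
fraction (default 5%), the coastal share of global marine primary production
(default 25%) and the global fixation range (default 3–7 × 10^10 t C/yr).

## Dilution method (`herbtox.dilution`)

The estimator is ordinary least squares of the apparent growth rate
k = ln(P_t/P_0)/t on the dilution fraction D, per size class; μ is the
intercept, g the negative slope, NGR = μ − g computed from the estimates so
the identity holds bitwise. Replicates enter as individual points (no
pre-averaging). Standard errors come from the usual OLS covariance (NaN with
only two points); r² is defined as 1 for an exact fit to constant data so
the no-grazing case is well behaved. A negative g estimate (apparent inverse
grazing) is reported as-is with a flag — truncation would bias μ.

The simulator draws P_t(D) = P_0·e^{(μ−D·g)t} with multiplicative lognormal
noise (log-sd `noise_sd`), chosen because chlorophyll readings are positive
and right-skewed. The recorded initial biomass is the supplied P_0 for every
bottle, matching the model equation; rescaling initials by D would not
change the recovered rates since k is computed per bottle. Defaults: t = 1
day (24 h incubations), dilutions {1.0, 0.8, 0.6, 0.4, 0.2}, triplicates.
The method assumes dilution does not affect growth and grazing is linear in
D; on noiseless model data the regression r² is exactly 1 and rates are
recovered to 1e−10.

## Risk score (`herbtox.risk`)

Dissipation is modelled as single first-order decay parameterized by DT50
(λ = ln2/DT50); DT90 is carried in the schema but redundant, since
first-order kinetics fix DT90 = DT50·log2(10). The exposure integral uses
the closed form −expm1(−λT)/λ (quadrature-checked in tests) over a
configurable horizon, default 365 days. The constants 4500 and 100 in the
PEC expression are reproduced verbatim from the source exposure indicator
without unit reinterpretation; PEC and PNEC are therefore "model units" and
only their ratio RQ is meaningful. RP = log10 ΣRQ — the decadic scale is
what makes the class boundaries 0, 1, 3 and their species-sensitivity
reading coherent. ΣRQ = 0 gives RP = −∞, classed negligible by convention.
Both soil (earthworm LC50) and water (fish LC50) compartments are computed;
the default aggregation takes the larger RQ of the two per pair
(configurable to either single compartment). Regional summaries report
area-weighted class fractions; zero-area cells are excluded from
denominators.

## Synthetic data (`herbtox.synthetic`)

The generators define the study conditions for all tests and for the
acceptance report.

**Curve panel.** Twelve triazine truth curves with EC50s spanning
4.3–849.1 nmol/L. Cybutryne and terbutryn are set 30× and 16× as potent as
atrazine, which pins atrazine's EC50 at 129 nmol/L and puts cybutryne at the
panel minimum 4.3 nmol/L; desethylatrazine takes the maximum 849.1 nmol/L
and the rest are spread between, with slopes 0.9–1.6 and a mix of logistic
and weibull families. θ is 1.0 throughout (whether real community fits cap
the asymptote below 100% is unknown; a full effect range is the conservative
choice for mixtures).

**Survey.** Seven sea areas with station counts (16, 128, 34, 271, 21, 168,
22; 660 stations total). Station totals are lognormal per region (log-sd
0.8) around region medians of 3.84 (Gulf of Mexico), 2.28 (East Asia), 1.64
(France) nmol/L for the three high-pollution areas and 0.025–0.30 nmol/L
for the remaining regions; totals are split across the 12 herbicides by a
Dirichlet draw (atrazine-dominated mean composition, concentration 30), and
multiplied by a stage factor (0.6, 1.0, 1.4 for the three chronological
stages) reflecting rising application. Per-herbicide left-censoring at LOQs
spread over 0.004–0.016 nmol/L records nondetects as zero. An optional
calibration rescales all concentrations by one factor so the dataset's TEQ
third quartile equals a requested value (default use: 5.09 nmol/L); the
factor is solved by bisection on the exact CA TEQ of the two order
statistics that the quantile interpolates. Stations are generated
independently — real surveys are spatially and temporally autocorrelated,
repeatedly sample the same bays, and mix analytical methods, so passing
tests here demonstrate correctness of the chain under the assumed
structure, not fidelity to any particular real dataset. In particular the
generated dataset-wide median total concentration (~0.4–0.5 nmol/L) is an
emergent property of the regional settings, not a calibrated quantity.

**Plates, dilution series, grids.** Plates add Gaussian noise (default
study condition sd 0.02) to the truth-curve effect over a two-fold
concentration series from 0.1 nmol/L, clipped to the accepted window.
Dilution series delegate to the simulator above. Grids come in a random
mode (lognormal application rates, 1–4 applications per cell) and a
planted-class mode that back-solves the application rate through the full
exposure chain so each cell's RP lands at the centre of a requested class
band, enabling exact recovery tests of class area fractions. The grid
property table carries plausible order-of-magnitude DT50/LC50 stand-ins,
not measured values.

## Problem sizes and determinism

Every stochastic routine takes a seed (numpy `default_rng`); the CLI and
acceptance script fan one top-level seed into per-stage streams via
`SeedSequence.spawn`. Default sizes — 660 survey stations, 60-well plates,
15-point dilution series, a few hundred to 2500 grid cells, bootstrap
B = 2000 (500–600 in the repeated coverage studies), 50-seed recovery
studies — keep the full test suite and the acceptance run at the scale of
seconds while leaving the statistical checks well-powered.

## Known limitations

* Concentration addition only; no independent action or interaction models.
* The community curve is anchored at three points; behaviour far outside
  5–35 nmol/L is a logit-linear extrapolation, not data.
* First-order decay is an idealization; biphasic dissipation would need a
  different exposure integral.
* The risk chain's absolute PEC/PNEC values are unitless model quantities;
  only RQ and RP comparisons are meaningful.
* Below-LOQ values are treated as zero rather than imputed, which biases
  sums slightly low at clean stations.
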