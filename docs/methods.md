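# Methods

## Gas-phase accounting

All conversions between meter readings (ppm v/v) and amounts of HCN use the
ideal-gas molar volume at STP, fixed at 22.4 L/mol: a chamber of volume *V*
litres at *p* ppm holds *p·V/22.4* μmol HCN. No temperature or pressure
correction is applied; field chambers are treated as being at standard
conditions, and the error from tropical field temperatures (~2% at 30 °C)
is far below the meter's own noise. All computation is double precision;
rounding happens only at presentation.

Default chamber volumes are 0.143 L (snap-lid cup), 0.052 L (mortar-pestle
unit) and 9.6 L (desiccator jar), overridable per sample or via config.
Amygdalin (457.4 g/mol, one mole HCN per mole on hydrolysis) is the bundled
standard: 59.09 μg HCN per mg. Other cyanogen standards are a
`CyanogenStandard(name, molecular_mass, hcn_stoichiometry)` away.

## Reduction of reading series

The evacuation protocol is modelled as complete chamber turnover: each
reading removes everything accumulated since the previous one and replaces
it with HCN-free air. A sample's total release is therefore the sum of its
readings converted to μmol. Readings strictly below the 0.3-ppm detection
limit are kept in storage (the stopping observation is data) but excluded
from totals and from the duration statistic: the meter cannot quantify
them, and the field protocol terminates the series there.

All real-world loss pathways of the open protocol — incomplete outgassing
during the pumping window, leakage, partial turnover — are absorbed by one
empirical multiplier, the calibration factor (default 10.2), estimated by
the fixed-ratio method below against a fully closed jar. We deliberately do
not model those pathways separately; the factor is exactly how the field
calibration is defined.

The weighted mean release duration D = Σ tₙ·ppmₙ / Σ ppmₙ uses times in
minutes since crushing. Its minimum is the first sampling time (5 min under
the cup protocol), it always lies within the span of positive reading
times, and it is invariant under rescaling of all ppm values. Samples are
classed *slow* when D exceeds a threshold (default 20 min, chosen midway
between the observed fast cluster at 5–10 min and the slow species at
~40 min). Depletion times for high-frequency jar series are computed by
linear interpolation after the peak; a series that never crosses the
threshold is flagged rather than extrapolated.

## Calibration statistics

**Fixed-ratio method comparison.** If two methods measure the same quantity
up to a constant factor ρ with multiplicative error, then
log₁₀y = b + s·log₁₀x with s = 1 and ρ = 10^b. We fit by ordinary least
squares on the log scale and report the slope with SE, R², and two separate
two-sided t-tests (slope vs 0 and slope vs 1, df = n−2) — conflating these
two hypotheses is a common reporting error, so both p-values are exposed.
Pairs with a non-positive member cannot enter a log fit and are dropped
with a logged count; at least three positive pairs are required.

**Standard curves.** OLS of standard mass (mg) on meter ppm, with the slope
also expressed as μg HCN per ppm through the standard's stoichiometry, and
inverse prediction of mass from a reading. A degenerate design (all ppm
equal) raises rather than returning a singular fit.

**Polynomial trend error.** Precision of a series of related measurements
(leaves along a branch) is the RMSE about a fitted quartic, expressed as a
percentage of the fitted curve's range over the observed positions. The
fitted-curve range matches how the published precision tables are labelled;
a raw-data-range variant is available. RMSE uses the population mean of
squared residuals (no df correction). Degree is 4 by default, overridable;
n ≥ degree + 2 distinct positions are required.

**Published-data comparison.** Literature concentrations in μg HCN per g
dry weight are mapped to μmol per g fresh weight by a single combined
factor (default 0.00769305 ≈ 0.208/27.03, i.e. an assumed dry:fresh tissue
mass ratio of 0.208). The factor was frozen as the zero-intercept
least-squares map between the two concentration columns of the bundled
species-comparison table and is exposed as a parameter because it encodes
an assumed water content, not a physical constant. Species means are
compared by a two-sided paired t-test on (published − calibrated cup) and
an OLS R² between the two mean vectors. No multiple-testing correction is
applied anywhere (single planned comparisons).

## The simulator

Release kinetics are a two-exponential mixture with a lag: fraction *f* of
the releasable pool q_total outgasses at k_fast and the rest at k_slow,
starting L minutes after crushing. This is the simplest form that
reproduces the three observed patterns: the common fast release (sharp peak
~2 min after crushing), the rare hour-scale slow release, and a dual-release
mixture. Chamber headspace obeys dC/dt = Q′(t)/V − λC; the first-order sink
λ stands in for sensor consumption and wall adsorption in closed jars —
the decline after the peak is observed but its mechanism is not, so the
sink is a modelling choice, not a claim. Everything is evaluated from the
analytic two-exponential solution at the reading times; there is no ODE
solver and no step-size tolerance.

The meter model applies, in order: per-evacuation recovery efficiency (cup
protocol only; 1/10.2 emulates the mechanism the calibration factor
corrects), multiplicative lognormal noise with unit mean and configurable
CV, quantization to the meter's 0.1-ppm display step, and the 0.3-ppm
detection floor, which terminates cup series at the first below-limit
reported reading (emitted and flagged, mirroring field practice). Identical
parameters and seed give identical series.

Scenario presets are tuned to the observed closed-jar kinetics: the fast
preset (k_fast = λ = 1.3/min, lag 1.5 min) peaks ≈ 136 s after crushing and
reaches 90% depletion ≈ 316 s; the slow preset (k_slow = λ = 0.06/min)
reaches 95% depletion ≈ 96 min. The default community scenario draws
per-gram totals log-uniformly within five strata spanning 0.01–15 μmol/g
plus an acyanogenic stratum (sample masses 0.05–0.25 g, 5-min cup readings,
5% meter noise), emulating the four-order-of-magnitude spread seen across a
real *Passiflora* community.

What the simulator does **not** emulate: β-glucosidase enzymology (pH,
temperature, enzyme limitation), within-leaf spatial heterogeneity,
meter sensitivity drift over months of use, and cross-sensitivity to other
gases. Passing recovery tests therefore show that the reduction and
calibration pipeline is self-consistent under the stated error model, not
that a field meter is unbiased.

## Parameter recovery

`recover_parameters` is a simulation self-check, not a field estimator. For
jar series it fits the analytic single-exponential chamber model (sink rate
taken as known from the measurement parameters) by nonlinear least squares
for (q_total, k, lag); for cup series it inverts the evacuation sums with
the known recovery efficiency and reads the rate off the weighted duration.
Series with fewer than three positive readings are flagged unidentifiable.

## Problem sizes and numerical choices

Monte Carlo checks use 200 replicates for regression-recovery medians and
30–50 for nonlinear parameter recovery — enough for stable medians at the
tolerances tested. The demo's paired calibration experiment uses 30
split samples with σ_log10 ≈ 0.04 (CV 10%) reading noise and estimates each
jar total from the mean of the final plateau readings rather than the
maximum, which noise would bias upward. Ties at a depletion threshold
resolve to the earlier time; a reading exactly at the detection limit is
quantifiable; a duration exactly at the kinetics threshold is *fast*.

## Known limitations

* The calibration factor is treated as species- and humidity-independent;
  the published validation suggests species-level deviations of up to ~2×.
* Cup-protocol data cannot resolve release kinetics finer than the 5-min
  reading interval; only jar series support depletion-time analysis.
* The dry→fresh conversion assumes one global tissue water content; real
  leaves vary, so cross-study comparisons inherit that assumption.
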