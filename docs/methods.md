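# Methods

This note records the models, parameter choices and numerical decisions
behind `pmrisk`, and what the synthetic-data tests do and do not establish.

## Synthetic campaign generator

The generator emulates a ~104-day winter PM2.5 filter campaign
*statistically*. Each analyte is marginally lognormal, parameterised by its
median and geometric standard deviation (GSD). The campaign literature for
these analytes reports only ranges and arithmetic means, so the lognormal
form is this package's choice: concentrations are strictly positive and
right-skewed, and the risk literature reports medians/GSDs. The shipped
defaults are calibrated once from the published summaries:

* log-scale sigma from the published (min, max) by the range rule — the
  expected span of n ≈ 104 standard-normal draws is ≈ 5.2 sigma — giving
  GSDs of ~1.73 (SCCPs), ~1.76 (MCCPs), ~2.47 (LCCPs) and ~2.20 (EPFRs);
* medians back-computed from the published arithmetic means via
  median = mean / exp(sigma²/2);
* co-pollutants (PM2.5/PM10/SO2/NO2/O3/CO) at typical winter urban levels.

Cross-analyte dependence is imposed by a Gaussian copula on ranks,
targeting **Spearman** (not Pearson) correlation because that is what the
campaign statistics report; the latent Pearson correlation is
2·sin(π·ρ_s/6). The target matrix uses published pairwise values where they
exist (CP classes vs EPFRs 0.24/0.33/0.19, vs NO₂ 0.27/0.47/0.26, CPs vs
O₃ −0.32, particulate-matter links) and plausible winter co-pollution
values elsewhere; it is checked positive semidefinite, with
eigenvalue-clipping repair (`nearest_psd`) offered as an explicit opt-in,
never applied silently.

Congener-group profiles are Dirichlet draws whose means equal the published
mean shares (e.g. SCCP carbon-chain C13/C11/C12/C10 =
0.4096/0.2541/0.2289/0.1074) with a precision of 300, i.e. per-day share
scatter of a few percent; chlorine-number shares peak at Cl6/Cl7 and
chlorine content is normal around 58.40/53.68/51.23% for S/M/LCCPs (sd 1
point). Meteorology is an annual sinusoid plus noise with winter-typical
parameters — it exists to exercise the correlation screens, with no claim
of realism.

What a green test on this world establishes: the *pipeline arithmetic* is
correct and stable under realistic marginals, dependence and noise. What it
does not establish: anything about real Shijiazhuang time series —
autocorrelation, pollution episodes, seasonal breaks and instrument
artefacts are all absent.

## EPR quantification

Spectra are first-derivative Gaussian lines. Baseline correction fits a
polynomial (order ≤ 3) to the outer 10% of the sweep on each side, leaving
a centred resonance untouched and making the operation idempotent. The
lineshape fit is plain least squares of the analytic derivative-Gaussian;
g = h·ν/(μ_B·B₀) with CODATA h and μ_B.

Double integration uses the cumulative trapezoid twice — the field
standard for first-derivative EPR — with two noise guards: (i) integration
is restricted to ±5 line widths around the fitted centre (truncating
< 10⁻⁶ of the area while keeping the noise random-walk variance, which
grows with the cube of the window length, bounded); (ii) the absorption
curve is re-baselined by a straight line anchored in its wings before the
second integration. With these guards, 100 seeded spectra at
signal-to-noise 20 recover the true spin count within 5% (worst case ~4%).
The calibration curve is ordinary least squares with a free intercept; on
ideal standards the intercept vanishes, and tests assert that.

The synthetic spectrometer's sensitivity (double-integral area per spin) is
an arbitrary constant (10⁻¹²); real calibrations replace it via measured
TEMPOL standards. The default filter geometry — 406.5 cm² exposed area of
an 8"×10" high-volume filter, three 1.2 cm² punches, 1512 m³ of air (1.05
m³/min for 24 h) — is configurable because exposed areas vary between
samplers.

## ICRP deposition

The module implements the standard empirical parameterisation of the ICRP
respiratory-tract model (the Hinds closed forms): inhalable fraction
IF = 1 − 0.5(1 − 1/(1 + 7.6×10⁻⁴·dp^2.8)) and double-lognormal fits for
HA/TB/AR deposition. All coefficients live in one table
(`pmrisk.constants`) so an alternative coefficient set can be swapped in
one place. The raw fits marginally overshoot the inhalable budget near
dp = 20 µm (sum exceeds IF by ~0.1%); because deposited mass cannot exceed
inhaled mass, the three regional fractions are proportionally rescaled onto
IF whenever their sum overshoots. Size averaging uses Gauss–Hermite
quadrature in ln dp (default 17 nodes; 9 vs 33 nodes agree to < 10⁻³), and
GSD = 1 collapses exactly to the point evaluation. The default size spec is
a 1.0 µm monodisperse particle — the campaign's mass median diameter is not
published, so deposition-weighted results are indicative, not reproductions.

## Risk engine

The five metrics are linear in concentration; unit conversions
(pg/µg/mg, ×10⁶ and ×10⁹) are centralised as exact powers of ten, and the
identities HQ·TDI(pg) = EDI and MOE·EDI = NOAEL(pg) hold to machine
precision by construction. EQ deliberately carries no body-weight or
outdoor-time term — it converts inhaled spins directly into cigarettes via
4.75×10¹⁶ spins/g tar × 0.013 g tar/cigarette = 6.175×10¹⁴ spins/cigarette
— which is why its age profile (tracking ventilation) differs from DED's
(tracking ventilation per kilogram). A zero intake yields MOE = ∞ with a
flag rather than an error or a silent drop. MOE < 1000 is flagged high
risk.

The shipped 17-group exposure-factor table uses handbook-typical long-term
inhalation rates and body weights (the primary source table is not public)
with T = 0.1 everywhere (~10% of the day outdoors). It was chosen once to
satisfy the qualitative patterns the published assessment shows — IR/BW
peaks in the 9-month-to-4-year groups, absolute IR peaks at 18–59 years —
and is explicitly replaceable via `pmrisk.io.load_age_table`. Both
mean-based and median-based assessments are computed and labelled, because
published practice mixes the two (mean-based intakes, median-based
cigarette equivalents).

## Monte Carlo

Only the concentration is stochastic by default, fitted as a lognormal by
maximum likelihood (mu, sigma = moments of the logs) with a Shapiro–Wilk
check on the logs (p ≤ 0.05 flags the fit as rejected; above n = 5000 an
evenly spaced subsample is tested because the p-value approximation
degrades). Optional exposure-factor variability (lognormal IR, truncated
normal BW) sits behind a flag and is independent across factors.
Percentiles use linear interpolation between order statistics. The
simulated mean of any linear metric agrees with the closed-form lognormal
moment exp(mu + sigma²/2) within 1% at 10⁵ draws, and the standard error
scales as n^(−1/2).

## PMF

Weighted alternating nonnegative least squares: with one factor matrix
fixed, each sample row (resp. species column) is an exact weighted NNLS
subproblem, so Q is non-increasing along the iteration path; the iteration
stops when the relative ΔQ < 10⁻⁸ or at 5000 iterations, and the best of
(default) 20 random nonnegative starts wins. Multi-start matters: with
fewer than ~10 starts the solver can land in visibly inferior local optima
(Q/Q_expected ~ 10 instead of ~1). The EPA tool's robust reweighting,
FPEAK rotations and bootstrap error analysis are intentionally not
reproduced. Uncertainties are u = K·x with K = 10% for CPs/EPFRs/OC/EC and
15% for routine pollutants, floored at a small positive epsilon for zero
concentrations (below-detection treatment in the source study is
unstated). The factor count k is a user decision; `factor_scan` provides
the Q/Q_expected evidence table over k = 3..7 instead of hard-coding the
published choice of five.

A caveat the recovery tests encode: a positive bilinear model is only
identifiable when both factors carry enough zeros. The bundled ground-truth
design (`example_factor_design`) therefore gives each source disjoint
tracer species over a 1% background and episodic contributions (inactive
days and a few near-pure days per source). On that world, noiseless fits
reach Q < 10⁻⁶ with profile cosines ≥ 0.999, and 10% noise keeps mean
cosines ≥ 0.95 and contribution percentages within 5 points. On dense,
always-active truths, rotational ambiguity makes such recovery impossible
for *any* solver — a property of the model, not the implementation.

## Campaign statistics

Composition shares are percentage ratios of class means. Kruskal–Wallis
uses mid-rank tie correction with the chi-square approximation (identical
constant groups short-circuit to H = 0, p = 1); the temporal comparison
bins by calendar month. The Spearman screen computes mid-rank correlations
for every off-diagonal upper-triangle pair of the requested variables (the
multiplicity family, since the source study does not define one), with
p-values from Fisher's z using Fieller's rank-correlation variance
1.06/(n−3) rather than the Student-t approximation: at n ≈ 104 the t
approximation is anticonservative near p ≈ 0.05 (measured type-I rate
~5.2%), which would push the Benjamini–Hochberg false-discovery rate above
its nominal level; the Fieller form is slightly conservative and preserves
the guarantee (null-simulation FDR ≤ 5%). Constant variables yield NaN
correlations excluded from the BH family, reported, never faked.

## Known limitations

* The deposition fractions are generic ICRP curves at a configurable
  particle size, not the (unpublished) size-resolved values of the source
  study; regional numbers are therefore order-of-magnitude comparable only.
* The exposure-factor table is handbook-typical, not the study's table;
  absolute per-group risk values shift with it, while the headline bounds
  (HQ ≪ 1, MOE ≫ 1000) are robust to any physiological parameter choice.
* The generator reproduces summary statistics, not dynamics: no
  autocorrelation, no episodes, no gas–particle partitioning physics.
* Linear mixed-effects and random-forest driver analyses, back-trajectory
  modelling and the hydroxyl-radical budget are out of scope.
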