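# pmrisk

Inhalation-exposure analysis of PM2.5-bound **chlorinated paraffins (CPs)**
and **environmentally persistent free radicals (EPFRs)**: EPR spin
quantification, uncertainty-weighted positive matrix factorization (PMF)
source apportionment, ICRP respiratory deposition, and an age-stratified
health-risk assessment with Monte Carlo uncertainty propagation.

It is written for exposure scientists and atmospheric chemists who have a
winter filter-sampling campaign (daily analyte concentrations, EPR spectra
of filter punches, co-pollutant and meteorology records) and want the
complete computational chain from raw signal to per-age-group risk numbers
— or who want to validate that chain on synthetic data with known ground
truth, which the `pmrisk.synthetic` module generates.

## The models

**EPR quantification** (`pmrisk.epr`). A field-swept first-derivative
spectrum is baseline-corrected, fitted with a Gaussian lineshape by least
squares, and double-integrated (cumulative trapezoid twice). The g-factor
follows from the resonance condition

    g = h·ν / (μ_B·B₀)

with g < 2.0030 indicating carbon-centred radicals, g > 2.0040
oxygen-centred, and the band between them mixed/heteroatom-adjacent
populations. The double-integral area maps through a TEMPOL-style
calibration curve to spins, then through punch/filter geometry and sampled
air volume to spins/m³.

**PMF** (`pmrisk.pmf`). The receptor model X ≈ G·F with G, F ≥ 0
minimizing the uncertainty-weighted objective

    Q = Σᵢⱼ ((xᵢⱼ − Σₖ gᵢₖ fₖⱼ) / uᵢⱼ)²,   uᵢⱼ = Kⱼ·xᵢⱼ

solved by multi-start alternating weighted nonnegative least squares
(each half-step exact, so Q is non-increasing), with the degrees-of-freedom
diagnostic Q_expected = n·m − k(n+m) and factor-to-species contribution
percentages.

**Deposition** (`pmrisk.deposition`). ICRP empirical closed forms for the
inhalable fraction IF(dp) and regional deposition fractions in the head
airways (HA), tracheobronchial tree (TB) and alveolar region (AR), plus
Gauss–Hermite mass-averaging over a lognormal size distribution.

**Risk metrics** (`pmrisk.risk`), per age group (IR inhalation rate, BW
body weight, T outdoor-time fraction; 17 life-stage groups from 0–3 months
to over 80 years):

    EDI = C·IR·T/BW            HQ = EDI/TDI         MOE = NOAEL/EDI
    DED = RC·IR·EF/BW          EQ = RC·IR/(RC_cig·C_tar)

with TDI = 100 µg/kg/day, NOAELs of 10/23/100 mg/kg/day for S/M/LCCPs,
RC_cig = 4.75×10¹⁶ spins/g tar and C_tar = 0.013 g/cigarette. Regional
variants are DF-weighted. `pmrisk.montecarlo` resamples a fitted lognormal
concentration 10,000 times to turn each point estimate into a distribution.

## Worked example

```sh
python examples/05_risk_assessment.py
```

prints, for the campaign mean concentrations (total CPs 1.17×10³ pg/m³,
EPFRs 1.43×10¹³ spins/m³), one row per age group; the adult rows read:

```
      group  EDI_pg_kg_day       HQ MOE_SCCP DED_spins_kg_day  EQ_cig_day
18-44 years           30.3 3.03e-07 6.44e+08         3.70e+11       0.364
45-59 years           29.5 2.95e-07 6.63e+08         3.60e+11       0.368
```

Every hazard quotient is far below 1 and every margin of exposure far above
the high-risk threshold of 1000, so campaign-level CP inhalation carries no
appreciable noncarcinogenic risk; the daily radical dose normalised by body
weight peaks in young children, while the cigarette-equivalent metric
(which tracks ventilation only) peaks in working-age adults at ~0.36
cigarettes/day whole-airway, splitting at 1 µm particle size into
HA 0.104 > AR 0.044 > TB 0.010.

The other examples cover campaign generation (`01`), EPR quantification
(`02`, recovering 5.35×10¹³ spins to 0.3% and g to 5 decimals), PMF source
recovery (`03`, factor cosines ≥ 0.999 and contributions within 2.3
percentage points at 10% noise), deposition curves (`04`), Monte Carlo
intake distributions (`06`) and the end-to-end report with manifest (`07`).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from the package's risk engine and its default 17-group
exposure-factor table at the published campaign mean concentrations: the
maximum hazard quotient over all age groups (t4), the maximum estimated
daily intake in µg/kg bw/day (t5), and the minimum margin of exposure over
the three CP classes and all groups (t6), writing them as JSON.
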