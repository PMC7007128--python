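# Methods

## Problem and model overview

Rice grown under elevated atmospheric CO2 (~580 ppm, free-air enrichment
conditions) carries measurably less thiamin, riboflavin and folate —
average losses on the order of 17–30%. Because rice is the single most
calorically important food worldwide, such losses can push large
populations below adequate B-vitamin intake. This package estimates that
effect in four linked stages and propagates input uncertainty through
all of them.

### 1. Intake and requirements

Per-capita daily nutrient supplies are taken per food, country, sex and
5-year age bin (folate in µg/day; thiamin and riboflavin in mg/day) and
used as a proxy for intake. Recommended nutrient intakes (RNIs),
published on irregular age groupings and by physiological state, are
converted to estimated average requirements (EARs) by a per-nutrient
factor (default 1.2, i.e. RNI = EAR × (1 + 2 × 0.10) for a 10%
requirement CV) and re-binned onto the 5-year grid by population
weighting, assuming people are uniformly distributed within each 5-year
population bin. For women aged 15–49 the EAR is a blend of the
non-reproductive, pregnant and lactating requirements: the pregnant
fraction is the age-specific fertility rate × 40/52 (the fraction of a
year occupied by a pregnancy), the lactating fraction is the fertility
rate × the national mean breastfeeding duration. The two states are
treated as mutually exclusive within a year; if their raw sum exceeds 1
the pair is rescaled proportionally. Lactating-state requirements are
applied at full increment for the entire breastfeeding duration.
Countries without breastfeeding data receive the population-weighted
mean of their region's reporting countries.

### 2. Fortification

National fortification programs add nutrient on top of the food supply.
A fortificant dose (mg compound/kg vehicle, vehicles: wheat flour, rice,
maize flour) is converted to pure nutrient by the compound's
standardization factor (averaged when several candidate compounds are
listed), multiplied by effective coverage (fraction industrially
processed × fraction of processed vehicle fortified) and by per-capita
vehicle consumption. National additions are allocated to age-sex strata
in proportion to each stratum's supply of the nutrient from the
fortified vehicles, which preserves the national per-capita total. No
dietary-folate-equivalent multiplier is applied to folic acid (factor
1.0, configurable).

### 3. EAR cut-point method and the CO2 scenario

Usual intake in a stratum is modelled as Normal(mean, cv × mean) with
cv = 0.30 for B vitamins. The prevalence of inadequate intake is the
mass below the EAR, Φ((EAR − mean)/sd). The normal is not truncated at
zero: at cv = 0.30 the sub-zero mass is Φ(−10/3) ≈ 4×10⁻⁴ and
truncation would change results cosmetically while complicating the
closed form. Strata with zero or missing mean supply are excluded and
logged rather than assigned prevalence 1, since zero means missing
supply data.

The elevated-CO2 intake distribution is the current one scaled by the
per-stratum supply ratio

    r = (total − rice × L + fortified) / (total + fortified),

where L is the fractional loss of the nutrient in rice and "total" and
"rice" are pre-fortification supplies. Multiplicative scaling preserves
the CV, so the scenario prevalence is Φ((EAR − r·m)/(cv·r·m)).
Fortification appears in both numerator and denominator and therefore
buffers the loss. The ratio is computed per stratum (each age-sex group
has its own rice share). Prevalence differences are applied to 2050
populations under a constant-diet assumption; sampled nutrient *gains*
(ratio > 1) yield negative newly-at-risk counts and are reported as
such, never clamped.

### 4. Folate → neural-tube-defect burden

A degree-2 polynomial (configurable) is least-squares fitted through
(folate intake, NTD risk) points on the absolute risk scale. Relative
risk is the fitted risk normalized at the reference intake — the
highest observed intake, i.e. best observed folate status — clamped to
the observed intake domain (no polynomial extrapolation) and floored at
RR = 1 (no protective extrapolation). The exposure-weighted RR of a
stratum is the mean of RR over its intake distribution, computed by
composite Simpson quadrature over [max(0, mean − 5sd), mean + 5sd],
split at the domain-clamp kinks so each piece is smooth, with grid
doubling until the relative change is below 1e-8, and normalized by the
analytic normal mass of the interval. The national exposure is the
folate intake of women 15–49, age groups weighted by births
(ASFR × population), since NTD risk attaches to pregnancies. The
potential impact fraction is

    PIF = (EWR_eCO2 − EWR_current) / EWR_current,

computed on the RR scale (any common normalization cancels), and
multiplies the current national burden of NTD deaths and DALYs. PIF is
not additive across countries; attributable burdens are, and are summed
to regions and globally.

### 5. Uncertainty propagation

Inputs reported as mean + 95% CI (rice loss factors, NTD burdens) are
matched by skew-normal samplers: (ξ, ω, α) minimize the summed squared
relative errors of the analytic mean and 2.5th/97.5th percentiles
(multi-start least squares; relative errors floored at 5% of the
interval width when a statistic sits near zero). A symmetric interval
short-circuits to α = 0, ω = (hi − lo)/(2 × 1.959964). Triples whose
upper/lower half-width ratio exceeds the skew-normal's attainable
quantile asymmetry (≈1.88) raise a fit error rather than being silently
approximated. Supply uncertainty uses a plain normal with the reported
standard error. All uncertain inputs are sampled independently; no
correlation structure is imposed (a documented simplification), and
inputs without reported uncertainty (the RR curve, EARs) are not
sampled, so intervals are understood to be lower bounds on the true
uncertainty.

The Monte Carlo ensemble (default N = 1,000) redraws every uncertain
input per draw — fixed order: rice supply noise, non-rice supply noise,
loss factor per nutrient, burden deaths then DALYs per country — reruns
the deterministic chain, and reports the empirical middle 95%
(percentiles with linear order-statistic interpolation) around the
deterministic central run as point estimate. The point estimate may
fall outside a strongly skewed interval; this is expected and not
corrected. Draw substreams derive from one master `SeedSequence`, so a
seed fixes the output byte-for-byte within this implementation
(cross-implementation bit-identity is not promised). Draws producing an
inconsistent world (negative supply or burden) are rejected and redrawn
from a spawned substream; more than 10% rejections aborts.

## Synthetic worlds

The generator emulates the *structure* of the real inputs — 5-year
age-sex strata with a decreasing age pyramid, fertility concentrated at
ages 20–34, breastfeeding durations of 6–24 months, per-stratum
log-normal supply heterogeneity (10% spread) around country means
anchored to adult EARs, rice shares drawn from a configurable range
(default 5–70%), fortification specs for the three grain vehicles, and
NTD burdens scaling with population (defaults 1–60 deaths and
150–6,000 DALYs per million per year, right-skewed CIs) — but none of
its magnitudes are claims about any real country. The bundled
dose-response table is a synthetic stand-in shaped like published
folate–NTD data (quadratic, risk falling from ~5.9 to 1.0 per 1,000
births over 150–500 µg/day), not a reprint of it. Default rice loss
factors are folate −0.30, thiamin −0.17, riboflavin −0.17, inside the
measured 17–30% range. Consequently, passing tests demonstrate the
estimation machinery (closed forms, conservation, oracle agreement,
reproducibility), not the real-world magnitudes of any quantity.

## Numerical choices and problem sizes

- Tables are CSV (UTF-8, "." decimal), floats at 12 significant digits;
  writes are deterministically sorted so reruns are byte-identical.
- Skew-normal fits accept a summed squared relative error ≤ 1e-4 and
  typically reach < 1e-12.
- Test and acceptance runs use 3–10 country worlds and 1,000-draw
  ensembles; sampling oracles use 10⁵–10⁶ draws with 3-standard-error
  bands. These sizes make the whole suite run in about a minute while
  keeping binomial oracle bands tight.
- Age bin 80 denotes 80+; bins are closed-open [a, a+5).

## Known limitations

- Supplies proxy intake; no within-household loss, waste or supplement
  model, so prevalence levels inherit food-balance-sheet bias.
- The cut-point method's validity conditions (intake independent of
  requirement, symmetric requirements) are assumed, not checked.
- Only rice loses nutrients in the scenario; other crops' CO2 responses
  are out of scope, so deltas are conservative by construction.
- The dose-response fit carries no sampled uncertainty.
- Thiamin and riboflavin health outcomes are not quantified; only the
  folate–NTD pathway has an implemented burden model.
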