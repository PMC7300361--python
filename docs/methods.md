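# Methods

## The experimental design being modeled

A pH-perturbation microcosm study: soils along a land-use gradient (two
forest soils LF and E, a riparian soil RR, and 2- and 7-year-old oil-palm
soils OP2 and OP7) are each incubated at their native pH and at an
artificially modified pH (neutral soils acidified, acidic soils limed),
under either ¹²C- or ¹³C-CO₂ headspace, in triplicate, destructively
sampled at days 0, 15 and 30. Day-0 microcosms are sampled before CO₂
amendment (one triplicate set, isotope `none`); later days carry
independent triplicates per isotope. Measurements are NH₄⁺, NOₓ⁻ and pH
(chemistry table), per-guild *amoA* copies by qPCR (abundance table), and
day-30 CsCl-gradient fractionation with per-fraction qPCR (gradient table;
15 fractions of which 2–14 are quantified, fraction 1 = heaviest).

## Simulator

### Dynamics

Daily discrete-time updates, not ODEs: a 30-day design with daily
resolution does not benefit from continuous integration, and the discrete
form makes every invariant (mass balance, clipping) exactly testable. Per
day and per soil × condition:

1. Oxidation capacity = Σ_guilds (copies / copies-per-cell) × per-cell
   activity × 24 h, converted at 14 × 10⁻⁹ µg N per fmol NH₃.
2. N oxidized = min(NH₄⁺ pool + that day's mineralization, capacity),
   attributed to guilds in proportion to their capacity (this attribution
   is the ground-truth "contribution" used in closure tests).
3. Pools update: NH₄⁺ += mineralization − oxidized; NOₓ⁻ += oxidized;
   pH −= oxidized / buffer capacity; all clipped at zero. Because oxidation
   never exceeds the available pool, Δ(NH₄⁺ + NOₓ⁻) equals the
   mineralization input exactly at every step.
4. Growth: while NH₄⁺ exceeds a hard limitation threshold (default
   1 µg N g⁻¹), each guild multiplies by exp(rate); below it, the update is
   skipped entirely. A hard threshold rather than Monod kinetics keeps the
   limitation behavior legible and testable; the threshold is configurable
   because field evidence for substrate limitation is qualitative.

Ground-truth ¹³C labeling uses a semiconservative-replication
approximation: each day's positive growth increment adds
`autotroph_fraction × Δcopies` labeled copies; decline removes labeled and
unlabeled copies proportionally. The true labeled fraction at day 30 is
labeled / total copies — for uninterrupted exponential growth this equals
`autotroph_fraction × (1 − N₀/N_T)`.

### Measurement noise

qPCR and chemistry measurements are the true values times mean-preserving
multiplicative lognormal noise: σ² = ln(1 + CV²), µ = −σ²/2, independent
per replicate and per analyte. Defaults CV = 0.2 (qPCR) and 0.1
(chemistry) are typical inter-replicate spreads for soil *amoA* qPCR and
colorimetric N assays. Multiplicative noise keeps abundances nonnegative by
construction. pH receives small additive noise (half the chemistry CV in pH
units) since it is already a log-scale quantity. Identical seed ⇒
byte-identical tables.

### Buoyant-density model

A Schildkraut-type linear relation: an unlabeled population bands at
`1.66 + 0.098 × GC` g ml⁻¹; full ¹³C labeling shifts the band heavier by
0.036 g ml⁻¹ (scaled by atom-fraction excess, default 1.0). Bands are
Gaussian with σ = 0.008 g ml⁻¹, integrated over 15 equal-width fraction
bins spanning 1.66–1.76 g ml⁻¹ (fraction 1 heaviest, densities decreasing
with index — stated once here, used everywhere). Each component's bin
masses are renormalized to sum to one over the gradient, so total copies
are conserved exactly and a `labeled_fraction` of 0.4 puts exactly 40% of
the pre-noise mass in the shifted component. All constants are configurable
defaults of this standard relation, not measured values.

### Stock scenarios

`default_scenarios()` encodes the five-soil design with field-typical
magnitudes: *amoA* pools of 10⁴–10⁶ copies g⁻¹ at day 0, AOB favored at
high pH (strong positive growth rates when neutral, declines when
acidified), AOA growing across a wider pH range, comammox minor with
soil-dependent responses, and a low-mineralization riparian soil where
ammonium limitation curtails growth — the qualitative structure the
analysis stages are meant to resolve. `closure_scenarios()` is a variant
for conservation checks: every guild grows (≥ 0.1 d⁻¹), is fully
autotrophic, and ammonium never limits, so the upper-bound contribution
arithmetic must cover the measured NOₓ⁻ production in every soil.

### What the simulator does not emulate

No NH₃/NH₄⁺ speciation chemistry, no pH dependence of activity, no Monod
kinetics, no N₂O fluxes, no comammox clade substructure, no gradient-to-
gradient density calibration drift, and noise is independent across
fractions (real gradient qPCR errors are partially correlated). Passing
recovery tests therefore demonstrates that the estimators are correct under
the stated statistical model, not that they are robust to every artifact of
real gradient data.

## Analysis stages

### Density profiles and labeling

Profiles are per-fraction counts divided by the total over the quantified
fractions ("proportion of the whole gradient"); an all-zero gradient yields
an explicit no-signal result (`None`) rather than a division error, and
no-signal replicates are dropped from downstream calls. The labeling
decision operationalizes "the buoyant-density peaks were distinct": the
replicate-averaged weighted-mean-density shift (¹³C − ¹²C) must reach
δ_min = 0.005 g ml⁻¹ *and* a one-sided unpaired two-sample *t* test on the
replicate weighted mean densities must give p < α = 0.05. Replicates are
unpaired across isotopes because the microcosms are independent. If either
isotope has no usable profiles the outcome is a *no-call*, distinct from
*unlabeled*. With zero within-group variance (noise-free data) the *t*
statistic is undefined and the effect-size criterion decides alone.

The labeled (growing) population is total day-30 abundance × the ¹³C
profiles' relative abundance at buoyant density ≥ 1.725 g ml⁻¹ (the
heavy-window default; "heavy fractions" has no standard numeric
definition, so the threshold is a named parameter). Subtracting the ¹²C
heavy-window background is available but off by default, matching the
plain heavy-fraction count; it is worth enabling when unlabeled heavy-tail
mass would inflate estimates. The estimate is monotone non-decreasing as
the window widens (pre-subtraction), and per-replicate values are retained
for the standard error.

Known quantization limit: the heaviest fraction is not quantified, so at
high labeled fraction and high GC part of the labeled band falls outside
both the numerator and the denominator. Noise-free recovery of the labeled
fraction is within ~3 percentage points for moderate labeling at mid-GC
and degrades to ~4–6 points in the worst corner of the (GC, labeled
fraction) plane; with default noise the replicate-mean estimate stays
within ±10 points of truth.

### Rates, growth, stability

Net nitrification is the day-30 − day-0 NOₓ⁻ difference of means, SE
propagated as √(se₀² + se_T²), tested against no change with a pooled
Student's *t*. qPCR growth is final − initial abundance; "detected"
requires a significant one-sided increase (df = n₀ + n_T − 2), otherwise
the output shows "n.d." while the signed point estimate is kept. All
two-sample tests are reconstructed from (mean, SE, n) summaries, which is
algebraically identical to the raw-data test when the summaries come from
the same replicates (tested to 1e-9); Welch's variant is a flag.

The stability index is `100 × (M̄ − N̄)/N̄`. Per-replicate indices place
each modified replicate against the native mean — with independent
microcosms there is no natural pairing — and their mean equals the
headline value. Stability comparisons between guilds use an independent
Student's *t* on these per-replicate indices, as is conventional. Caveat,
documented deliberately: because all of a guild's per-replicate indices
share the same estimated native denominator, that shared error is
invisible to the within-group scatter, and the naive test's type-I rate
runs above nominal (~12% at default noise versus α = 5% in simulation);
with exact (low-noise) native baselines it is calibrated. Interpret
borderline stability contrasts accordingly.

ANOVA uses the classical fixed-effects decomposition (statsmodels OLS +
`anova_lm`, type II), one- or two-way with optional interaction, and Tukey
HSD on the factor-combination cells; grouping letters use the standard
insert-and-absorb compact-letter-display algorithm (groups sharing a
letter are not significantly different). No multiple-testing correction is
applied by default; Benjamini–Hochberg is available as a helper.

### Apportionment

Per-cell activity constants (fmol NH₃ cell⁻¹ h⁻¹): AOA 2.6, AOB 23,
comammox 2.6. The comammox value is derived in-package from culture
kinetics — V_max × 10³ / (g wet weight per g protein) / (cells per g wet
weight) × 10⁹ — giving 2.5965, presented at two significant figures.
Rounding is presentation-only; all arithmetic uses the unrounded value.

A guild's putative contribution holds its end-of-incubation growing-cell
count at this maximal activity for the whole incubation (default 720 h).
This is deliberately an upper bound: the time course of growth is not
integrated (a trapezoidal option would halve the early-growth weighting,
but the end-point convention is the transparent default), and undetected
or negative growth contributes zero — declining guilds are not subtracted.
*amoA* copies per cell defaults to 1 (genes ≈ cells); AOB genomes often
carry 2–3 copies, so the parameter is exposed, and the contribution is
invariant under joint rescaling of (growth, copies-per-cell). The
unaccounted residual is max(0, measured − Σ contributions); when the
upper-bound estimates exceed the measurement the breakdown is flagged
overexplained and never rescaled, so conservation
(Σ contributions + unaccounted = measured) holds exactly whenever the flag
is off. Either growth estimator (SIP or qPCR) can feed the identical
downstream arithmetic; SIP is the default because it isolates autotrophic
growth. The area-scaling utility converts a per-area flux to a global
total (kg N ha⁻¹ yr⁻¹ × ha × 10⁻⁹ = Tg N yr⁻¹).

## Numerical choices and degenerate inputs

- Profile normalization asserts Σ = 1 within 1e-9 at construction.
- Zero-variance *t* tests: equal means return t = 0, p = 1; unequal means
  with zero variance return ±∞, p = 0.
- Gradient bin masses renormalized per component (conservation to 1e-6
  relative is tested; exact up to floating point).
- Simulator pools clipped at 0; clipping never violates N mass balance
  because oxidation is capped by availability.
- Seeds: the dataset generator uses one seeded generator for measurement
  noise and a second stream (seeded by `(seed, 1)`) for gradient noise, so
  adding gradients does not perturb the measurement tables.

## Problem sizes

Recovery and calibration experiments use 200 Monte-Carlo runs of
triplicate gradients or triplicate qPCR summaries, and the full synthetic
design (5 soils × 2 pH × 2 isotopes × 3 replicates × 3 days, 13 quantified
fractions × 3 guilds per gradient); these sizes give binomial standard
errors below 2 percentage points on detection rates while the entire suite
and the acceptance script each complete in well under a minute of compute.

## Known limitations

- The labeling decision is presence/absence; no qSIP-style quantitative
  atom-fraction-excess estimation.
- The stability comparison's type-I inflation under noisy native baselines
  (above).
- The heavy-window estimator inherits the gradient's binning: labeled mass
  in the unquantified heaviest fraction is invisible to it.
- Upper-bound contributions can exceed measured production by design;
  the overexplained flag is information, not an error.
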