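# Methods

## Scope and data model

The package operates on *study-level* summary results of economic
evaluations of familial hypercholesterolemia screening: one record per
(study, outcome-measure) membership, carrying the incremental cost and
incremental effect of a screening strategy against its comparator, both
standardized to 2023 US dollars, plus the study's willingness-to-pay
(WTP) threshold after the same conversion. A publication reporting
several outcome measures (QALYs, life-years gained, adverse events
averted, deaths averted) contributes one record per measure, so study ids
are not unique across rows. Records are pooled only within a
(strategy, outcome) cell — cascade and universal screening are never
mixed, nor are outcome units.

The decision models inside the source studies (Markov models, decision
trees, life tables) are out of scope: their outputs are this package's
inputs.

## Cost standardization

Conversion multipliers to 2023 USD are user-supplied per
(currency, price year) — purchasing-power-parity factors are treated as
data, not fetched. Conversion is linear and sign-preserving. Costs or
effects lacking a reported confidence interval receive a default
uncertainty interval of ±50% of the point value (endpoints reordered for
negative values); a reported interval always takes precedence.

### Back-solved thresholds

The published synthesis table prints each study's net monetary benefit
NHB = λ·Δe − Δc but not the converted threshold λ itself. The encoded
fixtures therefore back-solve λ = (NHB + Δc)/Δe per row at full float
precision and flag it `back_solved` in the record metadata. Two facts
support this reconstruction: (i) λ recovered independently from a study's
different outcome rows agrees to ~0.01% (e.g. the UK cascade study gives
50,730.8 / 50,731.0 / 50,731.0 from its QALY, events and deaths rows);
(ii) feeding back-solved λ through the pipeline reproduces every printed
NHB cell to ±1 USD and every printed weighted total to <0.1% (this is a
test, not an assumption).

## Evidence synthesis

Within a group of m studies with costs c_i and effects e_i:

- multi-cohort studies are first averaged: Δc and Δe are the arithmetic
  means over cohorts (the one such study reports two age cohorts);
- pooled totals are straight sums, and the pooled ICER is Σc/Σe. A
  pooled result that saves money while gaining health is reported as
  *dominant* (no finite ratio), the mirror case as *dominated*; records
  with negative costs still enter the sums unchanged;
- comparative-efficiency weights are ω_i = NHB_i⁻² / Σ_k NHB_k⁻²,
  computed after rescaling by the smallest |NHB| for numerical stability.
  The rule is sign-insensitive and scale-invariant, and concentrates
  weight on studies whose net benefit is closest to zero, i.e. closest to
  the decision margin. A zero NHB is rejected rather than approximated
  (its weight would be infinite); callers may supply explicit weights
  instead. The exact published weighting rule was specified only in
  supplementary material; ω ∝ NHB⁻² reproduces all published weight
  columns to ≤5·10⁻⁵ and all seven published TNHB values to <0.1%, and is
  falsifiable against any future row;
- weighted totals Σω·c, Σω·e and TNHB = Σω·NHB follow directly.

### Intervals

Two modes:

- **paper mode** (default): every point estimate is bracketed by ±25%.
  All intervals printed in the source tables obey exactly this band, so
  this mode is for reproduction and reporting;
- **delta mode**: a first-order delta-method interval for the pooled
  ICER, var(R) ≈ R²(se_c²/c² + se_e²/e² − 2ρ·se_c·se_e/(c·e)), with
  standard errors read from per-study intervals as normal 95% half-widths
  (half-width / 1.96) and summed in quadrature assuming independence.
  The symmetric first-order interval ignores the skew of a ratio
  distribution; against a 10⁶-draw Monte-Carlo oracle it agrees to 1%
  only while the *denominator's* coefficient of variation stays ≲0.05
  (the error grows as cv_e²: measured ~2.5% at cv_e = 0.08). Use with
  caution when pooled effects are noisy.

## Aggregate distributional cost-effectiveness analysis

Six steps per scenario (per-person ΔQALY and Δcost, threshold K, N
screened, a subgroup distribution, aversion ε):

1. baseline health: QALE h_j per person per group;
2. opportunity-cost shares d_j (Σd_j = 1);
3. group net health benefit NHB_j = ΔQALY·n_j − N·Δcost·d_j/K with
   n_j = N·pop_share_j (real-valued, no rounding). Summed over groups
   this collapses to ΔQALY·N − N·Δcost/K, which the implementation also
   uses as a closed-form conservation check;
4. post-intervention health h_j' = h_j + NHB_j/n_j;
5. Atkinson index A(ε) = 1 − ((1/J)Σ(h_j/ĥ)^{1−ε})^{1/(1−ε)} and
   EDEH = N·(1 − A)·ĥ, before and after;
6. equity impact = ΔEDEH − ΔNHB, with direction assigned by sign
   (neutral within 10⁻⁹ relative).

Numerical choices: the ε = 1 singularity uses the exact geometric-mean
limit A = 1 − GM(h)/ĥ (the general formula is numerically continuous
through ε = 1±10⁻⁶); the group mean ĥ is unweighted, as deprivation
quintiles are population fifths by construction, with a
population-share-weighted variant behind a flag for unequal groups;
non-positive post-intervention health aborts with an error (Atkinson
welfare is undefined there), and any group falling below its baseline
raises a warning.

### Default subgroup structure

The UK quintile endpoints are published (QALE 63.21 years in the most
deprived fifth, 75.00 in the least; opportunity-cost shares 26% and 14%)
but the middle-quintile values appear only in unpublished supplementary
material. Defaults here interpolate linearly — QALE (63.21, 66.1575,
69.105, 72.0525, 75.00), shares (0.26, 0.23, 0.20, 0.17, 0.14) — with
equal population fifths; all three vectors are overridable. ε defaults to
10.95, the UK empirical estimate used by the source analysis.

Consequence: incremental-NHB values are exact reproductions (they do not
depend on the quintile detail), but EDEH magnitudes are not — the
published baseline EDEH of 69.72 QALYs/person exceeds the interpolated
vector's 67.77, so the supplementary quintile values must differ from a
linear ramp. Published ΔEDEH values and some equity-impact signs are
therefore *not* reproduction targets under defaults; the distributional
machinery is instead validated by its mathematical properties (equality
ε-invariance, Pigou–Dalton transfers, EDEH ≤ N·ĥ, conservation,
permutation invariance) against an arbitrary-precision oracle.

## Synthetic evidence generator

`generate_studies` draws m studies around a known true ICER:
e_i ~ Lognormal(ln(scale), σ) with σ = 0.5 by default (moderate
heterogeneity — real screening evaluations span effects from <1 to
several hundred, but such extreme spread would make a 50-study pooled
ICER swing tens of percent and mask pipeline defects rather than reveal
them); c_i = ICER·e_i·(1 + η_i) with η_i ~ N(0, cv); the cost sign flips
with probability `dominance_prob` (default 0.1, matching the ~2-in-19
cost-saving rate of the published evidence base); λ_i ~ Uniform(20k,
150k), the range spanned by the published thresholds. One `numpy`
default_rng stream per call, seeded from the config.

The ratio-of-sums estimator is unbiased under this design; its per-set
spread is ≈ cv·√(E e²)/E e/√m (~3% at cv = 0.2, m = 50), so recovery is
checked on the *median* error across seed blocks — a bias measure robust
to individual draws — rather than on single sets. What passing these
tests shows: the pooling, weighting and IO machinery is self-consistent
under known ground truth. What it does not show: anything about
between-study heterogeneity of real evidence bases, which the generator
deliberately understates, nor about correlated costs and effects, which
it does not model (η is independent of e).

## Known limitations

- The ±25% reporting band and the NHB⁻² weight rule are reconstructions
  that exactly reproduce the published tables but rest on reverse
  engineering, not on a published formula.
- Deterministic pooling is not a random-effects meta-analysis; no
  between-study variance is estimated, and no probabilistic DCEA is
  offered.
- Equity conclusions inherit the UK-specific baseline and
  opportunity-cost gradients; other settings need their own vectors.
- Two encoded rows (the reverse-cascade events row and one DCEA
  scenario) were recovered from typographically garbled source cells;
  both carry provenance flags, and both satisfy the model equations they
  enter.
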