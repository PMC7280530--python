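# Methods

This note documents the statistical model behind `lipidmr`, the defaults
and why they are what they are, what the synthetic-data generator does and
does not emulate, and the numerical choices a maintainer would want
written down.

## The inference problem

Three correlated lipid fractions — LDL-c, HDL-c, TG, each measured in SD
units — are candidate causal factors for coronary artery disease.  For
SNP *j* the summary data give exposure effects β_jx (x ∈ {LDL, HDL, TG})
and an outcome effect β_jd on the CAD log-odds scale, with standard
errors and per-SNP sample sizes.  If the selected SNPs are valid
instruments, the outcome effects satisfy approximately

    β_jd = θ_LDL β_jLDL + θ_HDL β_jHDL + θ_TG β_jTG + ε_j ,

and the θ's are the causal effects of interest (reported as odds ratios
per 1 SD, exp θ).  Pleiotropic SNPs — associated with two or more lipids —
are the main threat: a lipid with no causal effect can inherit an apparent
one through instruments shared with a causal lipid whose per-SNP effects
are correlated with its own.

## Instrument selection

Selection from the merged table runs in a fixed order:

1. **Association** (inclusive): keep SNPs with P_vj ≤ P_v, where P_vj is
   the smallest of the three exposure p-values.  Default P_v = 5e-08
   (genome-wide significance).
2. **Sample-size proportions** (strict): keep SNPs with P_cj > P_c and
   P_dj > P_d, where P_cj is the SNP's summed exposure sample size over
   the largest such sum in the reference table and P_dj the analogous
   outcome proportion.  Meta-analysis tables mix SNPs genotyped in all
   cohorts with SNPs present in only a few; the proportion filters keep
   the former.  The mixed inequality conventions (≤ then >) are
   deliberate and tested at the boundaries.
3. **Distance pruning**: within each chromosome, retained SNPs must be at
   least AIL base pairs apart.  The greedy scan resolves conflicts by
   keeping the SNP with the smaller P_vj (the stronger association), ties
   going to the smaller position; displacing an incumbent re-opens the
   comparison with its predecessor, so the kept set is pairwise ≥ AIL
   apart.  AIL = 0 disables the stage.  No LD reference panel is used:
   the design intentionally prunes by distance, not by D′, because
   LD-based pruning can discard instruments needed to expose a weak
   exposure's association.

Stage-2 proportions are computed over the full merged table by default
(the `reference` argument switches to any other base, e.g. the stage-1
output).  The grid scan (`scan_grid`) reruns selection + harmonization +
MVMR for a list of threshold settings and reports SNP counts, the three
MVMR betas and a stability score (maximum absolute beta change to a
neighbouring grid point).  The most stable point is *advisory*: choosing
the operating point is an analyst's decision, and the two named scheme
presets (A: five (P_c, P_d) settings then an AIL ladder at 0.99/0.99;
B: two settings then the ladder at 0.979/0.979) are reconstructions of
the published scan design from its description, not a verbatim grid.

## Harmonization

All estimators need every effect expressed for the same allele; the CAD
reference allele anchors the orientation.  Per exposure the rules are,
in priority order: equal effect alleles → keep; exposure effect allele
equals the CAD other allele → flip the beta and swap the labels;
complement equals the CAD reference → keep, complement the labels;
complement equals the CAD other allele → flip, complement and swap;
anything else is an error (or, with `on_irreconcilable="letter"`, a bare
letter-rule flip — needed for simulated tables whose null allele columns
are independent permutations).  On single-strand consortium data rules
3–4 never fire and this is exactly the plain letter comparison.
Palindromic (A/T, C/G) SNPs are flagged and kept: no strand inference
from allele frequencies is attempted, so the flag is the audit trail.
Flip flags accumulate across rebuilds; re-harmonizing a harmonized table
is a no-op.  SEs, p-values and sample sizes pass through bit-identical.

## Estimators

* **IVW**: no-intercept regression of β_jd on β_jx weighted by 1/se_jd²;
  with one SNP it degenerates to the Wald ratio (SE undefined).
* **MR-Egger**: the same regression with an intercept after orienting
  every SNP to β_jx ≥ 0; the intercept estimates directional pleiotropy,
  the slope is the adjusted effect.
* **Medians**: the (weighted) median of the per-SNP ratios β_jd/β_jx.
  The weighted median uses weights (β_jx/se_jd)² — the inverse
  first-order variance of the ratio — with linear interpolation at the
  50% cumulative-weight point, which reduces exactly to the ordinary
  median (midpoint convention for even counts) under equal weights.  No
  closed-form SE exists; a seeded nonparametric bootstrap over SNPs
  (default 10,000 resamples) supplies one, with a normal two-sided p.
  Across seeds the bootstrap SE is stable to well under 10% at that
  resample count.
* **MVMR**: weighted (1/se_jd²) regression of β_jd on the three exposure
  beta columns jointly, no intercept by default — chosen so the
  single-exposure case collapses exactly to IVW; `weighted=False` and
  `intercept=True` expose the alternative conventions, since multivariable
  MR implementations differ on both.  Rank-deficient designs raise a
  collinearity error naming the exposures.

Weighted fits go through statsmodels WLS; p-values are two-sided from
the t distribution with n_snps − k degrees of freedom.  All estimators
are invariant to jointly re-orienting any SNP's (β_jx, β_jd), and the
test suite checks IVW/Egger/medians against independent brute-force
normal-equation and cumulative-weight oracles at 1e-10.

* **R²**: SNPs are grouped by their unordered allele pair and the
  statistic is the between-class share of effect-size variance (one-way
  ANOVA decomposition, class means weighted by class size), bounded in
  [0, 1].  Building genotype classes from summary-level allele pairs is
  one documented reading of a loosely specified quantity; it is reported
  descriptively and feeds no downstream decision.

## Shared/unique dissection

A SNP is associated with an exposure when its p-value is ≤ the partition
threshold (default 5e-08; 1e-03/1e-04 presets exist for re-partitioning
externally selected sets).  Exactly one membership → unique (restricted)
instrument; two or three → shared, with the seven Venn regions reported.
Comparing MVMR on the full set against the unique subset is the
operational test for pleiotropy-driven confounding: an exposure whose
effect survives only when shared SNPs are present was not causal.

## Null-embedding simulation

Per replicate: (1) build M null SNPs — per trait, betas from a normal
with the mother data's mean and variance, p-values uniform (linear
scale) on [p_low, 1], sample sizes from a normal with the mother's
moments (rounded, floored at 1), allele pairs a per-trait permutation of
the mother's pairs, positions uniform over 22 chromosomes; null SEs are
derived from (beta, p) so the table satisfies the same contracts as real
data.  (2) Embed the test set: each test SNP is written into one
randomly chosen null row per exposure it is associated with (placements
drawn without replacement; a two- or three-exposure SNP is duplicated or
triplicated to separate locations), copying its exposure fields *and*
CAD fields verbatim — so each exposure–outcome pair survives intact
while every cross-exposure co-association is broken.  The m/M < 0.005
bound (warned about above) keeps chance re-co-association negligible.
(3) Select per (P_c, P_d) cell at P_v, compute the FDR (fraction of
selected SNPs that are not labelled test rows; an empty selection has
FDR 0 with a warning), run MVMR on the harmonized selection, and average
over replicates.  A master seed spawns per-replicate substreams, making
the whole procedure a pure function of (mother, test set, config).

Two properties anchor the design.  First, whenever p_low > P_v no null
row can pass stage 1, so FDR = 0 *exactly* — the analytic calibration
point the acceptance script recomputes.  Second, within the simulation
the stage-2 proportions are computed over the stage-1 survivors (the
`proportions` switch restores full-table denominators): with full-table
denominators the maxima come from the unbounded normal null sample-size
draws, which no embedded real-valued row can reach at cutoffs ≥ 0.9, and
every cell selects nothing — a degenerate regime, not an interesting one.

Limits of the noisy regime: under the linear-uniform profile the
per-trait probability of a null p-value falling at or below 5e-08 is
(P_v − p_low)/(1 − p_low) < 5e-08 — about 0.001 expected stage-1 nulls
even at M in the tens of thousands.  Strictly positive FDR at desk scale
therefore requires either a permissive P_v or a heavier-tailed null
profile; the tests exercise the former and otherwise assert only the
analytic direction (FDR monotone in p_low, survival at the linear rate).
Note also that embedding breaks row-level co-association but not
cross-trait *effect correlation*: test SNPs drawn from a generator with
correlated per-SNP effects still carry a residual coupling between a
null-causal exposure and the outcome through each shared SNP's own
(β_jx, β_jd) pair.  The pleiotropy-free reading of the simulation is
exact only when that correlation channel is absent, and the qualitative
sign checks switch it off explicitly.

## Synthetic-data generator

The generator emulates the structure of merged lipid/CAD meta-analysis
tables at the scale of the metabochip-era consortium data:

* default association architecture: 76/96/83 SNPs unique to
  LDL/HDL/TG, 1 LDL∩HDL, 18 LDL∩TG, 47 HDL∩TG, 17 in all three
  (338 instruments, pleiotropy fraction ≈ 0.25 — the observed makeup of
  a real 338-SNP instrument set, with its characteristic near-empty
  LDL∩HDL overlap and heavy HDL∩TG sharing);
* planted causal effects θ = (+0.4, −0.3, 0.0) on the log-odds scale —
  LDL harmful, HDL protective, TG null;
* true effects γ_jx = sign(z)(γ_min + |z|·s) with z multivariate normal
  truncated at ±4, γ_min = 0.025, s = 0.02: every true effect clears
  genome-wide significance at the default sample sizes (truth
  memberships and observed classifications disagree on < 5% of
  memberships), while the truncation keeps p-values away from floating
  underflow so (beta, se, p) round-trip exactly;
* cross-trait effect correlations on shared SNPs default to
  LDL–HDL −0.1, LDL–TG +0.3, HDL–TG −0.6 (the lipid-biology pattern:
  TG and HDL strongly anticorrelated, LDL largely independent of HDL);
* estimation noise: exposure SE = 1/√n (per-SD trait scale), outcome
  SE = 2/√n (binary trait); lipid sample sizes ~90k, CAD ~180k
  (cases + controls), drawn as the range maximum minus an exponential
  deficit (scale 2% of the maximum) so most SNPs sit near full N and the
  P_c/P_d filters have real consequences;
* alleles: random ordered pairs over {A, C, G, T}; each trait presents
  the pair in an independent random orientation with the beta sign
  following the labels, so harmonization is exercised nontrivially;
* optional per-SNP direct (horizontal) outcome effects via
  `direct_effect_sd` (default 0).

Not emulated: LD between SNPs, allele-frequency spectra, population
structure, winner's-curse selection of the published instruments, and
overlap between exposure and outcome samples.  Passing tests on this
generator therefore demonstrate the pipeline's correctness and its
behaviour under the stated architecture — not robustness to those
real-data pathologies.

The recovery harness reruns generate → select → harmonize → MVMR over
seeded replicates and reports per-θ bias, empirical SE and 95%-CI
coverage; at the defaults the bias is within three Monte-Carlo SEs of
zero over 20 replicates and coverage sits in [0.85, 1.0].  The TG
confounding scenario (θ_TG = 0, no unique TG instruments, HDL–TG sharing
present) reproduces the headline qualitative result: full-set
single-variable IVW calls TG a risk factor (mean spurious β ≈ +0.15) in
≥ 90% of replicates while unique-set MVMR correctly finds nothing.

## Numerical and degenerate-input choices

* SE from p inverts the Wald test, se = |β|/Φ⁻¹(1 − p/2); undefined for
  β = 0 or p ∉ (0, 1), which raise rather than guess.
* Record invariants at load: p ∈ (0, 1], n ≥ 1, distinct alleles,
  positive SE when present; offending rows are dropped with a logged
  count, duplicate SNP ids are an error naming the first offender.
* Merging is an inner join on snp_id sorted by id, hence commutative in
  table order and idempotent; written tables canonicalize column order
  and round-trip floats exactly (shortest-repr formatting).
* Empty selections, < 4-SNP cells and collinear designs inside the grid
  scan and the simulation are flagged per row/cell, never fatal; the
  same conditions raise typed exceptions when requested directly.
* Default problem sizes in tests and the acceptance script: mother
  tables of 20,000 SNPs (4,000 in unit tests) with the instrument
  architecture scaled to keep the embedded set under the m/M bound —
  sizes chosen so the full statistical behaviour (selection gradients
  across the grid, recovery, confounding contrast) is visible while a
  complete run stays in the seconds-to-minutes range.
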