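# Methods

## Scope and model

`gbsig` chains four statistical procedures that together address one
epidemiological question: which drugs are disproportionately co-reported
with Guillain–Barré syndrome (GBS), and which plasma proteins plausibly
mediate that susceptibility.

1. disproportionality analysis of spontaneous adverse-event reports;
2. fixed-effect meta-analysis of two GBS case–control GWAS;
3. proteome-wide two-sample Mendelian randomization (MR) with plasma
   pQTL panels as exposures and the meta-analysed GWAS as outcome;
4. protein-interaction overlap and pathway/tissue enrichment between the
   MR-significant susceptibility genes and drug-target genes.

All inputs can be produced by the synthetic generator
(`gbsig.synthetic`), so every stage is exercised end to end without
external data.

## Disproportionality statistics

Each drug–event pair is reduced to the 2×2 table (a, b, c, d) by
report-level counting: a deduplicated report contributes exactly once to
exactly one cell, so N = a+b+c+d equals the number of reports. The
alternative — counting each drug mention — would inflate b for
polypharmacy reports; report-level counting is also what the inversion
evidence supports (the recovered event margin a+c sits at the total event
report count).

The four algorithms share the relative reporting ratio
RRR = aN/((a+b)(a+c)) as their core: IC = log₂(RRR) and EBGM = RRR, which
the suite enforces as an invariant (IC ≡ log₂ EBGM to 1e-9).

Numerical conventions, fixed after verifying them against the published
ranked table they reproduce:

- **IC centre.** Printed ICs equal the point IC log₂(RRR), not the
  prior-shrunk posterior expectation E(IC) (for the top row,
  log₂ 134.19 = 7.07 whereas E(IC) ≈ 3.9). The default `mode="point"`
  therefore centres the lower bound on the point IC,
  IC-2SD = IC − 2√V(IC); `mode="posterior"` gives E(IC) − 2√V(IC). E(IC)
  and V(IC) use the standard Dirichlet priors α₁ = β₁ = 1, α = β = 2,
  γ₁₁ = 1 with γ derived from the margins.
- **EBGM05.** The lower bound uses the one-sided 5th-percentile quantile
  z = 1.645, which reproduces printed values (88.42, 23.03, …); z = 1.96
  (sometimes printed alongside the formula) gives ≈81.5 and ≈19.1 and is
  available via the `ebgm_z` argument.
- **EBGM is the unshrunk RRR.** No gamma-Poisson mixture is fitted; this
  is a deliberate divergence from canonical MGPS shrinkage, matching what
  ranked signal tables of this kind actually print (their EBGM tracks PRR
  closely even at a = 3, which shrinkage would not allow).
- **Zero cells.** By default a zero cell raises; the Haldane–Anscombe
  +0.5 correction is opt-in (`continuity=True`) since the printed formulas
  carry no correction.
- **PRR confidence interval** follows the log-normal form
  exp(ln PRR ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d))). Published CI
  bounds of this statistic are occasionally ~1% off any closed form;
  inversion therefore conditions only on ROR, PRR and χ², never on the
  PRR CI.

### Contingency inversion

`invert_contingency(a, ROR, PRR, χ²)` recovers (b, c, d) from a published
row. Writing p₁ = a/(a+b) and p₀ = c/(c+d), the identities ROR/PRR =
(1−p₀)/(1−p₁) and PRR = p₁/p₀ give the closed form
p₁ = (ROR−PRR)/(ROR−1), pinning b. The remaining unknown N solves the χ²
equation, which is monotone and bounded on (a+b, ∞); the root is bracketed
on a log grid and refined by Brent's method, then the full triple is
polished by Levenberg–Marquardt least squares on (log b, log c, log d). A
multi-start least-squares fallback covers inputs where the closed form is
inapplicable (ROR = 1, or rounding pushes p₁ outside (0,1)). The solution
must reproduce the three inputs to a relative residual of 1e-6; otherwise
an error carrying the best residual is raised. Cells are real-valued:
printed inputs are rounded, so the integer table is not exactly
identifiable, but derived quantities (IC, EBGM, CI bounds) are stable to
well inside their printed precision.

One published value is *not* reproducible by the printed formulas: for the
second-ranked row (a = 3) the variance term 1/(a+γ₁₁) = 0.25 bounds
IC-2SD ≤ log₂(PRR) − 2·√(0.25)/ln 2 ≈ 4.460, while the table prints 4.47.
The corresponding acceptance assertion is left failing rather than
adjusting the formula or the tolerance; our recovered value is 4.445.

## Report generation and handling

The generator builds cases demographics-first. Demographic margins default
to the composition of a large spontaneous-report extract (49.98% male,
27.58% missing age, 24.94% US origin, 82.49% with a documented
indication). Each case receives 1 + Poisson(1) distinct drugs (Gumbel
top-k sampling by background-use weight, so multi-drug reports occur and
the report-level counting rule is exercised) and a Bernoulli draw per
event preferred term, with a weighted fallback event where none fired.

A planted signal (drug, event, RRR*) multiplies the event probability in
reports containing the drug by λ = RRR*(1−π)/(1−RRR*π), where π is the
realized fraction of reports containing the drug — calibrated after the
drug draw, so the expected RRR equals the target under the generated
margins. Duplicates are injected as an extra, content-identical case
version for a Bernoulli(duplicate_rate) subset of cases.

Deduplication keeps the highest case version per case id, then collapses
records identical on (sex, age, country, drugs, reactions, quarter) —
standard practice for versioned spontaneous-report files; the quantitative
claims this pipeline reproduces do not depend on the collapse rule. Ages
outside parseability map to Unknown; age bins are ≤18, 19–40, 41–64, ≥65.
Percentages are rounded half-up to two decimals so that published percent
columns recompute exactly from their counts. All drug role codes
(PS/SS/C/I) are retained by default; restriction to suspects is a
configuration choice, since disproportionality conventions differ.

## GWAS simulation and meta-analysis

Summary statistics are simulated directly at the summary level (no
genotypes): standard errors follow the binary-trait approximation
se ≈ 1/√(2f(1−f)·n_eff) with n_eff = 4/(1/n_cases + 1/n_controls), and
default arm sizes mirror a small-case biobank pairing (155/361,039 and
489/445,865 — which is why single-study hits are rare and pooling
matters). Effect alleles are randomly swapped between the two studies and
a small fraction of SNPs gets palindromic alleles, to exercise
harmonization; pQTL instruments are emitted oriented to the
exposure-increasing allele, the convention under which directional
pleiotropy keeps a consistent sign through MR-Egger's orientation step.

Pooling is effect-size (inverse-variance) weighted rather than
sample-size weighted because downstream MR consumes pooled betas. The
inflation factor uses the median-χ² estimator with the 0.4549 constant.
Loci merge genome-wide-significant hits within 500 kb on a chromosome —
a conventional window; none is dictated by the method. The QQ expected
quantiles use the (i−0.5)/n rank rule.

## Mendelian randomization

Instrument selection: cis window ±1 Mb around the encoding gene,
p < 5×10⁻⁸, F = (β/se)² > 10, then greedy LD pruning (keep the smallest-p
SNP, drop R² ≥ 0.1 neighbours, repeat). Reverse MR passes `locus=None`,
dropping the cis restriction while keeping the other thresholds, with
disease as exposure and each protein as outcome.

Estimators use first-order delta weights (exposure uncertainty ignored),
the convention of standard two-sample MR software: Wald ratio β_y/β_x
with se = se_y/|β_x|; fixed-effect IVW as the weighted regression of β_y
on β_x through the origin; MR-Egger as the weighted regression with free
intercept, multiplicative overdispersion φ = max(1, Q/(n−2)) and t(n−2)
inference; weighted median by cumulative-weight interpolation; weighted
and simple mode by the kernel-smoothed empirical density of ratio
estimates (modified Silverman bandwidth, φ = 1, configurable). Median and
mode standard errors come from a seeded parametric bootstrap (200 draws).
Cochran's Q uses weights β_x²/se_y² with n−1 df (IVW) or n−2 (Egger).

The robustness verdict is true iff Egger intercept p > 0.05, Q p > 0.05
and the primary estimate's sign is shared by at least two sensitivity
estimators; with fewer than three instruments the first two clauses are
vacuous and all available estimators must agree. FDR (Benjamini–Hochberg,
via statsmodels) is applied per exposure dataset, mirroring analyses that
report per-panel significant sets and their overlap.

Calibration under the generator's default conditions (50 independent
instruments, deCODE-scale exposure n = 35,559, outcome 644 cases /
806,904 controls): IVW mean bias < 0.01 at β = 0.3 over 500 replicates,
and type-I error 0.05 ± 0.02 at the null over 1,000 replicates — both
asserted in the acceptance suite.

## Network and enrichment

The edge-list loader keeps combined scores ≥ 400 (the conventional
medium-confidence cut; configurable), symmetrizes and drops self-loops.
Cross-set counting considers only A–B edges; the sums of cross-degrees
over either side equal the cross-edge count by construction.
Over-representation is the one-sided hypergeometric upper tail against a
universe defaulting to the union of pathway genes (the background any
gene-set tool effectively uses when none is supplied), BH-adjusted across
pathways. Tissue profiles are row subsets of the expression matrix with
an appended per-tissue arithmetic mean.

## Pipeline

A single YAML config drives the stage chain; the run seed fans out to
per-stage seeds via SHA-256 of `"{seed}:{stage}"` (truncated below 2³¹),
so toggling stages never changes another stage's stream. All tabular
outputs are TSV; signal tables print at two decimals. The manifest
records the config hash, per-stage timings and record counts, and
checksums of any external inputs; reruns under an identical config are
byte-identical except timings.

## Problem sizes and limitations

Default synthetic sizes — 20k–100k reports, 10k SNPs, tens of proteins
with ~12–50 instruments — were chosen so the full chain and its
calibration studies complete in seconds to a few minutes on one core
while leaving planted effects comfortably detectable; they are the
package's own desk-scale choices, two to three orders of magnitude below
the real databases they emulate.

What the generator does *not* emulate, and what passing tests therefore
do not certify about real data: reporting biases and duplicate reports
that differ subtly in content (only identical-content duplicates are
injected); MedDRA hierarchy effects (matching is exact preferred-term);
realistic LD (block-constant R² matrices only, with no LD-aware
inference); linkage between the pQTL panels and the meta-analysed GWAS
(the MR outcome is simulated per protein rather than drawn from the
meta-analysis stage); and winner's-curse or sample-overlap biases in MR.
Real-data quantities that depend on external databases — total report
counts, the identity of significant loci and proteins, interaction counts
against a specific STRING release — are out of desk scope; the pipeline
reproduces their structural analogues on planted synthetic truth, and the
published per-row statistics via contingency inversion.
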