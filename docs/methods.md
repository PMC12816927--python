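# Methods

This note documents the models implemented in `mrpv`, the assumptions they
make, the defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical choices that matter for
reproducing results.

## Spontaneous-report model and the ROR

A report database is four relational tables (demo/drug/reac/indi) keyed by
`primaryid`, with case versioning (`caseid`, `caseversion`). Deduplication
keeps the highest version per case, ties broken by the highest `primaryid`;
the source systems do not publish their dedup keys, so version-per-case is
the contract the generator plants and any downstream rule must satisfy.

The reporting odds ratio is computed from report-level 2×2 tables: a report
is a case for an event set if it carries at least one member PT (so a report
with two PTs of the same SMQ counts once), and it belongs to the target
margin only through a primary-suspect (PS) drug role — secondary-suspect and
concomitant mentions stay in the comparator. The Woolf interval requires all
four cells positive; zero-cell tables are reported as *not evaluable* unless
the Haldane–Anscombe 0.5 correction is requested. The signal criterion is
the standard one (`a ≥ 3` and lower 95% limit > 1). No multiplicity
adjustment is applied — raw RORs are the convention in disproportionality
screening — but every screen reports its number of evaluable tests so users
can post-filter.

Stratified screens (indication, sex) restrict the database *before* building
the tables, so the comparator is the same-stratum remainder. This is a
deliberate choice: comparing a weight-loss drug against other weight-loss
drugs controls indication confounding; the whole-database comparator is
available by simply not passing a stratum.

## Report generator

Reports are independent. Each case draws a PS drug from the catalog, an
indication from that drug's profile, demographics from fixed categorical
distributions (US-dominated reporter mix, 65.6% female among sex-known
reports by default), and events as independent Bernoulli trials per catalog
PT. A planted odds ratio R for (drug, event, stratum) multiplies the
event's reporting odds by ρ for matching reports: for a single PT, ρ = R
makes the report-level 2×2 table reproduce R exactly in expectation; for an
SMQ, a common per-member odds multiplier is solved with Brent's method so
the compound "any member PT" event has odds ratio exactly R under
independence. Reports that sample no event receive a filler PT (mapped to a
dedicated general-disorders chain) so every report carries a coded event
without perturbing any target table. With duplicate rate d and n records
requested, exactly ⌊dn⌋ cases are emitted twice (identical content,
version 2, new primaryid), so the post-dedup survivor count is exact by
construction.

What the generator does **not** emulate: reporting trends over time,
drug–drug interactions, correlated event co-reporting beyond the planted
structure, notoriety biases, or free-text coding noise. Passing tests
therefore demonstrate correctness of the estimators and plumbing against a
clean reporting model, not robustness to the messiness of real spontaneous
reports.

## Summary-statistics generator

Statistics are generated directly at the summary level: given joint
per-allele effects b and LD correlation R, marginal effects are Rb and
observed estimates are drawn b̂ ~ MVN(Rb, D R D) with D = diag(se),
se_j = 1/√(2 maf_j (1−maf_j) n), independent noise across traits
(two-sample, non-overlapping cohorts — the design assumption of the MR
methods). Binary-trait effects are log odds ratios throughout; case/control
imbalance enters only through the effective sample size
4/(1/n_case + 1/n_ctrl), which is what the scenario's `n_gwas` denotes.
Individual-level genotypes are never simulated: every downstream method
consumes summary data, and the MVN model is the exact sampling distribution
implied by it.

Allele bookkeeping exercises the harmonization paths: a configurable
fraction of variants is palindromic (default 10%), and outcome/mediator
records are emitted with swapped allele order (default 25%; beta negated,
EAF complemented) or on the opposite strand (default 10%; representation
only). The exposure file and the LD matrix share one canonical coding, so
LD signs stay interpretable after harmonization. Observed EAFs carry
binomial-scale sampling noise.

Scenario presets define the study conditions used throughout validation:

- **independent_cis**: 22 independent instruments, per-allele expression
  effects ±U(0.15, 0.45) SD, MAF U(0.1, 0.4), eQTL n = 31,684 and GWAS
  n = 500,000. This is the fully-clumped drug-target regime: the resulting
  instrument F statistics (≈130–1100) match a study whose instruments all
  exceed F = 47.
- **glp1r_like**: the same 22 signals embedded as leaders of 5-variant LD
  blocks (AR-1 ρ = 0.6 within block) to exercise clumping; greedy clumping
  at r² < 0.01 must recover exactly the 22 leaders. Palindromic variants are
  excluded from this preset — it emulates an instrument set in which every
  SNP survived harmonization.
- **cis_region**: 61 variants, AR-1 ρ = 0.85, one causal eQTL (0.35 SD) in
  the middle, GWAS n = 480,289 — the SMR/HEIDI regime. `mode="linkage"`
  adds an outcome-only variant two steps away (r² ≈ 0.52 with the eQTL,
  direct log-OR 0.1, i.e. a genome-wide-significant hit, z ≈ 28): the
  configuration HEIDI exists to reject.
- **reverse**: adds 8 strong outcome loci (log-OR 0.15, z ≈ 45–75) that leak
  a weak association into the expression statistics (0.085 SD, z ≈ 6–10) —
  instruments that pass the p < 5e-8 screen but explain more variance in
  the outcome, the Steiger target. The leaked effect size is set so the
  variants clear the significance filter while remaining unambiguous
  reverse signals.
- **outlier**: one instrument receives a direct outcome effect of 5 outcome
  SEs (MAF fixed at 0.25 so "its SE" is well defined).
- **mediation**: total effect ln(0.915) with 18% flowing through a mediator
  (β_XM = −0.25 SD/SD; β_MY and the direct effect derived), plus 30
  independent genome-wide mediator instruments (±U(0.025, 0.06) SD,
  n = 500,000).
- Directional pleiotropy (`pleio_mean`, `pleio_sd`) is planted relative to
  the exposure-increasing allele orientation — the MR-Egger convention.
  Planted in raw allele coding it would cancel after Egger orientation and
  the scenario would not be directional at all. The calibration scenario
  uses mean 0.02 / sd 0.005 on all instruments: modest ubiquitous direct
  effects about two-thirds the size of the mediated per-allele effect.

## Instrument QC

Selection: p < 5e-8 and minor-allele frequency > 1%, then greedy clumping
(ascending p; keep iff r² < 0.01 with everything kept; r² from the provided
LD matrix — no reference-panel fetching), then F = (β/se)² ≥ 10. The
per-SNP F form is used rather than the cohort (n−2)R²/(1−R²) form because
only summary data are available and the two agree asymptotically. An empty
survivor set raises an error carrying per-stage counts. The cis window,
where one is needed (mediation), is ±1 Mb around the strongest cis
instrument.

Harmonization resolves allele order swaps (sign/frequency flip) and strand
representation flips (complement match). Palindromic variants are retained
only when both traits' EAFs fall on the same side of 0.5 and the MAF is
below 0.42; anything else is dropped with a recorded reason — a
conservative policy chosen because allele order cannot distinguish a
strand flip from a true swap, and near-0.5 frequencies make the EAF signal
unreliable. Mismatched allele pairs are dropped with reason, never
silently.

Steiger filtering keeps a SNP iff r²_exposure > r²_outcome (r² = z²/(z²+n)
per trait) *and* the two-sided z-test on the difference of
Fisher-transformed correlations has p < 0.05. It runs per-SNP before
estimation.

## Estimators

- **IVW** defaults to multiplicative random effects: the fixed-effect SE is
  inflated by √(Q/(k−1)) when that exceeds 1, the common default of the
  established two-sample MR tooling; a fixed-effect flag is available. The
  first-order Wald-ratio SE ignores exposure-side variance (the default of
  the same tooling); at the strong-instrument regimes used here the MRE
  inflation absorbs the resulting mild underdispersion, and measured CI
  coverage is ≈0.95.
- **MR-Egger** orients instruments so all exposure betas are non-negative
  (required for the intercept to be interpretable) and uses classical
  σ-scaled weighted-least-squares inference with t (k−2 df) tests. Under
  the known-weights normal model this test is exactly calibrated, whereas
  truncating the dispersion at 1 makes the intercept test conservative
  (measured type-I ≈ 0.04 at k = 22). With the intercept constrained to
  zero the fit reduces exactly to fixed-effect IVW (no dispersion
  estimate), which doubles as a cross-check between the two code paths.
- **MR-PRESSO** implements the global RSS test (each SNP judged against the
  leave-that-SNP-out IVW fit) with parametric simulations, per-SNP outlier
  p-values from each SNP's simulated residual distribution
  (Bonferroni-corrected, flag at 0.05), and IVW on the non-outliers as the
  corrected estimate. The distortion test is not implemented (it is not
  used in the motivating workflow). 1000 simulations by default,
  vectorised, bit-reproducible for a fixed seed.
- **Mediation** gates on both steps being nominally significant (p < 0.05)
  before computing the product of coefficients; the proportion's CI is the
  delta-method normal interval (a parametric bootstrap is used as a test
  oracle, not as the reported interval). Step 2 is univariable — not
  adjusted for the exposure, mirroring the situation where cis-restricted
  exposure instruments rule out multivariable MR. To keep that univariable
  step unbiased at desk scale, the pipeline excludes the exposure's cis
  window from the mediator instrument set: with only ~30 mediator
  instruments, a cis SNP would carry ~1/30 of the weight and drag the
  mediator→outcome estimate toward the exposure's direct effect, a leakage
  that is negligible in genome-wide practice (hundreds of instruments) but
  not in a toy panel.
- **SMR/HEIDI**: the HEIDI SNP selection thresholds (eQTL p < 1.57e-3,
  r² with the top SNP in [0.05, 0.9], at most 20 and at least 3 SNPs)
  follow the published SMR-tool defaults; all are exposed as parameters.
  The weighted-χ² null is evaluated by seeded Monte Carlo over the
  eigendecomposition of the z_d correlation matrix (100,000 draws by
  default) rather than a saddlepoint approximation — simpler, testable,
  and accurate at the 0.01 decision threshold (p-values are stable to two
  decimals when the draw count is doubled). Covariances assume independent
  eQTL and GWAS cohorts. Verdicts: `pass`, `linkage-suspected`
  (HEIDI p < 0.01), or `not-testable` (fewer than 3 qualifying SNPs — a
  value, not an exception).

Known limiting behaviour: the SMR χ²₁ p-value converges to the Wald-ratio
normal p as z_eQTL → ∞, but the *relative* error of the tail probability is
≈ z_G⁴/(2 z_E²), so the 10%-agreement check is meaningful only for
sub-threshold GWAS associations (|z_G| ≲ 2 at z_E = 10); for large |z_G|
both p-values vanish and their ratio is uninformative.

## Thresholds and defaults

| Parameter | Default | Meaning |
|---|---|---|
| `p_max` | 5e-8 | instrument significance (genome-wide) |
| `eaf_min` | 0.01 | minor-allele-frequency floor |
| `r2_max` | 0.01 | clumping LD ceiling |
| `f_min` | 10 | weak-instrument F cut |
| `palindrome_eaf_limit` | 0.42 | palindromic ambiguity MAF bound |
| `steiger_alpha` | 0.05 | directionality test level |
| `gate_alpha` | 0.05 | two-step mediation gate |
| `heidi_alpha` | 0.01 | HEIDI linkage threshold |
| `alpha` | 0.05 | ROR confidence level |
| `min_cases` | 3 | ROR signal criterion on the a cell |
| `presso_n_sim` | 1000 | PRESSO parametric simulations |
| `mc_draws` | 100,000 | HEIDI Monte-Carlo draws |

All are surfaced as named keys in the pipeline config.

## Validation study sizes

The acceptance script and test suite use: 100 random tables for the ROR
oracle; one 200k-report database for planted-signal recovery and 200×20k
null databases for the false-signal rate; 500 replicates for IVW, SMR and
mediation recovery (bootstrap SE comparison on 50 of them, 2000 draws
each); 1000 null + 400 directional replicates for Egger calibration; 200
seeds each for PRESSO and Steiger; 400 seeds per HEIDI mode with 25,000
Monte-Carlo draws per test. These sizes give Monte-Carlo standard errors
well inside the decision margins while keeping a full run to a few minutes
on one CPU.

## Limitations

- Reports and variants are simulated under clean models (independence
  across reports; exact MVN summary noise); real-data pathologies
  (duplicated-but-edited cases, coding drift, sample overlap between
  cohorts, stratification) are out of scope.
- Multivariable MR, PRR/IC/EBGM disproportionality statistics,
  weighted-median/mode estimators, proxy-SNP lookup and multi-ancestry
  analysis are deliberately not implemented.
- The mediator's step-2 estimate remains biased if the mediator's
  instruments have direct outcome effects; the synthetic tests quantify
  behaviour only under the planted chain.
- One known hard bound: when a single outlier carries a direct effect of
  5 outcome SEs, the probability that outlier removal beats the raw IVW on
  a given draw is capped at Φ(2.5·√(u₀U′)/(u₀+U′)) ≤ Φ(1.25) ≈ 0.89 over
  all instrument configurations (u₀ the outlier's weight, U′ the rest), and
  is ≈0.7 at a realistic 22-instrument design — outlier correction removes
  a small bias but pays a variance price on the draws where the remaining
  noise happened to cancel it.
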