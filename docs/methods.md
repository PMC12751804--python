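# Methods

## Scope and data model

The package implements a summary-statistics pipeline: per-variant
association records (chromosome, 1-based position, effect/other allele,
effect-allele frequency, β, se, p, sample sizes) grouped into per-trait
regions, an individuals × variants dosage reference panel for LD queries,
and the derived objects — instruments, MR results, colocalization
posteriors, and the per-gene ledger. Variants are matched across sources
on (chromosome, position) with allele reconciliation, because rsids drift
between resources; allele-swapped records are flipped (β sign, frequency),
and strand-ambiguous A/T and C/G variants are dropped rather than
frequency-resolved, mirroring the reference-panel QC (MAF ≥ 1%,
Hardy–Weinberg 1-df chi-square p ≥ 10⁻⁶ on hard calls, no ambiguous
alleles). All window arithmetic is closed, [pos−w, pos+w].

## Instrument selection

Candidates are cis-eQTLs (±1 Mb of the TSS — the eQTL-catalog convention;
the window is configurable) at *P* < 5×10⁻⁸ for protein-coding genes, with
variants inside the MHC (chr6:25,726,063–33,400,644) removed. Greedy
clumping repeatedly takes the smallest-p remaining variant and removes
everything at reference *r*² ≥ 0.1 against it; ties are broken by position
then alleles so the result is independent of input order. Surviving
variants are harmonized to the outcome and screened by *F* = (β/se)² > 10
and Steiger directionality: variance explained is approximated by
r² = z²/(z²+n) (binary-trait effective sample size
n_eff = 4/(1/n_case+1/n_control) for the outcome), direction requires
r²_exposure > r²_outcome, and the p-value compares Fisher-z transformed
|correlations| with variances 1/(n−3). Steiger runs per variant after
harmonization, so instruments are outcome-specific.

## MR estimators

Single-variant instruments use the Wald ratio β_out/β_exp. The ratio SE is
the full delta method, se² = se_out²/β_exp² + β_out²·se_exp²/β_exp⁴. The
common first-order form (se_out/|β_exp|) is available as an option but is
not the default: with a biobank-scale outcome the outcome z-statistic can
exceed the instrument's, and the first-order interval then collapses
(measured 95%-CI coverage ≈ 0.38 at θ = 0.3 under the simulation
conditions below). Single-variant results additionally carry a Fieller
interval — the set {θ : |β_out − θβ_exp| ≤ 1.96·√(se_out² + θ²se_exp²)} —
which is exact for a ratio of independent normals and bounded whenever
F > 1.96²; measured coverage is ≈ 0.94. Multi-variant instruments are
combined by fixed-effect inverse-variance weighting of the ratios;
correlation between clumped variants (r² up to 0.1) is ignored in the
weights, a documented approximation. Cochran's Q (chi-square, k−1 df) and
I² = max(0, (Q−(k−1))/Q) are reported; heterogeneous variants are not
removed. Significance is Bonferroni within dataset: p < α / (unique genes
tested in that dataset). Egger/weighted-median estimators are out of
scope: cis instruments rarely carry enough variants.

## Colocalization with conditional analysis

Per-variant evidence is the Wakefield log approximate Bayes factor
labf = ½(log(1−r) + z²r) with r = W/(se²+W); prior effect variance
W = 0.15² for quantitative traits and 0.2² for case-control (log-odds),
the de-facto defaults of the method, configurable. The five-hypothesis
posterior is computed in log space with per-variant priors p1 = p2 = 10⁻⁴
and p12 = 5×10⁻⁵; the two-independent-signals term
Σ_{i≠j} BF1_i·BF2_j = exp(S1+S2) − exp(S12) is evaluated with log1p for
stability, and with a single shared variant PPH3 is structurally zero.
The implementation is checked against brute-force enumeration over all
single-variant configuration pairs (agreement ≤ 10⁻⁹ absolute).

Approximate conditional analysis follows the standard summary-data
algebra: with per-variant weight D_j and B_jk = r_jk√(D_jD_k), joint
estimates solve B·β_joint = D·β_marginal. D_j is n_j times the reference
panel's empirical dosage variance — equal to 2·eaf(1−eaf)·n_j under
Hardy–Weinberg, and exactly the OLS cross-product when the panel is the
analysis cohort itself, so joint fits reproduce exact multiple regression
in that case. The phenotypic sum of squares is recovered per variant from
the simple-regression identity y'y = D_j(se_j²(n_j−2) + β_j²) and
aggregated by median; conditional SEs use a per-target residual proxy that
reduces exactly to the marginal SE when the conditioning set is orthogonal
to the target. Stepwise selection seeds with the minimum-p variant,
repeatedly adds the smallest conditional p below 5×10⁻⁸ (skipping
candidates at reference r² ≥ 0.9 against the model), drops model variants
whose joint p rises above the cutoff, and stops at a fixed point (at most
10 signals per trait). Summary/panel allele-frequency mismatches > 0.2
exclude a variant from the conditional algebra.

PWCoCo: marginal colocalization first on the shared-variant window
(±500 kb around the instrumental variant); if PPH4 < 0.8, signals are
selected for each trait and every combination of marginal /
conditioned-on-all-but-one-signal summary statistics is colocalized; the
maximum-PPH4 entry decides. The alternative thresholds 0.7/0.9 are applied
afterwards to the same maximum-PPH4 values from the single run at 0.8 —
matching how alternative cut-offs are explored on one set of
colocalization results — which makes the per-threshold passing sets nested
by construction.

## Ledger, PheWAS, replication

Regions are single-linkage chains of instrumental-variant positions with
pairwise gaps ≤ 250 kb on one chromosome; a region with ≥ 2 unique passing
genes is flagged as horizontal pleiotropy. Novelty requires every
instrumental variant of every passing result to be both uncorrelated
(reference r² < 0.2) with and distant (> 250 kb) from every known disease
variant — the strict AND reading — and the gene must not appear on a
prior-study exclusion list. Prioritized = passing ∧ lone-in-region ∧
novel; direction concordance across datasets is reported (a gene can be
prioritized yet discordant, the pattern seen when tightly linked variants
have opposite expression effects in different cell types). PheWAS scans
query the top instrumental variant (smallest exposure p) across a
phenotype library; associations at *P* < 5×10⁻⁵ trigger PWCoCo against the
eQTL track, and a hit passes only with PPH4 > 0.8. Replication re-selects
instruments from an independent eQTL source with the primary rules and
runs MR against an inverse-variance fixed-effect meta-analysis of two GWAS
(effect-size METAL scheme, chosen because β/se are available in the data
model); genes are reported with sign concordance and the *P* < 0.1
reporting threshold.

## Synthetic data generator

Genotypes: each haplotype is a latent AR(1) Gaussian (within-block
correlation ρ = 0.8, blocks of 20 variants by default) thresholded at the
MAF-matched quantile; dosage = two independent haplotypes. This gives
direct control of block LD with no external simulators. Dichotomization
attenuates correlation, and mismatched MAFs cap attainable dosage r² well
below 1, so the distinct-causal pair is constructed directly: the second
causal variant's haplotype is a probabilistic copy of the first (copy
probability √r², preserving MAF), hitting the target r² = 0.7 by design.

Expression is simulated at the individual level (default cohorts of 500,
independent per dataset) with causal standardized effects scaled to
explain eqtl_h2 = 0.1 of expression variance, and summarised by marginal
per-variant regression. The disease GWAS is simulated at the summary
level: z ~ MVN(Rλ, R) with λ_j = √n_eff·a_j, where a holds standardized
liability effects, R is the panel LD matrix (eigenvalue-clipped at 10⁻⁸
when needed), and β = z·se with se = 1/√(n_eff·2·eaf(1−eaf)). Defaults
reproduce the scale of the seed study: 18,942 cases / 501,638 controls
(n_eff ≈ 73k). Under vertical causation the liability effects are
θ × (standardized expression effects), so the causal effect of expression
on liability is recovered by MR. Scenario ground truth (causal ids,
θ, shared-signal indicators) is recorded before noise and serialized
beside fixtures. All randomness flows from one seed via named substreams;
identical specs produce identical files.

What the generator does not emulate: realistic demographic history and
recombination maps, allele-frequency/LD mismatch between panel and study
populations, imputation uncertainty, trans-eQTLs, sample overlap between
exposure and outcome, and population stratification. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to those real-data complications.

## Validation conditions and measured limits

The operating-characteristic checks (tests/test_acceptance.py,
scripts/acceptance.py) use: eQTL cohorts of 500 with eqtl_h2 = 0.1
(causal z ≈ 7.5), GWAS n_eff = 70,000 with per-variant liability variance
5×10⁻⁴ (z ≈ 5.9), 100-variant regions; 200 replicates for the coloc and
MR checks, 100 for masked-signal rescue, 1000 gene-outcome pairs for null
calibration, 20 replicates of the 50-gene planted study. In the
masked-secondary scenario the shared (secondary) disease signal carries
liability variance 10⁻³ (z ≈ 8.4) so that both signals are unambiguously
selectable and the check isolates the conditioning behaviour rather than
discovery power; the masking signal carries 2×10⁻³.

A measured, inherent limit worth stating: with distinct causal variants at
r² = 0.7 and the signal strengths above, the per-variant Bayes-factor
discrimination between the two configurations is ~5–7 nats, below the
prior log-ratio log(p12/(p1·p2)) ≈ 8.5 nats, so the posterior favors a
shared signal in a large majority of replicates (~80%). This is a
property of ABF colocalization at these powers — confirmed against the
enumeration oracle — not an implementation artifact; discrimination
appears once both traits carry stronger signals (see the unit test with
eqtl_h2 = 0.3, GWAS variance 5×10⁻³). Conditioning cannot help here, since
conditioning never lowers the marginal PPH4 already achieved.

## Numerical choices and degenerate inputs

Two-sided p-values use the normal, not t, distribution throughout, floored
at the smallest positive float; missing p-values are recomputed from β/se.
Zero-variance dosage columns are an error for LD queries; duplicate or
collinear (r² ≥ 0.9) selections are an error for joint fits, with the
offending pair named. Empty harmonization intersections return empty
results for the caller to handle; a colocalization window with no shared
variants is an error for that pair. Clumping and stepwise selection break
p-value ties deterministically (position, then alleles). Output tables are
written with %.10g formatting, which with the digest-keyed stage cache
makes reruns byte-identical.

## Problem sizes

Default fixture sizes (reference panels of 2,000, eQTL cohorts of 500,
100-variant regions, 50-gene studies) were chosen so the statistical
regimes of interest — genome-wide-significant instruments, borderline
secondary signals, block LD — are realized while a full validation run
completes in about two minutes on a single CPU.
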