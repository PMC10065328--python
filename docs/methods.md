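# Methods

This note records the statistical models, the numerical choices, and the
design decisions behind `epiblup`, together with what the bundled simulator
does and does not emulate.

## Data model

All genotypes are doubled-haploid (DH): fully homozygous lines, one bit per
locus. A *predictor panel* is an n × p binary matrix over SNPs or
haplotype-block variants (a block variant is the indicator that a line
carries a particular founder segment). Phenotypes are per-line BLUEs keyed
by (line, year, environment, trait); the package treats them as adjusted
entry means, so the only fixed effect in every mixed model is a per-year
intercept.

Loaders enforce the 0/1 coding. Heterozygous calls are an error in strict
mode (a DH panel should not contain them) and are treated as missing in
lenient mode, where missing calls are imputed to the rounded column mean
with a logged count. Monomorphic predictors are dropped at load with a
logged count: the intended inputs are post-QC panels, so this is a guard,
not a modelling step.

### VIF pruning

`vif_prune` reimplements the idea of PLINK's `--indep <window> <step> <vif>`
(defaults 50, 5, 2): a window of `window` predictors slides by `step` along
the map order; within each window the predictor with the largest variance
inflation factor is removed until all VIFs are at or below the threshold.
It is *not* a bit-exact PLINK clone — PLINK's internal tie handling is not
published — and exact equivalence is a non-goal. Ties on the maximum VIF
remove the later predictor in map order; window enumeration stops once a
window reaches the end of the panel, truncating the final window if it
overruns. Positions are 1-based (VCF convention); window indexing is
0-based half-open internally.

## Kernels

**GBLUP.** VanRaden relationship from DH dosages X = 2M, frequencies taken
from the analysed panel itself, denominator Σ 2f(1−f). Fully inbred lines
give a mean diagonal near 2; estimators that convert variance components to
heritabilities must therefore use the kernel scale (see `genomic_heritability`,
which multiplies σ²_g by mean diag(K) − mean(K)).

**ERRBLUP.** One 0/1 column per unordered predictor pair including
self-pairs — p(p+1)/2 columns, which is exactly the arithmetic behind the
published interaction counts (3 330 blocks → 5 546 115 pairs). The kernel
is the VanRaden-analogous centred cross-product of that design. The paper
trail for this construction does not print a formula, so the
centring/scaling (column-frequency centring, Σf(1−f) denominator) is fixed
here and locked in by a brute-force oracle test. The fast path never
materializes the design: for binary M with S = MMᵀ, the uncentered pair
cross-product is (S² + S)/2 elementwise, and the row/column centring terms
and the scale c are all functions of S. Lines sharing s loci at value 1
share s(s+1)/2 pair columns — the identity the oracle test enumerates.

**sERRBLUP.** Identical construction restricted to a selected pair subset.
Selected columns are materialized in batches (default 2²⁰ columns; results
are batch-size invariant by contract and test) and centred by their
*full-panel* frequencies.

**PSD guard.** Kernels are stored as constructed; a ridge δI with
δ = max(0, −λ_min) + 10⁻⁸ · mean(diag) is applied when a kernel enters a
REML fit, and the ridge is logged. Keeping constructors ridge-free keeps
the fast-path/brute-force and sERRBLUP(q=1) = ERRBLUP identities exact.

## Interaction selection

Pair effects are backsolved from the genetic values of an ERRBLUP fit via
the equivalence of the kernel and random-regression formulations of BLUP:
α̂ = (1/c) Wᵀ K⁺ ĝ, with K⁺ the eigendecomposition pseudo-inverse of the
unridged kernel (singular values below 10⁻¹⁰·σ_max zeroed). The ranking
criterion is the variance a centred 0/1 column contributes,
v̂ = α̂² f(1−f). `select_top(q)` keeps the ⌈qP⌉ largest v̂ with
lexicographic pair-index tie-breaks, making selections total,
deterministic, and nested across q. The default q grid is
{10 %, 5 %, 1 %, 0.001, 0.0001, 0.00001}.

Selection is computed **once per evaluation on the complete source-year
data of the target environment**, never inside cross-validation folds.
This mirrors the across-year protocol: borrowing information from the
previous season is the point of the design, and target-season test
phenotypes never reach the kernel, the selection, or any training fit (a
dedicated leakage test asserts this).

Because the backsolve/variance formula is fixed here rather than copied
from a published equation, it is validated behaviourally: a planted pair
carrying at least half the genetic variance must appear in the top-1 %
ranking in ≥ 90 % of simulation replicates, which it does with a wide
margin.

## Mixed models

**Univariate.** y = 1μ + g + e with g ~ N(0, σ²_g K). REML is maximized
exactly over λ = σ²_g/σ²_e by eigendecomposition of the intercept-projected
kernel: a 161-point grid on ln λ ∈ [−20, 20] brackets the optimum, followed
by bounded scalar minimization (xatol 10⁻¹⁰). The restricted likelihood in
this projected form equals the dense formula
−½[(n−1)ln 2πσ²_e + ln|V| + ln|XᵀV⁻¹X| − ln|XᵀX| + yᵀPy], which the test
suite evaluates directly as an oracle. BLUPs for unphenotyped lines come
from the kernel cross-block. A kernel proportional to the identity on the
contrast space makes λ unidentifiable; the fit still returns (with a
warning) the boundary/interior optimum found.

**Bivariate.** The same trait in two seasons is modelled as two traits:
genetic covariance G₀ ⊗ K restricted to the observed incidence, residuals
independent within and between years with year-specific variances. The
residual covariance between years is structurally zero — different seasons
are grown on different plots — and this is a modelling decision, not an
estimate. Unbalanced line sets are supported; a line phenotyped in one year
only contributes through K and its one record.

Estimation: EM-REML via the mixed-model equations (the conditional
expectation updates G₀ ← (ÛᵀK⁻¹Û + tr-correction)/N and σ²_e,t ←
(êᵀê + tr-correction)/n_t), which is monotone in the restricted
likelihood, accelerated by an average-information (AI) step. The AI
proposal is accepted only if, after eigenvalue-clipping G₀ to the PSD cone
(clip at 10⁻¹⁰·trace) and flooring variances at 10⁻¹⁰·var(y), the
restricted likelihood does not decrease; otherwise the EM step is used.
Convergence requires both the maximum relative parameter change < 10⁻⁶ and
a log-likelihood change < 10⁻⁶. If the two years share no phenotyped lines
and no starting values are supplied, σ_g12 is unidentifiable and is fixed
at zero with a warning.

**Initialization protocol for cross-validation.** Components are
pre-estimated on the full two-year data with an iteration cap of 100; if
the pre-fit has not converged, the iteration-100 components are still used
as starting values. Each fold fit starts from the pre-fit components with
a cap of 50 iterations. A fold fit that does not converge is replaced by
BLUPs computed with the components *fixed at the starting values*
(`fixed_fallback=True`); the evaluation reports the fraction of converged
folds and the mean predictive ability over converged-only folds alongside
the all-folds mean.

Default starting values when none are given: half the phenotypic variance
to each of the genetic and residual components per year, and a genetic
covariance seeded from the phenotypic correlation on commonly phenotyped
lines (clipped to ±0.9 of its bound).

**Genomic correlation.** r_g = σ_g12/√(σ²_g1σ²_g2) from the full-data fit,
clipped to [−1, 1] with the clip logged.

## Evaluation pipeline

5-fold cross-validation, 5 repetitions by default (each repetition an
independent equal-split partition of the target-year phenotyped lines,
sizes differing by at most one, deterministic given a seed). Per fold, the
training data are the complete source-year records plus the target-year
records outside the test fold; predictive ability is the Pearson
correlation between predicted target-year genetic values and observed test
phenotypes; prediction accuracy divides the mean by √h², with h² supplied
externally per trait (the simulator provides the true value). Univariate
baselines: GBLUP trained within the target year only, and GBLUP trained on
the per-line average of both years' phenotypes.

Folds with fewer than three phenotyped test lines, or with degenerate
(zero-variance) predictions, are skipped with a log entry; the mean is
taken over computed folds. This skipping rule is this package's own.

`gain_regression` regresses the gain in predictive ability (best model
minus baseline) on the genomic or phenotypic correlation between years:
ordinary least squares, with the two-sided t-distribution p-value of the
Pearson correlation and no multiple-testing correction.

## Simulator

`simulate_dh_panel` builds lines as founder-haplotype mosaics: per region,
founder haplotypes are drawn with allele frequencies uniform on
[0.1, 0.9] (avoiding monomorphic columns), and each line follows a Markov
founder-identity chain switching with probability `switch_rate` between
adjacent SNPs. Low switch rates give long shared segments and hence block
LD. The block panel has one column per (region, founder): the indicator
that a line carries that founder over the majority of the region — a
deliberate simplification of windowed block-calling; the pipeline only
needs a binary block-variant matrix.

`simulate_two_year_phenotypes` draws additive effects at `n_add_qtl` SNPs
and interaction effects at `n_epi_pairs` segregating pairs
(1/1-combination frequency in [0.05, 0.95]), jointly across years with
correlation `r_g_target` (shared + year-specific components), so genomic
correlation is induced at the effect level and per-year variances stay
interpretable. The epistatic effect vectors are rescaled by one common
factor — the geometric mean of the per-year exact factors — so the
epistatic share of genetic variance matches `epi_var_fraction`
approximately per year without distorting the across-year effect
correlation. Residuals per environment are scaled to the target per-year
heritability, and a configurable fraction of lines is unphenotyped per
year (defaults 2 % / 20 %, emulating a season with markedly fewer
phenotyped lines).

Default architecture is polygenic (100 additive QTL over 25 LD regions of
a 500-SNP panel): with fewer effective loci the realized across-year
correlation of genetic values fluctuates strongly around its target
(Jensen-type attenuation of a correlation ratio), whereas at these
defaults the Monte Carlo mean is within a few hundredths of the target.

What the simulator does **not** emulate: realistic genetic maps or
recombination landscapes, allele-frequency spectra after selection/drift,
genotype-by-environment interaction (environments share one genetic value
per year), non-Gaussian residuals, and block-calling artefacts. Passing
tests therefore demonstrate correctness of the machinery and behaviour
under the assumed generative model, not performance guarantees on any
particular real panel.

## Problem sizes used by the test suite

The scientific acceptance tests run at sizes chosen to exercise every code
path while keeping the suite fast: ERRBLUP fast-path equivalence on 200
random instances (n ≤ 12, p ≤ 10); bivariate recovery at n = 300, p = 500
over 25 replicates (targets h² = 0.7/0.6, r_g ∈ {0.9, 0}); planted-pair
recovery over 50 replicates at n = 300, p = 80; model-ordering checks at
n = 250–300 with 2-repetition CV over 3 (additive ordering) and 10
(epistatic gain) simulation replicates; block-versus-SNP equivalence at
500 SNPs versus ~48 block variants (a 100-fold pair-count reduction) with
segment-level causal architecture.

## Known limitations

- The bivariate solver inverts dense mixed-model-equation systems of size
  2N + 2; it is comfortable to a few thousand lines but is not engineered
  for biobank scales.
- ERRBLUP's fast path is exact only for binary panels (the (S²+S)/2
  identity); heterozygous panels would need the four-category combination
  coding, which is out of scope.
- Selection ranks pairs by the fixed criterion α̂²f(1−f); alternative
  criteria (absolute effect size, significance tests) are not implemented.
- `vif_prune` approximates, but does not bit-match, PLINK's `--indep`.
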