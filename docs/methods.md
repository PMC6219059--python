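# Methods

## Model and assumptions

All evaluations are single-trait animal models
`y = Xβ + Zu + e`, `u ~ N(0, K σ²_g)`, `e ~ N(0, I σ²_e)`, solved exactly
through Henderson's mixed-model equations with a dense inverse of the
coefficient matrix. `K` is either the pedigree numerator relationship
matrix (tabular method, so `diag(K) = 1 + F` exactly) or a VanRaden
Method 1 genomic matrix `ZZ′/(2Σp_j(1−p_j))`. The model genetic variance
`σ²_g` is the *equilibrium* variance `σ²_u,∞ = (1−k)σ²_u`; without
selection (`k = 0`, the default) it equals the base variance. Using the
same `σ²_u,∞` in the solver, in the prediction-error (co)variance blocks
`C_uu = σ²_e · (animal block of the coefficient-matrix inverse)` and in
the LR expectations keeps all three internally consistent — this is the
package's resolution of the question which variance the statistics should
refer to when partial- and whole-data estimates differ (the whole-data,
user-supplied components are authoritative; per-partition REML estimates
are reported as a diagnostic, not substituted).

The comparison of a partial and a whole evaluation assumes
`Cov(û_w, û_p) = Var(û_p)`, unbiasedness of both runs, and joint
normality. Both assumptions are exactly true in the simulator when the
solver uses the true components, which is what makes the simulator an
oracle: every statistic can be checked against true breeding values and
against its own PEV/PEC expectation.

## Statistics and conventions

Sample (co)variances inside the ratio statistics use the 1/n convention
(the normalization cancels); the variance of EBV change `Vd_wp` uses
1/(n−1). The bias statistic is `mean(partial) − mean(whole)`. The variance
factor of a focal cohort is the trace form `mean(diag K_f) − mean(K_f)`
(grand mean *including* the diagonal), which is the exact quantity
appearing in the quadratic-form expectations; it differs from the verbal
`1 + F̄ − 2f̄` by O(1/n) self-coancestry terms. Accuracy estimators
(`ρ²_cov`, `r/h∞`) are never clipped: out-of-range values are returned
with a warning so users see the noise. Population accuracy from PEV/PEC
clips only a numerically negative numerator at zero.

Per-subset statistics ("reference" = individuals keeping records in the
partial data, "validation" = individuals with masked records) are computed
with subset means, i.e. each statistic is evaluated entirely within its
subset. Masking operates on records; the validation set is the individuals
with at least one masked record (equivalent when each animal has one
record). The number of masked records follows a floor rule.

## Fixed effects and precorrection

Factors are treatment-coded against an intercept (first level dropped);
solutions of estimable functions, EBV and the precorrected data
`y* = y − Xβ̂` are invariant to the constraint, which is tested. `β̂` for
precorrection comes from the whole-data solve (an option allows the
partial-data solve for sensitivity analysis). Rank-deficient designs are
rejected with the confounded columns named via a pivoted QR.

## EM-REML

Variance components for the per-partition heritability diagnostic are
estimated by EM-REML with the classical updates
`σ²_u ← (û′K⁻¹û + tr(K⁻¹C_uu))/q` and
`σ²_e ← (y′y − β̂′X′y − û′Z′y)/(n − rank X)`. The relationship matrix is
marginalized to the phenotyped individuals (the restricted likelihood is
unchanged, the per-iteration cost drops from (all animals)³ to
(phenotyped)³). Because the EM map contracts very slowly when the start is
far from the optimum or the optimum sits near a boundary, every fifth
iteration applies componentwise Aitken extrapolation, accepted only if the
restricted likelihood (computed from the same Cholesky factor) improves.
Convergence is declared at relative parameter change < 1e-6 or an absolute
likelihood change < 1e-6 on −2·logL_R; a collapse of either component
(e.g. σ²_u below 1e-3·σ²_e) is flagged on the result rather than raised.
The implementation was cross-checked against a direct Nelder-Mead
maximization of the eigendecomposition form of the restricted likelihood.

## Simulator

`simulate_population` builds discrete non-overlapping generations
(founders plus `n_dams × offspring_per_dam` offspring per generation; each
dam is mated to one sire, sires rotate over a shuffled dam list). True
breeding values follow the infinitesimal model: founders `N(0, σ²_u)`,
offspring = parent average + Mendelian sampling with variance
`½(1 − (F_s+F_d)/2)σ²_u`, with inbreeding tracked exactly through an
incrementally grown tabular NRM, so `Var(u) = A σ²_u` holds by
construction. Phenotypes are `y = contemporary-group effect + u + e` with
balanced random group assignment within generation and Gaussian group
effects (the field gives no canonical effect-size distribution; SD 0.5 on
a unit phenotypic scale is the default). Optional truncation selection (on
phenotype, TBV, or PBLUP EBV) picks the top `n_sires`/`n_dams` candidates
per sex; the realized per-generation genetic variance is recorded so the
equilibrium (Bulmer) variance can be read off. Genotypes are gene-dropped
at unlinked biallelic loci.

What the generator does *not* emulate: linkage and LD (so GRM ≈ NRM
convergence holds only in the unlinked sense), overlapping generations,
non-Gaussian traits, heterogeneous residual variances, maternal or
permanent-environment effects, and genotyping error. Passing tests
therefore certify the estimators under the model's own assumptions — the
setting in which their expectations are derived — not robustness to model
misspecification on real data.

## Study conditions and problem sizes

The standard replicated experiment is the unselected two-generation design:
20 sires × 100 dams × 5 offspring (500 phenotyped offspring), h² = 0.4 on
a unit phenotypic scale, 10 contemporary groups, 50% random record
masking. Replicate counts as used by the checks: 300 redraws of (u, e) for
the expectation-agreement experiment (at fixed mask, so the PEV/PEC
targets are constants), 500 fresh mask+data replicates for the headline
`b_wp`/`μ_wp` means, 200 maskings of a fixed dataset for the
heritability/predictivity sign pattern, 1000–1500 replicate families for
the parent-average results, and 12 runs of an eight-generation
truncation-selection scheme (30 sires × 150 dams × 4, selection on TBV)
for the selected-to-unselected accuracy conversion. Stochastic checks use
three Monte-Carlo standard errors of the replicate mean as their band.

## Design choices where the design was open

* **Accuracy conversion under selection.** The selected-to-unselected
  conversion is implemented as `acc₀ = sqrt(k + (1−k)acc²_∞)` — constant
  prediction error, reliability re-referenced from `σ²_u,∞` to `σ²_u`. It
  is validated by simulation before use: under equilibrium truncation
  selection with parent-average evaluation, the prediction error is the
  Mendelian-sampling variance in both the selected and the unselected
  population, so converting the realized selected-cohort accuracy with the
  realized k must recover the closed-form unselected accuracy `sqrt(½)`.
* **Young-bull counterexample.** The closed form uses the progeny-testing
  ratio `λ = (4−h²)/h²`; a brute-force selection-index computation (joint
  MVN of the dam record and n half-sib progeny records) reproduces it to
  machine precision and pins down the ratio.
* **Unknown parents** are coded "0" and contribute nothing (no
  unknown-parent groups — they are a known source of the very bias this
  package measures). Missing dosages are mean-imputed to `2p_j`; GRM
  allele frequencies default to observed, with user-supplied base
  frequencies as an option. GBLUP inverts `G + 1e-8·I` (an
  observed-frequency GRM is singular by construction).
* **Small related validation cohorts.** A widely cited caveat holds that
  the regression of whole on partial EBV is expected *below* 1 for small,
  related validation sets even under a correct model. In the exact-model
  setting of this package the opposite is provable: joint normality plus
  `Cov(û_w, û_p) = Var(û_p)` give `E[û_w | û_p] = û_p`, hence
  `E(b_wp | û_p) = 1` conditionally for any focal set; 20 000-replicate
  simulations of a 10-sib validation family confirm a mean slope of 1 to
  within 0.005. The depression must therefore originate outside these
  assumptions (estimated variance components, model misspecification,
  conditioning on realized family effects); the suite asserts the
  conditional unbiasedness, and one end-to-end check that encodes the
  depressed-slope expectation is knowingly left failing as documentation
  of this finding.
* **Constant predictors.** The within-family correlation of TBV with a
  predictor that is constant within the family (the parent average of full
  sibs) is taken as zero — the limit of "no ranking ability" — rather
  than left undefined.

## Known limitations

Dense linear algebra throughout: intended for desk-scale problems
(thousands of animals), not national evaluations. One genetic effect, one
trait, homogeneous residuals; no single-step blending of pedigree and
genomic information; no standard errors for the LR statistics themselves
(their replicate spread across partitions is the intended gauge).
`σ²_u,∞` is an input — supplied directly or via k — never estimated
internally.
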