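# Methods

This note documents the statistical machinery implemented in `longisal`,
the choices made where several reasonable constructions exist, and what
the synthetic cohorts do and do not emulate.

## Study structure assumed throughout

A two-genotype (WT / KO), two-sex murine cohort observed at weeks
{0, 4, 8, 12, 16, 22}, with an endpoint histopathology label
(ED/CIS vs OSCC) treated as a time-constant covariate applied to all of a
mouse's visits. Reference levels are WT, Male and ED/CIS. Default arm
sizes are 22/13/20/21 (WT-M / KO-M / WT-F / KO-F), 76 mice in total.

## Compositional preprocessing

- **Prevalence filter.** An OTU's prevalence is the fraction of *all*
  samples with count > 0; the rule is strict ("below threshold removed"),
  so an OTU exactly at the threshold is retained. Defaults: 5% for the
  longitudinal models, 10% for the networks.
- **Zero replacement.** Within each sample, zeros are replaced by half the
  smallest nonzero count of that sample, computed on the *post-filter*
  submatrix (the models only see retained OTUs). All-zero rows are a
  degenerate input: dropped with a warning in the matrix routine, an error
  in the row-level primitive.
- **CLR.** `log(x) − mean(log x)` per sample; rows sum to zero and the
  transform is invariant to per-sample count scaling (the half-minimum
  replacement scales along with the counts).
- **Order of operations.** The model input is CLR of *unrarefied* counts
  (filter → replace → transform); rarefaction (single seeded
  multivariate-hypergeometric draw per sample, default depth 9,484,
  shallower samples dropped) is used for the diversity / θ_YC analyses.
  A config switch (`clr_on_rarefied`) runs CLR on rarefied counts instead;
  neither order is asserted to be the only defensible one.

## Ecology statistics

θ_YC, inverse Simpson and richness are direct formula evaluations. AMOVA
partitions the pairwise squared-distance sum of squares among vs within
groups (Excoffier partition: total SS = Σ_{i<j} d²_ij / N, within-group SS
analogously per group), with the F-ratio referenced to whole-label
permutations and the add-one estimator p = (1 + #{F* ≥ F}) / (1 + B),
which cannot return p = 0. NMDS is plumbing for ordination figures
(scikit-learn SMACOF, nonmetric, precomputed distances) and carries no
inferential weight.

## LSVCMM

Per OTU, for mouse i at week t_j:

    y_ij = x_i' β(t_j) + b_i + ε_ij,   b_i ~ N(0, σ_b²), ε_ij ~ N(0, σ_e²).

The mouse intercept induces compound symmetry: corr(y_ij, y_ik) =
σ_b²/(σ_b²+σ_e²) for all week pairs. Missing visits enter through the
likelihood (each mouse contributes its observed weeks); no imputation.

**Representation.** β_k(·) is pointwise on the six observed weeks rather
than a spline basis: estimates and significance are reported per observed
week, and six points cannot support a meaningfully richer basis. Smoothness
is encouraged by λ_smooth · Σ_j (β_k(t_{j+1}) − β_k(t_j))².

**Local sparsity.** An adaptive-lasso penalty λ_sparsity · Σ w_kj |β_kj|
(intercept unpenalized; weights w = 1/|β̃| from the unpenalized fit,
capped at 10⁶) is applied per (coefficient, week). Proximal-gradient
(FISTA) updates soft-threshold to *exact* zeros, so a coefficient function
can vanish on a strict subset of weeks.

**Optimization.** Outer iterations alternate (i) FISTA on the penalized
GLS quadratic at current variances, assembled per observed-week pattern so
cluster-bootstrap refits reuse the same machinery, and (ii) an *exact*
variance-component MLE at fixed coefficients: with (σ_b², σ_e²) =
v·(r, 1−r), the scale v has a closed-form maximizer for each intraclass
correlation r, leaving a 1-D profile likelihood solved by bounded Brent
search. The profiled step replaces EM deliberately — EM's sublinear crawl
toward the σ_b = 0 boundary stalled convergence on null-ish OTUs.
Convergence: relative objective change < 1e-8, cap 500 outer iterations;
non-convergence flags the fit rather than raising.

**Penalty selection.** EBIC = −2·loglik + df·log N + 2γ·df·log(K·J) with
df = number of nonzero coefficient values, γ = 0.5 by default (γ = 0
reduces to BIC); grid of 20 log-spaced sparsity penalties from the
data-derived λ_max down 3 decades × 5 smoothness values; ties break to the
sparser model. The winning fit receives a *relaxed refit*: an unpenalized
GLS solve restricted to the selected support. This removes the
shrinkage bias of the lasso estimates while keeping the selected sparsity
pattern — without it, a true effect of 2 was systematically estimated
around 1.4–1.6. EBIC itself is evaluated on the penalized path.

**Bands.** Mice (clusters) are resampled with replacement, B = 1000 by
default; coefficients are refit at the selected penalty with adaptive
weights and variance components held at full-sample values (re-estimating
them per replicate changes nothing for the unpenalized balanced case and
roughly doubles cost), followed by the same relaxed refit. For a contrast
c(t) (e.g. OSCC−ED/CIS within KO = β_OSCC + β_KO:OSCC), the simultaneous
band is ĉ(t) ± q*·SE_boot(t) with q* the 95th percentile of
sup_t |c_b(t) − ĉ(t)|/SE_boot(t) — a sup-t band, simultaneous across weeks
within a contrast (not across contrasts or OTUs; the only cross-OTU
control is per-OTU simultaneity, and the summary table flags this).
Weeks with zero bootstrap SE (typically exact zeros throughout) collapse
the band to the point estimate, with a warning if that estimate is
nonzero. Calibration observed in the validation suite: simultaneous
coverage above 0.92 at nominal 0.95 (Gaussian replicates, n = 60, B = 200),
null familywise significance rate near 0 (EBIC zeroes null coefficient
functions, making the procedure conservative under the null).

**Variants.** `full` (intercept, KO, OSCC, KO:OSCC, Female; four
contrasts), `genotype` and `diagnosis` (three coefficients; one marginal
contrast each). A mouse lacking a diagnosis label is rejected, not
imputed.

## fPCA trend prediction

Per OTU, each mouse's CLR trajectory (≥ 2 observed weeks) is centered by
its observed mean, removing level and leaving shape. The week-by-week
covariance is estimated from pairwise-complete products (error if any week
pair has < 2 complete observations), projected to PSD by eigenvalue
clipping, and eigendecomposed; eigenfunction signs are fixed by making the
largest-magnitude entry positive so "positive fPC1" is reproducible.
Scores are best linear predictors given the observed entries
(λ_k φ_k,o' C_oo⁺ x_o), which reduce exactly to classical PCA scores on
complete data. Components are kept up to 99% cumulative variance.

fPCA is fitted per OTU (a pooled-basis alternative would force shared
shapes across OTUs; per-OTU was chosen so each taxon's dominant trends are
its own — neither is asserted as the original study's choice). Scores of
all OTUs' retained components feed two L1-penalized logistic regressions
of diagnosis, one per genotype, with stratified 5-fold CV on deviance and
the **one-standard-error rule** (strongest penalty within one SE of the
best mean deviance). The 1-SE rule is deliberate: with the plain CV
minimum, label-permutation nulls selected some OTU in up to a quarter of
permutations; with 1-SE the maximum per-OTU null selection rate drops
near 0.1 while planted-signal recovery stays at 100%. No class weighting
is applied despite ED/CIS vs OSCC imbalance (flagged in the report).
A genotype stratum with a single diagnosis class, or fewer than two
minority-class mice, is skipped with a warning.

Score-sign interpretation ("rising after week 8", "dip at week 12") is
only attached when the fitted eigenfunctions actually match those template
shapes; a shape-matching report (cosine similarity against the templates)
is emitted alongside the group-average score table.

## Co-presence networks

A compact re-implementation of the SPRING idea, written in-package so the
network stage is testable end-to-end:

1. **mclr**: CLR of the nonzero relative abundances, shifted so the
   smallest nonzero transformed value is ε (= 1) above zero; exact zeros
   preserved. Rank-based steps downstream make the shift immaterial.
2. **Latent correlation**: Kendall's τ-a (ties in the denominator) mapped
   to the latent Pearson correlation of a truncated Gaussian copula. With
   no zeros the closed form τ = (2/π)·arcsin(ρ) is inverted directly. With
   zeros, the truncated/truncated bridge is evaluated as a 2-D
   Gauss–Legendre quadrature (32×32 nodes) of an Owen's-T-based bivariate
   normal CDF — derived from
   τ = 2·E[1(Z₁>δ₁)(1(Z₂>δ₂)Φ₂(Z₁,Z₂) − Φ(Z₁) + Φ₂(Z₁, max(δ₂,Z₂)))] —
   and inverted by bisection (batched across all pairs of a matrix). A
   slower 4-D normal-CDF formulation of the same bridge is kept as an
   independent cross-check; the two agree to ~3e-5 and the quadrature
   matches Monte Carlo simulation of the copula. A pair with zeros in only
   one margin is handled by flooring the other margin's zero proportion at
   1e-3 instead of implementing the separate truncated/continuous formula —
   a documented approximation whose error vanishes as the floor tightens.
   The pairwise matrix is PSD-projected (eigenvalue floor) and rescaled to
   unit diagonal.
3. **Graph**: nodewise L1 regressions on the correlation matrix
   (covariance-input coordinate descent), OR-rule edges, sign from the
   symmetrized coefficient.
4. **StARS**: 20 subsamples without replacement of size ⌊10√n⌋ (capped at
   n−1), edge-selection instability 2p̂(1−p̂) averaged over node pairs,
   monotonized along decreasing λ; the selected λ is the *least*
   regularization whose monotonized instability stays ≤ β (default 0.05) —
   the published StARS rule. If nothing qualifies, the densest λ is
   returned with a warning.

Networks are built per genotype and per period (weeks 0–4, 8–12, 16–22
pooled), sexes and diagnoses pooled, at family or genus rank after a 10%
prevalence filter within the pooled samples. Edges are classified as core
(all six genotype × period cells), genotype-stable (all three periods of
exactly one genotype) or period-specific; the classes partition the
observed edge set. Confounder adjustment for the correlation stage is
deliberately not applied by default: residualizing mclr values would
destroy the exact zeros the copula model needs, and the adjustment set is
not well defined for this design.

## Synthetic cohorts

The generator is the package's test bed and default input. Latent
log-abundance per (mouse, week, OTU) = baseline + Σ active effects +
mouse intercept + noise; counts are multinomial at a Poisson library size
(mean 20,000) over the softmax of the latent vector, so row sums equal the
drawn depths exactly. Structural zeros are *host-level*: a (mouse, OTU)
pair flagged absent (per-OTU probability, default 0.3) is excluded from
the softmax support at every visit, which keeps zeros longitudinally
consistent and is what makes zero-inflation visible to the copula stage.
Effects are additive on the log scale — the scale the CLR analyses assume —
and an injected profile of +c on one OTU appears in CLR space as
c·(1 − 1/n_otus) on that OTU (centering spreads −c/n_otus over the rest).
Dropout is missing-completely-at-random (default 10% per visit, masks
redrawn until every mouse keeps ≥ 2 visits); no informative-missingness
mechanism is modeled because none is specified for the design. Diagnosis
is assigned per mouse (P(OSCC): WT 0.25, KO 0.55 — direction and rough
magnitude of the genotype difference, chosen once). Two RNG streams
separate cohort structure (arms, diagnoses, masks, baselines, structural
zeros, taxonomy) from realization (intercepts, noise, depths, counts), so
injecting a mean effect never changes who is in the cohort.

What the generator does **not** emulate: read-level error, chimeras,
taxonomic misclassification, overdispersion beyond the lognormal latent
(counts are multinomial given the latent), informative dropout, diagnosis
that depends on the microbiome, or serial (non-compound-symmetric)
within-mouse correlation. Passing tests therefore demonstrate estimator
correctness and calibration *under the stated model*, not robustness to
those real-data features.

## Numerical choices and degenerate inputs

- FISTA step 1/L with L from the exact Hessian eigenvalue (30×30),
  momentum restart on objective increase; λ_s = 0 solves the linear system
  directly (tiny ridge 1e-10·tr(H)/p for conditioning).
- Variance floor σ_e² ≥ 1e-12; ICC search bounded at 0.999; the r = 0
  endpoint is always evaluated explicitly.
- Bridge inversion: brentq (scalar, xtol 1e-6 default) or 20-iteration
  bisection (batched); estimates clamped to ±0.999. Kendall τ outside the
  attainable bridge range clamps to the boundary.
- PSD projections clip eigenvalues (floor 1e-6 for correlation matrices,
  0 for fPCA covariance).
- All-zero samples, all-zero OTU rows, single-class strata, groups of
  size < 2, mice with < 2 visits: each is either dropped with a warning or
  raises, as documented per function — never silently imputed.

## Problem sizes in the validation suite

The acceptance tests run the calibration studies at sizes chosen to make
the Monte-Carlo error small relative to the tolerance they check:
500 null AMOVA datasets (999 permutations each), 500 coverage replicates
and 100 recovery/null-error replicates at n = 60 mice (B = 200 bootstrap),
50 fPCA recovery replicates and 50 label permutations, an 11-replicate
median for chain-graph recovery at n = 400. EBIC grids in these
simulations use 10 sparsity × 2 smoothness points (the library default is
20 × 5). `scripts/acceptance.py` re-runs the same computations from
scratch at comparable sizes plus one full study-scale pipeline pass.

## Known limitations

- The LSVCMM estimator is this package's own construction of a locally
  sparse varying-coefficient mixed model; other penalty/band constructions
  of the same model class exist and would differ in finite samples.
- Bands are simultaneous within (OTU, contrast) only; the reported-OTU
  list carries no additional cross-OTU multiplicity control.
- The mixed truncated/continuous copula pair uses the flooring
  approximation described above.
- Penalty is not re-selected inside the bootstrap (fixed at the EBIC
  choice), trading some band width accuracy for tractability.
- NMDS is visualization plumbing; its stress is reported but untested
  beyond sanity checks.
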