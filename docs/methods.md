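# Methods

## The problem

Eggshell color of brown eggs is measured repeatedly per hen as the index
(L\*−a\*−b\*)×10. Besides its mean, its *uniformity* — the environmental
(residual) variance V_E — can carry genetic variation, in which case
selection can make eggs more uniform. Two complications shape the model:

1. **Two populations, one sire line.** Purebred hens (nucleus) are caged
   individually with repeated records; crossbred hens (production) are kept
   as paternal half-sib groups of 4–17 hens and an egg can be attributed
   only to its cage and sire family. The genetic correlation r_pc between
   purebred and crossbred expressions decides how valuable crossbred
   records are for purebred selection.
2. **Definition drift of V_E.** For purebreds V_E is the within-hen
   variance (hen effects are separable); for crossbreds it necessarily
   contains between-hen variance as well.

## The model

A 4-variate sire-model DHGLM over responses (y_p, y_c, y_vp, y_vc): the
trait in the two populations and working variables for the log of its
residual variance. Random structure:

* sire effects on all four scales, covariance ¼G⊗A (G the additive-scale
  4×4 genetic covariance, A the numerator relationship matrix from the sire
  pedigree; additive variance = 4 × sire variance);
* hen permanent-environment effects (purebred mean and log-variance, 2×2);
* cage effects (crossbred mean and log-variance, 2×2);
* diagonal residuals: record i of response r has variance σ²_εr / w_i with
  iteration weights w_i and free scaling variances σ²_εr (expected ≈ 1,
  since the weights already carry the reciprocal predicted variances).

Working variables: with mean-model residual e_i and leverage h_i (exact
hat-matrix diagonal), the deviance contribution is φ_i = e_i²/(1−h_i) and

    y_vp,i = log(σ̂²_i) + (φ_i − σ̂²_i)/σ̂²_i                    (purebred)
    y_vc,i = log(σ̂²_i) + (φ_i·(σ²_es/σ²_ea) − σ̂²_i)/σ̂²_i       (crossbred)

where σ²_es is the homogeneous crossbred sire-model residual variance,
σ²_ea = σ²_es − ¾σ²_ac the implied animal-model residual (σ²_ac = crossbred
additive variance of the mean), and the ratio σ²_es/σ²_ea is frozen after
the homogeneous fit. The adjustment compensates for the ¾ of additive
variance that a sire model leaves in the residual: without it the genetic
variance in V_E is shrunk by (σ²_ea/σ²_es)².

Weights per iteration:

    W_p = 1/exp(ŷ_vp);  W_c = 1/[σ²_ea·exp(ŷ_vc)/mean(exp(ŷ_vc)) + ¾σ²_ac]
    W_vp = ½(1−h_p);    W_vc = ½(1−h_c)²·(σ²_ea/σ²_es)²

The outer algorithm: (1) homogeneous-residual fit of the mean responses;
(2) initial working variables and weights with W = 1/σ²_e; (3) weighted
4-variate REML; (4) update working variables and weights; (5) iterate 3–4
until the sum of relative squared component differences falls below the
threshold (default 1e-2, cap 100 iterations; both configurable).

### Linearization points (a consequential numerical choice)

The purebred working variable is linearized around the per-record predicted
residual variance exp(ŷ_vp,i) (first-order Taylor expansion of log φ).
The crossbred variable is linearized around the *frozen* homogeneous
σ²_es. This asymmetry is deliberate and self-consistent with the weights:

* For crossbreds, only a frozen point gives the ratio-scaled deviance unit
  slope in true log V_E. If the point tracks the fitted variance model, the
  feedback between point and fit shrinks the slope to ratio/(2·ratio−1)
  and the genetic variance in V_E is biased down by its square — we
  verified this both algebraically and by regression of realized working
  variables on true breeding values in simulation. The weight
  W_vc = ½(1−h)²(σ²_ea/σ²_es)² equals the reciprocal working-variable
  variance only under the frozen point (var ≈ 2·ratio²), confirming the
  reading.
* For purebreds the slope is 1 under either choice, and the per-record
  point keeps the variable on the log scale, which matters when hen-level
  heterogeneity is strong (a frozen point maps hen effects through an
  exponential and inflates the permanent-environment log-variance).
  However, the per-record point feeds the model's own hen solutions back
  into its response; with small families this self-confirming loop can
  collapse the genetic signal. `freeze_linearization=True` selects the
  frozen point for purebreds too; the cage-definition experiment (small
  effective families after splitting) uses it by default.

### Damping

The alternation between variance-model estimates and cage/hen-level weights
can oscillate with period 2 (the cage log-variance component alternating
high/low); `damping=True` averages each new working variable with the
previous iteration's, which removed the oscillation in every case we
examined. It is off by default to keep the plain algorithm primary, but the
replicated simulation studies (recovery and cage-definition experiments)
switch it on.

## The REML engine

A purpose-built weighted multi-response engine: Henderson's mixed-model
equations with the block-diagonal hen/cage equations absorbed analytically
(one small block per level), dense Cholesky on the Schur complement
(fixed + sire equations), average-information updates with analytic scores,
EM fallback with back-tracking along the AI direction, and a trust region
capping each parameter's per-round movement at a few times its magnitude.
Leverages are exact, assembled from the partitioned inverse by vectorized
gathers. Sampling (co)variances come from the inverse AI matrix at the
optimum.

Numerical safeguards, all motivated by the five-orders-of-magnitude scale
gap between trait-mean (~10³) and log-variance (~10⁻²) components inside
one covariance block:

* covariance blocks are kept positive semi-definite by bending on the
  **correlation** scale (eigenvalues of the correlation matrix floored at
  1e-4); flooring eigenvalues of the raw covariance would let the dominant
  mean-scale directions leak variance into the log-scale entries;
* block inverses and log-determinants use the same correlation
  decomposition;
* variances are floored at 1e-6 of their starting magnitude; convergence is
  declared on relative log-likelihood change < 1e-8 together with a
  scale-adjusted gradient < 1e-4, or on a persistent likelihood plateau at
  a parameter-space boundary (where the gradient cannot vanish);
  non-convergence is flagged, never silent.

Fixed effects use first-observed-level reference coding; aliased columns
are detected by pivoted QR and pinned with a warning. Records with
leverage > 0.999 are excluded from the variance-model response (counted in
the state).

## Derived parameters

* GCV_Ve = σ_av: under the exponential model the log-scale genetic SD is
  the genetic CV of V_E.
* Additive-scale variances of V_E:
  σ²_av,add = σ⁴_E_exp·exp(σ²_cv)(exp(2σ²_av) − exp(σ²_av)), symmetrically
  for the pe/cage component, and
  h_v² = σ²_av,add / (2σ⁴_P + 3(σ²_av,add + σ²_cv,add)) — the regression of
  the breeding value for V_E on the squared phenotypic deviation.
  σ²_E_exp is calibrated so the expected environmental variance matches the
  homogeneous residual: σ²_E_exp = σ²_e/exp((σ²_av+σ²_cv)/2) (an
  `e_exp_calibration` switch selects σ²_e directly instead). σ²_P is the
  mean-trait phenotypic variance σ²_s + σ²_pe|cg + σ²_e.
* Delta-method sampling variances: var(σ²_av,add) ≈
  σ⁸_E_exp·exp(2σ²_cv)·var(σ²_av)·(4e^{4σ²_av} − 4e^{3σ²_av} + e^{2σ²_av});
  var(2σ⁴_P) = 8(2σ⁴_P·var(σ²_P) + var(σ²_P)²); the denominator variance
  adds 9× the two additive-scale variances; var(h_v²) uses the ratio
  formula with cov(num, denom) = 3·var(num); se(GCV) = se(σ²_av)/(2σ_av).
  Sampling covariances between distinct components are set to zero.
* Two-sided approximate difference test: z = (θ₁−θ₂)/√(se₁²+se₂²).

## Within/between back-calculation

From a paired analysis of the same purebred data under both housing
definitions (individual cages vs 4-hen cages with hen identity masked):
σ²_b = σ²_mc + σ²_ic − 2r·σ_ic·σ_mc; r_wb = (r·σ_mc − σ_w)/σ_b; and under
r_wb = 0 and the equal-proportion assumption,
r_w,pc = r_pc·√(σ²_mc/σ²_ic), with exact inverse
r_pc = r_w,pc·σ_w,c/σ_c. Slightly negative σ²_b within 1e-8 relative is
clipped; worse is an error (incoherent inputs).

## Synthetic data

The generator reads the model generatively. Defaults are the study's
estimated parameters: additive-scale genetic covariance built from
variances (2200, 2408.8, 0.077, 0.067) and correlations (0.86 mean,
0.70 log V_E, and the four mean–variance correlations −0.057/0.19/−0.013/
0.43); non-genetic hen effects pe = diag(1153, 0.262) — chosen so that the
*fitted* sire-model pe, which additionally absorbs ¾ of the additive
variance, matches the study's 2803 / 0.32; cage = diag(339, 0.098) (cage
effects absorb no genetics); means 206.4/189.7;
expected environmental variances 3547 (purebred) and 3776.4 (crossbred,
= 5583 − ¾·2408.8). Structure: grandsire founders with ~5 sons each (a
shallow sire pedigree giving non-trivial A), 30 purebred daughters per sire
with 8 records over 4 laying periods, 6 crossbred cages per sire with 4–17
hens and 8 records per hen over 3 periods. Fixed effects: 10 hatch weeks
(SD 15), 40 laying dates (SD 8), 4 dam lines (SD 10), 6 tiers (SD 5) —
magnitudes chosen as plausible husbandry effects; they are nuisance
parameters estimated and removed by every analysis. A daughter's additive
deviation is ½ sire BV + a Mendelian term with ¾ of the additive variance
on both scales; residuals are drawn with variance exp(μ_v + a_v + pe_v or
cg_v), with μ_v calibrated so E[V_E] matches the homogeneous residual.
`sigma2_a_between` optionally adds an independent sire-genetic component to
the *between-individual* variance (scaling the hen pe-mean spread), used to
study the cage-definition contrast.

What the generator does **not** emulate: skewness/kurtosis of real eggshell
color (residuals are Gaussian given their variance), maternal genetic
effects, selection or pedigree depth beyond two generations,
genotype-by-environment interaction between nucleus and production
environments, and seasonal trends in laying. Passing recovery tests
therefore demonstrates correctness of the estimator under the stated
model, not robustness to these departures.

## Problem sizes and replication

The replicated studies use 100 sires × 30 purebred daughters × 8 records,
plus (two-population runs) 100 × 6 cages × 5 hens × 8 records, five
replicates with consecutive seeds — family counts at which the
variance-model standard errors (≈0.02–0.03 on σ²_av) make recovery checks
meaningful while a full study runs in minutes on one CPU. The
cage-definition experiment defaults to 20 replicates of half/half splits
into 4-hen cages; its test fixture uses fewer, smaller replicates and
checks signs and mechanics rather than 2-SE recovery, which at that scale
would be underpowered.

## Known limitations

* The study's own estimates come from proprietary data; only the printed
  worked-example arithmetic is reproduced exactly.
* Period-pair refits with frozen weights can fail to converge for
  crossbred pairs (flagged per pair, mirroring experience with sparse
  crossbred designs).
* The scaling variance of the purebred variance model sits near 0.7 rather
  than 1 on simulated data (the weight ½(1−h) over-corrects slightly when
  residual χ² noise is leverage-deflated); it is a free parameter, so
  point estimates of the other components are unaffected.
* At very small family sizes the variance-model genetic components can hit
  the zero boundary in individual replicates — a property of the
  likelihood, not of the solver; the replicated studies average over
  replicates.
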