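# Methods

`facetrait` models perceived facial traits as directions in a
100-dimensional face space and tests, end to end on synthetic data with
known ground truth, whether perceived attractiveness and sexual
dimorphism can be manipulated independently of one another.

## Face space and trait directions

A face is a point `x` in R^100 (50 shape + 50 reflectance axes).  The
average face of the generating population is the origin and every axis is
expressed in population-SD units, so the Euclidean norm of `x` is a
natural distinctiveness ("averageness") measure, convex along any
exaggeration ray.

A perceptual trait is summarized per face by the mean Likert rating over
raters, z-scored across faces (sample SD, n−1).  When male and female
faces are rated in separate blocks, scores are standardized within face
sex and the fit is pooled (`sex_policy="pooled"`); a per-face-sex fit is
available.  The trait direction is the ordinary-least-squares fit

    score(x) ≈ α + βᵀx ,

well-posed because the number of faces (400 by default) exceeds the
dimensionality.  No regularization is applied — the n > p regime does not
need it and a penalty would bias the direction's geometry.

**SD-unit scaling.**  "Exaggerating a face by +1 SD" is defined as the
displacement that raises the predicted standardized score by exactly 1:
`unit_step = β / (βᵀβ)`.  Other conventions (e.g. one coordinate-norm SD)
are possible; this one makes validation slopes directly interpretable
(≈ 1 rating-SD per level) and is self-consistent after orthogonalization.
The intercept never enters the displacement.

**Orthogonalization.**  The target direction is projected off the
nuisance direction (one Gram–Schmidt step under the plain Euclidean inner
product, which is the natural metric on orthogonal feature axes):

    β⊥ = β_t − (β_tᵀβ_n / β_nᵀβ_n) β_n ,

then rescaled to SD units.  Two identities follow exactly, at machine
precision, and are enforced by tests: moving any face along the
orthogonalized target's `unit_step` (i) leaves the nuisance model's
predicted score unchanged and (ii) changes the target's predicted score
by exactly the level.  Orthogonalizing an already-orthogonalized
direction is a no-op; a target numerically parallel to the nuisance
(relative residual norm < 1e-12) is rejected.

## Reliability and correlation statistics

* **Cronbach's alpha** treats raters as items:
  `α = k/(k−1) (1 − Σ var_i / var(row sums))`, sample variances.
* **ICC(2,1)** is the two-way random-effects, single-rater,
  absolute-agreement intraclass correlation from the two-way ANOVA mean
  squares, with `F = MS_rows/MS_error` on `(n−1, (n−1)(k−1))` degrees of
  freedom and the McGraw–Wong 95% confidence interval.  Incomplete
  matrices are rejected rather than imputed.
* **Correlations** between rating dimensions are estimated with a
  Bayesian bivariate-normal model on rank-transformed data (a
  Spearman-style ρ): under the Jeffreys prior the posterior of the
  covariance is inverse-Wishart(n−1, S), from which 10,000 ρ draws give
  the EAP and central 95% CrI.  Differences between two independent
  correlations are draw-wise subtractions of the two posteriors.  The
  rank transform is a flag; output metadata records the formulation since
  a Fisher-z latent model would be an equally defensible reading.

## Hierarchical Bayesian rating regression

Ratings from the validation designs are modelled with a Gaussian linear
mixed model on the 1–9 scale,

    y_i = x_iᵀb + z_iᵀu_{participant(i)} + w_iᵀu_{face(i)} + ε_i ,
    ε_i ~ N(0, σ²),   u_g ~ N(0, Σ_g),

with fixed effects for the exaggeration level (linear, optionally
quadratic — never quadratic without linear), face sex, rater sex and
their interactions with the level terms (±0.5 centred sex coding).  The
random structure is maximal as justified by the data: each grouping
(participants; *source* faces, so the seven exaggerated versions of a
face share its effects) receives an intercept plus a slope for every
fixed term that varies within it.  Requesting a slope for a term constant
within every group unit is a specification error.  A Gaussian likelihood
on the integer ratings follows standard practice for 9-point scales; an
ordinal likelihood is out of scope.

**Priors.**  Fixed effects: normal(0, 5).  Residual scale: half-t(3, 2.5)
via its inverse-gamma scale-mixture representation.  Random-effect
covariances use the Huang–Wand (2013) inverse-Wishart scale mixture
(ν = 2, A = 2.5), which gives heavy-tailed scale margins and near-uniform
correlations, combined with a redundant multiplicative parameterization
`u = Λξ`, `Λ = diag(λ)`, `λ_k ~ N(0, 1)`, `ξ ~ N(0, Ψ)`.  The effective
prior on a random-effect SD is therefore `|λ|·√Ψ_kk` — weakly informative
on the scale of a 1–9 rating.  These families were chosen to keep every
conditional exactly conjugate.

**Sampler.**  Inference is a blocked Gibbs sampler: (1) fixed effects
jointly; (2) per-group raw effects ξ, batched over units; (3) the scale
multipliers λ, which enter the mean linearly and get a joint Gaussian
update — this is what lets near-zero variance components mix through zero
instead of sticking at the boundary; (4) exact location-interweaving
moves between each fixed effect and the random-effect block it is
confounded with (e.g. the intercept with participant intercepts, rater
sex with participant intercepts), which removes the slow random-walk
coupling of classic centered samplers; (5) covariance and residual-scale
updates.  Two sweeps of the random-effect blocks run per iteration.

Default settings are 13,000 iterations, 3,000 burn-in, 4 chains (seeded
independently from one root seed); a desk-scale configuration
(2,000/500/2) is used in tests and the acceptance script, with the full
settings exercised once in the convergence test, where every parameter of
the maximal model reaches split-R̂ < 1.01 (computed with arviz's
rank-normalized diagnostic; a warning is emitted whenever any R̂ exceeds
1.01).  Posterior summaries are EAP and central 95% CrI.

**WAIC.**  Model comparison uses WAIC = −2(lppd − p_waic) with
`lppd = Σ_i log mean_s p(y_i|θ_s)` and `p_waic = Σ_i var_s log p(y_i|θ_s)`
(sample variance, n−1), computed from pointwise conditional
log-likelihood draws retained during sampling (thinned to at most 1,000
draws per chain).  The candidate lattice always contains the linear level
term and optionally adds the quadratic term, face sex (+ interactions)
and rater sex (+ interactions) — 8 models; the ladder is sorted ascending
and the head is the best model.  Generated quantities (e.g. the
difference between the two transformations' exaggeration coefficients)
are draw-wise differences between fits.

## Synthetic data generator

The generator defines the study conditions and makes every stage testable
without human data.

* Faces: i.i.d. standard normal in 100 dimensions, alternating sex
  labels; 400 faces / 20 raters for model building, 20 novel base faces ×
  7 levels (−3…+3) × 2 transformations = 280 stimuli × 16 raters per
  validation cell.
* Ground truth: two unit-norm directions with a controllable cosine —
  −0.4 for male-face-like populations and −0.7 for female-face-like ones,
  round values near the attractiveness/masculinity rating correlations
  such populations show.  One pipeline run uses a single pair (−0.4 by
  default); the correlation analysis simulates both populations.
* Ratings: a rater maps the stimulus's true trait score
  `s = β_trueᵀx` to a latent value

      b0 + (b1 + u1_p)·s + b2·s² + u0_p + w_f + ε ,

  with rater intercept `u0`, rater trait-sensitivity `u1`, a face offset
  `w_f` shared by all exaggerated versions of a source face, and residual
  ε; the latent value is affinely mapped (identity by default, so b0 = 5
  and b1 = 1 make ±3 latent SD span ratings ≈ 2–8), rounded and clipped
  to 1–9.  In validation designs (stimuli indexed by an exaggeration
  level) raters additionally carry an idiosyncratic sensitivity to the
  transformation axis itself, `v1_p · level` — without it, simulated
  raters agree far more than human raters do and nuisance-task credible
  intervals become unrealistically narrow.
* Validation ratings are generated from the **true** directions while the
  stimuli are built from the **fitted, orthogonalized** directions, so
  estimation error leaks realistically into the nuisance task.

**Calibration.**  Noise defaults were set by variance arithmetic against
three observable anchors, in this order: target-cell single-rater ICCs in
the moderate 0.4–0.7 band; high rater consistency (α ≳ 0.95 at 20 raters)
alongside visibly lower absolute agreement (large rater intercept
spread); and by-participant level-slope spread ≈ 0.25, the value implied
by linear-term credible intervals of width ≈ ±0.13 with 16 raters.  The
resulting defaults are `sd_rater_intercept = 1.0`, `sd_rater_slope = 0.2`,
`sd_rater_level_slope = 0.25`, `sd_face = 0.3`, `sd_resid = 0.7`, with
latent gains `b1 = 1`, `b2 = −0.05`.  At these values a default run gives
target-cell ICCs ≈ 0.70, nuisance-cell ICCs ≈ 0.2–0.35, α ≈ 0.97, and
direction-recovery cosines ≈ 0.97.

**What the generator does not emulate.**  Real face-space structure
(FaceGen axes are neither exactly orthonormal nor variance-standardized),
rendering of coordinate vectors as images, ordinal response styles
(unequal category usage), cultural or within-rater state moderators, and
correlated rater effects across tasks.  Passing tests therefore show that
the *pipeline* — fitting, scaling, orthogonalization, validation
modelling — behaves correctly under the stated statistical structure, not
that any particular human population exhibits these effect sizes.

## Numerical choices and degenerate inputs

* Faces files round-trip exactly: 17-significant-digit text and
  round-trip float parsing.
* Standardization requires non-zero variance of face means; all-equal
  means raise a degenerate-data error rather than returning NaNs.
* Fits require more faces than dimensions; orthogonalization rejects
  parallel directions at relative residual < 1e-12; scaled directions
  must gain exactly +1 predicted score per unit step (checked to 1e-8).
* The correlation posterior adds a 1e-10·trace ridge to the scatter
  matrix so |r| = 1 inputs remain positive definite.
* Every stochastic routine takes an explicit seed; chains and pipeline
  stages derive child seeds from it, so all artifacts (including
  manifests) are bit-reproducible for a fixed configuration.
* Problem sizes in the test-suite and acceptance script (reduced MCMC at
  2,000/500/2; one full-settings convergence fit on a 10-rater × 14-face
  design) were chosen to keep a desk run in minutes while leaving every
  qualitative conclusion unchanged at the full settings.

## Known limitations

* The Gaussian likelihood ignores the discreteness and boundedness of
  ratings; with strong gains and wide noise, floor/ceiling compression
  attenuates recovered linear effects by a few percent and contributes a
  small negative quadratic component — visible in real rating data too.
* WAIC is computed from conditional (given random effects) likelihoods,
  the usual but not unique choice for mixed models.
* ICC confidence intervals assume the balanced complete design used here.
* The CrI-based dissociation check inherits Monte-Carlo and
  estimation-error variability: with leakage of order 0.03–0.09 rating
  units per level and nuisance CrIs of ≈ ±0.14, occasional seeds can
  produce a borderline nuisance interval, as the original validation data
  themselves do.
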