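# Methods

This note documents the statistical content of `smallgee`: the model and the
three estimating methods, the twelve covariance estimators, the nuisance
estimation cycle, the synthetic-data generator, and the numerical and design
choices made where the literature leaves latitude.

## Model and estimating equation

Clusters *i* = 1..K contain n_i binary observations Y_it with covariates
x_it ∈ R^p.  The marginal model is logistic, μ_it = expit(x_itᵀβ), with
variance φ·μ(1−μ) and a working within-cluster correlation R_i(α).  Writing
A_i = diag(μ_it(1−μ_it)), D_i = A_i X_i (canonical link) and
V_i = φ A_i^{1/2} R_i(α) A_i^{1/2}, the conventional estimate solves

    U(β) = Σ_i D_iᵀ V_i⁻¹ (Y_i − μ_i) = 0

by Fisher scoring, β ← β + Φ⁻¹U with Φ = Σ_i D_iᵀV_i⁻¹D_i.  Only the logit
link and binary outcomes are supported; the penalized method below is not
defined for counts, and restricting to the canonical link keeps every
derivative in closed form.

### Nuisance estimation cycle

After every accepted β step, Pearson residuals e_it = ε̂_it/√(μ̂(1−μ̂)) give

* scale:   φ̂ = Σ e²_it / (Σ n_i − p) (exactly 1 when `scale_fix`),
* exchangeable: α̂ = Σ_i Σ_{t<t'} e_it e_it' / [φ̂(Σ_i n_i(n_i−1)/2 − p)],
* AR(1):   α̂ = Σ adjacent-pair products / [φ̂(#adjacent pairs − p)],
* unstructured: entrywise pairwise products over clusters observed at both
  occasions, divided by φ̂(K_tt' − p).

Occasions are categorical positions in the pooled sorted occasion set (not
numeric times); AR(1) adjacency means positional lag 1, so a cluster missing
an intermediate occasion contributes no pair across the gap, and the
denominators use the pair counts actually available.  Out-of-range estimates
are clamped to 0.99 of the admissible boundary with a warning; an
unstructured estimate that is still not positive definite after entrywise
clamping is shrunk toward the identity by the smallest factor 0.9^k that
restores PD.  The score is re-evaluated at the same β after each nuisance
refresh, and the nuisance parameters are estimated once at the starting
values before the first step (otherwise a start at the independence solution
would be declared converged with α never estimated).

Iteration controls: `maxitr` 50, `tol` 1e−5 on max|Δβ| (the max-abs metric),
confidence level 0.95, up to 10 step-halvings whenever a step increases
‖U‖∞.  Starting values are the package's own Newton fits of ordinary
logistic regression (GEE/BCGEE) or Firth logistic regression (PGEE) treating
observations as independent.  Non-convergence returns the last iterate with
a warning rather than raising, so the surrounding grid machinery can record
it.  Coefficients drifting past |β_j| > 50 trigger a separation warning
suggesting the penalized method.

## Bias-corrected GEE

The estimating-function cumulants κ_rs = E[∂U_r/∂β_s], κ_{r,s} = E[U_r U_s],
κ_rsu = E[∂²U_r/∂β_s∂β_u], κ_{rs,u} = E[(∂U_r/∂β_s)U_u] yield the
second-order bias

    b_r = Σ_s κ^{rs} Σ_{u,v} [κ_{su,v} − ½ Σ_{k,ℓ} κ^{kℓ} κ_{svℓ} κ_{u,k}] κ^{uv},

and β̂_BC = β̂ − b, applied once (no re-iteration), with α̂, φ̂ held fixed
during differentiation.  Plug-in choices: the purely model-based cumulants
replace Y by μ̂ (so κ_rs = −Φ for the canonical link); κ_{r,s} and κ_{u,k}
are the empirical per-cluster score outer products (the sandwich meat); and
κ_{rs,u} pairs the *centered* per-cluster Jacobian (∂U_r^{(i)}/∂β_s minus
its model-based mean) with U_u^{(i)}.  Using empirical mixed cumulants is
what keeps the correction valid under correlation misspecification.  The
centered Jacobian has the closed form T_s ε̂ per cluster with
T_s = ½ Xᵀ(C_s W − A W C_s A⁻¹), W = V⁻¹, C_s = diag(a'·x_s),
a' = μ(1−μ)(1−2μ); κ_rsu = Σ_i[−T_s(a·x_u) − (∂Φ/∂β_u)[:,s]].  All tensors
are verified against central finite differences in the test suite, and the
einsum contraction of b against a naive quadruple loop.  κ_rs^{(u)} =
∂κ_rs/∂β_u is computed and retained for completeness but does not enter b.
After subtraction, residuals, φ̂, α̂, Φ and all per-cluster quantities are
re-evaluated at β̂_BC so the covariance estimators use the corrected
coefficients consistently.  If [κ_rs] is singular the uncorrected fit is
returned with a warning.

## Penalized GEE

The penalized equation adds g_r = ½ tr[Φ⁻¹ ∂Φ/∂β_r] to each score
component.  With the logit link both D_i and V_i depend on β only through
A_i, giving ∂Φ/∂β_r = Σ_i Xᵀ(S_r + S_rᵀ)X with
S_r = (1/2φ) A^{−1/2} diag(a'·x_r) R⁻¹ A^{1/2} — the full product rule over
both D factors and V⁻¹.  The Newton step uses Φ as the Jacobian (Fisher
scoring; ∂g/∂β is ignored), with the same nuisance cycle and step-halving
as the conventional fit; φ̂ is profiled on unpenalized Pearson residuals.
For size-1 clusters, independence and φ = 1 the penalty reduces exactly to
Firth's modified score Xᵀ(h ⊙ (½ − μ)), which the tests exploit as an
independent oracle, and the fit stays finite under complete separation.

## Covariance estimators

All twelve estimators share the bread Φ⁻¹ and are evaluated at the fitted
coefficients of whichever method produced the fit, with that method's own
residuals and nuisance values (each method column in a grid gets its own
SEs).  With H_ij = D_iΦ⁻¹D_jᵀV_j⁻¹, d_i = D_iᵀV_i⁻¹ε̂_i:

* SA: meat Σ d_i d_iᵀ.
* MK = K/(K−p) · SA;  GS = K/(K−p) · PA;  FW = ½(KC + MD) — exact
  identities, tested to machine precision.
* KC / MD: residuals premultiplied by (I−H_ii)^{−1/2} / (I−H_ii)^{−1}.
* FG: meat contributions wrapped in F_i with [F_i]_ss =
  {1 − min(δ, [N_i]_ss)}^{−1/2}, N_i = D_iᵀV_i⁻¹D_iΦ⁻¹; δ defaults to 0.75
  (the customary bound) and is exposed as an argument.
* PA / WL / WB: the standardized residual outer products
  A^{−1/2}ε̂ε̂ᵀA^{−1/2} (raw, MD-adjusted, KC-adjusted) are pooled across
  clusters on the pooled occasion grid and re-inserted per cluster.  With
  balanced data this is the plain 1/K average; with unequal occasion
  patterns each entry is averaged over the clusters observed at both
  occasions.
* MB: Φ⁻¹{Ψ + γ₁γ₂Φ}Φ⁻¹ with Ψ = [(Σn_i − 1)/(Σn_i − p)]·[K/(K−1)]·
  Σ(d_i−d̄)(d_i−d̄)ᵀ, γ₁ = min(0.5, p/(K−p)), γ₂ = max(1, tr(Φ⁻¹Ψ)/p).
  d_i uses the working-model V_i whatever the structure.
* FZ: MD-style bread around ε̂ε̂ᵀ − Σ_{j≠i} H_ij ε̂_j ε̂_jᵀ H_ijᵀ; the
  leverage factor "(I − H_i)" is implemented as (I − H_ii), the only
  dimensionally conforming reading.  The cross-cluster sum collapses to
  D_iΦ⁻¹(Σ_j d_j d_jᵀ − d_i d_iᵀ)Φ⁻¹D_iᵀ, avoiding the K×K grid (the
  brute-force grid is kept as a test oracle).  FZ can be indefinite; a
  negative diagonal yields NaN standard errors with a warning.

Matrix square roots of (I−H_ii)⁻¹ are principal roots (scipy `sqrtm`);
imaginary parts above 1e−8 raise an error, below are discarded.  For size-1
clusters under independence with fixed scale, SA/KC/MD coincide with the
HC0/HC2/HC3 heteroskedasticity-robust forms — another test oracle.

Inference is Wald on the standard normal reference: z = β̂_j/SE_j,
two-sided p, OR = exp(β̂_j), CI = exp(β̂_j ± z_{α/2}SE_j).  No
multiple-testing adjustment and no t-reference are applied.

## Data handling

Formulas are patsy-encoded: treatment coding against the lowest-sorted
level (so age 9 is the reference in the worked schema), intercept always
included.  Rows with missing outcome or model terms are dropped complete-case
with a logged count.  With an occasion column, rows are sorted within cluster
by occasion and duplicate occasions are an error; without one, cluster rows
must be contiguous (as in classical GEE software) and occasions are row
positions.  Rank deficiency is detected at the solver, not the encoder, so
legitimately tiny datasets (even a single row) can still be represented.

## Synthetic data generator

`generate` draws, per cluster, a latent multivariate normal with unit
variances thresholded at ndtri(μ_it), so marginal means match the logistic
model exactly.  The latent pairwise correlation is solved by bisection (to
1e−10) so that the *binary-scale* correlation of each outcome pair equals
the requested exchangeable or AR(1) ρ — the same quantity the moment
estimator of α targets, which is why α̂ recovers ρ in the tests.  Requested
correlations outside the Fréchet-compatible range for the implied margins,
or producing a non-PD latent matrix, raise a feasibility error reporting
the attainable range.  The default covariate layout emulates the worked
16×4 design: a cluster-level Bernoulli(0.5) exposure and a categorical
occasion effect; the packaged `wheeze_like_fixture` uses true coefficients
(−0.3, 0.4 exposure, −0.15/−0.30/−0.45 occasions), AR(1) ρ = 0.3 — odds
decreasing with age, as in the motivating study — and is *synthetic*: it
reproduces the schema and magnitudes of small longitudinal wheeze data, not
the real observations.  What passing tests on it show is that the full
pipeline (reader → fit → grid → inference) behaves correctly on data of
exactly that shape; they cannot certify agreement with any particular real
dataset, which should be supplied externally through the same CSV path.

The generator does not emulate missing visits, covariate measurement error,
informative cluster sizes or dropout.

`simulation_study` repeats generate→fit over seeded replicates (replicate r
uses seed+r), excludes failed or non-converged fits with a count, and
reports mean estimate, bias, empirical SD, mean SE and Wald coverage per
method/estimator/coefficient.  The repeated-sampling checks in the tests and
acceptance script use K = 500 × 200 replicates (consistency) and
K = 20 × 500 replicates (small-sample SE behavior), sizes chosen to put
Monte-Carlo error well below the effects being measured while completing in
about a minute.

## Known limitations and open choices

* Binary outcomes and logit link only; no offsets, weights, or
  numeric-time correlation structures; no covariance-inflation variants and
  no t/df-adjusted inference.
* The moment estimators use the −p degrees-of-freedom correction
  throughout.  A consequence worth knowing: duplicating every cluster m
  times leaves the estimating equation's root unchanged at fixed nuisance
  values, but α̂/φ̂ shift slightly through the −p terms, so fitted
  coefficients drift by O(10⁻³) rather than being bit-identical.
* The downward bias of the unadjusted sandwich at small K concentrates on
  between-cluster (cluster-level) contrasts; for within-cluster occasion
  contrasts it can be negligible, and the repeated-sampling checks therefore
  read the directional claims off the cluster-level exposure coefficient.
* BCGEE's κ_{rs,u} uses the centered-Jacobian convention described above;
  alternative (uncentered) conventions exist in the literature and differ at
  O(1/K²) in the resulting correction.
* Eta is clipped at ±30 before expit; beyond that the variance function
  underflows and working weights explode — this is the graceful-divergence
  path for separated data rather than an error.
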