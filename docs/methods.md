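# Methods

## Model

`knotpgm` implements the linear–linear piecewise latent growth model
(PGM) with a freely estimated knot. Subject *i* observed at occasions
*t*₁ < … < *t*_J follows

    y_i = Λ(γ) η_i + ε_i,          ε_i ~ N(0, diag(σ²₁, …, σ²_J))
    η_i = α + ζ_i,                 ζ_i ~ N(0, Ω_η)

with three growth factors — intercept, pre-knot slope, post-knot slope —
and loading rows Λ_j(γ) = [1, min(t_j, γ), max(t_j − γ, 0)]. The knot γ
lives on the raw time-code scale; no internal rescaling is done. At
least five occasions are required for identification. The residual
covariance is diagonal and heteroscedastic by occasion.

## Priors

Four parameter blocks:

| block | prior | default |
|---|---|---|
| growth-factor means α_m | N(μ_α, σ²_α), independent | N(0, 10⁶) |
| factor covariance Ω_η | inverse-Wishart IW(Ψ, ν) | IW(I₃, 3) |
| residual variances σ²_j | inverse-gamma IG(a, b), independent | IG(0.001, 0.001) |
| knot γ | uniform or truncated normal on (min t, max t) | preset-dependent |

The inverse-gamma density is taken proportional to x^(−a−1) e^(−b/x) and
the inverse-Wishart proportional to |Ω|^(−(ν+p+1)/2) e^(−tr(ΨΩ⁻¹)/2)
(the JAGS conventions).

Seven named knot priors are provided. On the canonical 0..6 grid:
DIF = U(0, 6); I-ATK = N(3, 0.146)T(0, 6); WI-ATK = N(3, 0.730)T(0, 6);
I-PRK/WI-PRK center 1.5; I-PSK/WI-PSK center 4.5, with the same two
variances. "ATK" centers at the (hypothesized) true knot, "PRK"/"PSK"
halfway between an endpoint and that center; weakly informative
variances are informative × 5. On any other grid the centers move to
the grid midpoint and quarter points, and the informative variance is
derived from a 10% overlap rule between adjacent informative priors:
with center spacing d = range/4, solve 2Φ(−d/(2σ)) = 0.10, i.e.
σ = d / (2 · 1.6449). On a 0–8.5 window this gives variance 0.417
(weakly informative 2.085). On the default grid the canonical 0.146 is
used verbatim rather than recomputed — the overlap rule would give
0.208 there, and the canonical hyperparameters take precedence.

## Sampler

`mcmc.fit` runs an n-chain Metropolis-within-Gibbs sampler. Per
iteration, in order: (1) missing outcomes are drawn from
N(Λ_j(γ)ᵀη_i, σ²_j) (data augmentation, so later updates see complete
data); (2) all η_i jointly from their multivariate-normal full
conditional (one shared 3×3 precision since the residual covariance is
common across subjects); (3) α from its normal full conditional; (4)
Ω_η from IW(Ψ + Σζζᵀ, ν + n); (5) each σ²_j from
IG(a + n/2, b + RSS_j/2); (6) γ by random-walk Metropolis with Gaussian
proposals against the complete-data likelihood times the knot prior —
proposals outside the truncation support are rejected through the
prior's −∞ log density, so draws never leave the support.

The proposal SD starts at 0.2 and is multiplicatively adapted every 50
iterations during burn-in only (×0.8 below 25% acceptance, ×1.25 above
45%), then frozen, keeping the post-burn-in chain time-homogeneous.

Numerical choices: the 3×3 Cholesky factors, triangular inverses and
inverse-Wishart draws (Bartlett construction) are closed-form — the
per-call overhead of general linear-algebra routines dominates the
sampler at this dimension. Non-finite likelihood values raise a
diagnostic error carrying the iteration index. With n = 0 subjects
(a test-only path) every update collapses to its prior, which is how
the prior-recovery tests work; the near-flat IG(0.001, 0.001) can then
legitimately produce astronomically large variance draws.

Starting values are dispersed: γ from the interior 10–90% of its prior
(nudged 2% off boundaries, where the loading matrix loses rank); α from
a least-squares fit of the occasion means through Λ(γ₀); residual
variances from occasion-wise sample variances; η_i at α₀; missing cells
at occasion means. Chains are seeded hierarchically
(study seed → cell → replication → chain), so any run is a pure
function of the master seed regardless of scheduling.

Convergence is screened with the split-chain rank-normalized potential
scale reduction factor (with folding), computed in-house and
cross-checked against `arviz` in the test suite; the classic statistic
is available as `method="split"`. Monitored parameters are the
structural block only — α (3), the unique entries of Ω_η (6), σ² (J)
and γ — not the latent scores or imputed values, mirroring standard
monitor practice. A fit is "converged" when every monitored R-hat is
strictly below 1.1.

Known limitation: the knot update is conditional on η, and the two are
strongly coupled. Chains started far from a well-identified knot can be
self-trapped: η adapts to explain the data under the wrong γ, and the
conditional Metropolis step then sees little reason to move. This is
most visible under the diffuse prior at small n or on irregular grids
with wide observation gaps, and it is the mechanism behind low
convergence rates for diffuse priors in the simulation study. The R-hat
screen reliably flags it; all converged-only summaries are unaffected.
A collapsed (η-marginalized) knot update would mix better but would also
erase the convergence-rate phenomenology the study is about, so it is
deliberately not used.

## Synthetic data and attrition

`simulate.generate_complete` draws exactly from the population model.
The default population is: α = (50, 1.0, 1.4), Ω_η = diag(25, 0.25,
0.25), σ²_j = 5 at all seven occasions (codes 0..6), γ = 3 (the fourth
occasion). The slope change of 0.4 equals 0.8 pre/post-knot slope
standard deviations — a Cohen-style *large* standardized effect. With
these values the knot is clearly present but the likelihood does not
overwhelm an informative prior at n = 50, which is the regime the
prior-sensitivity questions are about; a much sharper kink would make
every prior irrelevant even at small n.

`simulate.apply_mar` imposes attrition-style MAR missingness: for
occasions 2..J the missingness indicator is Bernoulli with
logit⁻¹(b₀_j + b₁ z_i1), where z_i1 standardizes the first-occasion
outcome (sample mean/SD) and b₁ = 1.48 by default (a strong
missingness–cause association). Target marginal schedules, in percent
on the 0..6 grid, are quadratic/linear/quadratic in t for the
decelerated ("concen_s"), constant and accelerated ("concen_e")
patterns, scaled so the final occasion hits the terminal proportion
(canonically 30% or 70%); e.g. constant-30% is 5t_j percent. The
intercepts b₀_j are solved by 1-D root finding under 101-point
Gauss–Hermite quadrature over the standard-normal predictor
(tolerance ≪ 1e-8); occasions with a zero target get a NaN sentinel,
never −∞ arithmetic.

The default generator draws the per-occasion indicators independently,
which reproduces the target marginal proportions exactly; an opt-in
`monotone` flag additionally carries dropout forward (once missing,
always missing), giving staircase masks at the cost of slightly
exceeding the marginal targets at interior occasions. The first
occasion is never deleted.

What the generator does *not* emulate: non-normal outcomes, MNAR or
intermittent missingness, measurement non-invariance, and
subject-varying knots. Passing tests therefore certify the estimator
under the stated population model, not robustness beyond it.

## Outcome measures

Per design cell (sample size × missing level × knot prior), replications
are summarized by: convergence rate (over all replications) and, over
converged replications only, coverage of the true knot by the
equal-tailed 95% credible interval, average bias of the posterior mean,
and RMSE. With no converged replications the converged-only metrics are
NaN sentinels, never zero. The true knot defaults to 3.

## Problem sizes and protocols

Full-scale settings (4 chains × 25,000 post-burn-in iterations, 5,000
burn-in, thin 10; 500 replications per cell; 147 cells) are the
`MCMCConfig()` and `StudyDesign()` defaults for the factorial study
factors, but the study runner's default MCMC protocol is the desk-scale
`MCMCConfig.scaled()` — 2 chains, 1,000 burn-in, 4,000 retained, thin
1 — and the bundled acceptance checks use 100 replications of single
n = 50 cells. These are the package's own reduced problem sizes for
routine verification; the full-scale protocol is one config flag away.
The shorter chains mainly depress convergence rates in the hardest
cells (diffuse priors at n = 50, heavy early attrition), exactly where
the full protocol also struggles.

## Design choices that were genuinely open

- **Residual variances in data generation** are equal across occasions
  (5.0); only the *model* is heteroscedastic. Any occasion-specific
  vector can be supplied.
- **Monotone dropout** defaults to off (see above); both behaviors are
  available because the attrition literature describes carry-forward
  dropout while the generation recipe is per-occasion Bernoulli.
- **R-hat variant** defaults to rank-normalized; the classic statistic
  is an option.
- **Replication-level failures** (non-finite likelihood, singular
  updates) are logged and counted as nonconverged rather than aborting
  a cell.
- **Parallelism** is omitted: per-replication seeds are derived
  independently of scheduling, so a parallel map would be a drop-in,
  but serial execution keeps determinism trivially auditable.
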