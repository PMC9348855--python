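# Methods

## The model family

Naive CD4 and CD8 T cell numbers in mice are shaped by three processes:
export of new cells from the thymus, loss (death or onward
differentiation), and self-renewal by division.  The package implements
six candidate descriptions of the per-cell rates, all sharing a binary
Ki67 structure and the same thymic influx:

| variant | loss rate | division rate | extra parameters |
|---|---|---|---|
| `neutral` | δ₀ | ρ₀ | — |
| `dd_loss` | δ₀·(N/N_ref)^γ | ρ₀ | γ |
| `dd_division` | δ₀ | ρ₀·(N/N_ref)^γ | γ |
| `rte_mn` | δ_r / δ_m | ρ_r / ρ_m | maturation μ |
| `age_loss` | δ₀·e^(−r_δ·a) | ρ₀ | r_δ |
| `age_division` | δ₀ | ρ₀·e^(+r_ρ·a) | r_ρ |

Here `a` is post-thymic cell age (days since the cell, or its ancestor,
left the thymus) and `N` the total pool size.  The age-structured
variants track the joint density u(a, k, t) of cell age and Ki67 state k
over mouse age t.

**Ki67 bookkeeping.**  Ki67 is treated as a binary marker switched on by
division and decaying to undetectable at rate β = 1/3.5 per day (the
~3–4-day detectability window; overridable).  A dividing Ki67⁻ mother
yields two Ki67⁺ daughters (−1/+2); a dividing Ki67⁺ mother adds a net
+1 Ki67⁺ cell.  Cell age is *not* reset by division.

**Thymic influx.**  Export is proportional to late-stage single-positive
thymocyte numbers S(t), with the Ki67⁺ split of new emigrants given by
the SP Ki67⁺ fraction κ(t).  Both are empirical curves of mouse age:
S(t) = e^c0·e^(−νt)(1−e^(−ωt)) (fast neonatal growth, slow involution)
and κ(t) = k_min + (1−k_min)/(1+(t/τ)^h), ≈1 in neonates and ≈0.2 by
three months.  The absolute export scale ψ (cells per SP thymocyte per
day) multiplies S(t) and is not identified by SP data; it is estimated
or fixed downstream.  These functional families are this package's
registered defaults behind a stable interface — any smooth positive pair
(S, κ) can be substituted.  Reference default parameters put the peak
export around 7 weeks of age and an adult naive CD4 pool near 10⁷ cells.

## Solvers

The age-structured system is linear and lineage-blind, which admits a
fast, essentially closed-form solution along characteristics
(a − t constant):

* the total density along a characteristic propagates as
  v(a) = v(0)·exp(∫ρ − ∫δ), with both integrals in closed form for
  exponential age dependence;
* the Ki67⁺ fraction W = u⁺/(u⁺+u⁻) satisfies
  dW/da = 2ρ(a) − (2ρ(a)+β)·W — notably independent of the loss rate —
  and is integrated exactly in log space (`np.logaddexp.accumulate`), so
  no step-size stability constraint arises.

Solutions at arbitrary (observation age, BMT age) pairs are assembled
from one set of tables per parameter vector; a likelihood evaluation for
~100 mice costs ~1.5 ms.  Compartmental variants (neutral,
density-dependent, RTE/MN) integrate their ODE systems with LSODA;
density-dependent cohort bookkeeping first solves the scalar pool-size
ODE and then transports entry cohorts through the resulting
time-varying rates; the RTE/MN variant uses the eigendecomposition of
its constant-coefficient 4×4 system.

The characteristics solver is validated against two independent oracles
(test suite): a fine-grid first-order upwind finite-difference scheme
(agreement <0.5% on totals and Ki67⁺ fractions) and an individual-based
stochastic simulation with ~10⁵ cells (agreement within 3 Monte-Carlo
standard deviations).

**Initial condition.**  Lifespan runs start at t = 1 day with an empty
pool, so the age distribution is generated self-consistently by influx.
Closed-cohort analyses pass an explicit initial age distribution.

**Chimera bookkeeping.**  After bone marrow transplant at `t_bmt`, thymic
export carries the stable bone-marrow (DP1) chimerism χ of donor cells.
The normalised donor fraction f_d then reduces to the fraction of cells
that entered the pool after t_bmt; it rises towards 1 under complete
turnover, and saturates below 1 when older (host) cells out-persist new
ones.  Host Ki67⁺ fractions mix pre-BMT survivors with the (1−χ) host
share of post-BMT export.  A thymic transit delay between BMT and first
donor export is configurable (default 0; DP1 normalisation absorbs it).

## Inference

Fitting targets four observable streams simultaneously: total counts
(lognormal error, scale σ_N), normalised donor fraction and host/donor
Ki67⁺ fractions (normal on the logit scale, scales σ_f, σ_k).  These
error-model and prior choices are this package's own — the original
analysis defers its exact priors to its deposited code — and are
weakly-informative log-normals centred on biologically plausible scales
(residence times tens of days, interdivision times many months).

Sampling uses the affine-invariant ensemble sampler (emcee) with
differential-evolution moves, initialised from a Nelder–Mead MAP point;
rates are explored on the log scale.  Walkers are treated as chains for
rank-normalised R-hat and ESS diagnostics; fits with R-hat > 1.05 are
flagged unreliable.  Default reduced settings (14 walkers, 150 burn-in +
250 retained steps) are sized for the replicate harnesses; replication
runs should scale these up via `SamplerConfig`.

One "pointwise unit" for predictive comparison is one observation stream
value.  PSIS-LOO is computed by arviz from per-draw pointwise
log-likelihoods; pseudo-BMA weights come in the plain (∝ exp elpd) and
Bayesian-bootstrap-regularised ("plus", default) variants.  elpd
differences below 4 are reported as comparable predictive performance.

## Hierarchical cohort model

Tamoxifen fate-mapping timecourses identify only the net loss rate
λ(a) = λ₀·e^(−r_λ·a); the labelled-cohort curve is
N(a) = N₀·exp(−(λ₀/r_λ)(1−e^(−r_λ a))), evaluated series-safely near
r_λ = 0.  Four hierarchy variants cross N₀ and λ₀ varying by mouse or by
age group, always as normal hyper-distributions on log parameters
(positivity by construction); r_λ and the lognormal count noise are
shared.  Group-level λ₀ estimates are summarised by a Hill curve
λ₀(t) = λ_min + (λ_max−λ_min)/(1+(t/t_half)^h).

**Scoring the hierarchies.**  PSIS-LOO with observation-level pointwise
units is unreliable when single observations strongly inform unit-level
parameters (one N0 or λ₀ per mouse, six bleeds each): exact
leave-one-out refits show it overestimating the elpd of the
mouse-level-λ₀ hierarchy by ~20 at this study size, while the Pareto-k
diagnostic under-reports the failure at ensemble-sampler effective
sample sizes.  `kfold_elpd` therefore provides K-fold cross-validation
(refit without each fold, score held-out bleeds from the refit draws;
units absent from a training fold are predicted from their
hyper-distribution) as the robust scorer for hierarchy comparison; its
pointwise output plugs directly into the pseudo-BMA weights.  PSIS-LOO
remains the default scorer everywhere the Pareto diagnostics are clean,
as in the chimera model comparison.

The registered CD8 neonatal modifier (λ_max/λ_min = 2, t_half = 35 d,
h = 5) encodes the observed decline of the CD8 baseline loss rate from
~3 weeks of age to a ~50% lower adult plateau by 9 weeks.  When
extrapolating the CD8 age-structured model to birth, a cohort exported
at mouse age τ carries baseline loss δ₀·λ₀(τ)/λ₀(∞); the exponential
decline with cell age is unchanged, and the Ki67 kinetics are untouched
(W is δ-independent).

## Residence-time summaries

Table-style summaries define the expected residence time of a cell of
age a as 1/δ(a).  For the *population-average* residence time of mature
naive cells (age ≥ 21 d) in a 12-week-old mouse, the package's default
(`method="sojourn"`) averages, over the model age distribution, the
expected further time a cell and its progeny persist in the pool:
∫₀^H exp(−∫ₐ^(a+s) λ) ds with the net loss hazard λ(a) = δ(a) − ρ(a) and
a mouse-lifespan horizon H = 730 d (the integral diverges at H → ∞
because the hazard decays with age).  This is the definition under which
the published CD4/CD8 values (≈60/76 d) are reproducible; the literal
population average of 1/δ(a) (`method="instantaneous"`) is also exposed,
but is bounded by 1/δ(t) ≈ 41 d for CD4 at t = 84 d and therefore cannot
produce those values.  Both methods agree exactly for constant δ.

## Prediction engines

* **Co-transfer** — RTE and MN pools are built from donor-age cell-age
  distributions weighted by the GFP⁺ probability e^(−a/T_gfp) and its
  complement (probabilistic definition of RTE; a hard age cut-off is
  available for sensitivity analysis), averaged uniformly over the donor
  age windows (5–9 wk; ≥14 wk capped at 20 wk).  Both pools evolve
  without influx under δ(a), ρ(a); the reported ratio is normalised to 1
  at transfer and is invariant to the (equal) transferred numbers.
* **Reporter mapping** — GFP⁺ counts and %GFP⁺Ki67± integrate
  u±(a,t)·e^(−a/T_gfp) over age.  T_gfp is estimated by quadrature on a
  log grid (the problem is one-dimensional), with kinetic parameters
  held fixed.
* **Thymic grafts** — n extra lobes scale influx by (1 + n/2) from the
  graft age; the excess pool is also expressed as days-equivalent of
  extra export.

## Synthetic data

Generators for all four schemas (SP timecourses, chimera cohorts,
fate-mapping cohorts, reporter timecourses) draw around the forward
model with lognormal count noise (CV 0.2 by default) and logit-normal
fraction noise (SD 0.25), and are pure functions of (parameters, design,
seed).  The default chimera design mirrors the study: three BMT age
groups (7–9, 11–15, 20–25 wk), ~35 mice each, observation ages from
BMT + 4 wk to 600 d, DP1 chimerism 0.85.  The generators emulate the
statistical structure the likelihood assumes — they do not simulate flow
cytometry mechanics (gating, spillover), litter effects, or any
model-misspecification, so passing recovery tests demonstrates correct
inference under the assumed model, not robustness to real-data
artefacts.

## Problem sizes and numerical choices

* Cell-age/characteristic grid: 0.25 d for trajectories (Richardson-style
  step-halving agreement verified in tests), 1.0 d inside MCMC
  likelihoods (<1% stream error).
* Replicate harnesses: 20 synthetic cohorts of n = 100 mice (chimera
  recovery/selection) and 20 cohorts of 3 groups × 5 mice × 6 bleeds
  (hierarchical recovery), at the reduced sampler settings above.
* Month↔day conversion fixed at 30.44 d/month.
* Degenerate inputs: point-mass priors freeze parameters; empty donor
  pools yield flagged-missing Ki67; κ fits falling on the constant
  boundary collapse to the exactly-constant representation.

## Known limitations

* emcee's ensemble sampler at the reduced settings yields conservative
  R-hat values on hierarchical fits (~1.2); quantiles are stable across
  configurations, but replication-grade runs should use longer chains.
* The exact functional forms of the deposited analysis (influx curves,
  density dependence, priors) are not transcribed here; the registered
  families reproduce their described behaviour and sit behind interfaces
  that accept replacements.
* Density-dependent fitting shares the cohort-transport approximation
  that division along an entry cohort follows the background pool's
  time-varying rates; this is exact for the linear variants.
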