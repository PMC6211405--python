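# Methods

`denphen` implements two Bayesian analyses of brown-bear denning
phenology — the timing of last den entry in autumn and first den exit in
spring across a network of protected areas ("parks") — together with a
synthetic-data generator that makes the whole chain testable without the
original monitoring records, which are not publicly deposited.

## 1. Event-aligned trajectory model (temperature)

For every recorded event we re-index the nearest station's daily mean
temperature to lags t ∈ [−30, +30] days around the event day (lag 0 =
event day).  The observed trajectories are modelled hierarchically:

    v_iy(t) ~ GP(u_i(t),      k3_i)      park-year trajectories
    u_i(t)  ~ GP(w(t) + h_i,  k2)        park means
    w(t)    ~ GP(mu,          k1)        population mean

* `k1`, `k2` are squared-exponential kernels — average conditions vary
  smoothly with lag.
* `k3_i` are exponential (Ornstein–Uhlenbeck) kernels with one shared
  range and park-specific variances — daily residuals are rough and
  mean-reverting, and climate variability differs between parks.
* `h_i` is a constant park offset with a Normal(0, τ²) prior.  The
  hierarchy's park level only identifies the *sum* of a level shift and
  a smooth deviation; absorbing the shift into a single constant with
  its own scale is the simplest parameterization that keeps the two
  interpretable.

**Inference.**  Given the kernel hyperparameters the model is
linear-Gaussian, so `w` and all `u_i` are integrated out analytically
and only the hyperparameters (kernel SDs and length-scales, τ, the OU
range and park variances, and μ) are sampled, by an affine-invariant
ensemble sampler (emcee, differential-evolution moves) on the marginal
posterior.  For complete lag windows the marginal likelihood uses the
sufficiency of per-park year-mean trajectories: within-park contrasts
depend only on `k3_i`, and the stacked year means have covariance
`K1 (coupling all parks) + blockdiag(K2 + τ²J + K3_i/n_i)`.  Windows
with missing lags fall back to an exact dense path that conditions only
on the observed entries (practical up to a few thousand values).
Function draws are recovered exactly: draw `w | data`, then each
`u_i | w, data` — which factorizes over parks — so draws of `w` and
`u_i` are *jointly* consistent.  With hyperparameters held fixed the
conditional means are exact; the test suite gates this path against an
independently coded dense joint-Gaussian conditioning oracle at 1e-6.

**Priors** (configurable; data-scaled defaults): half-Normal(empirical
SD of the windows) on all kernel SDs and τ; log-Normal(log 10 d, 0.75)
on length-scales and the OU range; Normal(grand mean, 10²) on μ.

**Variance partition.**  Relative to the pooled empirical variance of
all observed window values: *shared* = variance over the lag grid of
the posterior-mean `w`; *park-additional* = mean over parks of the lag
variance of `u_i − w` (posterior means); *idiosyncratic* = remainder.
A draw-wise variant (using the joint function draws instead of the
means) is exposed for sensitivity.  The plug-in version is the default
because the posterior means are the quantities plotted and reported.

**Snow.**  Daily snow depth mixes spiky accumulation, slow compaction
and fast melt; a stationary GP is the wrong model for it.  Snow is
therefore summarized exploratorily: per-park mean trajectories over
years, loess-smoothed (span 0.3 over the 61-lag grid — no principled
span exists for this design, the value is an artifact default), clipped
at zero, then averaged across parks.  Parks with fewer than 3 years are
computed but flagged.

## 2. Time-varying-coefficient event-date model

The observed event day responds to *every* day's climate over a season
grid [t0, T] (defaults 211–365 for last entry, 1–150 for first exit)
through coefficient functions:

    z_iy  = mu + r_i + Σ_t a_i(t) u_iy(t) + Σ_t b_i(t) v_iy(t) + ε_iy
    a_i ~ GP(α, k_a),  b_i ~ GP(β, k_b),  α ~ GP(0, k_α),  β ~ GP(0, k_β)
    r_i ~ N(0, σ_r²),  ε_iy ~ N(0, σ_i²)

`k_α`/`k_β` share one SE length-scale with separate variances, likewise
`k_a`/`k_b`.  The integer response is treated as continuous Gaussian;
rounding noise (variance 1/12) is negligible against residual SDs of
days.

**Centering.**  Climate covariates are centered per park × day-of-year
(long-term mean removed) before entering the sums, both in the
generator and at fit time.  Without centering, `Σ a_i(t) u_iy(t)`
contains a park-level constant that is unidentifiable against
`mu + r_i`; with it, adding a constant to one park's temperatures
changes nothing at all (covariates are invariant), which the test suite
checks.

**Residual hierarchy.**  The park residual SDs are hierarchical.  A
Normal hierarchy directly on σ_i admits negative SDs, so it is placed
on log σ_i: `log σ_i ~ N(m_σ, ρ²)` with hyperpriors
`m_σ ~ N(log sd(z), 1)` and ρ ~ half-Normal(0.5).

**Inference.**  All Gaussian parameters — μ (Normal(mean date, 20²)
prior), r, α, β and the park deviations — are integrated out; the
marginal covariance of z is assembled in function space and the
hyperparameters sampled as in the trajectory model.  Coefficient curves
are recovered by exact conditional-Gaussian draws per hyperparameter
draw (≥ 500 pooled draws required for credibility summaries).  The
fixed-hyperparameter path is gated at 1e-6 against a closed-form
weight-space Bayesian-linear-model oracle.

The ensemble is warm-started at the marginal MAP (Powell).  One caveat
found during development: the profile density of the hierarchical
spread ρ is unbounded as ρ→0 with all log σ_i equal — a standard
funnel, harmless to the sampler but fatal to an optimizer.  The
warm-start therefore freezes the ρ coordinate; MCMC still samples it.

A reduced-rank sine-basis (Hilbert-space) representation of the SE
kernels is available for long grids (`low_rank=m`); the exact dense
representation is the default and is what the oracle tests gate.

**Coefficient-SD prior scales.**  Half-Normal with scale
`sd(z) / (sd(covariate)·√L)` — the coefficient size at which a
uniformly spread seasonal effect would reproduce the full response SD.
This is intentionally generous; it is weakly informative, not
shrinkage-calibrated.

**Summaries.**
* *Window-sum credibility*: P(Σ_{t1..t2} coef(t) ≥ 0) over all windows,
  from pooled draws (upper-triangular surface; the diagonal equals
  1 − pointwise P(coef < 0)).
* *Pointwise sign credibility*: maximal runs of days with
  P(coef(t) < 0) above a threshold (default 0.95).
* *Event-shift prediction*: for a per-day increase δ over [t1, t2],
  shift = δ·Σ α(t) per draw, mean ± SD (negative = earlier).
* *Variance explained*: total R² = 1 − Var(z − posterior-mean linear
  predictor)/Var(z).  The climate component after removing park means
  is reported as a variance *share*, Var(climate predictor)/Var(centered
  z) — the same component/total form as the trajectory partition.  The
  residual-subtraction variant is also returned
  (`climate_subtraction_pct`) but is not the headline: as an in-sample
  statistic it absorbs ≈ 2·dof/n of pure noise-fitting for any flexible
  posterior-mean smoother (~3% per kernel component at these sizes,
  confirmed by exact 1-D numerical integration of the marginal
  posterior on null data), so it cannot distinguish a weak climate
  signal from no signal.  The share stays near zero under a
  climate-free null and recovers true shares under signal.

## 3. Model comparison by exact-refit LOO-CV

Candidate "standard" models average the centered climate over a window
[t1, t2], with t1, t2 on a 7-day step grid from t0 (253 windows for the
autumn season, 231 for spring), and fit a Gaussian random-intercept LMM
(park intercept; both averaged covariates by default, single-covariate
variants available).  The LMM is fitted by marginal ML with fixed
effects profiled out by GLS; per-group sufficient statistics make each
leave-one-out refit a rank-1 downdate, so exact refit over hundreds of
windows is cheap.  The implementation is cross-checked against
statsmodels MixedLM.

Scores are leave-one-out log predictive densities summed over
observations (one park-year event each); higher is better.

* *LMM predictive*: exact ML refit without the held-out observation;
  the predictive integrates the park intercept at its conditional
  posterior given the park's remaining rows (or over the prior for an
  unseen park / `new` mode) and propagates the GLS fixed-effect
  covariance through the conditional mean (delta method).  Propagating
  the raw x'Vx instead double-counts intercept uncertainty — the
  conditional intercept compensates fixed-effect error — and was
  measurably miscalibrated.
* *Flexible-model predictive*: for each hyperparameter draw the
  Gaussian layer is re-solved without each observation in closed form
  (precision-matrix leave-one-out identities — an exact refit of all
  Gaussian parameters); densities are averaged over draws.  The
  hyperparameters themselves come from the full-data posterior:
  re-running the hyper-MCMC per observation is not feasible at desk
  scale.  Measured on ~100-observation simulations whose truth *is* a
  window-average effect, this reuse leaves the flexible model an
  optimism of a few LPD units, which shrinks with n; the comparison
  tests therefore check the *direction contrast* (time-varying truth vs
  window-constant truth, paired by seed) rather than a sign flip alone.

## 4. Synthetic-data generator

The generator defines the study conditions for every test:

* **Temperature**: park offset (SD 2 °C) + annual sinusoid (mean 2 °C,
  amplitude 15 °C, coldest mid-January) + linear warming trend
  (0.034 °C/yr, the long-term regional rate) + AR(1) daily residual
  (coefficient 0.7, innovation SD 3 °C).
* **Snow**: on sub-zero days, snowfall with probability 0.35 and
  exponential depth (mean 3 cm); daily multiplicative compaction (2 %);
  melt of 1 cm per positive °C-day; clipped at zero.  This three-term
  balance reproduces the qualitative spiky-rise / slow-decay / fast-melt
  shape; it is not an energy-balance snow model.
* **Events**: the same linear model the fitting module estimates, with
  defaults placing last entries near day 304 ± 18 and first exits near
  day 99 ± 15 (park-intercept SD 13/11 d, residual SD 12/10 d,
  between-park residual-SD spread 2 d, drawn as |N(σ̄, ρ²)|).
  Coefficient functions are explicit vectors or SE-GP draws; the
  un-rounded event mean is exposed for exact unit tests.
* **Calendar**: 365-day years everywhere (Feb 29 folded onto Feb 28),
  so day-of-year is comparable across years.
* **Randomness**: one seed, split hierarchically by stream, park and
  year (Philox counter streams), so adding a park or year never
  perturbs existing draws.

What the generator does *not* emulate: spatial correlation between
parks, observation effort, station-to-park representativeness error,
missing data patterns, and any behavioural (non-linear) response of
bears to climate.  Passing recovery tests therefore show that the
estimators work when their assumptions hold, not that the assumptions
hold in the field data.

## 5. Numerical choices and test-scale settings

* Covariance factorizations add diagonal jitter only when plain
  Cholesky fails, escalating from 1e-10 to 1e-4 of the mean diagonal;
  the amount used is recorded.
* Haversine distances on a 6371-km sphere; nearest-station ties break
  lexicographically.
* Climate gap-filling: linear interpolation (temperature) and forward
  fill (snow) for gaps ≤ 3 days; longer gaps are reported and left
  missing.  Lag windows with > 20 % missing lags are excluded.
* Ensemble settings: walkers default to 2·dim + 6; warm start by
  Powell on the marginal posterior.  Split-R̂ > 1.05 logs a warning
  (short exploratory chains are expected to trip it; headline runs
  should use longer chains).
* Test-suite problem sizes are deliberate desk-scale choices:
  recovery studies use 12 parks × 40 years on 80–100-day season grids
  with ~3500-evaluation chains; the comparison study uses 8 parks ×
  12 years on a 60-day grid; the variance-partition study uses
  6 parks × 10 years on a 31-lag grid with component draws rescaled so
  the realized shared/park/noise split is exactly 30:20:50 (a single
  GP draw's realized grid variance is otherwise too variable for the
  partition target to be meaningful per seed).

## 6. Known limitations

* Hyperparameter chains in the bundled tests are short; they are
  adequate for posterior means and the tested summaries but understate
  tail uncertainty.  For production analyses increase `n_steps`.
* LOO for the flexible model conditions on full-data hyperparameters
  (see §3).
* The exponential kernel is used exactly as specified for daily
  residuals; it is Markovian and cannot represent longer-memory
  weather regimes.
* The event model is associational: photoperiod, resource availability
  and other drivers correlated with season are not controlled.
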