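# denphen

Bayesian models of brown-bear denning phenology and daily climate.

Long-term monitoring programmes in Russian protected areas record, for
each park and year, the last day bear activity is seen in autumn (last
den entry) and the first day it is seen in spring (first den exit).
`denphen` asks two questions of such records joined with daily
meteorological series:

1. **What do climate conditions look like around denning events?**
   Daily mean temperature re-indexed to lags −30..+30 days around each
   event is modelled with a three-level hierarchical Gaussian-process
   regression,

   v_iy(t) ~ GP(u_i(t), k₃ᵢ),  u_i(t) ~ GP(w(t) + h_i, k₂),  w(t) ~ GP(μ, k₁),

   with squared-exponential kernels for the smooth park and population
   means and exponential (Ornstein–Uhlenbeck) kernels for rough daily
   residuals.  It yields the population trajectory w(t) with
   uncertainty, the expected conditions on the event day w(0), the
   local slope, and a variance partition into shared / park-specific /
   idiosyncratic components.  Snow depth, whose spiky
   accumulation–compaction–melt dynamics defeat a stationary GP, gets a
   matching exploratory summary: per-park averages, loess smoothing,
   park mean.

2. **Which days' climate moves the event date?**  The event day is
   regressed on *every* day's centered temperature and snow depth over
   the preceding season through time-varying coefficients with GP
   priors,

   z_iy = μ + r_i + Σₜ a_i(t)·u_iy(t) + Σₜ b_i(t)·v_iy(t) + ε_iy,
   a_i ~ GP(α, k_a), α ~ GP(0, k_α) (likewise snow), ε_iy ~ N(0, σ_i²),

   a scalar-on-function (distributed-lag) extension of a linear mixed
   model.  Summaries include the coefficient curves α(t)/β(t) with
   credible bands, window-sum credibility surfaces
   P(Σ_{t₁..t₂} α(t) ≥ 0), pointwise sign credibility, variance
   explained, and predicted event-day shifts per unit climate change.
   The model is benchmarked against every windowed-average linear mixed
   model on a 7-day step grid by exact-refit leave-one-out
   cross-validated log predictive density.

Because the original phenology records are not deposited, the package
ships a synthetic-data generator (`denphen.simulate`) that emulates
multi-park daily climate (sinusoid + warming trend + AR(1);
snowfall/compaction/melt balance) and event dates drawn from the same
time-varying-coefficient model, with the generative truth exposed — so
every estimator here is exercised and validated by parameter recovery.

Inference throughout is marginal-likelihood MCMC: the linear-Gaussian
layer (all mean functions and coefficients) is integrated out
analytically, kernel/variance hyperparameters are sampled with an
ensemble sampler, and function posteriors are recovered by exact
conditional-Gaussian draws.  See `docs/methods.md` for assumptions,
priors, and numerical choices.

## Worked example

```python
import numpy as np
import denphen
from denphen import SamplerConfig

# a synthetic study: 6 parks, 25 years of daily climate + spring den-exit dates
scenario = denphen.SyntheticScenario(
    n_parks=6, first_year=1990, last_year=2014, seed=42,
    event_params=denphen.EventParams.first_exit(),
)
climate = denphen.simulate_climate(scenario)
coefs = denphen.simulate_coefficient_functions(scenario)
events, truth = denphen.simulate_event_dates(climate, coefs, scenario)

# 1. event-aligned temperature trajectories
windows, _ = denphen.align_event_windows(events, climate, "temperature_c")
traj = denphen.TemperatureTrajectoryModel(windows).fit(
    SamplerConfig(n_steps=120, n_warmup=70, n_keep=80, seed=42))
print(traj.summary())

# 2. snow around the event day
snow_windows, _ = denphen.align_event_windows(events, climate, "snow_cm")
snow = denphen.snow_trajectory_summary(snow_windows)
print("snow at exit: %.1f cm, slope %.2f cm/day"
      % (snow.event_day_summary()["value_at_event_day"],
         snow.event_day_summary()["slope_per_day"]))

# 3. which days' temperature moves the exit date?
fit = denphen.EventDateModel(events, climate, "first_exit").fit(
    SamplerConfig(n_steps=120, n_warmup=70, n_keep=100, seed=42))
print(fit.summary())
shift = fit.predict_event_shift((69, 89), delta=1.0, variable="temperature")
print("+1 degC on days 69-89 shifts exit by %.2f +/- %.2f days"
      % (shift["mean_days"], shift["sd_days"]))
```

Output (abridged):

```
Hierarchical GP trajectory model
================================================
parks: 6   windows: 150   lags: -30..30
w(0) = 2.04 (+/- 1.308 posterior SD)
slope of w at lag 0: +0.254 per day
variance partition (% of observed): shared 36.9 / park +0.0 / idiosyncratic 63.1
...
snow at exit: 18.4 cm, slope -0.91 cm/day
Time-varying-coefficient event-date model
================================================
event kind: first_exit   observations: 150   parks: 6   season grid: 1..150
overall mean day mu: 102.3
variance explained: total 42.2%, climate after park-centering 10.2%
days with P(alpha<0)>0.95: none
coefficient draws: 500
max split-R-hat 2.103, min bulk ESS 24
+1 degC on days 69-89 shifts exit by 0.03 +/- 0.18 days
```

Reading it: bears in this simulated network emerge around day 102 as
temperature crosses ≈ +2 °C (warming ≈ 0.25 °C/day) under ≈ 18 cm of
melting snow; about a third of the temperature variation around events
is a pattern shared by all parks.  The generator's default coefficient
functions are weak GP draws, so the event-date model correctly finds
only a small, uncertain climate effect here — the parameter-recovery
tests in `tests/test_acceptance.py` use stronger planted signals and
verify that planted coefficient bumps are found at the right location.
(The R-hat warning reflects the deliberately short demo chains;
increase `n_steps` for production runs.)

A command-line pipeline wraps the same stages
(`denphen run-all --config run.yaml --seed 1`), writing per-stage CSV/
JSON outputs, plots and a manifest into a run directory; see
`denphen --help`.

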