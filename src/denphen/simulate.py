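"""Synthetic multi-park climate and denning-event generator.

The generator emulates the structure of the long-term Russian
protected-area monitoring data used for brown-bear denning phenology:
daily mean air temperature and snow depth per park, and one observed
event date (last den entry in autumn, or first den exit in spring) per
park and year.  Every downstream model in the package can therefore be
exercised, and its parameter recovery measured, without any external
download.

Temperature is a park offset plus an annual sinusoid plus a linear
warming trend plus an AR(1) residual.  Snow depth follows a three-term
daily balance: stochastic snowfall accumulation on sub-zero days,
multiplicative compaction decay, and melt proportional to positive
temperature, clipped at zero.  Event dates follow the same
time-varying-coefficient linear model the fitting module estimates, so
generative truth is available for recovery tests.

All years have 365 days (no Feb 29); day-of-year runs 1..365.

Randomness is split hierarchically from a single scenario seed, by
stream, park and year, so adding a park or a year never perturbs the
draws of existing parks/years.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import se_kernel
from .gaussian import chol_with_jitter

__all__ = [
    "TempParams",
    "SnowParams",
    "EventParams",
    "CoefParams",
    "SyntheticScenario",
    "CoefficientFunctions",
    "simulate_climate",
    "simulate_coefficient_functions",
    "simulate_event_dates",
    "center_climate",
    "seasonal_temperature",
]

DAYS_PER_YEAR = 365
# coldest day of the sinusoid (mid-January)
_COLDEST_DOY = 15

# stream tags for hierarchical seeding
_S_OFFSET, _S_TEMP, _S_SNOW, _S_INTERCEPT, _S_SIGMA, _S_NOISE, _S_COEF, _S_COEF_PARK = range(8)


class ScenarioError(ValueError):
    """A scenario field violates its constraints."""


@dataclass(frozen=True)
class TempParams:
    """Daily temperature process: sinusoid + trend + AR(1) residual."""

    annual_mean: float = 2.0          # °C
    seasonal_amplitude: float = 15.0  # °C, half peak-to-trough
    trend: float = 0.034              # °C per year
    ar1_coefficient: float = 0.7
    innovation_sd: float = 3.0        # °C
    park_offset_sd: float = 2.0       # °C between-park spread


@dataclass(frozen=True)
class SnowParams:
    """Snow balance: stochastic accumulation, compaction, melt."""

    snowfall_probability_at_subzero: float = 0.35
    snowfall_depth_mean: float = 3.0  # cm per snowfall event
    compaction_rate: float = 0.02     # fraction lost per day
    melt_rate: float = 1.0            # cm per positive °C-day


@dataclass(frozen=True)
class EventParams:
    """Event-date model truth: z = mu + r_i + climate terms + noise."""

    kind: str = "first_exit"          # "last_entry" | "first_exit"
    mu: float = 99.0                  # overall mean day-of-year
    park_intercept_sd: float = 11.0   # sigma_r, days
    residual_sd_mean: float = 10.0    # sigma-bar, days
    residual_sd_spread: float = 2.0   # rho, days
    t0: int = 1
    T: int = 150

    @staticmethod
    def last_entry(**kw) -> "EventParams":
        base = dict(kind="last_entry", mu=304.0, park_intercept_sd=13.0,
                    residual_sd_mean=12.0, residual_sd_spread=2.0, t0=211, T=365)
        base.update(kw)
        return EventParams(**base)

    @staticmethod
    def first_exit(**kw) -> "EventParams":
        base = dict(kind="first_exit", mu=99.0, park_intercept_sd=11.0,
                    residual_sd_mean=10.0, residual_sd_spread=2.0, t0=1, T=150)
        base.update(kw)
        return EventParams(**base)


@dataclass(frozen=True)
class CoefParams:
    """Time-varying coefficient functions alpha/beta and park deviations.

    ``alpha``/``beta`` may be explicit vectors over the season grid
    [t0, T]; otherwise each is drawn from a zero-mean squared-exponential
    GP with the stated variance and length-scale.  Park curves are the
    global curve plus a zero-mean SE-GP deviation with
    ``park_deviation_variance``.
    """

    alpha: np.ndarray | None = None       # days per °C, length T-t0+1
    beta: np.ndarray | None = None        # days per cm
    alpha_gp_variance: float = 0.02**2
    beta_gp_variance: float = 0.005**2
    gp_length_scale: float = 10.0         # days, shared by alpha and beta draws
    park_deviation_variance: float = 0.0
    park_deviation_length_scale: float = 10.0


@dataclass(frozen=True)
class SyntheticScenario:
    n_parks: int = 12
    first_year: int = 1946
    last_year: int = 2014
    seed: int = 0
    temp_params: TempParams = field(default_factory=TempParams)
    snow_params: SnowParams = field(default_factory=SnowParams)
    event_params: EventParams = field(default_factory=EventParams)
    coef_params: CoefParams = field(default_factory=CoefParams)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_parks < 1:
            raise ScenarioError(f"n_parks must be >= 1, got {self.n_parks}")
        if self.last_year < self.first_year:
            raise ScenarioError(
                f"empty year range: first_year={self.first_year}, last_year={self.last_year}"
            )
        tp, sp, ep = self.temp_params, self.snow_params, self.event_params
        if not (0.0 <= tp.ar1_coefficient < 1.0):
            raise ScenarioError(f"ar1_coefficient must be in [0,1), got {tp.ar1_coefficient}")
        for obj, name in [
            (tp, "innovation_sd"), (tp, "park_offset_sd"), (tp, "seasonal_amplitude"),
            (sp, "snowfall_depth_mean"), (sp, "melt_rate"),
            (ep, "park_intercept_sd"), (ep, "residual_sd_mean"), (ep, "residual_sd_spread"),
        ]:
            if getattr(obj, name) < 0:
                raise ScenarioError(f"{name} must be >= 0, got {getattr(obj, name)}")
        if not (0.0 <= sp.snowfall_probability_at_subzero <= 1.0):
            raise ScenarioError(
                "snowfall_probability_at_subzero must be in [0,1], got "
                f"{sp.snowfall_probability_at_subzero}"
            )
        if not (0.0 <= sp.compaction_rate < 1.0):
            raise ScenarioError(f"compaction_rate must be in [0,1), got {sp.compaction_rate}")
        if not ep.t0 < ep.T:
            raise ScenarioError(f"event interval requires t0 < T, got t0={ep.t0}, T={ep.T}")
        if ep.kind not in ("last_entry", "first_exit"):
            raise ScenarioError(f"unknown event kind {ep.kind!r}")
        cp = self.coef_params
        for name in ("alpha_gp_variance", "beta_gp_variance", "park_deviation_variance"):
            if getattr(cp, name) < 0:
                raise ScenarioError(f"{name} must be >= 0, got {getattr(cp, name)}")
        L = ep.T - ep.t0 + 1
        for vec, name in [(cp.alpha, "alpha"), (cp.beta, "beta")]:
            if vec is not None and len(np.atleast_1d(vec)) != L:
                raise ScenarioError(
                    f"explicit {name} has length {len(np.atleast_1d(vec))}, "
                    f"expected T-t0+1 = {L}"
                )

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    @property
    def park_ids(self) -> list[str]:
        return [f"park{i + 1:02d}" for i in range(self.n_parks)]

    def replace(self, **kw) -> "SyntheticScenario":
        return dataclasses.replace(self, **kw)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(np.random.SeedSequence((seed, *key))))


def seasonal_temperature(doy: np.ndarray | float, tp: TempParams) -> np.ndarray:
    """Deterministic annual cycle: minimum at mid-January."""
    return tp.annual_mean - tp.seasonal_amplitude * np.cos(
        2.0 * np.pi * (np.asarray(doy, float) - _COLDEST_DOY) / DAYS_PER_YEAR
    )


def simulate_climate(scenario: SyntheticScenario) -> pd.DataFrame:
    """Daily temperature and snow depth for every park and year.

    Returns a long frame with columns ``park_id, year, doy,
    temperature_c, snow_cm``, contiguous over all scenario years.
    Snow is non-negative everywhere; with zero snowfall probability and
    zero initial snow it is identically zero.
    """
    scenario.validate()
    tp, sp = scenario.temp_params, scenario.snow_params
    years = scenario.years
    doy = np.arange(1, DAYS_PER_YEAR + 1)
    season = seasonal_temperature(doy, tp)

    frames = []
    for i, park in enumerate(scenario.park_ids):
        offset = float(_rng(scenario.seed, _S_OFFSET, i).normal(0.0, tp.park_offset_sd)) \
            if tp.park_offset_sd > 0 else 0.0
        ar_state = 0.0
        snow = 0.0
        temp_all = np.empty(len(years) * DAYS_PER_YEAR)
        snow_all = np.empty_like(temp_all)
        for yi, year in enumerate(years):
            g_t = _rng(scenario.seed, _S_TEMP, i, int(year))
            innov = g_t.normal(0.0, tp.innovation_sd, DAYS_PER_YEAR) \
                if tp.innovation_sd > 0 else np.zeros(DAYS_PER_YEAR)
            resid = np.empty(DAYS_PER_YEAR)
            a = tp.ar1_coefficient
            for d in range(DAYS_PER_YEAR):
                ar_state = a * ar_state + innov[d]
                resid[d] = ar_state
            temp = offset + season + tp.trend * (year - years[0]) + resid

            g_s = _rng(scenario.seed, _S_SNOW, i, int(year))
            u = g_s.random(DAYS_PER_YEAR)
            fall = g_s.exponential(sp.snowfall_depth_mean, DAYS_PER_YEAR)
            sd = np.empty(DAYS_PER_YEAR)
            tl, ul, fl = temp.tolist(), u.tolist(), fall.tolist()
            p, c, m = sp.snowfall_probability_at_subzero, sp.compaction_rate, sp.melt_rate
            for d in range(DAYS_PER_YEAR):
                t = tl[d]
                if t < 0.0 and ul[d] < p:
                    snow += fl[d]
                snow *= 1.0 - c
                if t > 0.0:
                    snow -= m * t
                    if snow < 0.0:
                        snow = 0.0
                sd[d] = snow
            lo, hi = yi * DAYS_PER_YEAR, (yi + 1) * DAYS_PER_YEAR
            temp_all[lo:hi] = temp
            snow_all[lo:hi] = sd
        frames.append(pd.DataFrame({
            "park_id": park,
            "year": np.repeat(years, DAYS_PER_YEAR),
            "doy": np.tile(doy, len(years)),
            "temperature_c": temp_all,
            "snow_cm": snow_all,
        }))
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class CoefficientFunctions:
    """True coefficient curves on the integer season grid [t0, T]."""

    grid: np.ndarray       # days t0..T
    alpha: np.ndarray      # (L,) days per °C
    beta: np.ndarray       # (L,) days per cm
    a: np.ndarray          # (n_parks, L)
    b: np.ndarray          # (n_parks, L)


def simulate_coefficient_functions(scenario: SyntheticScenario) -> CoefficientFunctions:
    """Draw (or pass through) alpha, beta and the park curves a_i, b_i."""
    scenario.validate()
    cp, ep = scenario.coef_params, scenario.event_params
    grid = np.arange(ep.t0, ep.T + 1, dtype=float)
    L = grid.size

    def global_curve(explicit, variance, which: int) -> np.ndarray:
        if explicit is not None:
            return np.asarray(explicit, dtype=float).copy()
        if variance == 0:
            return np.zeros(L)
        k = se_kernel(variance, cp.gp_length_scale)(grid)
        chol = chol_with_jitter(k, scale=max(variance, 1e-12))
        z = _rng(scenario.seed, _S_COEF, which).standard_normal(L)
        return chol.lower @ z

    alpha = global_curve(cp.alpha, cp.alpha_gp_variance, 0)
    beta = global_curve(cp.beta, cp.beta_gp_variance, 1)

    a = np.tile(alpha, (scenario.n_parks, 1))
    b = np.tile(beta, (scenario.n_parks, 1))
    if cp.park_deviation_variance > 0:
        k = se_kernel(cp.park_deviation_variance, cp.park_deviation_length_scale)(grid)
        chol = chol_with_jitter(k, scale=cp.park_deviation_variance)
        for i in range(scenario.n_parks):
            g = _rng(scenario.seed, _S_COEF_PARK, i)
            a[i] += chol.lower @ g.standard_normal(L)
            b[i] += chol.lower @ g.standard_normal(L)
    return CoefficientFunctions(grid=grid, alpha=alpha, beta=beta, a=a, b=b)


def center_climate(climate: pd.DataFrame) -> pd.DataFrame:
    """Remove per park x day-of-year long-term means from both climate columns.

    This is the covariate convention shared by the generator and the
    event-date fit: it decouples the climate sums from the intercepts.
    """
    out = climate.copy()
    for col in ("temperature_c", "snow_cm"):
        out[col] = out[col] - out.groupby(["park_id", "doy"])[col].transform("mean")
    return out


def simulate_event_dates(
    climate: pd.DataFrame,
    coefs: CoefficientFunctions,
    scenario: SyntheticScenario,
) -> tuple[pd.DataFrame, dict]:
    """One event record per park x year from the linear event-date model.

    The real-valued mean is mu + r_i + sum_t a_i(t) u~_iy(t) +
    sum_t b_i(t) v~_iy(t) with centered climate, then park-specific
    Gaussian noise is added and the result rounded to an integer day.
    Records rounding outside [t0, T] are kept but flagged.

    Returns ``(records, truth)`` where truth holds r_i, sigma_i, the
    coefficient curves and the un-rounded means for exact unit tests.
    """
    scenario.validate()
    ep = scenario.event_params
    grid_days = np.arange(ep.t0, ep.T + 1)
    centered = center_climate(climate)

    parks = scenario.park_ids
    years = scenario.years
    have = set(zip(climate["park_id"], climate["year"], climate["doy"]))
    missing = [
        (p, int(y)) for p in parks for y in years
        if any((p, y, int(d)) not in have for d in grid_days)
    ]
    if missing:
        raise ValueError(
            f"climate does not cover [t0={ep.t0}, T={ep.T}] for park-years: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )

    sub = centered[centered["doy"].between(ep.t0, ep.T)]
    piv_t = sub.pivot_table(index=["park_id", "year"], columns="doy",
                            values="temperature_c", sort=True)
    piv_s = sub.pivot_table(index=["park_id", "year"], columns="doy",
                            values="snow_cm", sort=True)

    rows = []
    truth_means = {}
    r = np.zeros(len(parks))
    sig = np.zeros(len(parks))
    for i, park in enumerate(parks):
        r[i] = float(_rng(scenario.seed, _S_INTERCEPT, i).normal(0.0, ep.park_intercept_sd)) \
            if ep.park_intercept_sd > 0 else 0.0
        if ep.residual_sd_spread > 0:
            # positive by construction; a folded normal around sigma-bar
            sig[i] = abs(float(_rng(scenario.seed, _S_SIGMA, i)
                               .normal(ep.residual_sd_mean, ep.residual_sd_spread)))
        else:
            sig[i] = ep.residual_sd_mean
        for year in years:
            u = piv_t.loc[(park, year)].to_numpy()
            v = piv_s.loc[(park, year)].to_numpy()
            mean = ep.mu + r[i] + float(coefs.a[i] @ u) + float(coefs.b[i] @ v)
            noise = float(_rng(scenario.seed, _S_NOISE, i, int(year)).normal(0.0, sig[i])) \
                if sig[i] > 0 else 0.0
            z = mean + noise
            day = int(round(z))
            rows.append({
                "park_id": park, "year": int(year), "event_kind": ep.kind,
                "day_of_year": day,
                "outside_interval": not (ep.t0 <= day <= ep.T),
            })
            truth_means[(park, int(year))] = mean
    records = pd.DataFrame(rows)
    truth = {
        "mu": ep.mu,
        "r": dict(zip(parks, r)),
        "sigma": dict(zip(parks, sig)),
        "alpha": coefs.alpha.copy(),
        "beta": coefs.beta.copy(),
        "a": coefs.a.copy(),
        "b": coefs.b.copy(),
        "grid": coefs.grid.copy(),
        "unrounded_mean": truth_means,
    }
    return records, truth
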