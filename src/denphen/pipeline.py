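"""Configurable end-to-end pipeline: simulate/ingest -> fit -> compare -> report.

Each stage writes its outputs into the run directory as soon as it
completes; a manifest records the package version, a hash of the
configuration, the seed, and per-stage status and wall time.  A failing
stage stops downstream stages but leaves completed outputs intact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._mcmc import SamplerConfig
from .comparison import compare_models, evaluate_candidate_windows
from .events import SEASON_GRIDS, EventDateModel
from .io import (
    align_event_windows,
    assign_nearest_station,
    fill_gaps,
    read_climate,
    read_coordinates,
    read_phenology,
    write_climate,
    write_phenology,
)
from .simulate import (
    EventParams,
    SyntheticScenario,
    simulate_climate,
    simulate_coefficient_functions,
    simulate_event_dates,
)
from .trajectory import TemperatureTrajectoryModel, snow_trajectory_summary

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "annual_trend_report", "ConfigError", "StageError"]


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Everything a pipeline run needs; file values < flag overrides."""

    outdir: str = "denphen_run"
    seed: int = 0
    event_kind: str = "first_exit"
    # either a synthetic scenario ...
    scenario: dict | None = None
    # ... or paths to real tables
    phenology_path: str | None = None
    climate_path: str | None = None
    park_coords_path: str | None = None
    station_coords_path: str | None = None
    # analysis settings
    t0: int | None = None
    T: int | None = None
    lag_range: tuple[int, int] = (-30, 30)
    loess_span: float = 0.3
    loo_mode: str = "existing"
    window_step: int = 7
    chains: int | None = None      # ensemble walkers
    draws: int = 120               # kept hyperparameter draws
    steps: int = 120
    warmup: int = 70
    max_gap_days: int = 3
    make_plots: bool = True

    @staticmethod
    def from_yaml(path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = RunConfig(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.t0 is not None and self.T is not None and self.t0 >= self.T:
            raise ConfigError(f"t0 must be < T, got {self.t0} >= {self.T}")
        if self.event_kind not in SEASON_GRIDS:
            raise ConfigError(f"unknown event_kind {self.event_kind!r}")
        if self.scenario is None and (self.phenology_path is None or self.climate_path is None):
            raise ConfigError("need either a scenario or phenology+climate paths")
        for p in (self.phenology_path, self.climate_path,
                  self.park_coords_path, self.station_coords_path):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
        if self.lag_range[0] > self.lag_range[1]:
            raise ConfigError(f"invalid lag_range {self.lag_range}")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def sampler_config(self) -> SamplerConfig:
        return SamplerConfig(n_walkers=self.chains, n_steps=self.steps,
                             n_warmup=self.warmup, n_keep=self.draws, seed=self.seed)


def _build_scenario(cfg: RunConfig) -> SyntheticScenario:
    raw = dict(cfg.scenario or {})
    ev = raw.pop("event_params", {})
    ev_defaults = (EventParams.last_entry() if cfg.event_kind == "last_entry"
                   else EventParams.first_exit())
    ev = dataclasses.replace(ev_defaults, **ev)
    from .simulate import CoefParams, SnowParams, TempParams

    kw = {}
    for key, cls in (("temp_params", TempParams), ("snow_params", SnowParams),
                     ("coef_params", CoefParams)):
        if key in raw:
            kw[key] = cls(**raw.pop(key))
    return SyntheticScenario(seed=cfg.seed, event_params=ev, **raw, **kw)


def annual_trend_report(climate: pd.DataFrame, min_years: int = 3,
                        id_col: str = "park_id") -> dict:
    """Per-day-of-year OLS slope of each climate variable against year.

    Days with fewer than ``min_years`` of data are omitted and listed.
    Returns per-park tables plus the across-park mean curve (unsmoothed).
    """
    out = {"per_park": {}, "mean": {}, "omitted": []}
    for var in ("temperature_c", "snow_cm"):
        tables = []
        for pid, g in climate.groupby(id_col, sort=False):
            piv = g.pivot_table(index="year", columns="doy", values=var)
            counts = piv.notna().sum(axis=0)
            years = piv.index.to_numpy(float)
            slopes = {}
            for doy in piv.columns:
                if counts[doy] < min_years:
                    out["omitted"].append((pid, var, int(doy), int(counts[doy])))
                    continue
                y = piv[doy].to_numpy(float)
                ok = np.isfinite(y)
                xv = years[ok] - years[ok].mean()
                slopes[int(doy)] = float(xv @ (y[ok] - y[ok].mean()) / (xv @ xv))
            tables.append(pd.Series(slopes, name=pid))
        per_park = pd.DataFrame(tables).T.sort_index()
        out["per_park"][var] = per_park
        out["mean"][var] = per_park.mean(axis=1)
    return out


def _stage_simulate(cfg: RunConfig, outdir: Path) -> dict:
    scenario = _build_scenario(cfg)
    climate = simulate_climate(scenario)
    coefs = simulate_coefficient_functions(scenario)
    events, truth = simulate_event_dates(climate, coefs, scenario)
    write_phenology(events, outdir / "phenology.csv")
    write_climate(climate, outdir / "climate.csv", id_col="park_id")
    sidecar = {
        "mu": truth["mu"], "r": truth["r"], "sigma": truth["sigma"],
        "alpha": truth["alpha"].tolist(), "beta": truth["beta"].tolist(),
        "grid": truth["grid"].tolist(), "seed": scenario.seed,
    }
    (outdir / "truth.json").write_text(json.dumps(sidecar, indent=1))
    return {"events": events, "climate": climate,
            "t0": scenario.event_params.t0, "T": scenario.event_params.T}


def _stage_ingest(cfg: RunConfig, outdir: Path) -> dict:
    events, report = read_phenology(cfg.phenology_path)
    events = events[events["event_kind"] == cfg.event_kind]
    station_climate = read_climate(cfg.climate_path)
    station_climate, gap_report = fill_gaps(station_climate, cfg.max_gap_days)
    if cfg.park_coords_path and cfg.station_coords_path:
        mapping = assign_nearest_station(
            read_coordinates(cfg.park_coords_path),
            read_coordinates(cfg.station_coords_path),
        )
        mapping.to_csv(outdir / "station_assignment.csv", index=False)
    else:
        # station ids double as park ids (already park-level data)
        mapping = pd.DataFrame({"park_id": station_climate["station_id"].unique()})
        mapping["station_id"] = mapping["park_id"]
    climate = station_climate.merge(mapping, on="station_id")[
        ["park_id", "year", "doy", "temperature_c", "snow_cm"]
    ]
    (outdir / "ingest_report.json").write_text(json.dumps({
        "flagged_out_of_interval": report.flagged_out_of_interval,
        "long_gaps": gap_report.long_gaps,
    }, indent=1, default=str))
    d0, dT = SEASON_GRIDS[cfg.event_kind]
    return {"events": events, "climate": climate,
            "t0": cfg.t0 or d0, "T": cfg.T or dT}


def _stage_trajectory(cfg: RunConfig, data: dict, outdir: Path) -> dict:
    temp_windows, rep_t = align_event_windows(
        data["events"], data["climate"], "temperature_c", cfg.lag_range
    )
    snow_windows, _ = align_event_windows(
        data["events"], data["climate"], "snow_cm", cfg.lag_range
    )
    model = TemperatureTrajectoryModel(temp_windows)
    fit = model.fit(sampler_config=cfg.sampler_config())
    fit.curves_to_csv(outdir / "trajectory_curves.csv")
    snow = snow_trajectory_summary(snow_windows, cfg.loess_span)
    summary = {
        "temperature": {**fit.event_day_summary(), **fit.variance_partition()},
        "snow": {**snow.event_day_summary(), **snow.variance_partition(snow_windows)},
        "excluded_windows": rep_t.excluded_windows,
        "seed": cfg.seed, "config_hash": cfg.hash(),
    }
    (outdir / "trajectory_summary.json").write_text(json.dumps(summary, indent=1, default=str))
    pd.DataFrame({
        "lag": snow.lags,
        "global_mean": snow.global_mean,
        **{f"u_{pk}": snow.smoothed[i] for i, pk in enumerate(snow.park_ids)},
    }).to_csv(outdir / "snow_trajectory.csv", index=False)
    if cfg.make_plots:
        _plot_trajectory(fit, snow, outdir)
    return {"trajectory_fit": fit, "snow_summary": snow}


def _stage_event_model(cfg: RunConfig, data: dict, outdir: Path) -> dict:
    model = EventDateModel(data["events"], data["climate"], cfg.event_kind,
                           t0=data["t0"], T=data["T"])
    fit = model.fit(sampler_config=cfg.sampler_config())
    fit.coefficient_table().to_csv(outdir / "coefficient_curves.csv", index=False)
    for coef in ("alpha", "beta"):
        surf = fit.window_sum_credibility(coef)
        surf.to_csv(outdir / f"credibility_{coef}.csv")
        if cfg.make_plots:
            _plot_surface(surf, outdir / f"credibility_{coef}.png")
    ve = fit.variance_explained()
    (outdir / "variance_explained.json").write_text(json.dumps(
        {**ve, "seed": cfg.seed, "config_hash": cfg.hash()}, indent=1))
    return {"event_fit": fit}


def _stage_compare(cfg: RunConfig, data: dict, outdir: Path) -> dict:
    flexible = data["event_fit"].loo_lpd()
    windows = evaluate_candidate_windows(
        data["events"], data["climate"], data["t0"], data["T"],
        step=cfg.window_step, loo_mode=cfg.loo_mode,
    )
    report = compare_models(flexible["total_lpd"], windows)
    report["table"].to_csv(outdir / "comparison_table.csv", index=False)
    slim = {k: v for k, v in report.items() if k != "table"}
    slim.update({"seed": cfg.seed, "config_hash": cfg.hash()})
    (outdir / "comparison.json").write_text(json.dumps(slim, indent=1, default=str))
    return {"comparison": report}


def _stage_report(cfg: RunConfig, data: dict, outdir: Path) -> dict:
    lines = [data["trajectory_fit"].summary(), "", data["event_fit"].summary(), ""]
    cmp_ = data["comparison"]
    lines.append(
        f"LOO-CV comparison: flexible {cmp_['flexible_lpd']:.1f} vs best window "
        f"{cmp_['best_window']} at {cmp_['best_window_lpd']:.1f} "
        f"(delta {cmp_['delta_lpd']:+.1f}; "
        f"{'flexible' if cmp_['flexible_preferred'] else 'window LMM'} preferred)"
    )
    (outdir / "report.txt").write_text("\n".join(lines))
    return {}


def _plot_trajectory(fit, snow, outdir: Path) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        q = fit.w_quantiles()
        for i in range(fit.u_mean.shape[0]):
            axes[0].plot(fit.lags, fit.u_mean[i], color="gray", lw=0.7)
        axes[0].plot(q["lag"], q["q50"], "r-", lw=2)
        axes[0].plot(q["lag"], q["q5"], "r--", q["lag"], q["q95"], "r--")
        axes[0].set(xlabel="lag (days)", ylabel="temperature (°C)",
                    title="event-aligned temperature")
        for i in range(snow.smoothed.shape[0]):
            axes[1].plot(snow.lags, snow.smoothed[i], color="gray", lw=0.7)
        axes[1].plot(snow.lags, snow.global_mean, "r-", lw=2)
        axes[1].set(xlabel="lag (days)", ylabel="snow depth (cm)",
                    title="event-aligned snow depth")
        fig.tight_layout()
        fig.savefig(outdir / "trajectories.png", dpi=110)
        plt.close(fig)
    except Exception as exc:  # plots never gate the pipeline
        log.warning("trajectory plot failed: %s", exc)


def _plot_surface(surf, path: Path) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(surf.matrix, origin="upper", cmap="RdBu_r", vmin=0, vmax=1,
                       extent=[surf.grid[0], surf.grid[-1], surf.grid[-1], surf.grid[0]])
        ax.set(xlabel="t2 (day of year)", ylabel="t1 (day of year)",
               title=f"P(sum {surf.coefficient} >= 0)")
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        fig.savefig(path, dpi=110)
        plt.close(fig)
    except Exception as exc:
        log.warning("surface plot failed: %s", exc)


_STAGES = [
    ("data", None),   # simulate or ingest, chosen at run time
    ("trajectory", _stage_trajectory),
    ("event_model", _stage_event_model),
    ("compare", _stage_compare),
    ("report", _stage_report),
]


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; returns the run directory.

    Deterministic given (config, seed).  The manifest lists per-stage
    status and wall time; a stage failure stops downstream stages and
    raises :class:`StageError` after the manifest is written.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "config_hash": config.hash(),
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    data: dict = {}
    failed = None
    for name, func in _STAGES:
        start = time.perf_counter()
        try:
            if name == "data":
                stage_out = (_stage_simulate(config, outdir) if config.scenario is not None
                             else _stage_ingest(config, outdir))
            else:
                stage_out = func(config, data, outdir)
            data.update(stage_out)
            manifest["stages"][name] = {
                "status": "complete",
                "wall_time_s": round(time.perf_counter() - start, 3),
            }
        except Exception as exc:
            manifest["stages"][name] = {
                "status": "failed", "error": str(exc),
                "wall_time_s": round(time.perf_counter() - start, 3),
            }
            failed = (name, exc)
            log.error("stage %s failed: %s", name, exc)
            break
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    if failed:
        raise StageError(f"stage {failed[0]} failed: {failed[1]}") from failed[1]
    return outdir
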