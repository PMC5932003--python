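"""Declarative pipeline: calibrate -> agemodel -> accumulate -> proxies ->
pca -> changepoint.

One YAML config drives the whole analysis; a single seed feeds named
sub-streams per stage, so reruns with identical (inputs, config, seed) are
bit-reproducible regardless of the output directory.  Every output CSV
carries ``#`` header comments with the stage name, seed and config hash;
``manifest.json`` records inputs, outputs and stage order.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accumulation import (
    McErrorModel,
    car_series,
    dust_flux_series,
    elemental_mar,
    par_series,
)
from .agemodel import fit_age_depth, flag_outliers, sedimentation_rates
from .calibrate import calibrate, hpd_ranges
from .changepoint import ChangepointPriors, McmcSettings, SeriesData, run_changepoint
from .curves import load_calibration_curve
from .errors import ConfigError
from .geochem import builtin_reference, eu_anomaly, ree_ratio
from .io import load_core_csv, load_dates_csv, write_table
from .omquality import build_om_matrix, pca_correlation

__all__ = ["RunConfig", "run_pipeline", "DEFAULT_CONFIG"]

_STAGES = ("calibrate", "agemodel", "accumulate", "proxies", "pca", "changepoint")

DEFAULT_CONFIG: dict = {
    "seed": None,
    "paths": {"core": None, "dates": None, "curve": None, "out_dir": "peatflux_out"},
    "stages": {s: True for s in _STAGES},
    "calibrate": {"level": 0.95, "grid_step": 1.0},
    "agemodel": {
        "smoothing": 0.3,
        "iterations": 1000,
        "grid_step_cm": 1.0,
        "screen_outliers": True,
    },
    "accumulate": {"n_draws": 100_000, "elements": ["Al"], "conc_rel_sd_fallback": 0.10},
    "proxies": {"reference": "ucc_mclennan2001", "replicate_rsd": 0.13},
    "pca": {"n_components": 2},
    "changepoint": {
        "series": "par_median",
        "n_iter": 100_000,
        "burn_in": 20_000,
        "thin": 10,
        "k_max": 20,
    },
}


class RunConfig:
    """Validated pipeline configuration (defaults merged in)."""

    def __init__(self, raw: dict):
        cfg = _deep_merge(DEFAULT_CONFIG, raw or {})
        unknown = set(cfg) - set(DEFAULT_CONFIG)
        if unknown:
            raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
        for sec in _STAGES:
            extra = set(cfg[sec]) - set(DEFAULT_CONFIG[sec])
            if extra:
                raise ConfigError(f"{sec}: unknown option(s) {sorted(extra)}")
        enabled = [s for s in _STAGES if cfg["stages"].get(s)]
        stochastic = {"agemodel", "accumulate", "changepoint"}
        if stochastic & set(enabled) and cfg["seed"] is None:
            raise ConfigError("seed: required when a stochastic stage is enabled")
        for key in ("dates", "curve"):
            if cfg["paths"][key] is None and (
                "calibrate" in enabled or "agemodel" in enabled
            ):
                raise ConfigError(f"paths.{key}: required")
            if cfg["paths"][key] is not None and not Path(cfg["paths"][key]).exists():
                raise ConfigError(f"paths.{key}: file not found: {cfg['paths'][key]}")
        needs_core = {"accumulate", "proxies", "pca"} & set(enabled)
        if needs_core:
            if cfg["paths"]["core"] is None:
                raise ConfigError("paths.core: required")
            if not Path(cfg["paths"]["core"]).exists():
                raise ConfigError(f"paths.core: file not found: {cfg['paths']['core']}")
        self.cfg = cfg
        self.enabled = enabled

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    @property
    def hash(self) -> str:
        blob = json.dumps(
            {k: v for k, v in self.cfg.items() if k != "paths"}, sort_keys=True
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _deep_merge(base: dict, override: dict) -> dict:
    out = {}
    for k, v in base.items():
        if isinstance(v, dict):
            out[k] = _deep_merge(v, override.get(k, {}) or {})
        else:
            out[k] = override.get(k, v)
    for k in override:
        if k not in base:
            out[k] = override[k]
    return out


def run_pipeline(config: RunConfig | dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run the enabled stages in dependency order; return the manifest."""
    if isinstance(config, (str, Path)):
        config = RunConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = RunConfig(config)
    cfg = config.cfg
    seed = cfg["seed"] if cfg["seed"] is not None else 0
    out = Path(out_dir or cfg["paths"]["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    header = [
        f"peatflux {__version__}",
        f"config_hash {config.hash}",
        f"seed {seed}",
    ]
    manifest: dict = {
        "config_hash": config.hash,
        "seed": seed,
        "version": __version__,
        "inputs": {k: v for k, v in cfg["paths"].items() if v and k != "out_dir"},
        "stages": [],
        "outputs": [],
    }

    def record(stage: str, files: list[Path]) -> None:
        manifest["stages"].append(stage)
        manifest["outputs"].extend(str(f.name) for f in files)

    curve = dates = None
    if cfg["paths"]["curve"]:
        curve = load_calibration_curve(cfg["paths"]["curve"])
    if cfg["paths"]["dates"]:
        dates = load_dates_csv(cfg["paths"]["dates"])
    profile = core_df = None
    if cfg["paths"]["core"]:
        profile, core_df = load_core_csv(cfg["paths"]["core"])

    model = None
    slice_age_mid = slice_age_edges = None
    par = None

    if "calibrate" in config.enabled:
        rows = []
        for d in dates:
            dist = calibrate(d, curve, grid_step=cfg["calibrate"]["grid_step"])
            intervals, env = hpd_ranges(dist, cfg["calibrate"]["level"])
            rows.append(
                {
                    "lab_id": d.lab_id,
                    "depth_cm": d.depth,
                    "c14_age": d.c14_age,
                    "c14_error": d.c14_error,
                    "cal_min": round(env[0]),
                    "cal_max": round(env[1]),
                    "n_intervals": len(intervals),
                    "mean_cal_age": dist.mean(),
                }
            )
        f = out / "calibrated.csv"
        write_table(pd.DataFrame(rows), f, header + ["stage calibrate"])
        record("calibrate", [f])

    if "agemodel" in config.enabled:
        am = cfg["agemodel"]
        retained = list(dates)
        flagged: list[str] = []
        if am["screen_outliers"]:
            flagged = flag_outliers(
                dates,
                curve,
                seed=seed,
                smoothing_parameter=am["smoothing"],
                n_iterations=max(200, am["iterations"] // 5),
            )
            retained = [d for d in dates if d.lab_id not in flagged]
        depth_grid = None
        if profile is not None:
            depth_grid = profile.depth_edges
        model = fit_age_depth(
            retained,
            curve,
            smoothing_parameter=am["smoothing"],
            n_iterations=am["iterations"],
            grid_step_cm=am["grid_step_cm"],
            seed=seed,
            depth_grid=depth_grid,
        )
        df = pd.DataFrame(
            {
                "depth_cm": model.depth_grid,
                "age_point": model.point_estimate,
                "age_low": model.envelope_low,
                "age_high": model.envelope_high,
            }
        )
        f = out / "agemodel.csv"
        write_table(
            df,
            f,
            header
            + [
                "stage agemodel",
                f"flagged_outliers {','.join(flagged) or 'none'}",
                f"accepted {model.n_accepted}/{model.n_proposed}",
            ],
        )
        record("agemodel", [f])

    if profile is not None and model is not None:
        slice_age_edges = model.age_at(profile.depth_edges)
        slice_age_mid = model.age_at(profile.depth_mid)

    if "accumulate" in config.enabled:
        if model is None:
            raise ConfigError("stages.accumulate: requires the agemodel stage")
        ac = cfg["accumulate"]
        err = McErrorModel(
            n_draws=ac["n_draws"], conc_rel_sd_fallback=ac["conc_rel_sd_fallback"]
        )
        rates = sedimentation_rates(model)
        srates = rates["point"]
        par = par_series(profile, srates, err, seed=seed, midpoint_age=slice_age_mid)
        cols = {
            "depth_mid_cm": profile.depth_mid,
            "age_mid": slice_age_mid,
            "sed_rate_cm_yr": srates,
            "par": par.deterministic,
            "par_median": par.mc_median,
            "par_q25": par.mc_q25,
            "par_q75": par.mc_q75,
        }
        c_pct = profile.column("c_pct")
        if np.all(np.isfinite(c_pct)):
            car = car_series(par, c_pct)
            cols.update(
                car=car.deterministic,
                car_median=car.mc_median,
                car_q25=car.mc_q25,
                car_q75=car.mc_q75,
            )
        for el in ac["elements"]:
            mar = elemental_mar(
                profile, srates, el, err, seed=seed, midpoint_age=slice_age_mid
            )
            cols[f"{el}_mar"] = mar.deterministic
            cols[f"{el}_mar_median"] = mar.mc_median
            cols[f"{el}_mar_q25"] = mar.mc_q25
            cols[f"{el}_mar_q75"] = mar.mc_q75
            if el == "Al":
                dust = dust_flux_series(mar)
                cols["dust_flux"] = dust.deterministic
        f = out / "rates.csv"
        write_table(pd.DataFrame(cols), f, header + ["stage accumulate"])
        record("accumulate", [f])

    if "proxies" in config.enabled:
        ref = builtin_reference(cfg["proxies"]["reference"])
        rsd = cfg["proxies"]["replicate_rsd"]
        sample = {el: profile.concentration(el) for el in ("La", "Sm", "Eu", "Gd", "Lu")}
        la_lu = ree_ratio(sample, "La", "Lu", ref)
        gd_lu = ree_ratio(sample, "Gd", "Lu", ref)
        eu = eu_anomaly(sample["Eu"], sample["Sm"], sample["Gd"], ref)
        df = pd.DataFrame(
            {
                "depth_mid_cm": profile.depth_mid,
                "age_mid": slice_age_mid
                if slice_age_mid is not None
                else profile.depth_mid,
                "la_lu_ucc": la_lu,
                "la_lu_err": la_lu * rsd,
                "gd_lu_ucc": gd_lu,
                "gd_lu_err": gd_lu * rsd,
                "eu_anomaly_ucc": eu,
                "eu_anomaly_err": eu * rsd,
            }
        )
        f = out / "proxies.csv"
        write_table(df, f, header + ["stage proxies", f"reference {ref.name}"])
        record("proxies", [f])

    if "pca" in config.enabled:
        age = (
            slice_age_mid if slice_age_mid is not None else profile.depth_mid
        )
        matrix = build_om_matrix(
            age=age,
            c_pct=core_df["C_pct"].to_numpy(),
            n_pct=core_df["N_pct"].to_numpy(),
            d13c=core_df["d13C_permil"].to_numpy(),
            d15n=core_df["d15N_permil"].to_numpy(),
            dph=core_df["DPH_abs"].to_numpy(),
            ftir_1040=core_df["ftir_1040"].to_numpy(),
            ftir_1650=core_df["ftir_1650"].to_numpy(),
            ftir_2920=core_df["ftir_2920"].to_numpy(),
        )
        res = pca_correlation(matrix)
        f1 = out / "loadings.csv"
        write_table(
            res.loadings.reset_index(names="variable"), f1, header + ["stage pca"]
        )
        f2 = out / "scores.csv"
        write_table(
            pd.DataFrame(
                res.scores[:, : cfg["pca"]["n_components"]],
                columns=[f"Cp{i+1}" for i in range(cfg["pca"]["n_components"])],
            ).assign(age=age),
            f2,
            header + ["stage pca"],
        )
        f3 = out / "variance.json"
        f3.write_text(
            json.dumps(
                {
                    "eigenvalues": res.eigenvalues.tolist(),
                    "explained_variance": res.explained_variance.tolist(),
                },
                indent=1,
            )
        )
        record("pca", [f1, f2, f3])

    if "changepoint" in config.enabled:
        cp = cfg["changepoint"]
        series_name = cp["series"]
        if series_name in ("par_median", "par") and par is not None:
            t = par.midpoint_age
            y = par.mc_median if series_name == "par_median" else par.deterministic
        else:
            rates_df = pd.read_csv(out / "rates.csv", comment="#")
            if series_name not in rates_df.columns:
                raise ConfigError(
                    f"changepoint.series: column {series_name!r} not in rates.csv"
                )
            t = rates_df["age_mid"].to_numpy()
            y = rates_df[series_name].to_numpy()
        post = run_changepoint(
            SeriesData(t, y),
            ChangepointPriors(k_max=cp["k_max"]),
            McmcSettings(n_iter=cp["n_iter"], burn_in=cp["burn_in"], thin=cp["thin"]),
            seed=seed,
        )
        f1 = out / "k_posterior.csv"
        write_table(
            pd.DataFrame(
                {"k": np.arange(post.k_posterior.size), "prob": post.k_posterior}
            ),
            f1,
            header + ["stage changepoint", f"series {series_name}"],
        )
        f2 = out / "location_density.csv"
        mids = 0.5 * (post.location_bins[:-1] + post.location_bins[1:])
        write_table(
            pd.DataFrame({"t": mids, "mass": post.location_density}),
            f2,
            header + ["stage changepoint"],
        )
        f3 = out / "mean_curve.csv"
        write_table(
            pd.DataFrame(
                {
                    "t": post.grid,
                    "mean": post.mean_curve,
                    "ci_low": post.ci_low,
                    "ci_high": post.ci_high,
                }
            ),
            f3,
            header + ["stage changepoint"],
        )
        record("changepoint", [f1, f2, f3])

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
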