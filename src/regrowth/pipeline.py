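"""Config-driven end-to-end orchestration.

Runs the stages simulate -> select-model -> fit -> hindcast/validate ->
forecast -> ratio in dependency order from a single JSON config, writing
every artifact (CSV/JSON) under one output directory together with a
manifest of SHA-256 content hashes. All randomness derives from the single
master seed in the config, so a rerun with the same config reproduces the
manifest hashes bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import growth, hbmodel, inventory, projection, spatial, synthetic

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("regrowth.pipeline")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run (JSON-serializable)."""

    output_dir: str
    seed: int = 0
    plots_path: str | None = None
    scenario_climate_path: str | None = None
    generator: synthetic.GeneratorConfig | None = None
    prior_variant: str = "flat"
    chains: int = 5
    iterations: int = 10_000
    burn_in: int | None = None
    scenarios: list[str] = field(default_factory=lambda: ["RCP4.5", "RCP8.5"])
    periods: list[str] = field(default_factory=lambda: ["2020s", "2050s", "2080s"])
    grid_resolution_arcmin: float = 10.0
    cv_train_frac: float = 0.75
    run_cv: bool = True
    run_forecast: bool = True
    ratio_numerator: str = "observed"  # or "modelled"

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if raw.get("generator") is not None:
            raw["generator"] = synthetic.GeneratorConfig.from_dict(raw["generator"])
        return cls(**raw)

    def to_json(self, path) -> None:
        raw = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(raw, fh, indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kw):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kw)
            except Exception as exc:  # noqa: BLE001 - annotate with stage name
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


@_stage("simulate")
def _simulate(cfg: RunConfig, outdir: Path, artifacts: list[Path]):
    gen = cfg.generator
    plots, params = synthetic.generate_dataset(gen)
    plots_path = outdir / "plots.csv"
    inventory.write_plot_table(plots, plots_path)
    artifacts.append(plots_path)
    tp_path = outdir / "true_params.csv"
    synthetic.true_params_frame(params).to_csv(tp_path, index=False)
    artifacts.append(tp_path)
    scen_frames = []
    for scenario in cfg.scenarios:
        for period in cfg.periods:
            if f"{scenario}/{period}" in gen.future_delta:
                scen_frames.append(
                    synthetic.generate_future_climate(plots, gen, scenario, period)
                )
    scen_path = None
    if scen_frames:
        scen_path = outdir / "scenario_climate.csv"
        pd.concat(scen_frames, ignore_index=True).to_csv(scen_path, index=False)
        artifacts.append(scen_path)
    return plots, scen_path


@_stage("select-model")
def _select_model(plots: pd.DataFrame, outdir: Path, artifacts: list[Path]):
    table = growth.select_by_type(plots.loc[plots["period"] == "current"])
    path = outdir / "model_selection.csv"
    table.to_csv(path, index=False)
    artifacts.append(path)
    return table


@_stage("fit")
def _fit(cfg: RunConfig, plots: pd.DataFrame, outdir: Path, artifacts: list[Path]):
    prior = hbmodel.PriorSpec(variant=cfg.prior_variant)
    fits = hbmodel.fit_all_types(
        plots, prior=prior, chains=cfg.chains, iterations=cfg.iterations,
        burn_in=cfg.burn_in, seed=cfg.seed,
    )
    draws_dir = outdir / "draws"
    draws_dir.mkdir(exist_ok=True)
    summaries = []
    geweke_rows = []
    for ftype, d in sorted(fits.items()):
        p = draws_dir / f"{ftype}.csv"
        d.to_frame().to_csv(p, index=False)
        artifacts.append(p)
        s = hbmodel.summarize_posterior(d)
        s.insert(0, "forest_type", ftype)
        summaries.append(s)
        g = hbmodel.geweke_table(d)
        g.insert(0, "forest_type", ftype)
        geweke_rows.append(g)
        if not g["passed"].all():
            log.warning("Geweke |z| >= 2 for %s", ftype)
    for name, frames in (("posterior_summary.csv", summaries), ("geweke.csv", geweke_rows)):
        path = outdir / name
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        artifacts.append(path)
    return fits


@_stage("hindcast")
def _hindcast(plots, fits, outdir: Path, artifacts: list[Path]):
    past = plots.loc[plots["period"] == "past"]
    if past.empty:
        return None
    pred = projection.hindcast(past, fits)
    path = outdir / "hindcast_pred.csv"
    pred.to_csv(path, index=False)
    artifacts.append(path)
    return pred


@_stage("validate")
def _validate(cfg: RunConfig, plots, outdir: Path, artifacts: list[Path]):
    current = plots.loc[plots["period"] == "current"]
    cv = spatial.spatial_cv(
        current, train_frac=cfg.cv_train_frac, seed=cfg.seed,
        chains=max(2, cfg.chains // 2), iterations=max(2000, cfg.iterations // 2),
        resolution_arcmin=cfg.grid_resolution_arcmin,
    )
    grid_path = outdir / "cv_grid.csv"
    cv.grid.to_csv(grid_path, index=False)
    artifacts.append(grid_path)
    report = {
        "r": cv.ttest.r,
        "n_cells": cv.ttest.n_cells,
        "effective_n": cv.ttest.effective_n,
        "t_stat": cv.ttest.t_stat,
        "p_value": cv.ttest.p_value,
        "n_train": int(cv.train_idx.size),
        "n_test": int(cv.test_idx.size),
        "excluded_types": cv.excluded_types,
    }
    path = outdir / "cv_report.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
    artifacts.append(path)
    return report


@_stage("forecast")
def _forecast(cfg: RunConfig, plots, fits, scen: pd.DataFrame, outdir: Path,
              artifacts: list[Path]):
    current = plots.loc[plots["period"] == "current"]
    out = {}
    for scenario in cfg.scenarios:
        for period in cfg.periods:
            mask = (scen["scenario"] == scenario) & (scen["period"] == period)
            if not mask.any():
                continue
            pred = projection.forecast(current, fits, scen, scenario, period)
            key = f"{scenario}_{period}".replace(".", "")
            path = outdir / f"forecast_{key}.csv"
            pred.to_csv(path, index=False)
            artifacts.append(path)
            out[(scenario, period)] = pred
    return out


@_stage("ratio")
def _ratio(cfg: RunConfig, plots, in_sample, forecasts, outdir: Path,
           artifacts: list[Path]):
    current = plots.loc[plots["period"] == "current"]
    numerator = in_sample if cfg.ratio_numerator == "modelled" else current
    summary = {}
    for (scenario, period), pred in forecasts.items():
        res = projection.saturation_ratio(numerator, pred)
        key = f"{scenario}_{period}".replace(".", "")
        path = outdir / f"ratio_{key}.csv"
        res.per_plot.to_csv(path, index=False)
        artifacts.append(path)
        summary[key] = {
            "mean": res.mean, "sd": res.sd, **res.quantiles,
            "n": int(len(res.per_plot)), "n_excluded": res.n_excluded,
        }
    path = outdir / "ratio_summary.json"
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
    artifacts.append(path)
    return summary


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns the artifact manifest.

    The manifest maps artifact paths (relative to the output directory) to
    SHA-256 content hashes and is itself written as ``manifest.json``.
    Stage failures raise :class:`PipelineError` naming the stage; artifacts
    written before the failure are retained for debugging.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    if config.generator is not None:
        plots, scen_path = _simulate(config, outdir, artifacts)
    elif config.plots_path:
        plots = inventory.read_plot_table(config.plots_path)
        scen_path = config.scenario_climate_path
    else:
        raise PipelineError("stage 'input' failed: config needs generator or plots_path")
    plots = inventory.filter_undisturbed(plots)
    current = plots.loc[plots["period"] == "current"]

    _select_model(plots, outdir, artifacts)
    fits = _fit(config, current, outdir, artifacts)

    in_sample = projection.point_predict(
        current,
        {ft: d.posterior_mean_params() for ft, d in fits.items()},
    )
    in_path = outdir / "in_sample_pred.csv"
    in_sample.to_csv(in_path, index=False)
    artifacts.append(in_path)

    _hindcast(plots, fits, outdir, artifacts)
    if config.run_cv:
        _validate(config, plots, outdir, artifacts)

    if config.run_forecast:
        if scen_path is None:
            raise PipelineError(
                "stage 'forecast' failed: no scenario climate table "
                "(scenario_climate_path missing and generator produced none)"
            )
        scen = pd.read_csv(scen_path)
        forecasts = _forecast(config, plots, fits, scen, outdir, artifacts)
        _ratio(config, plots, in_sample, forecasts, outdir, artifacts)

    manifest = {
        str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(artifacts))
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
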