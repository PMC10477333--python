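"""End-to-end orchestration: generate -> calibrate -> impute -> simulate ->
counterfactual -> estimate -> map, with cached intermediates and provenance.

Every stage is a pure function of the run configuration and the master
seed's named substreams, so re-running any stage from cached upstream
intermediates reproduces its outputs exactly; output files carry the config
hash in a leading comment line and a run log records per-stage seeds and
counts.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calibration, counterfactual, estimation, imputation, mapping, soc_model, synthetic
from .config import AdoptionCurves, RunConfig

log = logging.getLogger("cropcarb")


@dataclass
class RunState:
    """In-memory bundle of stage outputs."""

    config: RunConfig
    frame: synthetic.SurveyFrame | None = None
    weather: synthetic.WeatherSet | None = None
    truth: pd.DataFrame | None = None
    donors: pd.DataFrame | None = None
    calibration_sites: pd.DataFrame | None = None
    bias_model: calibration.BiasModel | None = None
    sensitivity: pd.DataFrame | None = None
    imputations: list[imputation.ImputationSet] = field(default_factory=list)
    effect_tables: list[counterfactual.EffectTable] = field(default_factory=list)
    national: pd.DataFrame | None = None
    residual: pd.DataFrame | None = None
    grids: dict[str, mapping.EffectGrid] = field(default_factory=dict)


def _write_csv(df: pd.DataFrame, path: str, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {cfg_hash}\n")
        df.to_csv(fh, index=False)


def stage_generate(state: RunState) -> RunState:
    cfg = state.config
    log.info("generate: n=%d area=%.3g seed=%d", cfg.n_locations, cfg.total_area_ha, cfg.master_seed)
    state.frame = synthetic.generate_frame(
        cfg.n_locations, domain=cfg.domain_km, total_area=cfg.total_area_ha,
        n_replicates=cfg.n_replicates, n_regions=cfg.n_regions, seed=cfg.master_seed,
    )
    state.weather = synthetic.generate_weather(state.frame, seed=cfg.master_seed)
    curves = AdoptionCurves(cfg.adoption)
    state.truth = synthetic.generate_truth_histories(state.frame, curves, seed=cfg.master_seed)
    state.donors = synthetic.generate_donors(state.frame, state.truth, cfg.n_donors, seed=cfg.master_seed)
    return state


def stage_calibrate(state: RunState) -> RunState:
    cfg = state.config
    params = soc_model.ModelParams(**cfg.model_params)
    state.calibration_sites = synthetic.generate_calibration_sites(
        cfg.n_calibration_sites,
        bias_slope=cfg.bias_slope, bias_intercept=cfg.bias_intercept,
        re_sd=cfg.bias_re_sd, resid_sd=cfg.bias_resid_sd,
        params=params, seed=cfg.master_seed,
    )
    state.bias_model = calibration.fit_bias_model(state.calibration_sites)

    # sensitivity screen of the surrogate's equilibrium SOC to its main knobs
    ranges = {
        "k_active": (3.0, 12.0),
        "k_slow": (0.1, 0.4),
        "k_passive": (0.002, 0.008),
        "q10": (1.5, 2.5),
        "till_ft": (1.1, 1.5),
        "dummy": (0.0, 1.0),
    }

    def model_fn(X):
        out = np.empty(X.shape[0])
        for i, row in enumerate(X):
            p = soc_model.ModelParams(
                k_active=row[0], k_slow=row[1], k_passive=row[2], q10=row[3],
                till_mult={"NT": 1.0, "RT": (1.0 + row[4]) / 2, "FT": row[4]},
            )
            out[i] = soc_model.solve_equilibrium(p, (12.0, 0.5, "FT"), 3.2, 0.2).sum()
        return out

    res = calibration.sobol_total_indices(model_fn, ranges, n_base=128, seed=cfg.master_seed)
    state.sensitivity = calibration.sensitivity_table(res)
    return state


def stage_impute(state: RunState) -> RunState:
    cfg = state.config
    state.imputations = imputation.build_imputations(
        state.frame, state.donors, state.truth,
        M=cfg.n_imputations, seed=cfg.master_seed,
        termination=cfg.termination_variant,
    )
    return state


def stage_counterfactual(state: RunState) -> RunState:
    cfg = state.config
    params = soc_model.ModelParams(**cfg.model_params)
    state.effect_tables = []
    for imp in state.imputations:
        log.info("counterfactual: imputation %d", imp.imputation_id)
        table = counterfactual.run_all_scenarios(
            state.frame, imp.histories, params, state.weather,
            seed=cfg.master_seed + imp.imputation_id,
            scenarios=cfg.scenarios,
            termination_primary=cfg.termination_variant,
        )
        state.effect_tables.append(table)
    return state


def stage_estimate(state: RunState) -> RunState:
    cfg = state.config
    bias = state.bias_model or calibration.BiasModel.identity()
    state.national, state.residual = estimation.summarize_national(
        state.effect_tables,
        [imp.histories for imp in state.imputations],
        bias, state.frame,
        n_iter=cfg.n_iterations, seed=cfg.master_seed,
    )
    return state


def stage_map(state: RunState) -> RunState:
    cfg = state.config
    effects_long = pd.concat(
        [t.to_frame().assign(imputation=i) for i, t in enumerate(state.effect_tables)],
        ignore_index=True,
    )
    mean_effects = (
        effects_long.groupby(["scenario", "location_id", "year"], as_index=False)["effect"].mean()
    )
    spec = mapping.GridSpec.covering(
        state.frame.table["x_km"].to_numpy(), state.frame.table["y_km"].to_numpy(),
        cell_size=cfg.grid_cell_km,
    )
    state.grids = {}
    for scen in mean_effects["scenario"].unique():
        if scen == "TOTAL":
            continue
        pts = mapping.average_effect_map(mean_effects, state.frame, scen)
        state.grids[scen] = mapping.idw_interpolate(
            pts, spec, radius_km=cfg.idw_radius_km,
            min_points=cfg.idw_min_points, power=cfg.idw_power, scenario=scen,
        )
    return state


_STAGES = {
    "generate": stage_generate,
    "calibrate": stage_calibrate,
    "impute": stage_impute,
    "counterfactual": stage_counterfactual,
    "estimate": stage_estimate,
    "map": stage_map,
}
STAGE_ORDER = ("generate", "calibrate", "impute", "counterfactual", "estimate", "map")


def run(config: RunConfig, output_dir: str | None = None, stages=STAGE_ORDER) -> RunState:
    """Execute the pipeline stages in order and write the output bundle."""
    state = RunState(config=config)
    for name in stages:
        try:
            state = _STAGES[name](state)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    outdir = output_dir or config.output_dir
    if outdir:
        write_outputs(state, outdir)
    return state


def write_outputs(state: RunState, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    h = state.config.config_hash()
    with open(os.path.join(outdir, "run_config.json"), "w") as fh:
        json.dump({"config": state.config.to_dict(), "config_hash": h}, fh, indent=2)
    if state.frame is not None:
        _write_csv(state.frame.table, os.path.join(outdir, "survey_frame.csv"), h)
    if state.truth is not None:
        _write_csv(state.truth, os.path.join(outdir, "truth_histories.csv"), h)
    if state.donors is not None:
        _write_csv(state.donors, os.path.join(outdir, "donors.csv"), h)
    if state.sensitivity is not None:
        _write_csv(state.sensitivity, os.path.join(outdir, "sensitivity.csv"), h)
    if state.bias_model is not None:
        with open(os.path.join(outdir, "bias_model.json"), "w") as fh:
            json.dump({"config_hash": h, **state.bias_model.to_dict()}, fh, indent=2)
    for imp in state.imputations:
        _write_csv(imp.histories, os.path.join(outdir, f"imputation_{imp.imputation_id}.csv"), h)
    if state.effect_tables:
        eff = pd.concat(
            [t.to_frame().assign(imputation=i + 1) for i, t in enumerate(state.effect_tables)],
            ignore_index=True,
        )
        _write_csv(eff, os.path.join(outdir, "practice_effects.csv"), h)
    if state.national is not None:
        _write_csv(state.national, os.path.join(outdir, "national_series.csv"), h)
    if state.residual is not None:
        _write_csv(state.residual, os.path.join(outdir, "residual_series.csv"), h)
    for scen, grid in state.grids.items():
        safe = scen.replace("@", "_")
        mapping.write_asc(grid, os.path.join(outdir, f"effect_map_{safe}.asc"))
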