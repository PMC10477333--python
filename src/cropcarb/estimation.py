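"""National estimation: survey-weighted totals, replicate-weight variance,
practice areas and rates, and three-source Monte Carlo uncertainty.

Per-location annual effects (t C ha^-1 yr^-1) scale to national totals
(Mt C yr^-1) through the expansion weights.  Uncertainty combines three
sources drawn independently each Monte Carlo iteration: which imputation
set's simulations are used, a fixed-effect draw (plus prediction-error
draws) from the empirical bias model, and which replicate-weight vector
scales locations to the nation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import BiasModel, draw_fixed_effects
from .config import REPORT_YEARS, substream
from .counterfactual import EffectTable
from .soc_model import c_to_co2e
from .synthetic import SurveyFrame, jackknife_variance

T_PER_MT = 1e6
HA_PER_MHA = 1e6


def weighted_total(effects: np.ndarray, weights: np.ndarray) -> float:
    """National total in Mt C yr^-1 from per-ha effects and ha weights."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    e = np.asarray(effects, dtype=float)
    return float(np.sum(e * w) / T_PER_MT)


def replicate_interval(estimator_fn, frame: SurveyFrame, level: float = 0.95):
    """Full-sample estimate with delete-a-group jackknife s.d. and normal CI.

    ``estimator_fn(weights) -> float`` is evaluated under the full weights
    and under each replicate-weight vector; replicates on which it fails are
    dropped (with a warning) and G adjusted.
    """
    from scipy.stats import norm

    if frame.n_replicates < 2:
        raise ValueError("need >= 2 replicate-weight vectors")
    full = float(estimator_fn(frame.weights))
    reps = []
    for g in range(frame.n_replicates):
        try:
            reps.append(float(estimator_fn(frame.replicate_weights[:, g])))
        except Exception:
            warnings.warn(f"estimator failed on replicate {g}; dropping it", stacklevel=2)
    if len(reps) < 2:
        raise RuntimeError("fewer than 2 usable replicates")
    var = jackknife_variance(full, np.array(reps))
    sd = float(np.sqrt(var))
    z = norm.ppf(0.5 + level / 2.0)
    return full, sd, (full - z * sd, full + z * sd)


_EXPOSURE = {
    "NO_COVER_CROP": lambda h: h["cover_crop"].to_numpy(dtype=bool),
    "FULL_TILLAGE": lambda h: h["tillage"].isin(["NT", "RT"]).to_numpy() & ~h["set_aside"].to_numpy(dtype=bool),
    "NO_HAY_PASTURE": lambda h: h["crop"].isin(["hay", "pasture"]).to_numpy(),
    "MANURE_TO_SYNTHETIC": lambda h: h["manure_n"].to_numpy() > 0,
    "SET_ASIDE_DIRECT": lambda h: h["set_aside"].to_numpy(dtype=bool),
}


def exposure_mask(histories: pd.DataFrame, scenario: str, year: int) -> pd.Series:
    """Boolean exposure per location for the practice a scenario eliminates."""
    base = scenario.split("@")[0]
    if base not in _EXPOSURE:
        raise ValueError(f"unknown scenario {scenario!r}")
    h = histories[histories["year"] == year]
    return pd.Series(_EXPOSURE[base](h), index=h["location_id"].to_numpy())


@dataclass
class AreaRate:
    area_mha: float
    rate: float
    defined: bool


def practice_area_and_rate(
    histories: pd.DataFrame,
    frame: SurveyFrame,
    scenario: str,
    year: int,
    effects: pd.DataFrame | None = None,
) -> AreaRate:
    """Exposed area (Mha) and per-area stock-change rate (t C ha^-1 yr^-1).

    rate = national effect total / exposed area; undefined (flagged, not
    zero) when no location is exposed.  ``effects`` is the long per-location
    effect table for the scenario-year; omitting it returns the area only
    (rate NaN, defined when area > 0).
    """
    mask = exposure_mask(histories, scenario, year)
    w = frame.table.set_index("location_id")["weight"].reindex(mask.index).to_numpy()
    area_ha = float(np.sum(w[mask.to_numpy()]))
    if area_ha <= 0:
        return AreaRate(area_mha=0.0, rate=float("nan"), defined=False)
    rate = float("nan")
    if effects is not None:
        sub = effects[effects["year"] == year].set_index("location_id")["effect"]
        sub = sub.reindex(mask.index).fillna(0.0)
        total_mt = weighted_total(sub.to_numpy(), w)
        rate = total_mt * T_PER_MT / area_ha
    return AreaRate(area_mha=area_ha / HA_PER_MHA, rate=rate, defined=True)


# ---------------------------------------------------------------------------
# Monte Carlo
# ---------------------------------------------------------------------------

@dataclass
class MCEstimate:
    """Summary of the Monte Carlo draws for every scenario-year."""

    table: pd.DataFrame  # scenario, year, mean, sd, ci_low, ci_high, n_iter


def run_monte_carlo(
    effect_tables: list[EffectTable],
    bias_model: BiasModel,
    frame: SurveyFrame,
    n_iter: int = 1000,
    seed: int = 0,
    use_replicates: bool = True,
    include_prediction_error: bool = True,
) -> MCEstimate:
    """Three-source Monte Carlo over cached per-imputation simulations.

    Each iteration draws, independently: an imputation set (uniform over M),
    a bias-model fixed-effect vector from Normal(beta, beta_cov) plus
    prediction-error draws, and one replicate-weight vector (uniform over G;
    the full-sample weights when ``use_replicates`` is off).  Prediction
    error is applied on the annual-stock scale and differenced into stock
    changes; the site and region random-effect components are persistent
    for a location and cancel in the differencing, so only the residual
    component contributes per-year noise.  With all three sources
    degenerate (M=1, zero covariance/variances, full weights) every
    iteration reproduces the deterministic estimate exactly.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    rng = substream(seed, "monte_carlo")
    M = len(effect_tables)
    scen_names = list(effect_tables[0].effects)
    years = effect_tables[0].years
    ny = years.size
    n = len(effect_tables[0].location_ids)
    G = frame.n_replicates
    pred_sd = bias_model.sigma_resid if include_prediction_error else 0.0
    slope_idx = bias_model.beta_names.index("simulated_soc")

    # cached effect stacks: (M, n, ny) per series
    stacks = {s: np.stack([t.effects[s] for t in effect_tables]) for s in scen_names}

    draws = np.empty((n_iter, len(scen_names), ny))
    w_full = frame.weights
    for it in range(n_iter):
        m = int(rng.integers(0, M))
        beta = draw_fixed_effects(bias_model, rng)
        slope = beta[slope_idx]
        if use_replicates and G > 0:
            g = int(rng.integers(0, G))
            w = frame.replicate_weights[:, g]
        else:
            w = w_full
        for si, s in enumerate(scen_names):
            eff = slope * stacks[s][m]
            if pred_sd > 0:
                # residual prediction error on annual stocks, differenced
                stock_eps = rng.normal(0.0, pred_sd, size=(n, ny + 1))
                eff = eff + np.diff(stock_eps, axis=1)
            draws[it, si] = (eff * w[:, None]).sum(axis=0) / T_PER_MT
    mean = draws.mean(axis=0)
    sd = draws.std(axis=0, ddof=1)
    # bit-identical draws (all sources degenerate) have exactly zero spread;
    # suppress the epsilon-level rounding noise of the mean subtraction
    constant = np.ptp(draws, axis=0) == 0.0
    sd[constant] = 0.0
    mean[constant] = draws[0][constant]
    lo = np.percentile(draws, 2.5, axis=0)
    hi = np.percentile(draws, 97.5, axis=0)
    rows = []
    for si, s in enumerate(scen_names):
        for yi, y in enumerate(years):
            rows.append(
                {
                    "scenario": s,
                    "year": int(y),
                    "mean": mean[si, yi],
                    "sd": sd[si, yi],
                    "ci_low": lo[si, yi],
                    "ci_high": hi[si, yi],
                    "n_iter": n_iter,
                }
            )
    return MCEstimate(table=pd.DataFrame(rows))


def deterministic_series(effect_tables: list[EffectTable], bias_model: BiasModel,
                         frame: SurveyFrame) -> pd.DataFrame:
    """Point-estimate national series: bias slope at its point value,
    full-sample weights, averaged over imputation sets."""
    scen_names = list(effect_tables[0].effects)
    years = effect_tables[0].years
    slope = bias_model.slope
    w = frame.weights
    rows = []
    for s in scen_names:
        eff = np.mean([t.effects[s] for t in effect_tables], axis=0) * slope
        tot = (eff * w[:, None]).sum(axis=0) / T_PER_MT
        for yi, y in enumerate(years):
            rows.append({"scenario": s, "year": int(y), "total_mt_c": tot[yi]})
    return pd.DataFrame(rows)


def summarize_national(
    effect_tables: list[EffectTable],
    imputation_histories: list[pd.DataFrame],
    bias_model: BiasModel,
    frame: SurveyFrame,
    n_iter: int = 1000,
    seed: int = 0,
    report_years: tuple[int, int] = REPORT_YEARS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the national tables: per-scenario-year totals with MC
    uncertainty, exposed areas, per-area rates, CO2-eq, and the residual
    all-other-management series (TOTAL minus the sum of practice effects;
    practice effects are not additive, so the residual is reported rather
    than forced to zero).
    """
    scen_names = list(effect_tables[0].effects)
    missing = [s for s in ("TOTAL",) if s not in scen_names]
    if missing:
        raise RuntimeError(f"incomplete scenario output: missing {missing}")
    mc = run_monte_carlo(effect_tables, bias_model, frame, n_iter=n_iter, seed=seed)
    det = deterministic_series(effect_tables, bias_model, frame)

    national = mc.table.merge(det, on=["scenario", "year"])
    # areas and rates from the first imputation set (area is survey-observed
    # for most practices and nearly identical across sets)
    hist0 = imputation_histories[0]
    area_rows = []
    years = sorted(national["year"].unique())
    for s in scen_names:
        if s == "TOTAL":
            continue
        eff0 = effect_tables[0]
        ny = eff0.years.size
        eff_long = pd.DataFrame(
            {
                "location_id": np.repeat(eff0.location_ids, ny),
                "year": np.tile(eff0.years, len(eff0.location_ids)),
                "effect": np.mean([t.effects[s] for t in effect_tables], axis=0).ravel(),
            }
        )
        for y in years:
            ar = practice_area_and_rate(hist0, frame, s, int(y), effects=eff_long)
            area_rows.append(
                {"scenario": s, "year": int(y), "area_mha": ar.area_mha,
                 "rate_t_c_ha_yr": ar.rate, "rate_defined": ar.defined}
            )
    areas = pd.DataFrame(area_rows)
    national = national.merge(areas, on=["scenario", "year"], how="left")
    national["co2e_mt"] = national["mean"].map(c_to_co2e)

    # residual: total minus sum of practice means (one termination variant)
    primary = [s for s in scen_names if s != "TOTAL" and not s.endswith("@tillage")]
    piv = national.pivot(index="year", columns="scenario", values="mean")
    resid = piv["TOTAL"] - piv[primary].sum(axis=1)
    residual = pd.DataFrame(
        {"scenario": "ALL_OTHER", "year": resid.index, "mean": resid.to_numpy()}
    )
    return national, residual
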