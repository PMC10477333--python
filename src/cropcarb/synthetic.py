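"""Synthetic survey world: frame, weights, weather, management truth, donors.

Generates every input the pipeline consumes, with the statistical structure
the downstream analysis assumes: a weighted area-survey frame with
delete-a-group jackknife replicate weights, daily weather with seasonal and
autocorrelated structure, per-location management histories whose weighted
national adoption follows configurable trend curves, donor surveys for
hot-deck / predictive-mean-matching imputation, and calibration sites with a
known, configurable model bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import (
    ANNUAL_CROPS,
    GRASS,
    SIM_YEARS,
    AdoptionCurves,
    default_climate,
    substream,
)

DAYS_PER_YEAR = 365  # simplified calendar; leap days ignored


# ---------------------------------------------------------------------------
# Survey frame
# ---------------------------------------------------------------------------

@dataclass
class SurveyFrame:
    """Area-survey frame: one row per location plus replicate weights.

    ``table`` columns: location_id, x_km, y_km, weight (ha), clay_frac,
    sand_frac, region_id.  ``replicate_weights`` is an (n, G) array of
    delete-a-group jackknife weight vectors.
    """

    table: pd.DataFrame
    replicate_weights: np.ndarray
    total_area: float

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def n_replicates(self) -> int:
        return self.replicate_weights.shape[1]

    @property
    def weights(self) -> np.ndarray:
        return self.table["weight"].to_numpy()


def generate_frame(
    n: int,
    domain: tuple[float, float] = (1000.0, 1000.0),
    total_area: float = 1e6,
    n_replicates: int = 30,
    n_regions: int = 4,
    seed: int = 0,
) -> SurveyFrame:
    """Generate a clustered survey frame with expansion and replicate weights.

    Locations are scattered around ``n_regions`` stratum centres on a planar
    km domain.  Expansion weights are lognormal, rescaled to sum exactly to
    ``total_area``.  Replicate weights implement the delete-a-group jackknife
    with balanced groups (locations dealt to groups in weight order, so each
    replicate total stays within a few percent of the full-sample total).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if total_area <= 0:
        raise ValueError("total_area must be positive")
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    rng = substream(seed, "frame")
    width, height = domain

    centers = rng.uniform([0.1 * width, 0.1 * height], [0.9 * width, 0.9 * height], size=(n_regions, 2))
    region = rng.integers(0, n_regions, size=n)
    xy = centers[region] + rng.normal(0.0, min(width, height) / 8.0, size=(n, 2))
    xy[:, 0] = np.clip(xy[:, 0], 0.0, width)
    xy[:, 1] = np.clip(xy[:, 1], 0.0, height)

    weight = rng.lognormal(mean=0.0, sigma=0.5, size=n)
    weight *= total_area / weight.sum()

    clay = 0.05 + 0.45 * rng.beta(2.0, 3.0, size=n)
    sand = (1.0 - clay) * rng.uniform(0.1, 0.9, size=n)

    G = int(n_replicates)
    # balanced delete-a-group assignment: deal locations to groups in
    # descending weight order so each group carries ~1/G of the total area
    order = np.argsort(-weight)
    group = np.empty(n, dtype=int)
    group[order] = np.arange(n) % G
    rep = np.repeat(weight[:, None], G, axis=1)
    for g in range(G):
        rep[group == g, g] = 0.0
    rep *= G / (G - 1)

    table = pd.DataFrame(
        {
            "location_id": [f"L{i:06d}" for i in range(n)],
            "x_km": xy[:, 0],
            "y_km": xy[:, 1],
            "weight": weight,
            "clay_frac": clay,
            "sand_frac": sand,
            "region_id": [f"R{r}" for r in region],
            "jk_group": group,
        }
    )
    return SurveyFrame(table=table, replicate_weights=rep, total_area=float(total_area))


def jackknife_variance(full_estimate: float, replicate_estimates: np.ndarray) -> float:
    """Delete-a-group jackknife variance: (G-1)/G * sum((theta_g - theta)^2)."""
    reps = np.asarray(replicate_estimates, dtype=float)
    G = reps.size
    return (G - 1) / G * float(np.sum((reps - full_estimate) ** 2))


# ---------------------------------------------------------------------------
# Weather
# ---------------------------------------------------------------------------

@dataclass
class WeatherSet:
    """Daily weather for every frame location over the simulation span.

    Arrays are (n_locations, n_days) on a 365-day calendar.  ``rel_water``
    is a [0, 1] soil-moisture proxy from a single-bucket water balance.
    ``tmean_clim`` / ``rel_water_clim`` are (n, 365) day-of-year
    climatologies used for the pre-survey base-history years.
    """

    years: tuple[int, int]
    location_ids: list[str]
    tmean: np.ndarray
    precip: np.ndarray
    rel_water: np.ndarray
    tmean_clim: np.ndarray
    rel_water_clim: np.ndarray

    @property
    def n_days(self) -> int:
        return self.tmean.shape[1]

    def year_slice(self, year: int) -> slice:
        i = year - self.years[0]
        return slice(i * DAYS_PER_YEAR, (i + 1) * DAYS_PER_YEAR)

    def to_frame(self) -> pd.DataFrame:
        y0 = self.years[0]
        n, d = self.tmean.shape
        years = y0 + np.arange(d) // DAYS_PER_YEAR
        doy = np.arange(d) % DAYS_PER_YEAR + 1
        return pd.DataFrame(
            {
                "location_id": np.repeat(self.location_ids, d),
                "year": np.tile(years, n),
                "doy": np.tile(doy, n),
                "tmean_c": self.tmean.ravel(),
                "precip_mm": self.precip.ravel(),
                "rel_water": self.rel_water.ravel(),
            }
        )


def generate_weather(
    frame: SurveyFrame,
    years: tuple[int, int] = SIM_YEARS,
    climate: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    ar1_rho: float = 0.7,
    temp_noise_sd: float = 3.0,
    bucket_capacity_mm: float = 100.0,
) -> WeatherSet:
    """Generate daily weather: sinusoidal seasonal cycle + AR(1) temperature
    noise, a two-state wet/dry occurrence chain with exponential rain
    intensities, and a bucket-model relative soil moisture."""
    y0, y1 = years
    if y1 < y0:
        raise ValueError("empty year span")
    n_years = y1 - y0 + 1
    D = n_years * DAYS_PER_YEAR
    n = frame.n
    regions = frame.table["region_id"].tolist()
    if climate is None:
        climate = default_climate(sorted(set(regions)))
    rng = substream(seed, "weather")

    mean_t = np.array([climate[r]["mean_temp_c"] for r in regions])
    amp = np.array([climate[r]["amplitude_c"] for r in regions])
    annual_p = np.array([climate[r]["annual_precip_mm"] for r in regions])

    doy = np.arange(D) % DAYS_PER_YEAR
    seasonal = mean_t[:, None] - amp[:, None] * np.cos(2 * np.pi * (doy[None, :] - 15) / DAYS_PER_YEAR)

    eps = rng.normal(0.0, temp_noise_sd * np.sqrt(1 - ar1_rho**2), size=(n, D))
    noise = lfilter([1.0], [1.0, -ar1_rho], eps, axis=1)
    tmean = seasonal + noise

    # precipitation occurrence: two-state chain with stationary wet prob 0.3
    pi_wet, p11 = 0.3, 0.6
    p01 = pi_wet * (1 - p11) / (1 - pi_wet)
    mean_intensity = annual_p / (DAYS_PER_YEAR * pi_wet)
    wet = np.zeros((n, D), dtype=bool)
    u = rng.random(size=(n, D))
    wet[:, 0] = u[:, 0] < pi_wet
    for d in range(1, D):
        wet[:, d] = u[:, d] < np.where(wet[:, d - 1], p11, p01)
    precip = np.where(wet, rng.exponential(1.0, size=(n, D)) * mean_intensity[:, None], 0.0)

    rel_water = _bucket_moisture(tmean, precip, bucket_capacity_mm)

    # day-of-year climatology for base-history years
    tmean_clim = tmean.reshape(n, n_years, DAYS_PER_YEAR).mean(axis=1)
    rel_water_clim = rel_water.reshape(n, n_years, DAYS_PER_YEAR).mean(axis=1)

    return WeatherSet(
        years=years,
        location_ids=frame.table["location_id"].tolist(),
        tmean=tmean,
        precip=precip,
        rel_water=rel_water,
        tmean_clim=tmean_clim,
        rel_water_clim=rel_water_clim,
    )


def _bucket_moisture(tmean: np.ndarray, precip: np.ndarray, capacity: float) -> np.ndarray:
    """Single-bucket water balance; PET is a linear function of temperature."""
    n, D = tmean.shape
    pet = np.maximum(0.2, 0.12 * (tmean + 5.0))
    s = np.full(n, capacity / 2.0)
    rel = np.empty((n, D))
    for d in range(D):
        s = np.clip(s + precip[:, d] - pet[:, d], 0.0, capacity)
        rel[:, d] = s / capacity
    return rel


# ---------------------------------------------------------------------------
# Management truth histories
# ---------------------------------------------------------------------------

def generate_truth_histories(
    frame: SurveyFrame,
    adoption: AdoptionCurves | None = None,
    years: tuple[int, int] = SIM_YEARS,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate the 'true' per-location annual management histories.

    Practice adoption is realised with a persistent-uniform (nested) rule:
    location *i* practices in year *y* iff its fixed uniform draw is below
    the national trend fraction for that year, which makes the weighted
    national adoption match the curve in expectation while keeping
    per-location practice sequences temporally persistent.  Cover crops are
    forced off before 1990.
    """
    adoption = adoption or AdoptionCurves()
    rng = substream(seed, "truth")
    n = frame.n
    y0, y1 = years
    yr = np.arange(y0, y1 + 1)
    ny = yr.size

    u_cc = rng.random(n)
    u_ct = rng.random(n)
    u_hay = rng.random(n)
    u_man = rng.random(n)
    u_sa = rng.random(n)
    nt_coin = rng.random(n) < 0.5          # NT vs RT within conservation tillage
    hay_coin = rng.random(n) < 0.5         # hay vs pasture label
    term_coin = rng.random(n) < 0.5        # tillage vs herbicide termination
    irrigated_loc = rng.random(n) < 0.10
    rot_offset = rng.integers(0, 3, size=n)
    hay_offset = rng.integers(0, 4, size=n)
    fert_noise = rng.lognormal(0.0, 0.15, size=n)

    f_cc = np.asarray(adoption.fraction("cover_crop", yr))
    f_ct = np.asarray(adoption.fraction("cons_till", yr))
    f_hay = np.asarray(adoption.fraction("hay_pasture", yr))
    f_man = np.asarray(adoption.fraction("manure", yr))
    f_sa = np.asarray(adoption.fraction("set_aside", yr))

    # (n, ny) practice masks
    set_aside = u_sa[:, None] < f_sa[None, :]
    # hay rotation: membership threshold 2*f so hay occupies ~half of member
    # years (2-on / 2-off blocks), keeping annual crops in the rotation
    hay_member = u_hay[:, None] < np.minimum(1.0, 2.0 * f_hay)[None, :]
    hay_year = hay_member & (((yr[None, :] + hay_offset[:, None]) // 2) % 2 == 0)
    hay_year &= ~set_aside
    cons = u_ct[:, None] < f_ct[None, :]
    cover = (u_cc[:, None] < f_cc[None, :]) & (yr[None, :] >= 1990) & ~set_aside
    manure = (u_man[:, None] < f_man[None, :]) & ~set_aside

    # crops
    rot = np.array(ANNUAL_CROPS)
    crop = rot[(yr[None, :] + rot_offset[:, None]) % 3].astype(object)
    crop[hay_year] = np.where(np.broadcast_to(hay_coin[:, None], crop.shape)[hay_year], "hay", "pasture")
    crop[set_aside] = GRASS

    # tillage
    tillage = np.full((n, ny), "FT", dtype=object)
    tillage[cons & np.broadcast_to(nt_coin[:, None], cons.shape)] = "NT"
    tillage[cons & ~np.broadcast_to(nt_coin[:, None], cons.shape)] = "RT"
    tillage[set_aside] = "NT"

    # N inputs
    base_n = {"corn": 150.0, "soybean": 15.0, "wheat": 80.0, "hay": 40.0, "pasture": 20.0, GRASS: 0.0}
    trend = 0.8 + 0.3 * (yr - y0) / max(1, y1 - y0)  # rising fertilisation intensity
    fert = np.vectorize(base_n.get)(crop) * trend[None, :] * fert_noise[:, None]
    manure_n = np.where(manure, 120.0 * fert_noise[:, None], 0.0)
    fert = np.where(manure, 0.4 * fert, fert)
    fert[set_aside] = 0.0

    termination = np.full((n, ny), "none", dtype=object)
    termination[cover & np.broadcast_to(term_coin[:, None], cover.shape)] = "tillage"
    termination[cover & ~np.broadcast_to(term_coin[:, None], cover.shape)] = "herbicide"

    hist = pd.DataFrame(
        {
            "location_id": np.repeat(frame.table["location_id"].to_numpy(), ny),
            "year": np.tile(yr, n),
            "crop": crop.ravel(),
            "tillage": tillage.ravel(),
            "fert_n": fert.ravel(),
            "manure_n": manure_n.ravel(),
            "cover_crop": cover.ravel(),
            "termination": termination.ravel(),
            "irrigated": np.repeat(irrigated_loc, ny),
            "set_aside": set_aside.ravel(),
        }
    )
    assert not hist.loc[hist["year"] < 1990, "cover_crop"].any(), "cover crops must not occur before 1990"
    return hist


# ---------------------------------------------------------------------------
# Donor survey
# ---------------------------------------------------------------------------

def texture_class(clay_frac: np.ndarray | float) -> np.ndarray:
    """Coarse/medium/fine texture from clay fraction."""
    c = np.asarray(clay_frac)
    out = np.where(c < 0.18, "coarse", np.where(c < 0.35, "medium", "fine"))
    return out

def crop_group(crop: pd.Series | np.ndarray) -> np.ndarray:
    c = np.asarray(crop, dtype=object)
    grp = np.where(np.isin(c, ["corn", "soybean"]), "row",
          np.where(c == "wheat", "smallgrain", "forage"))
    return grp


ANCHOR_BLOCK = (2001, 2005)


def generate_donors(
    frame: SurveyFrame,
    truth: pd.DataFrame,
    n_donors: int = 300,
    seed: int = 0,
    noise_sd: float = 0.10,
) -> pd.DataFrame:
    """Sample a donor survey from the truth histories (anchor-period years)
    with lognormal observation noise on N rates.

    Every (region, crop_group, texture_class) stratum present in the frame's
    anchor-period records gets at least one donor; remaining donors are drawn
    at random.
    """
    rng = substream(seed, "donors")
    anchor = truth[(truth["year"] >= ANCHOR_BLOCK[0]) & (truth["year"] <= ANCHOR_BLOCK[1])].copy()
    meta = frame.table.set_index("location_id")
    anchor["region_id"] = meta.loc[anchor["location_id"], "region_id"].to_numpy()
    anchor["clay_frac"] = meta.loc[anchor["location_id"], "clay_frac"].to_numpy()
    anchor["texture_class"] = texture_class(anchor["clay_frac"].to_numpy())
    anchor["crop_group"] = crop_group(anchor["crop"])
    anchor = anchor.reset_index(drop=True)

    strata = anchor.groupby(["region_id", "crop_group", "texture_class"], sort=True).indices
    if n_donors < len(strata):
        raise ValueError(f"n_donors must cover all {len(strata)} strata")
    picks: list[int] = []
    for key in sorted(strata):
        picks.append(int(rng.choice(strata[key])))
    remaining = n_donors - len(picks)
    if remaining > 0:
        picks.extend(rng.choice(len(anchor), size=remaining, replace=True).tolist())
    donors = anchor.iloc[picks].reset_index(drop=True)
    donors["fert_n"] = donors["fert_n"] * rng.lognormal(0.0, noise_sd, size=len(donors))
    donors["manure_n"] = donors["manure_n"] * rng.lognormal(0.0, noise_sd, size=len(donors))
    donors.insert(0, "donor_id", np.arange(len(donors)))
    cols = [
        "donor_id", "region_id", "crop_group", "texture_class", "year",
        "fert_n", "manure_n", "tillage", "cover_crop", "clay_frac",
    ]
    return donors[cols]


# ---------------------------------------------------------------------------
# Calibration sites
# ---------------------------------------------------------------------------

def generate_calibration_sites(
    n_sites: int,
    bias_slope: float = 0.9,
    bias_intercept: float = 5.0,
    re_sd: float = 4.0,
    resid_sd: float = 3.0,
    params=None,
    n_treatments: int = 4,
    n_regions: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-term-experiment-style sites with known linear model bias.

    Each site contributes ``n_treatments`` treatments (tillage x input-level
    contrasts); the surrogate model supplies the simulated SOC and the
    measured value is ``intercept + slope*sim + site_effect + noise``.
    """
    from .soc_model import ModelParams, solve_equilibrium

    if n_sites < 3:
        raise ValueError("n_sites must be >= 3")
    if n_treatments < 2:
        raise ValueError("need >= 2 treatments per site for random-effect estimability")
    params = params or ModelParams()
    rng = substream(seed, "calibration_sites")

    rows = []
    tillages = ["FT", "NT", "RT", "FT"]
    input_scale = [1.0, 1.0, 0.8, 1.3]
    for s in range(n_sites):
        clay = float(0.05 + 0.45 * rng.beta(2.0, 3.0))
        tmean = float(rng.uniform(6.0, 16.0))
        relw = float(rng.uniform(0.3, 0.7))
        site_eff = rng.normal(0.0, re_sd)
        region = f"R{s % n_regions}"
        for t in range(n_treatments):
            till = tillages[t % len(tillages)]
            c_in = 3.2 * input_scale[t % len(input_scale)]
            state = solve_equilibrium(params, (tmean, relw, till), c_in, clay_frac=clay)
            sim = float(state.sum())
            measured = bias_intercept + bias_slope * sim + site_eff + rng.normal(0.0, resid_sd)
            rows.append(
                {
                    "site_id": f"S{s:04d}",
                    "region_id": region,
                    "treatment_id": f"T{t}",
                    "simulated_soc": sim,
                    "measured_soc": measured,
                    "clay_frac": clay,
                    "mean_temp_c": tmean,
                }
            )
    return pd.DataFrame(rows)
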