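"""Surrogate multi-pool soil organic carbon simulator.

A three-pool (active / slow / passive) first-order decomposition model in the
CENTURY tradition, run on a daily step to 30 cm depth.  Decomposition of each
pool is scaled by temperature (Q10 response, capped), moisture
(half-saturation on relative water) and tillage (multiplier on the active and
slow pools).  Decayed carbon splits into respiration and inter-pool
transfers whose fractions depend on clay content; crop-derived inputs enter
the active pool.  The model is an explicitly documented surrogate for a full
daily ecosystem model: it reproduces the structure the pipeline needs
(equilibrium spin-up, staged base history, management response) with
parameters held in one config block so a different simulator could be
plugged in behind the same interface.

Units: pools and stocks t C ha^-1 (0-30 cm); decay rates yr^-1; inputs
t C ha^-1 yr^-1; temperatures degC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import ANNUAL_CROPS, GRASS, SIM_YEARS
from .synthetic import DAYS_PER_YEAR, SurveyFrame, WeatherSet

POOLS = ("active", "slow", "passive")


class NumericalInstabilityError(RuntimeError):
    """A pool went negative during a step: the time step is too large."""


class NoEquilibriumError(RuntimeError):
    """The pool system has no finite steady state for these parameters."""


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class ModelParams:
    """Surrogate model parameters (defaults are CENTURY-like).

    ``till_mult`` multiplies decomposition of the active and slow pools;
    full tillage (FT) accelerates turnover relative to reduced (RT) and
    no-till (NT).  Transfer fractions out of the decayed flux are
    clay-dependent: higher clay routes more carbon to the passive pool.
    """

    k_active: float = 7.3
    k_slow: float = 0.2
    k_passive: float = 0.0045
    resp_active: float = 0.55
    resp_slow: float = 0.55
    resp_passive: float = 0.55
    a2p_base: float = 0.004
    a2p_clay: float = 0.03
    s2p_base: float = 0.003
    s2p_clay: float = 0.009
    q10: float = 2.0
    t_ref: float = 20.0
    t_cap: float = 2.0
    w_half: float = 0.3
    till_mult: dict = field(default_factory=lambda: {"NT": 1.00, "RT": 1.15, "FT": 1.30})
    crop_c_input: dict = field(
        default_factory=lambda: {
            "corn": 3.8, "soybean": 2.2, "wheat": 2.8,
            "hay": 3.2, "pasture": 3.0, GRASS: 4.2,
        }
    )
    native_c_input: float = 3.0
    cover_crop_c: float = 0.8
    manure_cn: float = 15.0
    n_half: float = 60.0            # kg N/ha at half of the N-responsive yield gain
    n_resp_frac: float = 0.35       # fraction of annual-crop C input modulated by N
    lowinput_scale: float = 0.5     # pre-1950 productivity relative to modern
    base_start_year: int = 1910
    till_pulse_days: int = 30       # extra-tillage window for tillage-terminated cover crops

    def __post_init__(self):
        if not (self.k_active > 0 and self.k_slow > 0 and self.k_passive > 0):
            raise ValueError("decay rates must be positive")
        if not (self.k_active > self.k_slow > self.k_passive):
            raise ValueError("require k_active > k_slow > k_passive")
        for f in (self.resp_active, self.resp_slow, self.resp_passive):
            if not 0.0 <= f <= 1.0:
                raise ValueError("respired fractions must lie in [0, 1]")
        tm = self.till_mult
        if not (tm["FT"] >= tm["RT"] >= tm["NT"]):
            raise ValueError("require till_mult[FT] >= till_mult[RT] >= till_mult[NT]")

    def transfer_fracs(self, clay_frac):
        """Per-pool split of the decayed flux: (respired, to-other fractions).

        Returns dict pool -> dict destination -> fraction of that pool's
        decayed flux.  Fractions sum to 1 per pool.
        """
        c = np.asarray(clay_frac, dtype=float)
        a2p = self.a2p_base + self.a2p_clay * c
        s2p = self.s2p_base + self.s2p_clay * c
        return {
            "active": {"resp": self.resp_active, "passive": a2p, "slow": 1.0 - self.resp_active - a2p},
            "slow": {"resp": self.resp_slow, "passive": s2p, "active": 1.0 - self.resp_slow - s2p},
            "passive": {"resp": self.resp_passive, "active": 1.0 - self.resp_passive},
        }


# ---------------------------------------------------------------------------
# Modifiers and single step
# ---------------------------------------------------------------------------

def decomp_modifiers(tmean_c, rel_water, tillage, params: ModelParams):
    """(m_T, m_W, m_till): temperature Q10 (capped), moisture half-saturation,
    tillage multiplier."""
    w = np.asarray(rel_water, dtype=float)
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("rel_water must lie in [0, 1]")
    t = np.asarray(tmean_c, dtype=float)
    m_t = np.minimum(params.q10 ** ((t - params.t_ref) / 10.0), params.t_cap)
    m_w = w / (w + params.w_half)
    if isinstance(tillage, str):
        m_till = params.till_mult[tillage]
    else:
        m_till = np.vectorize(params.till_mult.get)(np.asarray(tillage, dtype=object))
    return m_t, m_w, m_till


def step_pools(state, c_input_day, modifiers, params: ModelParams, dt_days: float = 1.0,
               clay_frac=0.2):
    """Advance pools one step; returns (new_state, respired_c).

    ``state`` is (..., 3) in pool order (active, slow, passive).  Each pool
    decays by k * m_T * m_W * (m_till on active/slow) * dt; the decayed flux
    splits into respiration and transfers; inputs enter the active pool.
    Mass balance is exact: d(total) = input - respired.
    """
    if dt_days <= 0:
        raise ValueError("dt_days must be positive")
    c_input_day = np.asarray(c_input_day, dtype=float)
    if np.any(c_input_day < 0):
        raise ValueError("c_input_day must be nonnegative")
    x = np.asarray(state, dtype=float)
    m_t, m_w, m_till = modifiers
    dt = dt_days / DAYS_PER_YEAR
    m = np.asarray(m_t, dtype=float) * np.asarray(m_w, dtype=float)
    fr = params.transfer_fracs(clay_frac)

    flux_a = params.k_active * m * np.asarray(m_till) * x[..., 0] * dt
    flux_s = params.k_slow * m * np.asarray(m_till) * x[..., 1] * dt
    flux_p = params.k_passive * m * x[..., 2] * dt

    respired = (fr["active"]["resp"] * flux_a + fr["slow"]["resp"] * flux_s
                + fr["passive"]["resp"] * flux_p)
    new = np.empty_like(x)
    new[..., 0] = x[..., 0] - flux_a + fr["slow"]["active"] * flux_s \
        + fr["passive"]["active"] * flux_p + c_input_day
    new[..., 1] = x[..., 1] - flux_s + fr["active"]["slow"] * flux_a
    new[..., 2] = x[..., 2] - flux_p + fr["active"]["passive"] * flux_a \
        + fr["slow"]["passive"] * flux_s
    if np.any(new < 0):
        raise NumericalInstabilityError("pool went negative; reduce dt_days")
    return new, respired


# ---------------------------------------------------------------------------
# Equilibrium
# ---------------------------------------------------------------------------

def _daily_map(params: ModelParams, m_tw: float, m_till: float, input_yr: float, clay_frac: float):
    """One-day affine update x' = M x + u of the pool system under constant
    forcing.  ``input_yr`` is the annual C input (enters the active pool)."""
    dt = 1.0 / DAYS_PER_YEAR
    fr = params.transfer_fracs(clay_frac)
    ka = params.k_active * m_tw * m_till * dt
    ks = params.k_slow * m_tw * m_till * dt
    kp = params.k_passive * m_tw * dt
    M = np.array(
        [
            [1.0 - ka, fr["slow"]["active"] * ks, fr["passive"]["active"] * kp],
            [fr["active"]["slow"] * ka, 1.0 - ks, 0.0],
            [fr["active"]["passive"] * ka, fr["slow"]["passive"] * ks, 1.0 - kp],
        ]
    )
    u = np.array([input_yr * dt, 0.0, 0.0])
    return M, u


def solve_equilibrium(params: ModelParams, mean_forcing, mean_input: float,
                      clay_frac: float = 0.2) -> np.ndarray:
    """Analytic steady state of the daily-step pool system.

    ``mean_forcing`` is (tmean_c, rel_water, tillage) held constant; the
    returned pools are the fixed point of the exact daily update the
    simulator iterates, so a long spin-up converges to it.
    """
    tmean, relw, tillage = mean_forcing
    m_t, m_w, m_till = decomp_modifiers(tmean, relw, tillage, params)
    M, u = _daily_map(params, float(m_t * m_w), float(m_till), float(mean_input), clay_frac)
    A = np.eye(3) - M
    try:
        x = np.linalg.solve(A, u)
    except np.linalg.LinAlgError as exc:
        raise NoEquilibriumError("singular transfer structure") from exc
    if not np.all(np.isfinite(x)) or np.any(x < -1e-9):
        raise NoEquilibriumError("no nonnegative steady state")
    return x


def spin_up(params: ModelParams, mean_forcing, mean_input: float,
            clay_frac: float = 0.2, years: int = 6000) -> np.ndarray:
    """Brute-force spin-up: iterate the daily map for ``years`` years.

    The 365 daily updates of one year are composed exactly into a single
    affine map, then iterated, so this is the literal long-run simulation
    at daily resolution without the Python-loop cost.
    """
    tmean, relw, tillage = mean_forcing
    m_t, m_w, m_till = decomp_modifiers(tmean, relw, tillage, params)
    M, u = _daily_map(params, float(m_t * m_w), float(m_till), float(mean_input), clay_frac)
    My = np.eye(3)
    uy = np.zeros(3)
    for _ in range(DAYS_PER_YEAR):
        uy = M @ uy + u
        My = M @ My
    x = np.zeros(3)
    for _ in range(years):
        x = My @ x + uy
    return x


def _batched_equilibrium(params: ModelParams, m_tw: np.ndarray, m_till: float,
                         input_yr: np.ndarray, clay: np.ndarray) -> np.ndarray:
    """Vectorised analytic equilibrium over locations; returns (n, 3)."""
    n = m_tw.size
    dt = 1.0 / DAYS_PER_YEAR
    fr = params.transfer_fracs(clay)
    ka = params.k_active * m_tw * m_till * dt
    ks = params.k_slow * m_tw * m_till * dt
    kp = params.k_passive * m_tw * dt
    A = np.zeros((n, 3, 3))
    A[:, 0, 0] = ka
    A[:, 0, 1] = -fr["slow"]["active"] * ks
    A[:, 0, 2] = -fr["passive"]["active"] * kp
    A[:, 1, 0] = -fr["active"]["slow"] * ka
    A[:, 1, 1] = ks
    A[:, 2, 0] = -fr["active"]["passive"] * ka
    A[:, 2, 1] = -fr["slow"]["passive"] * ks
    A[:, 2, 2] = kp
    u = np.zeros((n, 3))
    u[:, 0] = input_yr * dt
    return np.linalg.solve(A, u[:, :, None])[:, :, 0]


# ---------------------------------------------------------------------------
# Location simulation
# ---------------------------------------------------------------------------

@dataclass
class SOCBatch:
    """Annual Dec-31 SOC stocks for a batch of locations.

    ``soc`` is (n, n_years) over ``years``; ``delta`` is soc[y] - soc[y-1]
    for years[1:] (the first simulated year has no within-array change).
    """

    location_ids: list[str]
    years: np.ndarray
    soc: np.ndarray
    delta: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        n, ny = self.soc.shape
        delta_full = np.full((n, ny), np.nan)
        delta_full[:, 1:] = self.delta
        return pd.DataFrame(
            {
                "location_id": np.repeat(self.location_ids, ny),
                "year": np.tile(self.years, n),
                "soc": self.soc.ravel(),
                "delta_soc": delta_full.ravel(),
            }
        )


def _annual_c_input(params: ModelParams, crop: np.ndarray, fert_n: np.ndarray,
                    manure_n: np.ndarray) -> np.ndarray:
    """Annual plant + amendment C input (t C ha^-1 yr^-1) for one year.

    Annual crops respond to available N with a saturating yield response;
    perennial/grass inputs are flat.  Manure contributes carbon via its C:N.
    """
    base = np.vectorize(params.crop_c_input.get)(crop).astype(float)
    n_avail = fert_n + manure_n
    n_mult = (1.0 - params.n_resp_frac) + params.n_resp_frac * n_avail / (n_avail + params.n_half)
    is_annual = np.isin(crop, ANNUAL_CROPS)
    plant = np.where(is_annual, base * n_mult, base)
    manure_c = manure_n * params.manure_cn / 1000.0  # kg N * kgC/kgN -> t C
    return plant + manure_c


def growing_season_index(series: np.ndarray, window: int = 33, poly_order: int = 2,
                         season: tuple[int, int] = (120, 270)) -> float:
    """Growing-season mean of a daily vegetation-index series with gaps.

    Gap-fills the (typically ~8-day) observations with :func:`sg_gapfill`
    and averages over the growing-season day-of-year window; the result is
    the per-year production multiplier ``simulate_batch`` accepts.
    """
    filled = sg_gapfill(np.asarray(series, dtype=float), window=window, poly_order=poly_order)
    a, b = season
    return float(np.mean(filled[a:b]))


def simulate_batch(
    frame: SurveyFrame,
    weather: WeatherSet,
    histories: pd.DataFrame,
    params: ModelParams | None = None,
    location_ids: list[str] | None = None,
    production_index: pd.DataFrame | None = None,
) -> SOCBatch:
    """Simulate all (or a subset of) frame locations through the full staged
    history and return annual stocks for the survey era.

    Phases: analytic equilibrium under native grass at the climatological
    mean modifiers; low-input agriculture (scaled C inputs, full tillage)
    from ``params.base_start_year`` to 1949 on the weather climatology; a
    linear productivity ramp 1950-1978; then management-driven years
    1979-2015 on the generated daily weather.

    ``production_index`` optionally scales annual-crop C inputs by an
    observed production signal: a table (location_id, year, index) of
    growing-season index multipliers (see :func:`growing_season_index`);
    years/locations absent from the table keep the per-crop defaults.
    """
    params = params or ModelParams()
    table = frame.table
    all_ids = table["location_id"].tolist()
    if location_ids is None:
        location_ids = all_ids
        sel = np.arange(len(all_ids))
    else:
        pos = {lid: i for i, lid in enumerate(all_ids)}
        sel = np.array([pos[lid] for lid in location_ids])
    n = len(location_ids)
    clay = table["clay_frac"].to_numpy()[sel]

    y0, y1 = weather.years
    h = histories[histories["location_id"].isin(location_ids)]
    hyears = h["year"].unique()
    need = np.arange(y0, y1 + 1)
    if not np.all(np.isin(need, hyears)):
        missing = sorted(set(need) - set(hyears))
        raise ValueError(f"history missing years: {missing[:5]}")
    # pivot management to (n, ny) arrays in location order
    ny = y1 - y0 + 1
    hp = h.pivot(index="location_id", columns="year")
    idx = pd.Index(location_ids)
    crop = hp["crop"].reindex(idx).to_numpy(dtype=object)
    tillage = hp["tillage"].reindex(idx).to_numpy(dtype=object)
    fert_n = hp["fert_n"].reindex(idx).to_numpy(dtype=float)
    manure_n = hp["manure_n"].reindex(idx).to_numpy(dtype=float)
    cover = hp["cover_crop"].reindex(idx).to_numpy(dtype=bool)
    term = hp["termination"].reindex(idx).to_numpy(dtype=object)

    # --- climatological modifiers for pre-survey phases ---
    t_clim = weather.tmean_clim[sel]
    w_clim = weather.rel_water_clim[sel]
    m_t = np.minimum(params.q10 ** ((t_clim - params.t_ref) / 10.0), params.t_cap)
    m_w = w_clim / (w_clim + params.w_half)
    mtw_clim = m_t * m_w                      # (n, 365)
    mtw_clim_mean = mtw_clim.mean(axis=1)

    # --- equilibrium under native vegetation (grass, no tillage) ---
    x = _batched_equilibrium(
        params, mtw_clim_mean, params.till_mult["NT"],
        np.full(n, params.native_c_input), clay,
    )

    fr = params.transfer_fracs(clay)
    ka_base = params.k_active / DAYS_PER_YEAR
    ks_base = params.k_slow / DAYS_PER_YEAR
    kp_base = params.k_passive / DAYS_PER_YEAR
    s2a = fr["slow"]["active"]
    p2a = fr["passive"]["active"]
    a2s = fr["active"]["slow"]
    a2p = fr["active"]["passive"]
    s2p = fr["slow"]["passive"]

    def run_year(x, mtw_days, till_days, input_day_days):
        """mtw_days (365, n); till_days (365, n) multiplier; input (365, n)."""
        xa, xs, xp = x[:, 0].copy(), x[:, 1].copy(), x[:, 2].copy()
        for d in range(DAYS_PER_YEAR):
            m = mtw_days[d]
            mt = m * till_days[d]
            fa = ka_base * mt * xa
            fs = ks_base * mt * xs
            fp = kp_base * m * xp
            xa = xa - fa + s2a * fs + p2a * fp + input_day_days[d]
            xs = xs - fs + a2s * fa
            xp = xp - fp + a2p * fa + s2p * fs
        return np.stack([xa, xs, xp], axis=1)

    mtw_clim_T = np.ascontiguousarray(mtw_clim.T)  # (365, n)
    ft_const = np.full((DAYS_PER_YEAR, n), params.till_mult["FT"])

    # mean annual-crop C input at modern productivity, no fertiliser response
    base_crop = np.mean([params.crop_c_input[c] for c in ANNUAL_CROPS])
    for year in range(params.base_start_year, y0):
        if year < 1950:
            scale = params.lowinput_scale
        else:
            scale = params.lowinput_scale + (1.0 - params.lowinput_scale) * (year - 1950) / (y0 - 1 - 1950)
        inp = np.full((DAYS_PER_YEAR, n), base_crop * scale / DAYS_PER_YEAR)
        x = run_year(x, mtw_clim_T, ft_const, inp)

    # --- survey era on generated weather ---
    years = np.arange(y0, y1 + 1)
    soc = np.empty((n, ny))
    t_all = weather.tmean[sel]
    w_all = weather.rel_water[sel]
    m_t_all = np.minimum(params.q10 ** ((t_all - params.t_ref) / 10.0), params.t_cap)
    mtw_all = m_t_all * (w_all / (w_all + params.w_half))

    prod_mult = None
    if production_index is not None:
        prod_mult = (
            production_index.pivot(index="location_id", columns="year", values="index")
            .reindex(idx)
            .reindex(columns=years)
            .to_numpy(dtype=float)
        )

    till_vals = params.till_mult
    winter_days = np.zeros(DAYS_PER_YEAR, dtype=bool)
    winter_days[300:] = True
    winter_days[:60] = True
    n_winter = int(winter_days.sum())
    pulse_days = np.zeros(DAYS_PER_YEAR, dtype=bool)
    pulse_days[90:90 + params.till_pulse_days] = True

    for j, year in enumerate(years):
        sl = weather.year_slice(year)
        mtw_days = np.ascontiguousarray(mtw_all[:, sl].T)
        c_in_yr = _annual_c_input(params, crop[:, j], fert_n[:, j], manure_n[:, j])
        if prod_mult is not None:
            scale = prod_mult[:, j]
            use = np.isfinite(scale) & np.isin(crop[:, j], ANNUAL_CROPS)
            c_in_yr = np.where(use, c_in_yr * scale, c_in_yr)
        inp = np.repeat((c_in_yr / DAYS_PER_YEAR)[None, :], DAYS_PER_YEAR, axis=0)
        cc = cover[:, j]
        if cc.any():
            inp[np.ix_(winter_days, cc)] += params.cover_crop_c / n_winter
        base_till = np.vectorize(till_vals.get)(tillage[:, j]).astype(float)
        till_days = np.repeat(base_till[None, :], DAYS_PER_YEAR, axis=0)
        pulse = cc & (term[:, j] == "tillage")
        if pulse.any():
            till_days[np.ix_(pulse_days, pulse)] = np.maximum(
                till_days[np.ix_(pulse_days, pulse)], till_vals["FT"]
            )
        x = run_year(x, mtw_days, till_days, inp)
        soc[:, j] = x.sum(axis=1)

    delta = np.diff(soc, axis=1)
    return SOCBatch(location_ids=list(location_ids), years=years, soc=soc, delta=delta)


def simulate_location(frame: SurveyFrame, weather: WeatherSet, histories: pd.DataFrame,
                      params: ModelParams | None = None, location_id: str | None = None) -> pd.DataFrame:
    """Single-location convenience wrapper around :func:`simulate_batch`."""
    if location_id is None:
        location_id = frame.table["location_id"].iloc[0]
    batch = simulate_batch(frame, weather, histories, params, location_ids=[location_id])
    return batch.to_frame()


# ---------------------------------------------------------------------------
# Savitzky-Golay gap filling
# ---------------------------------------------------------------------------

def sg_gapfill(series: np.ndarray, window: int = 15, poly_order: int = 3) -> np.ndarray:
    """Fill missing (NaN) entries of a daily series by local polynomial
    least-squares (Savitzky-Golay-style) fits to the observed neighbours.

    Observed entries are preserved exactly; each missing entry is the value
    at its own position of a polynomial of degree ``poly_order`` fitted to
    the observations within the centred ``window``.
    """
    y = np.asarray(series, dtype=float)
    if window % 2 == 0 or window <= poly_order:
        raise ValueError("window must be odd and > poly_order")
    if window >= y.size:
        raise ValueError("window must be smaller than the series length")
    out = y.copy()
    half = window // 2
    missing = np.flatnonzero(np.isnan(y))
    obs_idx = np.flatnonzero(~np.isnan(y))
    if obs_idx.size == 0:
        raise ValueError("series has no observed entries")
    for i in missing:
        lo, hi = i - half, i + half
        pts = obs_idx[(obs_idx >= lo) & (obs_idx <= hi)]
        if pts.size < poly_order + 1:
            # widen to the nearest poly_order+1 observations (series edges)
            order = np.argsort(np.abs(obs_idx - i), kind="stable")
            pts = np.sort(obs_idx[order[: poly_order + 1]])
        k = min(poly_order, pts.size - 1)
        coeff = np.polyfit(pts - i, y[pts], k)
        out[i] = np.polyval(coeff, 0.0)
    return out


# ---------------------------------------------------------------------------
# Units
# ---------------------------------------------------------------------------

def c_to_co2e(mt_c: float) -> float:
    """Convert Mt C to Mt CO2 equivalent (molar mass ratio 44/12)."""
    return mt_c * 44.0 / 12.0
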