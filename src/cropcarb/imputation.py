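"""Management imputation: tillage trends and Markov sequences, N inputs by
predict-then-match, and cover crops with a linear adoption ramp.

The survey frame observes cropping, irrigation and set-aside directly;
tillage, N inputs and winter cover crops are unobserved and are imputed from
donor-survey records and national/regional trend series.  M complete
imputation sets carry the imputation uncertainty into the Monte Carlo.

Tillage sequences use an inhomogeneous Markov chain whose per-block
transition matrices are maximal-stay couplings of consecutive marginal
distributions: tillage type changes as rarely as the trend allows, which is
how real tillage systems behave (operators rarely switch).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import TILLAGE_LEVELS, substream
from .synthetic import SurveyFrame, crop_group, texture_class

# blocks align to the 2001-2005 hot-deck anchor, so the first block spans
# 1980-1985 (six years; 1979 folds into it)
BLOCKS: list[tuple[int, int]] = [(1980, 1985)] + [(y, y + 4) for y in range(1986, 2015, 5)]
BLOCK_LABELS = [f"{a}-{b}" for a, b in BLOCKS]
ANCHOR_LABEL = "2001-2005"


def year_block(year: int) -> str:
    """Block label for a survey-era year (1979 folds into the first block)."""
    for a, b in BLOCKS:
        if year <= b:
            return f"{a}-{b}"
    return BLOCK_LABELS[-1]


# ---------------------------------------------------------------------------
# Trend harmonisation
# ---------------------------------------------------------------------------

def harmonize_tillage_series(
    legacy_series: pd.DataFrame,
    recent_series: pd.DataFrame,
    overlap_index: list,
) -> pd.DataFrame:
    """Splice two tillage-proportion series into one consistent trend.

    Per tillage class, an OLS line is fit over the overlap (newer series as a
    function of the older); pre-overlap rows of the older series are mapped
    through the fit, clamped to [0, 1] and renormalised across classes.
    Rows present in the newer series are taken verbatim; index entries
    missing from both (all-NaN rows) are linearly interpolated between
    neighbours and renormalised.
    """
    overlap = [i for i in overlap_index if i in legacy_series.index and i in recent_series.index]
    if len(overlap) < 2:
        raise ValueError("need >= 2 overlap points per tillage class")
    classes = [c for c in TILLAGE_LEVELS if c in legacy_series.columns]
    fits = {}
    for cls in classes:
        x = legacy_series.loc[overlap, cls].to_numpy(dtype=float)
        y = recent_series.loc[overlap, cls].to_numpy(dtype=float)
        if np.allclose(x, x[0]):
            fits[cls] = (1.0, float(np.mean(y) - x[0]))  # degenerate overlap: pure offset
        else:
            slope, intercept = np.polyfit(x, y, 1)
            fits[cls] = (float(slope), float(intercept))

    index = sorted(set(legacy_series.index) | set(recent_series.index))
    out = pd.DataFrame(index=index, columns=classes, dtype=float)
    for idx in index:
        if idx in recent_series.index and not recent_series.loc[idx, classes].isna().any():
            out.loc[idx] = recent_series.loc[idx, classes].astype(float)
        elif idx in legacy_series.index and not legacy_series.loc[idx, classes].isna().any():
            row = {cls: fits[cls][0] * float(legacy_series.loc[idx, cls]) + fits[cls][1] for cls in classes}
            out.loc[idx] = pd.Series(row)
    out = out.clip(lower=0.0, upper=1.0)
    filled = out.apply(pd.to_numeric).interpolate(method="linear", limit_direction="both")
    out = filled.div(filled.sum(axis=1), axis=0)
    return out


# ---------------------------------------------------------------------------
# Maximal-stay coupling
# ---------------------------------------------------------------------------

def max_stay_transition(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Transition matrix with maximal diagonal (stay) mass coupling
    marginals ``p`` (current) to ``q`` (next).

    The joint mass puts min(p_i, q_i) on each diagonal cell -- the largest
    stay mass any coupling can achieve -- and distributes the residual
    supply/demand by the northwest-corner rule over the fixed state order,
    so the off-diagonal pattern is deterministic.  Rows with p_i = 0 are set
    to ``q``.  Satisfies p @ T = q exactly.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6 or abs(q.sum() - 1.0) > 1e-6:
        raise ValueError("marginals must each sum to 1")
    k = p.size
    J = np.zeros((k, k))
    diag = np.minimum(p, q)
    np.fill_diagonal(J, diag)
    supply = p - diag
    demand = q - diag
    i = j = 0
    eps = 1e-15
    while i < k and j < k:
        if supply[i] <= eps:
            i += 1
            continue
        if demand[j] <= eps:
            j += 1
            continue
        m = min(supply[i], demand[j])
        J[i, j] += m
        supply[i] -= m
        demand[j] -= m
    T = np.zeros((k, k))
    nz = p > 0
    T[nz] = J[nz] / p[nz, None]
    T[~nz] = q
    return T


# ---------------------------------------------------------------------------
# Tillage imputation
# ---------------------------------------------------------------------------

def impute_tillage(
    frame: SurveyFrame,
    donors: pd.DataFrame,
    marginal_series: pd.DataFrame,
    seed: int = 0,
    loc_crop_group: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-location tillage class for every 5-year block.

    The 2001-2005 anchor block is hot-decked from donors within
    (region, crop_group, texture_class) strata (falling back to
    region-level, then all donors, with a warning); earlier and later blocks
    are sampled location-wise through the chained maximal-stay transition
    matrices so realised marginals track the trend series while individual
    sequences change tillage type only rarely.
    """
    missing = [b for b in BLOCK_LABELS if b not in marginal_series.index]
    if missing:
        raise ValueError(f"marginal series missing blocks: {missing}")
    rng = substream(seed, "tillage")
    tab = frame.table
    n = len(tab)
    region = tab["region_id"].to_numpy()
    tex = texture_class(tab["clay_frac"].to_numpy())
    if loc_crop_group is None:
        cg = np.full(n, "row", dtype=object)
    else:
        cg = loc_crop_group.reindex(tab["location_id"]).fillna("row").to_numpy(dtype=object)

    # --- anchor hot-deck ---
    donor_key = donors.groupby(["region_id", "crop_group", "texture_class"]).indices
    donor_region = donors.groupby(["region_id"]).indices
    anchor = np.empty(n, dtype=object)
    fallback = 0
    for i in range(n):
        key = (region[i], cg[i], tex[i])
        pool = donor_key.get(key)
        if pool is None or len(pool) == 0:
            pool = donor_region.get((region[i],))
            fallback += 1
        if pool is None or len(pool) == 0:
            pool = np.arange(len(donors))
        anchor[i] = donors["tillage"].iloc[int(rng.choice(pool))]
    if fallback:
        warnings.warn(f"{fallback} locations hot-decked from region-level donors", stacklevel=2)

    levels = list(TILLAGE_LEVELS)
    lvl_idx = {t: i for i, t in enumerate(levels)}
    out = pd.DataFrame(index=tab["location_id"].to_numpy(), columns=BLOCK_LABELS, dtype=object)
    out[ANCHOR_LABEL] = anchor

    a = BLOCK_LABELS.index(ANCHOR_LABEL)

    def chain(from_idx, to_indices):
        state = out[BLOCK_LABELS[from_idx]].to_numpy(dtype=object)
        cur = BLOCK_LABELS[from_idx]
        for bi in to_indices:
            nxt = BLOCK_LABELS[bi]
            p = marginal_series.loc[cur, list(levels)].to_numpy(dtype=float)
            q = marginal_series.loc[nxt, list(levels)].to_numpy(dtype=float)
            T = max_stay_transition(p / p.sum(), q / q.sum())
            u = rng.random(n)
            cum = np.cumsum(T, axis=1)
            rows = np.array([lvl_idx[s] for s in state])
            nxt_state_idx = (u[:, None] > cum[rows]).sum(axis=1)
            state = np.array(levels, dtype=object)[nxt_state_idx]
            out[nxt] = state
            cur = nxt

    chain(a, range(a - 1, -1, -1))   # backward to 1980-1984
    chain(a, range(a + 1, len(BLOCK_LABELS)))  # forward to 2011-2015
    out.index.name = "location_id"
    return out


# ---------------------------------------------------------------------------
# N inputs: predict then match
# ---------------------------------------------------------------------------

def _default_predictor(donors: pd.DataFrame, value_col: str):
    """Linear regression of the donor N value on clay and crop-group dummies."""
    groups = sorted(donors["crop_group"].unique())

    def design(clay, cg):
        cols = [np.ones_like(clay), np.asarray(clay, dtype=float)]
        for g in groups[1:]:
            cols.append((np.asarray(cg, dtype=object) == g).astype(float))
        return np.column_stack(cols)

    X = design(donors["clay_frac"].to_numpy(), donors["crop_group"].to_numpy())
    y = donors[value_col].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)

    def predict(clay, cg):
        return design(clay, cg) @ beta

    return predict


def pmm_assign(
    recipient_pred: np.ndarray,
    donor_pred: np.ndarray,
    donor_values: np.ndarray,
    donor_ids: np.ndarray,
) -> np.ndarray:
    """Predictive mean matching: each recipient receives the observed value
    of the donor whose own prediction is nearest; ties go to the lowest
    donor_id.  Assigned values therefore always lie in the donor support."""
    order = np.lexsort((donor_ids, donor_pred))
    dp = donor_pred[order]
    dv = donor_values[order]
    did = donor_ids[order]
    out = np.empty(recipient_pred.size, dtype=float)
    for r, pr in enumerate(np.asarray(recipient_pred, dtype=float)):
        d = np.abs(dp - pr)
        dmin = d.min()
        cand = np.flatnonzero(d <= dmin + 0.0)
        best = cand[np.argmin(did[cand])]
        out[r] = dv[best]
    return out


def impute_n_inputs(
    frame: SurveyFrame,
    donors: pd.DataFrame,
    trend_by_region,
    predictor_fn=None,
    seed: int = 0,
    years: tuple[int, int] = (1979, 2015),
    loc_crop_group: pd.Series | None = None,
) -> pd.DataFrame:
    """Impute fertiliser and manure N per location-year.

    A predictor (linear regression on stratum covariates by default) is
    trained on the donors; predictive mean matching then assigns each
    location the observed donor rates nearest in predicted value, and
    regional year multipliers from ``trend_by_region`` (region -> year ->
    multiplier, or a callable (region, year) -> multiplier) scale the base
    rate into the annual series.
    """
    if donors.empty:
        raise RuntimeError("no donors in scope")
    tab = frame.table
    n = len(tab)
    clay = tab["clay_frac"].to_numpy()
    if loc_crop_group is None:
        cg = np.full(n, "row", dtype=object)
    else:
        cg = loc_crop_group.reindex(tab["location_id"]).fillna("row").to_numpy(dtype=object)

    out_cols = {}
    for col in ("fert_n", "manure_n"):
        predict = predictor_fn(donors, col) if predictor_fn else _default_predictor(donors, col)
        rec_pred = np.asarray(predict(clay, cg), dtype=float)
        don_pred = np.asarray(predict(donors["clay_frac"].to_numpy(), donors["crop_group"].to_numpy()), dtype=float)
        out_cols[col] = pmm_assign(
            rec_pred, don_pred, donors[col].to_numpy(dtype=float), donors["donor_id"].to_numpy()
        )

    y0, y1 = years
    yr = np.arange(y0, y1 + 1)
    region = tab["region_id"].to_numpy()
    if callable(trend_by_region):
        mult = np.array([[float(trend_by_region(r, y)) for y in yr] for r in region])
    elif trend_by_region is None:
        mult = np.ones((n, yr.size))
    else:
        mult = np.array([[float(trend_by_region[r][int(y)]) for y in yr] for r in region])

    return pd.DataFrame(
        {
            "location_id": np.repeat(tab["location_id"].to_numpy(), yr.size),
            "year": np.tile(yr, n),
            "fert_n": (out_cols["fert_n"][:, None] * mult).ravel(),
            "manure_n": (out_cols["manure_n"][:, None] * mult).ravel(),
        }
    )


# ---------------------------------------------------------------------------
# Cover crops
# ---------------------------------------------------------------------------

def impute_cover_crops(
    frame: SurveyFrame,
    donors: pd.DataFrame,
    census_targets: dict[str, float] | None = None,
    seed: int = 0,
    termination: str = "herbicide",
    years: tuple[int, int] = (1979, 2015),
) -> pd.DataFrame:
    """Impute winter cover crop flags with a linear pre-2001 adoption ramp.

    The 2001-2005 anchor block is hot-decked from donor cover-crop rates
    within region; before 2001 adoption ramps linearly down to exactly zero
    in 1990 (adopters are thinned with persistent uniforms so individual
    locations drop out monotonically going back in time); blocks after 2005
    randomly add or remove adopters to hit the census target fractions.
    """
    census_targets = census_targets or {}
    for b, t in census_targets.items():
        if t > 1.0 or t < 0.0:
            raise ValueError(f"census target for {b} outside [0, 1]")
    rng = substream(seed, "cover_crop")
    tab = frame.table
    n = len(tab)
    w = tab["weight"].to_numpy()
    region = tab["region_id"].to_numpy()

    # anchor adoption probability per region from donors
    p_region = donors.groupby("region_id")["cover_crop"].mean()
    p_anchor = np.array([float(p_region.get(r, donors["cover_crop"].mean())) for r in region])
    adopter = rng.random(n) < p_anchor

    y0, y1 = years
    yr = np.arange(y0, y1 + 1)
    cc = np.zeros((n, yr.size), dtype=bool)
    v = rng.random(n)  # persistent thinning uniforms for the backward ramp

    anchor_level = float(np.sum(w * adopter) / w.sum())
    for j, year in enumerate(yr):
        if year < 1991:
            continue
        if year <= 2000:
            ramp = (year - 1990) / 10.0  # fraction of the 2000/anchor level retained
            cc[:, j] = adopter & (v < ramp)
        elif year <= 2005:
            cc[:, j] = adopter

    # post-2005 blocks: add/remove to match census targets
    post_blocks = [b for b in BLOCK_LABELS if int(b[:4]) > 2005]
    current = adopter.copy()
    for b in post_blocks:
        target = census_targets.get(b, anchor_level)
        level = float(np.sum(w * current) / w.sum()) if current.any() else 0.0
        nxt = current.copy()
        if target > level:
            add_p = (target - level) / max(1e-12, 1.0 - level)
            nxt |= (~current) & (rng.random(n) < add_p)
        elif target < level:
            keep_p = target / max(level, 1e-12)
            nxt &= rng.random(n) < keep_p
        a, bb = int(b[:4]), int(b[-4:])
        mask = (yr >= a) & (yr <= bb)
        cc[:, mask] = nxt[:, None]
        current = nxt

    term = np.where(cc, termination, "none").astype(object)
    return pd.DataFrame(
        {
            "location_id": np.repeat(tab["location_id"].to_numpy(), yr.size),
            "year": np.tile(yr, n),
            "cover_crop": cc.ravel(),
            "termination": term.ravel(),
        }
    )


# ---------------------------------------------------------------------------
# Full imputation sets
# ---------------------------------------------------------------------------

@dataclass
class ImputationSet:
    imputation_id: int
    histories: pd.DataFrame


def default_marginal_series() -> pd.DataFrame:
    """Default tillage-proportion trend over the 5-year blocks: conservation
    tillage (NT+RT) rising over time, faster after 2000."""
    rows = {
        "1980-1985": [0.06, 0.12, 0.82],
        "1986-1990": [0.08, 0.14, 0.78],
        "1991-1995": [0.10, 0.16, 0.74],
        "1996-2000": [0.11, 0.17, 0.72],
        "2001-2005": [0.13, 0.19, 0.68],
        "2006-2010": [0.17, 0.21, 0.62],
        "2011-2015": [0.21, 0.23, 0.56],
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(TILLAGE_LEVELS))
    df = df.reindex(BLOCK_LABELS)
    df = df.interpolate(method="linear", limit_direction="both")
    return df.div(df.sum(axis=1), axis=0)


def build_imputations(
    frame: SurveyFrame,
    donors: pd.DataFrame,
    observed: pd.DataFrame,
    marginal_series: pd.DataFrame | None = None,
    n_trend=None,
    census_targets: dict[str, float] | None = None,
    M: int = 6,
    seed: int = 0,
    termination: str = "herbicide",
) -> list[ImputationSet]:
    """Build M complete, independently seeded imputation sets.

    ``observed`` supplies the survey-observed columns (crop, irrigated,
    set_aside) per location-year; tillage, N inputs and cover crops are
    imputed and merged in.  Set-aside years are forced to grass/NT with no
    amendments or cover crops, consistent with retired land.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    marginal_series = marginal_series if marginal_series is not None else default_marginal_series()
    anchor_crops = observed[(observed["year"] >= 2001) & (observed["year"] <= 2005)]
    loc_cg = (
        anchor_crops.assign(cg=crop_group(anchor_crops["crop"]))
        .groupby("location_id")["cg"]
        .agg(lambda s: s.mode().iloc[0])
    )

    sets = []
    for m in range(1, M + 1):
        sub = int(substream(seed, "imputation", m).integers(0, 2**31 - 1))
        try:
            till_blocks = impute_tillage(frame, donors, marginal_series, seed=sub, loc_crop_group=loc_cg)
            n_inputs = impute_n_inputs(frame, donors, n_trend, seed=sub, loc_crop_group=loc_cg)
            cc = impute_cover_crops(frame, donors, census_targets, seed=sub, termination=termination)
        except Exception as exc:
            raise RuntimeError(f"imputation set {m} failed in stage: {exc}") from exc

        hist = observed[["location_id", "year", "crop", "irrigated", "set_aside"]].copy()
        hist["block"] = [year_block(y) for y in hist["year"]]
        till_long = till_blocks.stack().rename("tillage").reset_index()
        till_long.columns = ["location_id", "block", "tillage"]
        hist = hist.merge(till_long, on=["location_id", "block"], how="left").drop(columns="block")
        hist = hist.merge(n_inputs, on=["location_id", "year"], how="left")
        hist = hist.merge(cc, on=["location_id", "year"], how="left")

        sa = hist["set_aside"].to_numpy(dtype=bool)
        hist.loc[sa, "tillage"] = "NT"
        hist.loc[sa, ["fert_n", "manure_n"]] = 0.0
        hist.loc[sa, "cover_crop"] = False
        hist.loc[sa, "termination"] = "none"
        forage = hist["crop"].isin(["hay", "pasture"]).to_numpy()
        hist.loc[forage, "cover_crop"] = False
        hist.loc[forage, "termination"] = "none"
        hist["cover_crop"] = hist["cover_crop"].astype(bool)

        cols = ["location_id", "year", "crop", "tillage", "fert_n", "manure_n",
                "cover_crop", "termination", "irrigated", "set_aside"]
        sets.append(ImputationSet(imputation_id=m, histories=hist[cols]))
    return sets
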