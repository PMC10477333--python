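"""Counterfactual scenarios: remove one practice, rerun, attribute the effect.

Each scenario edits exactly one practice across the full 1979-2015 record
(extending edits back to 1979 avoids artificial stock trends during the
1995-2015 assessment window that an abrupt 1995 switch would create), the
paired simulation is rerun, and the practice effect is the difference in
annual SOC stock changes, baseline minus counterfactual.  Set-aside is
attributed directly from the baseline simulation because retired land has no
other concurrent practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ANNUAL_CROPS, HAY_PASTURE, REPORT_YEARS, substream
from .soc_model import ModelParams, SOCBatch, simulate_batch
from .synthetic import SurveyFrame, WeatherSet

SCENARIOS = (
    "NO_COVER_CROP",
    "FULL_TILLAGE",
    "NO_HAY_PASTURE",
    "MANURE_TO_SYNTHETIC",
    "SET_ASIDE_DIRECT",
)
_EDITED_FIELDS = {
    "NO_COVER_CROP": {"cover_crop", "termination"},
    "FULL_TILLAGE": {"tillage"},
    "NO_HAY_PASTURE": {"crop"},
    "MANURE_TO_SYNTHETIC": {"fert_n", "manure_n"},
    "SET_ASIDE_DIRECT": set(),
}


def apply_scenario(history: pd.DataFrame, scenario: str, seed: int = 0) -> pd.DataFrame:
    """Return an edited copy of ``history`` with one practice eliminated.

    NO_COVER_CROP clears cover crops; FULL_TILLAGE converts NT/RT to FT on
    cultivated (non-set-aside) years; NO_HAY_PASTURE replaces each
    hay/pasture year by a uniformly sampled annual crop already grown at
    that location (region-modal annual crop, with a warning, where the
    location grows none); MANURE_TO_SYNTHETIC moves manure N into synthetic
    fertiliser so total N available to crops is unchanged while the manure
    carbon disappears.  SET_ASIDE_DIRECT is attributed directly and returns
    the history unchanged.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    h = history.copy()
    if scenario == "NO_COVER_CROP":
        h["cover_crop"] = False
        h["termination"] = "none"
    elif scenario == "FULL_TILLAGE":
        mask = h["tillage"].isin(["NT", "RT"]) & ~h["set_aside"]
        h.loc[mask, "tillage"] = "FT"
    elif scenario == "MANURE_TO_SYNTHETIC":
        h["fert_n"] = h["fert_n"] + h["manure_n"]
        h["manure_n"] = 0.0
    elif scenario == "NO_HAY_PASTURE":
        rng = substream(seed, "no_hay_pasture")
        is_hp = h["crop"].isin(HAY_PASTURE)
        if is_hp.any():
            annual_mask = h["crop"].isin(ANNUAL_CROPS)
            loc_annuals = h[annual_mask].groupby("location_id")["crop"].unique()
            modal = (
                h[annual_mask].groupby("crop").size().idxmax()
                if annual_mask.any() else ANNUAL_CROPS[0]
            )
            new_crop = h["crop"].to_numpy(dtype=object).copy()
            warned = False
            for lid, idxs in h.index[is_hp].groupby(h.loc[is_hp, "location_id"]).items():
                pool = loc_annuals.get(lid)
                if pool is None or len(pool) == 0:
                    if not warned:
                        warnings.warn(
                            "location(s) growing only hay/pasture: substituting modal annual crop",
                            stacklevel=2,
                        )
                        warned = True
                    new_crop[h.index.get_indexer(idxs)] = modal
                else:
                    pool = np.sort(np.asarray(pool, dtype=object))
                    new_crop[h.index.get_indexer(idxs)] = rng.choice(pool, size=len(idxs))
            h["crop"] = new_crop
    return h


@dataclass
class EffectTable:
    """Per-location annual practice effects (t C ha^-1 yr^-1), plus the
    baseline stock-change arrays needed for national totals.

    ``effects[scenario]`` is (n_locations, n_report_years); baseline deltas
    are keyed "TOTAL" (primary termination variant).  Cover-crop effects are
    stored per termination variant as NO_COVER_CROP@herbicide /
    NO_COVER_CROP@tillage.
    """

    location_ids: list[str]
    years: np.ndarray
    effects: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        ny = self.years.size
        for scen, arr in self.effects.items():
            frames.append(
                pd.DataFrame(
                    {
                        "scenario": scen,
                        "location_id": np.repeat(self.location_ids, ny),
                        "year": np.tile(self.years, len(self.location_ids)),
                        "effect": arr.ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EffectTable":
        years = np.sort(df["year"].unique())
        lids = list(pd.unique(df["location_id"]))
        et = cls(location_ids=lids, years=years)
        for scen, sub in df.groupby("scenario"):
            piv = sub.pivot(index="location_id", columns="year", values="effect")
            et.effects[scen] = piv.reindex(lids).to_numpy(dtype=float)
        return et


def _report_slice(batch_years: np.ndarray, report=REPORT_YEARS) -> np.ndarray:
    return np.flatnonzero((batch_years >= report[0]) & (batch_years <= report[1]))


def attribute_effect(baseline: SOCBatch, counterfactual: SOCBatch,
                     report_years: tuple[int, int] = REPORT_YEARS) -> pd.DataFrame:
    """effect(y) = delta_soc_baseline(y) - delta_soc_counterfactual(y),
    reported over the assessment window."""
    if baseline.location_ids != counterfactual.location_ids or not np.array_equal(
        baseline.years, counterfactual.years
    ):
        raise ValueError("trajectories must share locations and years")
    dyears = baseline.years[1:]
    keep = (dyears >= report_years[0]) & (dyears <= report_years[1])
    eff = baseline.delta[:, keep] - counterfactual.delta[:, keep]
    ny = int(keep.sum())
    return pd.DataFrame(
        {
            "location_id": np.repeat(baseline.location_ids, ny),
            "year": np.tile(dyears[keep], len(baseline.location_ids)),
            "effect": eff.ravel(),
        }
    )


def setaside_effect(baseline: SOCBatch, history: pd.DataFrame,
                    report_years: tuple[int, int] = REPORT_YEARS) -> pd.DataFrame:
    """Direct attribution: the baseline stock change on set-aside years,
    zero elsewhere."""
    dyears = baseline.years[1:]
    keep = (dyears >= report_years[0]) & (dyears <= report_years[1])
    yrs = dyears[keep]
    sa = (
        history.pivot(index="location_id", columns="year", values="set_aside")
        .reindex(baseline.location_ids)[yrs]
        .to_numpy(dtype=bool)
    )
    eff = np.where(sa, baseline.delta[:, keep], 0.0)
    ny = yrs.size
    return pd.DataFrame(
        {
            "location_id": np.repeat(baseline.location_ids, ny),
            "year": np.tile(yrs, len(baseline.location_ids)),
            "effect": eff.ravel(),
        }
    )


def run_all_scenarios(
    frame: SurveyFrame,
    histories: pd.DataFrame,
    params: ModelParams,
    weather: WeatherSet,
    seed: int = 0,
    scenarios: tuple[str, ...] = SCENARIOS,
    termination_primary: str = "herbicide",
) -> EffectTable:
    """One baseline run plus one paired run per elimination scenario.

    Locations whose counterfactual history is identical to the baseline are
    not re-simulated: their effect is exactly zero by construction.  The
    cover-crop scenario is evaluated against baselines under both
    termination variants (the counterfactual itself has no cover crops, so
    one counterfactual run serves both).
    """
    lids = frame.table["location_id"].tolist()

    def with_termination(h, variant):
        out = h.copy()
        cc = out["cover_crop"].to_numpy(dtype=bool)
        out["termination"] = np.where(cc, variant, "none")
        return out

    base_hist = with_termination(histories, termination_primary)
    base = simulate_batch(frame, weather, base_hist, params)
    dyears = base.years[1:]
    keep = (dyears >= REPORT_YEARS[0]) & (dyears <= REPORT_YEARS[1])
    yrs = dyears[keep]
    ny = yrs.size
    n = len(lids)

    table = EffectTable(location_ids=lids, years=yrs)
    table.effects["TOTAL"] = base.delta[:, keep].copy()

    other_variant = "tillage" if termination_primary == "herbicide" else "herbicide"
    base_other = None

    cmp_cols = ["crop", "tillage", "fert_n", "manure_n", "cover_crop", "termination"]

    def changed_locations(h_cf, h_base):
        a = h_base.sort_values(["location_id", "year"])[cmp_cols].reset_index(drop=True)
        b = h_cf.sort_values(["location_id", "year"])[cmp_cols].reset_index(drop=True)
        lid = h_base.sort_values(["location_id", "year"])["location_id"].reset_index(drop=True)
        diff = (a != b).any(axis=1)
        return sorted(lid[diff].unique())

    for scen in scenarios:
        if scen == "SET_ASIDE_DIRECT":
            eff_df = setaside_effect(base, base_hist)
            piv = eff_df.pivot(index="location_id", columns="year", values="effect")
            table.effects[scen] = piv.reindex(lids)[yrs].to_numpy(dtype=float)
            continue
        cf_hist = apply_scenario(base_hist, scen, seed=seed)
        changed = changed_locations(cf_hist, base_hist)
        eff = np.zeros((n, ny))
        if changed:
            cf_batch = simulate_batch(frame, weather, cf_hist, params, location_ids=changed)
            pos = {lid: i for i, lid in enumerate(lids)}
            rows = [pos[lid] for lid in changed]
            base_delta = base.delta[rows][:, keep]
            eff[rows] = base_delta - cf_batch.delta[:, keep]
        if scen == "NO_COVER_CROP":
            table.effects[f"{scen}@{termination_primary}"] = eff
            # same counterfactual against the other termination baseline
            if base_other is None:
                base_other_hist = with_termination(histories, other_variant)
                changed_o = changed_locations(base_other_hist, base_hist)
                base_other = base.delta.copy()
                if changed_o:
                    bo = simulate_batch(frame, weather, base_other_hist, params, location_ids=changed_o)
                    pos = {lid: i for i, lid in enumerate(lids)}
                    rows_o = [pos[lid] for lid in changed_o]
                    base_other[rows_o] = bo.delta
            eff_o = np.zeros((n, ny))
            if changed:
                cf_delta_full = np.array(base.delta, copy=True)
                cf_delta_full[rows] = cf_batch.delta
                eff_o = base_other[:, keep] - cf_delta_full[:, keep]
            table.effects[f"{scen}@{other_variant}"] = eff_o
        else:
            table.effects[scen] = eff
    return table
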