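"""Run configuration, named random substreams, and study-condition defaults.

Every stochastic stage draws from a substream derived from one master seed and
a stage name, so stages are independently reproducible: regenerating donors
does not perturb the weather, and imputation set *m* is a function of
(master_seed, "imputation", m) only.
"""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import yaml

SIM_YEARS = (1979, 2015)
REPORT_YEARS = (1995, 2015)
TILLAGE_LEVELS = ("NT", "RT", "FT")
ANNUAL_CROPS = ("corn", "soybean", "wheat")
HAY_PASTURE = ("hay", "pasture")
GRASS = "grass"


def substream(master_seed: int, name: str, index: int | None = None) -> np.random.Generator:
    """Named, order-independent child RNG of ``master_seed``.

    The stage name is hashed into the seed sequence so adding a new stage
    never shifts the streams of existing ones.
    """
    key = [int(master_seed) % (2**31), zlib.crc32(name.encode("utf8"))]
    if index is not None:
        key.append(int(index))
    return np.random.default_rng(np.random.SeedSequence(key))


# ---------------------------------------------------------------------------
# National adoption trends (area fraction of cropland per year)
# ---------------------------------------------------------------------------
#
# Piecewise-linear curves over 1979-2015.  The default shapes encode the
# study conditions the pipeline is designed around: cover-crop area zero
# before 1990 then ramping to a few percent of cropland; conservation
# tillage (NT+RT) rising, faster after 2000; hay/pasture rotation area
# declining by roughly half over the series; manure-amended area flat;
# set-aside (CRP-style) enrollment peaking in the early 1990s and then
# declining.

DEFAULT_ADOPTION: dict[str, dict[int, float]] = {
    "cover_crop": {1979: 0.0, 1990: 0.0, 2000: 0.02, 2015: 0.03},
    "cons_till": {1979: 0.18, 2000: 0.24, 2008: 0.33, 2015: 0.40},
    "hay_pasture": {1979: 0.045, 1995: 0.038, 2015: 0.018},
    "manure": {1979: 0.036, 2015: 0.036},
    "set_aside": {1979: 0.0, 1986: 0.0, 1993: 0.08, 1996: 0.08, 2015: 0.035},
}


class AdoptionCurves:
    """Per-practice national area-fraction trends, linear between knots."""

    def __init__(self, curves: Mapping[str, Mapping[int, float]] | None = None):
        curves = dict(curves) if curves is not None else dict(DEFAULT_ADOPTION)
        self._knots: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for practice, pts in curves.items():
            years = np.array(sorted(pts), dtype=float)
            fracs = np.array([pts[int(y)] for y in years], dtype=float)
            if np.any(fracs < 0) or np.any(fracs > 1):
                raise ValueError(f"adoption fractions for {practice!r} must lie in [0, 1]")
            self._knots[practice] = (years, fracs)

    def practices(self) -> list[str]:
        return list(self._knots)

    def fraction(self, practice: str, year: int | np.ndarray) -> np.ndarray | float:
        years, fracs = self._knots[practice]
        return np.interp(np.asarray(year, dtype=float), years, fracs)

    @classmethod
    def zero(cls) -> "AdoptionCurves":
        return cls({p: {1979: 0.0, 2015: 0.0} for p in DEFAULT_ADOPTION})


# ---------------------------------------------------------------------------
# Regional climate normals
# ---------------------------------------------------------------------------

def default_climate(region_ids: list[str]) -> dict[str, dict[str, float]]:
    """Simple cross-region gradient of climate normals.

    mean_temp_c: annual mean air temperature; amplitude_c: half peak-to-trough
    seasonal swing; annual_precip_mm: long-run annual precipitation.
    """
    out = {}
    for i, rid in enumerate(sorted(region_ids)):
        out[rid] = {
            "mean_temp_c": 8.0 + 2.5 * (i % 4),
            "amplitude_c": 12.0,
            "annual_precip_mm": 650.0 + 150.0 * (i % 3),
        }
    return out


# ---------------------------------------------------------------------------
# RunConfig
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = (
    "master_seed",
    "n_locations",
    "total_area_ha",
    "n_replicates",
    "n_imputations",
    "n_iterations",
)


@dataclass
class RunConfig:
    """Validated end-to-end run configuration.

    All module parameter blocks are optional dicts handed to the respective
    stage; the required scalar knobs are validated up front so a typo fails
    before any stage runs.
    """

    master_seed: int = 20150101
    n_locations: int = 500
    total_area_ha: float = 125.4e6
    n_replicates: int = 30
    n_imputations: int = 6
    n_iterations: int = 1000
    domain_km: tuple[float, float] = (1000.0, 1000.0)
    n_regions: int = 4
    scenarios: tuple[str, ...] = (
        "NO_COVER_CROP",
        "FULL_TILLAGE",
        "NO_HAY_PASTURE",
        "MANURE_TO_SYNTHETIC",
        "SET_ASIDE_DIRECT",
    )
    termination_variant: str = "herbicide"
    adoption: dict = field(default_factory=lambda: dict(DEFAULT_ADOPTION))
    model_params: dict = field(default_factory=dict)
    n_donors: int = 300
    n_calibration_sites: int = 40
    bias_slope: float = 0.9
    bias_intercept: float = 5.0
    bias_re_sd: float = 4.0
    bias_resid_sd: float = 3.0
    grid_cell_km: float = 5.0
    idw_radius_km: float = 20.0
    idw_min_points: int = 5
    idw_power: float = 2.0
    output_dir: str = "cropcarb_out"

    def __post_init__(self):
        if self.n_locations < 1:
            raise ValueError("n_locations must be >= 1")
        if self.total_area_ha <= 0:
            raise ValueError("total_area_ha must be positive")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.n_imputations < 1:
            raise ValueError("n_imputations must be >= 1")
        if self.n_iterations < 2:
            raise ValueError("n_iterations must be >= 2")
        if self.termination_variant not in ("herbicide", "tillage"):
            raise ValueError("termination_variant must be 'herbicide' or 'tillage'")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        missing = [k for k in _REQUIRED_KEYS if k not in raw]
        if missing:
            raise KeyError(f"missing required config keys: {', '.join(missing)}")
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = [k for k in raw if k not in known]
        if unknown:
            raise KeyError(f"unknown config keys: {', '.join(unknown)}")
        kwargs = dict(raw)
        if "domain_km" in kwargs:
            kwargs["domain_km"] = tuple(kwargs["domain_km"])
        if "scenarios" in kwargs:
            kwargs["scenarios"] = tuple(kwargs["scenarios"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["domain_km"] = list(self.domain_km)
        d["scenarios"] = list(self.scenarios)
        return d

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode("utf8")).hexdigest()[:12]
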