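"""Model calibration: Sobol screening, SIR, and the empirical bias model.

The calibration chain mirrors how process models are prepared for inventory
use: a global sensitivity screen selects the parameters worth calibrating,
sampling importance resampling (SIR) approximates their posterior from site
measurements, and a linear mixed-effects bias model maps simulated SOC onto
measured SOC with site/region random intercepts, supplying the structural
uncertainty term used inside the Monte Carlo.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.special import logsumexp

SOBOL_SELECT_THRESHOLD = 0.025


class DegenerateLikelihoodError(RuntimeError):
    """All importance weights underflowed to zero."""


# ---------------------------------------------------------------------------
# Sobol total-order indices (Saltelli sampling, Jansen estimator)
# ---------------------------------------------------------------------------

@dataclass
class SensitivityResult:
    param_name: str
    total_index: float
    selected: bool


def sobol_total_indices(
    model_fn,
    param_ranges: dict[str, tuple[float, float]],
    n_base: int = 1024,
    seed: int = 0,
    threshold: float = SOBOL_SELECT_THRESHOLD,
) -> list[SensitivityResult]:
    """Total-order Sobol indices via Saltelli's A/B/AB design.

    ``model_fn`` receives an (m, k) array of parameter vectors (columns in
    the order of ``param_ranges``) and returns m outputs.  The Jansen
    estimator S_Ti = E[(f(A) - f(AB_i))^2] / (2 Var f) is used; parameters
    with S_Ti above ``threshold`` are flagged selected.
    """
    if n_base < 64:
        raise ValueError("n_base must be >= 64")
    names = list(param_ranges)
    lo = np.array([param_ranges[p][0] for p in names], dtype=float)
    hi = np.array([param_ranges[p][1] for p in names], dtype=float)
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
        raise ValueError("parameter ranges must be finite")
    k = len(names)
    rng = np.random.default_rng(seed)
    A = lo + (hi - lo) * rng.random((n_base, k))
    B = lo + (hi - lo) * rng.random((n_base, k))

    def evaluate(X):
        y = np.asarray(model_fn(X), dtype=float).ravel()
        if y.shape != (X.shape[0],):
            raise ValueError("model_fn must return one output per row")
        if not np.all(np.isfinite(y)):
            bad = X[~np.isfinite(y)][0]
            raise RuntimeError(f"non-finite model output at parameters {bad.tolist()}")
        return y

    fA = evaluate(A)
    fB = evaluate(B)
    var = np.var(np.concatenate([fA, fB]), ddof=0)
    results = []
    for i, name in enumerate(names):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        fABi = evaluate(ABi)
        sti = float(np.mean((fA - fABi) ** 2) / (2.0 * var)) if var > 0 else 0.0
        results.append(SensitivityResult(name, sti, sti > threshold))
    return results


def sensitivity_table(results: list[SensitivityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"param_name": r.param_name, "total_index": r.total_index, "selected": r.selected}
         for r in results]
    )


# ---------------------------------------------------------------------------
# Sampling importance resampling
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSample:
    """SIR posterior approximation.

    ``prior_draws``/``weights`` are the importance sample (weights normalised
    to 1); ``draws`` is the equal-weight resampled set; ``map_estimate`` is
    the resampled particle with the highest posterior weight.
    """

    prior_draws: np.ndarray
    weights: np.ndarray
    draws: np.ndarray
    map_estimate: np.ndarray
    effective_sample_size: float


def sir_calibrate(
    prior_sampler,
    loglik_fn,
    n_prior: int = 10000,
    n_resample: int = 1000,
    seed: int = 0,
) -> PosteriorSample:
    """Sampling importance resampling.

    Draw ``n_prior`` particles from ``prior_sampler(n, rng)``, weight by the
    normalised likelihood (log-sum-exp stabilised), and resample
    ``n_resample`` particles with replacement.  Particles whose output
    matches the measurements more closely carry higher weight and are more
    likely to survive the resampling step.
    """
    if n_resample > n_prior:
        raise ValueError("n_resample must be <= n_prior")
    rng = np.random.default_rng(seed)
    draws = np.atleast_2d(np.asarray(prior_sampler(n_prior, rng), dtype=float))
    if draws.shape[0] != n_prior:
        draws = draws.T
    logw = np.asarray(loglik_fn(draws), dtype=float).ravel()
    logw = np.where(np.isnan(logw), -np.inf, logw)
    lse = logsumexp(logw)
    if not np.isfinite(lse):
        raise DegenerateLikelihoodError("all importance weights are zero")
    w = np.exp(logw - lse)
    ess = float(1.0 / np.sum(w**2))
    idx = rng.choice(n_prior, size=n_resample, replace=True, p=w)
    resampled = draws[idx]
    map_idx = idx[np.argmax(w[idx])]
    return PosteriorSample(
        prior_draws=draws,
        weights=w,
        draws=resampled,
        map_estimate=draws[map_idx].copy(),
        effective_sample_size=ess,
    )


# ---------------------------------------------------------------------------
# Bias model (linear mixed effects)
# ---------------------------------------------------------------------------

@dataclass
class BiasModel:
    """Linear map from simulated to measured SOC with uncertainty.

    measured = beta0 + beta1 * simulated (+ covariates) + site + region + e.
    ``beta_cov`` is the sampling covariance of the fixed effects;
    ``sigma_*`` are random-effect and residual standard deviations.
    """

    beta: np.ndarray
    beta_names: list[str]
    beta_cov: np.ndarray
    sigma_site: float
    sigma_region: float
    sigma_resid: float

    @property
    def prediction_sd(self) -> float:
        return float(np.sqrt(self.sigma_site**2 + self.sigma_region**2 + self.sigma_resid**2))

    @property
    def slope(self) -> float:
        return float(self.beta[self.beta_names.index("simulated_soc")])

    @property
    def intercept(self) -> float:
        return float(self.beta[self.beta_names.index("Intercept")])

    @classmethod
    def identity(cls) -> "BiasModel":
        return cls(
            beta=np.array([0.0, 1.0]),
            beta_names=["Intercept", "simulated_soc"],
            beta_cov=np.zeros((2, 2)),
            sigma_site=0.0,
            sigma_region=0.0,
            sigma_resid=0.0,
        )

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.tolist(),
            "beta_names": list(self.beta_names),
            "beta_cov": self.beta_cov.tolist(),
            "sigma_site": self.sigma_site,
            "sigma_region": self.sigma_region,
            "sigma_resid": self.sigma_resid,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BiasModel":
        return cls(
            beta=np.asarray(d["beta"], dtype=float),
            beta_names=list(d["beta_names"]),
            beta_cov=np.asarray(d["beta_cov"], dtype=float),
            sigma_site=float(d["sigma_site"]),
            sigma_region=float(d["sigma_region"]),
            sigma_resid=float(d["sigma_resid"]),
        )


def fit_bias_model(calibration_sites: pd.DataFrame, covariates: list[str] | None = None) -> BiasModel:
    """REML fit of measured ~ simulated SOC with site and region random
    intercepts (site nested in region as a variance component).

    Falls back to a site-only random intercept, with a warning, when the
    two-level fit fails or yields non-identifiable components; a perfect
    (noise-free) fit degenerates gracefully to the OLS solution.
    """
    df = calibration_sites.copy()
    if df["site_id"].nunique() < 3:
        raise ValueError("need >= 3 sites")
    covariates = covariates or []
    fixed = "measured_soc ~ simulated_soc" + "".join(f" + {c}" for c in covariates)

    def _extract(result, sigma_region):
        fe = result.fe_params
        names = list(fe.index)
        cov = np.asarray(result.cov_params().loc[names, names], dtype=float)
        vc = getattr(result, "vcomp", np.array([]))
        sigma_site = float(np.sqrt(max(vc[0], 0.0))) if vc.size else float(
            np.sqrt(max(np.asarray(result.cov_re)[0, 0], 0.0))
        )
        return BiasModel(
            beta=fe.to_numpy(),
            beta_names=names,
            beta_cov=cov,
            sigma_site=sigma_site,
            sigma_region=sigma_region,
            sigma_resid=float(np.sqrt(max(result.scale, 0.0))),
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(
                fixed, df, groups="region_id", re_formula="1",
                vc_formula={"site": "0 + C(site_id)"},
            )
            result = model.fit(reml=True)
            sigma_region = float(np.sqrt(max(np.asarray(result.cov_re)[0, 0], 0.0)))
            bm = _extract(result, sigma_region)
            if np.all(np.isfinite(bm.beta)) and np.all(np.isfinite(bm.beta_cov)):
                return bm
        except Exception:
            pass
        warnings.warn("two-level random-effects fit failed; falling back to site-only", stacklevel=2)
        try:
            model = smf.mixedlm(fixed, df, groups="site_id", re_formula="1")
            result = model.fit(reml=True)
            fe = result.fe_params
            names = list(fe.index)
            cov = np.asarray(result.cov_params().loc[names, names], dtype=float)
            return BiasModel(
                beta=fe.to_numpy(),
                beta_names=names,
                beta_cov=cov,
                sigma_site=float(np.sqrt(max(np.asarray(result.cov_re)[0, 0], 0.0))),
                sigma_region=0.0,
                sigma_resid=float(np.sqrt(max(result.scale, 0.0))),
            )
        except Exception:
            # perfectly collinear / zero-noise data: plain least squares
            ols = smf.ols(fixed, df).fit()
            names = list(ols.params.index)
            return BiasModel(
                beta=ols.params.to_numpy(),
                beta_names=names,
                beta_cov=np.asarray(ols.cov_params().loc[names, names], dtype=float),
                sigma_site=0.0,
                sigma_region=0.0,
                sigma_resid=float(np.sqrt(max(ols.mse_resid, 0.0))) if ols.df_resid > 0 else 0.0,
            )


def adjust_prediction(
    simulated_soc,
    covariates: dict[str, np.ndarray] | None,
    bias_model: BiasModel,
    param_draw: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Apply the bias model's linear predictor to simulated SOC.

    ``param_draw`` substitutes a fixed-effect vector (e.g. sampled from
    Normal(beta, beta_cov)) for the point estimate.  Returns the adjusted
    values and the total prediction s.d. (site + region + residual).
    """
    beta = bias_model.beta if param_draw is None else np.asarray(param_draw, dtype=float)
    if beta.shape != bias_model.beta.shape:
        raise ValueError("param_draw shape does not match the fitted coefficients")
    sim = np.asarray(simulated_soc, dtype=float)
    out = np.zeros_like(sim)
    for name, b in zip(bias_model.beta_names, beta):
        if name == "Intercept":
            out = out + b
        elif name == "simulated_soc":
            out = out + b * sim
        else:
            if not covariates or name not in covariates:
                raise ValueError(f"missing covariate {name!r}")
            out = out + b * np.asarray(covariates[name], dtype=float)
    return out, bias_model.prediction_sd


def draw_fixed_effects(bias_model: BiasModel, rng: np.random.Generator) -> np.ndarray:
    """One draw from Normal(beta, beta_cov); exact beta when the covariance
    is identically zero (degenerate case)."""
    if not np.any(bias_model.beta_cov):
        return bias_model.beta.copy()
    L = np.linalg.cholesky(bias_model.beta_cov + 1e-12 * np.eye(len(bias_model.beta)))
    return bias_model.beta + L @ rng.standard_normal(len(bias_model.beta))
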