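"""Metropolis MCMC estimation of radiosensitivity parameters.

The sampled parameter vector is θ = (α0, β0, a+c, 1/σ), where σ is the
standard deviation of the measurement noise on −ln S.  The likelihood
of a survival record (D_i, Ḋ_i, y*_i, S_exp_i) is Gaussian in −ln S:

    P(d|θ) = Π_i (2πσ²)^{-1/2} exp[ −(−ln S_exp,i + ln S_mod,i)² / 2σ² ],

with S_mod from the constant-rate kinetic model at the record's dose,
dose rate and quality.  Sampling is plain random-walk Metropolis with
per-parameter Gaussian proposals whose widths are adapted during
burn-in (toward a 20–50% acceptance rate) and then frozen, so the
post-burn-in chain targets the exact posterior.  Zero-truncation of the
parameters is enforced through the prior support.

Sequential (empirical-Bayes style) updating across cell lines is done by
turning one chain's posterior marginal into a zero-truncated normal
prior for the next fit — the route by which a well-measured repair rate
from one cell line informs the others.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import GY_PER_MIN_TO_GY_PER_H, CellLineParams, protraction_factor
from .microdosimetry import DomainGeometry
from .core import gamma_factor

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalDataset",
    "PriorSpec",
    "PosteriorSet",
    "default_priors",
    "log_likelihood",
    "metropolis_fit",
    "update_with_posterior",
]

PARAM_NAMES = ("alpha0", "beta0", "repair_rate", "inv_sigma")

REQUIRED_COLUMNS = ("dose_Gy", "dose_rate_Gy_per_min", "surviving_fraction", "quality")


@dataclass
class SurvivalDataset:
    """Clonogenic survival records with their delivery conditions.

    ``data`` columns: dose_Gy, dose_rate_Gy_per_min, surviving_fraction,
    quality (label), optional sd.  ``quality_map`` resolves each label to
    a y* value in keV/μm.  An empty dataset is allowed (prior-only
    sampling); otherwise at least 4 records are needed to fit.
    """

    data: pd.DataFrame
    quality_map: dict[str, float]
    provenance: str = ""
    geom: DomainGeometry = field(default_factory=DomainGeometry)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"survival dataset missing columns: {missing}")
        if len(df):
            if (df["dose_Gy"] < 0).any():
                raise ValueError("doses must be non-negative")
            if (df["dose_rate_Gy_per_min"] <= 0).any():
                raise ValueError("dose rates must be positive")
            sf = df["surviving_fraction"]
            if ((sf <= 0) | (sf > 1)).any():
                raise ValueError("surviving fractions must lie in (0, 1]")
            unknown = set(df["quality"]) - set(self.quality_map)
            if unknown:
                raise ValueError(f"quality labels without a y* mapping: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.data)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(dose Gy, dose rate Gy/h, γ* Gy, observed −ln S) as flat arrays.

        Cached after the first call (the dataset is treated as frozen
        once it enters a fit).
        """
        cached = getattr(self, "_arrays_cache", None)
        if cached is not None:
            return cached
        df = self.data
        dose = df["dose_Gy"].to_numpy(float)
        rate_h = df["dose_rate_Gy_per_min"].to_numpy(float) * GY_PER_MIN_TO_GY_PER_H
        gam = np.array(
            [gamma_factor(self.quality_map[q], self.geom) for q in df["quality"]]
        )
        nls_obs = -np.log(df["surviving_fraction"].to_numpy(float))
        self._arrays_cache = (dose, rate_h, gam, nls_obs)
        return self._arrays_cache


@dataclass(frozen=True)
class PriorSpec:
    """Per-parameter prior: uniform(lo, hi) or normal(mean, sd) truncated at 0."""

    kind: str  # "uniform" | "truncnormal"
    a: float  # lo or mean
    b: float  # hi or sd

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "truncnormal"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.kind == "uniform":
            if not (np.isfinite(self.a) and np.isfinite(self.b) and self.a < self.b):
                raise ValueError("uniform prior needs finite lo < hi")
        else:
            if not (np.isfinite(self.a) and self.b > 0):
                raise ValueError("truncated-normal prior needs finite mean and sd > 0")

    def in_support(self, x: float) -> bool:
        if self.kind == "uniform":
            return self.a <= x <= self.b
        return x > 0

    def logpdf(self, x: float) -> float:
        if not self.in_support(x):
            return -np.inf
        if self.kind == "uniform":
            return -np.log(self.b - self.a)
        alpha = (0.0 - self.a) / self.b
        return stats.truncnorm.logpdf(x, alpha, np.inf, loc=self.a, scale=self.b)

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "uniform":
            return float(rng.uniform(self.a, self.b))
        alpha = (0.0 - self.a) / self.b
        return float(
            stats.truncnorm.rvs(alpha, np.inf, loc=self.a, scale=self.b, random_state=rng)
        )

    @property
    def scale(self) -> float:
        """Characteristic width, used to seed proposal step sizes."""
        return (self.b - self.a) / np.sqrt(12.0) if self.kind == "uniform" else self.b

    @property
    def center(self) -> float:
        return 0.5 * (self.a + self.b) if self.kind == "uniform" else max(self.a, self.b / 2)


def default_priors() -> dict[str, PriorSpec]:
    """Weakly-informative defaults: generous uniform boxes.

    α0 ∈ [0, 3] Gy⁻¹, β0 ∈ [0, 1] Gy⁻², (a+c) ∈ [0, 50] h⁻¹,
    1/σ ∈ (0, 100].
    """
    return {
        "alpha0": PriorSpec("uniform", 0.0, 3.0),
        "beta0": PriorSpec("uniform", 0.0, 1.0),
        "repair_rate": PriorSpec("uniform", 0.0, 50.0),
        "inv_sigma": PriorSpec("uniform", 0.0, 100.0),
    }


def _model_nls(
    theta: np.ndarray,
    dose: np.ndarray,
    rate_h: np.ndarray,
    gam: np.ndarray,
) -> np.ndarray:
    a0, b0, k = theta[0], theta[1], theta[2]
    q = protraction_factor(k, dose / rate_h)
    return (a0 + gam * b0) * dose + b0 * q * dose**2


def log_likelihood(theta, dataset: SurvivalDataset) -> float:
    """Gaussian log likelihood of θ = (α0, β0, a+c, 1/σ) on −ln S."""
    theta = np.asarray(theta, float)
    inv_sigma = theta[3]
    if inv_sigma <= 0:
        raise ValueError("1/sigma must be positive")
    if len(dataset) == 0:
        return 0.0
    dose, rate_h, gam, nls_obs = dataset.arrays()
    resid = nls_obs - _model_nls(theta, dose, rate_h, gam)
    sigma = 1.0 / inv_sigma
    n = resid.size
    return float(
        -n * np.log(np.sqrt(2.0 * np.pi) * sigma) - np.sum(resid**2) / (2.0 * sigma**2)
    )


@dataclass
class PosteriorSet:
    """Post-burn-in Metropolis draws of (α0, β0, a+c, 1/σ) plus bookkeeping."""

    samples: pd.DataFrame  # columns PARAM_NAMES + "sigma"
    burn_in: int
    acceptance_rate: float
    seed: int
    proposal_widths: dict[str, float] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def param_array(self) -> np.ndarray:
        """(n, 3) array of (α0, β0, a+c) draws, for RBE propagation."""
        return self.samples[["alpha0", "beta0", "repair_rate"]].to_numpy(float)

    def summary(self) -> pd.DataFrame:
        """Mean, SD and 16th/84th percentiles per parameter."""
        cols = list(PARAM_NAMES) + ["sigma"]
        s = self.samples[cols]
        return pd.DataFrame(
            {
                "mean": s.mean(),
                "sd": s.std(ddof=1),
                "p16": s.quantile(0.16),
                "p84": s.quantile(0.84),
            }
        )

    def to_cell_line_params(self, name: str = "") -> CellLineParams:
        """Posterior means/SDs as a CellLineParams summary."""
        m = self.summary()
        return CellLineParams(
            alpha0=m.loc["alpha0", "mean"],
            beta0=m.loc["beta0", "mean"],
            repair_rate=m.loc["repair_rate", "mean"],
            alpha0_sd=m.loc["alpha0", "sd"],
            beta0_sd=m.loc["beta0", "sd"],
            repair_rate_sd=m.loc["repair_rate", "sd"],
            name=name,
        )


def metropolis_chain(
    log_post,
    x0: np.ndarray,
    widths: np.ndarray,
    n_samples: int,
    burn_in: int,
    rng: np.random.Generator,
    adapt: bool = True,
    adapt_window: int = 50,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Adaptive random-walk Metropolis, frozen after burn-in.

    Burn-in proceeds in two phases: component-wise Gaussian proposals
    whose per-coordinate widths are rescaled every ``adapt_window``
    sweeps toward a 20–50% acceptance rate (robust localisation of the
    posterior), then — once the chain is in the bulk — the second half
    of burn-in records states from which an empirical covariance is
    built.  The retained chain uses a frozen joint Gaussian proposal
    with covariance ``2.38²/d · Σ̂`` (the standard random-walk scaling),
    which captures posterior correlations and shortens autocorrelation
    times; with too little burn-in to estimate Σ̂ the component-wise
    kernel is kept throughout.  Candidates are accepted when a uniform
    draw falls below the posterior ratio.  Returns (post-burn-in
    samples, post-burn-in acceptance rate, final widths).
    """
    x = np.asarray(x0, float).copy()
    widths = np.asarray(widths, float).copy()
    lp = log_post(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has zero posterior density")
    dim = x.size
    out = np.empty((n_samples, dim))
    accepted_post = 0
    window_accepts = np.zeros(dim)
    cov_states: list[np.ndarray] = []
    cov_from = burn_in // 2
    chol: np.ndarray | None = None
    for t in range(burn_in + n_samples):
        if chol is None:
            for j in range(dim):
                cand = x.copy()
                cand[j] += widths[j] * rng.standard_normal()
                lp_cand = log_post(cand)
                if np.log(rng.uniform()) < lp_cand - lp:
                    x, lp = cand, lp_cand
                    window_accepts[j] += 1
                    if t >= burn_in:
                        accepted_post += 1
            if adapt and t < burn_in and (t + 1) % adapt_window == 0:
                rates = window_accepts / adapt_window
                widths[rates < 0.2] *= 0.5
                widths[rates > 0.5] *= 2.0
                window_accepts[:] = 0.0
        else:
            cand = x + chol @ rng.standard_normal(dim)
            lp_cand = log_post(cand)
            if np.log(rng.uniform()) < lp_cand - lp:
                x, lp = cand, lp_cand
                accepted_post += 1
        if t < burn_in:
            if adapt and t >= cov_from:
                cov_states.append(x.copy())
            if t == burn_in - 1 and len(cov_states) >= 10 * dim:
                cov = np.cov(np.asarray(cov_states).T)
                cov += 1e-12 * np.eye(dim) * max(np.trace(cov), 1.0)
                try:
                    chol = np.linalg.cholesky(cov) * (2.38 / math.sqrt(dim))
                except np.linalg.LinAlgError:
                    chol = None
        else:
            out[t - burn_in] = x
    denom = n_samples if chol is not None else n_samples * dim
    acc = accepted_post / max(denom, 1)
    return out, acc, widths


def metropolis_fit(
    dataset: SurvivalDataset,
    priors: dict[str, PriorSpec] | None = None,
    n_samples: int = 10_000,
    burn_in: int = 1_000,
    seed: int | None = None,
) -> PosteriorSet:
    """Fit (α0, β0, a+c, 1/σ) to a survival dataset by Metropolis MCMC.

    Defaults follow the standard protocol for this model family: 10⁴
    retained draws after a burn-in of 10³.  ``seed`` is required for
    reproducibility; the same seed gives a bit-identical chain.
    """
    if seed is None:
        raise ValueError("seed is required for a reproducible chain")
    if 0 < len(dataset) < 4:
        raise ValueError("at least 4 records are required to fit")
    priors = priors or default_priors()
    prior_list = [priors[name] for name in PARAM_NAMES]

    def log_post(theta: np.ndarray) -> float:
        lp = 0.0
        for p, x in zip(prior_list, theta):
            lpx = p.logpdf(x)
            if not np.isfinite(lpx):
                return -np.inf
            lp += lpx
        if theta[3] <= 0:
            return -np.inf
        return lp + log_likelihood(theta, dataset)

    rng = np.random.default_rng(seed)
    x0 = np.array([p.center for p in prior_list])
    if x0[3] <= 0:
        x0[3] = 1.0
    widths = np.array([0.25 * p.scale for p in prior_list])
    samples, acc, widths = metropolis_chain(
        log_post, x0, widths, n_samples, burn_in, rng
    )
    if not 0.05 <= acc <= 0.8:
        warnings.warn(
            f"Metropolis acceptance rate {acc:.3f} outside [0.05, 0.8] after adaptation",
            RuntimeWarning,
        )
    df = pd.DataFrame(samples, columns=list(PARAM_NAMES))
    df["sigma"] = 1.0 / df["inv_sigma"]
    return PosteriorSet(
        samples=df,
        burn_in=burn_in,
        acceptance_rate=acc,
        seed=seed,
        proposal_widths=dict(zip(PARAM_NAMES, widths)),
    )


def update_with_posterior(source: PosteriorSet, which: str) -> PriorSpec:
    """Posterior marginal of one fit → zero-truncated-normal prior for the next.

    E.g. a repair-rate posterior of 8.857 ± 2.175 h⁻¹ becomes the
    (a+c) prior when fitting a related cell line.
    """
    if which not in PARAM_NAMES:
        raise ValueError(f"unknown parameter {which!r}")
    m = source.summary()
    mean, sd = float(m.loc[which, "mean"]), float(m.loc[which, "sd"])
    if sd <= 0:
        raise ValueError("degenerate posterior (sd = 0) cannot form a prior")
    return PriorSpec("truncnormal", mean, sd)
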