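"""Hierarchical linear trend across learning trials.

The model is the brms-style random-intercept/random-slope regression

    y_ij = (beta0 + b0_i) + (beta1 + b1_i) * seq_j + eps_ij
    (b0_i, b1_i) ~ N(0, Sigma),   eps_ij ~ N(0, sigma^2)

with trial index ``seq`` coded from 0 so the intercept is the first-trial
level.  Priors: Normal(0, 10) on the betas, Half-Cauchy(0, 2) on the
group-level SDs and (by symmetry) on the residual SD, uniform on the
intercept-slope correlation.

Sampling: the subject effects are marginalized analytically
(y_i ~ N(X beta, sigma^2 I + X Sigma X')), leaving a 6-parameter posterior
over (beta0, beta1, log sd_b0, log sd_b1, atanh rho, log sigma) that an
affine-invariant ensemble sampler (emcee) explores efficiently.  Several
independent ensembles play the role of chains and split-R-hat is computed
across them; R-hat > 1.05 flags non-convergence (reported, never silently
swallowed).  A slope is flagged significant when its 95% credible interval
excludes 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import emcee
import numpy as np
import pandas as pd

__all__ = [
    "TrendPriors",
    "SamplerConfig",
    "ParamSummary",
    "TrendFit",
    "fit_trend",
    "ConvergenceWarning",
]

PARAM_NAMES = ["beta0", "beta1", "sd_b0", "sd_b1", "corr_b0b1", "sigma"]
_LOG_SD_BOUNDS = (-18.0, 8.0)
_Z_BOUND = 12.0


class ConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class TrendPriors:
    beta_sd: float = 10.0
    sd_scale: float = 2.0  # Half-Cauchy scale for group-level SDs
    sigma_scale: float = 2.0  # Half-Cauchy scale for the residual SD


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC settings; ``n_iter`` includes ``n_warmup`` discarded steps."""

    n_chains: int = 4
    n_iter: int = 4000
    n_warmup: int = 2000
    n_walkers: int = 16
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_warmup >= self.n_iter:
            raise ValueError("n_warmup must be smaller than n_iter")
        if self.n_walkers < 14:  # emcee needs > 2 * ndim
            raise ValueError("n_walkers must be >= 14 for the 6-d posterior")


#: reduced preset for tests and repeated recovery studies
FAST_SAMPLER = SamplerConfig(n_chains=2, n_iter=1000, n_warmup=500)


@dataclass
class ParamSummary:
    mean: float
    ci_low: float
    ci_high: float

    @property
    def excludes_zero(self) -> bool:
        return self.ci_low > 0.0 or self.ci_high < 0.0


@dataclass
class TrendFit:
    beta0: ParamSummary
    beta1: ParamSummary
    sd_b0: ParamSummary
    sd_b1: ParamSummary
    corr_b0b1: ParamSummary
    sigma: ParamSummary
    rhat: dict = field(default_factory=dict)
    converged: bool = True
    n_chains: int = 0
    n_iter: int = 0
    n_warmup: int = 0

    @property
    def slope_significant(self) -> bool:
        """95% credible interval of the population slope excludes 0."""
        return self.beta1.excludes_zero

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name in PARAM_NAMES:
            p: ParamSummary = getattr(self, name)
            rows.append(
                {
                    "parameter": name,
                    "mean": p.mean,
                    "ci_low": p.ci_low,
                    "ci_high": p.ci_high,
                    "rhat": self.rhat.get(name, np.nan),
                }
            )
        return pd.DataFrame(rows)


def _log_posterior_factory(Y: np.ndarray, x: np.ndarray, priors: TrendPriors):
    """Vectorized log posterior over walker batches.

    ``Y`` is (n_subjects, n_trials); ``x`` the common trial coding.  Subject
    effects are integrated out with the Woodbury identity on the 2x2
    random-effect covariance.
    """
    n_subj, n_t = Y.shape
    g00, g01, g11 = float(n_t), float(x.sum()), float((x**2).sum())
    sy0 = Y.sum(axis=1)
    sy1 = Y @ x
    yy = (Y**2).sum(axis=1)

    def log_prob(theta: np.ndarray) -> np.ndarray:
        th = np.atleast_2d(theta)
        b0, b1, ls0, ls1, z, lsg = (th[:, i] for i in range(6))
        out = np.full(len(th), -np.inf)
        ok = (
            (ls0 > _LOG_SD_BOUNDS[0]) & (ls0 < _LOG_SD_BOUNDS[1])
            & (ls1 > _LOG_SD_BOUNDS[0]) & (ls1 < _LOG_SD_BOUNDS[1])
            & (lsg > _LOG_SD_BOUNDS[0]) & (lsg < _LOG_SD_BOUNDS[1])
            & (np.abs(z) < _Z_BOUND)
        )
        if not np.any(ok):
            return out if theta.ndim > 1 else out[0]
        b0, b1, ls0, ls1, z, lsg = (v[ok] for v in (b0, b1, ls0, ls1, z, lsg))
        sd0, sd1, sig = np.exp(ls0), np.exp(ls1), np.exp(lsg)
        rho = np.tanh(z)
        sig2 = sig**2
        S00, S11 = sd0**2, sd1**2
        S01 = rho * sd0 * sd1
        err = np.errstate(all="ignore")
        err.__enter__()
        # M = sigma^2 I + Sigma G  (2x2 per walker)
        M00 = sig2 + S00 * g00 + S01 * g01
        M01 = S00 * g01 + S01 * g11
        M10 = S01 * g00 + S11 * g01
        M11 = sig2 + S01 * g01 + S11 * g11
        detM = M00 * M11 - M01 * M10
        # K = M^{-1} Sigma, symmetrized
        k00 = (M11 * S00 - M01 * S01) / detM
        k11 = (-M10 * S01 + M00 * S11) / detM
        k01 = 0.5 * ((M11 * S01 - M01 * S11) + (-M10 * S00 + M00 * S01)) / detM
        logdetV = (n_t - 2) * np.log(sig2) + np.log(detM)
        # residual cross-products per (walker, subject)
        w0 = sy0[None, :] - (g00 * b0 + g01 * b1)[:, None]
        w1 = sy1[None, :] - (g01 * b0 + g11 * b1)[:, None]
        rr = (
            yy[None, :]
            - 2.0 * (b0[:, None] * sy0[None, :] + b1[:, None] * sy1[None, :])
            + (g00 * b0**2 + 2.0 * g01 * b0 * b1 + g11 * b1**2)[:, None]
        )
        quad = (
            rr - (k00[:, None] * w0**2 + 2.0 * k01[:, None] * w0 * w1
                  + k11[:, None] * w1**2)
        ) / sig2[:, None]
        # the quadratic form is PSD; clamp rounding-induced negatives
        quad = np.maximum(quad, 0.0)
        loglik = -0.5 * (
            n_subj * (n_t * np.log(2.0 * np.pi) + logdetV) + quad.sum(axis=1)
        )
        loglik = np.where(np.isfinite(loglik) & (detM > 0), loglik, -np.inf)
        err.__exit__(None, None, None)
        # priors: Normal(0, beta_sd) betas; Half-Cauchy SDs sampled on the log
        # scale (Jacobian = sd); uniform correlation via z = atanh(rho)
        def log_half_cauchy(s, scale):
            return np.log(2.0 / (np.pi * scale)) - np.log1p((s / scale) ** 2)

        logprior = (
            -0.5 * (b0**2 + b1**2) / priors.beta_sd**2
            + log_half_cauchy(sd0, priors.sd_scale) + ls0
            + log_half_cauchy(sd1, priors.sd_scale) + ls1
            + log_half_cauchy(sig, priors.sigma_scale) + lsg
            + np.log1p(-rho**2)  # d rho / d z = 1 - rho^2
        )
        out[ok] = loglik + logprior
        return out if theta.ndim > 1 else out[0]

    return log_prob


def _init_walkers(
    Y: np.ndarray, x: np.ndarray, n_walkers: int, rng: np.random.Generator
) -> np.ndarray:
    """Start walkers near the per-subject OLS summary, jittered."""
    n_subj, n_t = Y.shape
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    b0s, b1s = coef
    resid = Y.T - X @ coef
    sig = max(float(np.std(resid)), 1e-4)
    center = np.array(
        [
            float(np.mean(b0s)),
            float(np.mean(b1s)),
            np.log(max(float(np.std(b0s)), 1e-4)),
            np.log(max(float(np.std(b1s)), 1e-5)),
            0.0,
            np.log(sig),
        ]
    )
    scale = np.array([0.05 * sig + 1e-4, (0.05 * sig + 1e-5) / max(x.max(), 1.0),
                      0.1, 0.1, 0.2, 0.05])
    return center[None, :] + rng.normal(0, 1, (n_walkers, 6)) * scale[None, :]


def _split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat for one parameter; ``chains`` is (n_chains, n_draws)."""
    n_chains, n_draws = chains.shape
    half = n_draws // 2
    splits = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = splits.shape
    means = splits.mean(axis=1)
    W = splits.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def fit_trend(
    data: pd.DataFrame,
    metric: str | None = None,
    priors: TrendPriors = TrendPriors(),
    sampler: SamplerConfig = SamplerConfig(),
    seed=None,
) -> TrendFit:
    """Fit the hierarchical trend model to a per-trial metric series.

    ``data`` is either a tidy frame with columns ``subject_id``,
    ``trial_index`` and the metric column named by ``metric``, or a wide
    (n_subjects x n_trials) array-like.  Trial indices must start at 0.
    """
    if isinstance(data, pd.DataFrame):
        if metric is None:
            raise ValueError("metric column name required for a tidy frame")
        wide = data.pivot(index="subject_id", columns="trial_index", values=metric)
        if wide.isna().any().any():
            raise ValueError("unbalanced trial series (missing subject/trial cells)")
        x = wide.columns.to_numpy(dtype=float)
        Y = wide.to_numpy(dtype=float)
    else:
        Y = np.asarray(data, dtype=float)
        x = np.arange(Y.shape[1], dtype=float)
    if Y.shape[0] < 2:
        raise ValueError(
            "a single subject cannot identify group-level effects; use a "
            "simple linear regression instead"
        )
    if x.min() != 0.0:
        raise ValueError("trial indices must be coded starting at 0")

    if seed is None:
        seed = sampler.seed
    ss = np.random.SeedSequence(seed)
    log_prob = _log_posterior_factory(Y, x, priors)
    keep = sampler.n_iter - sampler.n_warmup
    all_chains = []  # per chain: (keep * n_walkers, 6)
    for chain_seed in ss.spawn(sampler.n_chains):
        rng = np.random.default_rng(chain_seed)
        p0 = _init_walkers(Y, x, sampler.n_walkers, rng)
        es = emcee.EnsembleSampler(
            sampler.n_walkers, 6, log_prob, vectorize=True
        )
        es._random = np.random.RandomState(int(chain_seed.generate_state(1)[0]))
        es.run_mcmc(p0, sampler.n_iter, progress=False)
        chain = es.get_chain(discard=sampler.n_warmup)  # (keep, n_walkers, 6)
        all_chains.append(chain.reshape(keep * sampler.n_walkers, 6))
    raw = np.stack(all_chains)  # (n_chains, draws, 6)

    # transform to the reporting scale
    out = np.empty_like(raw)
    out[..., 0] = raw[..., 0]
    out[..., 1] = raw[..., 1]
    out[..., 2] = np.exp(raw[..., 2])
    out[..., 3] = np.exp(raw[..., 3])
    out[..., 4] = np.tanh(raw[..., 4])
    out[..., 5] = np.exp(raw[..., 5])

    rhat = {
        name: _split_rhat(raw[:, :, i]) if raw.shape[0] > 1 else np.nan
        for i, name in enumerate(PARAM_NAMES)
    }
    finite_rhats = [v for v in rhat.values() if np.isfinite(v)]
    converged = all(v <= 1.05 for v in finite_rhats) if finite_rhats else True
    if not converged:
        bad = {k: round(v, 3) for k, v in rhat.items() if np.isfinite(v) and v > 1.05}
        warnings.warn(
            f"MCMC may not have converged (split-R-hat > 1.05): {bad}",
            ConvergenceWarning,
            stacklevel=2,
        )

    flat = out.reshape(-1, 6)
    summaries = {}
    for i, name in enumerate(PARAM_NAMES):
        lo, hi = np.percentile(flat[:, i], [2.5, 97.5])
        summaries[name] = ParamSummary(float(flat[:, i].mean()), float(lo), float(hi))
    return TrendFit(
        **summaries,
        rhat=rhat,
        converged=converged,
        n_chains=sampler.n_chains,
        n_iter=sampler.n_iter,
        n_warmup=sampler.n_warmup,
    )
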