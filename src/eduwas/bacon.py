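"""Empirical-Bayes estimation of bias and inflation of test statistics.

A genome-wide vector of z statistics is modelled as a three-component
Gaussian mixture:

    z_i ~ pi0 N(mu0, sigma0^2) + pi1 N(mu1, sigma1^2) + pi2 N(mu2, sigma2^2)

The centre component (identified by the ordering constraint
mu1 <= mu0 <= mu2, not by its weight) represents the null distribution of
the statistics; its mean is the systematic *bias* and its standard
deviation the *inflation* of the test statistics.  The outer components
absorb true associations, so — unlike genomic control, whose lambda rises
with any true signal — the inflation estimate stays near 1 when a
substantial fraction of sites carries real effects.

The posterior is explored by Gibbs sampling with conjugate priors
(Dirichlet on the weights, normal on the means with truncation enforcing
the ordering, inverse-gamma on the variances).  Bias and inflation are the
posterior medians of (mu0, sigma0) after burn-in.

Corrected statistics follow

    z' = (z - bias) / inflation,   se' = se * inflation,
    effect' = effect - bias * se,  p' = 2 Phi(-|z'|).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import norm

__all__ = ["BaconSettings", "BaconFit", "fit_mixture", "correct", "qq_summary"]

#: median of the chi-square(1) distribution, the genomic-control denominator
CHI2_MEDIAN = 0.4549364231195724


@dataclass(frozen=True)
class BaconSettings:
    """Sampler settings and priors.

    The mixture is only weakly identified when the data are close to a pure
    (possibly shifted/scaled) Gaussian: narrow outer components sitting just
    off-centre can absorb flank mass of the null and bias (mu0, sigma0).
    Two defaults guard against that: an informative Dirichlet prior that
    favours a dominant null component, and the ``sigma_ordering`` constraint
    sigma1, sigma2 >= sigma0 (true associations add spread on top of the
    null, so signal components should never be tighter than the null).
    Both are configurable.
    """

    n_iter: int = 5000
    burn_in: int = 2000
    seed: int = 0
    dirichlet: tuple[float, float, float] = (90.0, 5.0, 5.0)
    mu_prior_mean: tuple[float, float, float] = (0.0, -4.0, 4.0)
    mu_prior_sd: float = 2.0
    sigma2_prior_shape: float = 2.0
    sigma2_prior_scale: float = 1.0
    sigma_ordering: bool = True
    rhat_threshold: float = 1.1


@dataclass
class BaconFit:
    """Posterior summary of the three-component mixture.

    Component 0 is the null (centre) component; ``bias`` and ``inflation``
    are the posterior medians of its mean and sd.
    """

    pi: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    bias: float
    inflation: float
    settings: BaconSettings
    rhat_bias: float
    rhat_inflation: float
    converged: bool
    n_stats: int
    chain: pd.DataFrame | None = field(default=None, repr=False)

    def to_json(self, path: str | Path) -> None:
        d = {
            "pi": self.pi.tolist(), "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "bias": self.bias, "inflation": self.inflation,
            "rhat_bias": self.rhat_bias, "rhat_inflation": self.rhat_inflation,
            "converged": self.converged, "n_stats": self.n_stats,
            "settings": {"n_iter": self.settings.n_iter,
                         "burn_in": self.settings.burn_in,
                         "seed": self.settings.seed},
        }
        Path(path).write_text(json.dumps(d, indent=2))


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float = -np.inf, hi: float = np.inf) -> float:
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    if b - a < 1e-300:  # numerically degenerate window: clamp
        return float(min(max(mean, lo), hi))
    u = rng.uniform(a, b)
    return float(mean + sd * ndtri(u))


def _trunc_gamma(rng: np.random.Generator, shape: float, rate: float,
                 lo: float = 0.0, hi: float = np.inf) -> float:
    """One draw from Gamma(shape, rate) truncated to [lo, hi]."""
    from scipy.stats import gamma as _gamma
    dist = _gamma(shape, scale=1.0 / rate)
    a, b = dist.cdf(lo), dist.cdf(hi) if np.isfinite(hi) else 1.0
    if b - a < 1e-12:  # degenerate window
        return float(min(max(dist.mean(), lo), hi if np.isfinite(hi) else dist.mean()))
    return float(dist.ppf(rng.uniform(a, b)))


def _split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction of a single chain."""
    m = len(x) // 2
    if m < 2:
        return np.nan
    halves = np.stack([x[:m], x[m: 2 * m]])
    w = halves.var(axis=1, ddof=1).mean()
    b = m * halves.mean(axis=1).var(ddof=1)
    if w <= 0:
        return 1.0
    return float(np.sqrt((m - 1) / m + b / (w * m)))


def fit_mixture(z, settings: BaconSettings | None = None) -> BaconFit:
    """Fit the three-component mixture to a vector of z statistics by Gibbs
    sampling.  Warns (via the returned fit) if the split-chain diagnostic for
    bias or inflation exceeds the threshold."""
    z = np.asarray(z, dtype=float).ravel()
    if z.size == 0 or not np.all(np.isfinite(z)):
        raise ValueError("statistics must be a nonempty finite vector")
    if z.size < 1000:
        import warnings
        warnings.warn(f"only {z.size} statistics; mixture estimates may be "
                      "unstable below ~1000", stacklevel=2)
    s = settings or BaconSettings()
    rng = np.random.default_rng(s.seed)
    n = z.size

    mu = np.array([np.median(z), np.quantile(z, 0.05), np.quantile(z, 0.95)])
    mu[1] = min(mu[1], mu[0] - 1.0)
    mu[2] = max(mu[2], mu[0] + 1.0)
    sigma = np.array([max(z.std(), 0.1)] * 3)
    pi = np.array([0.9, 0.05, 0.05])

    keep = s.n_iter - s.burn_in
    chain_mu0 = np.empty(keep)
    chain_sig0 = np.empty(keep)
    chain_pi = np.empty((keep, 3))
    chain_mu = np.empty((keep, 3))
    chain_sig = np.empty((keep, 3))

    prior_prec = 1.0 / s.mu_prior_sd ** 2
    a0, b0 = s.sigma2_prior_shape, s.sigma2_prior_scale

    zcol = z[:, None]
    for it in range(s.n_iter):
        # component assignments (unnormalised Gaussian weights; the exponent
        # is capped to keep a nonzero total for extreme outliers)
        d = (zcol - mu[None, :]) / sigma[None, :]
        q = (pi / sigma)[None, :] * np.exp(-np.minimum(0.5 * d * d, 700.0))
        cum = np.cumsum(q, axis=1)
        u = rng.random(n) * cum[:, -1]
        comp = (u[:, None] > cum[:, :2]).sum(axis=1)

        counts = np.bincount(comp, minlength=3)
        sums = np.bincount(comp, weights=z, minlength=3)

        # means, with the ordering constraint enforced by truncation
        for j, (lo, hi) in ((1, (-np.inf, None)), (2, (None, np.inf)),
                            (0, (None, None))):
            prec = counts[j] / sigma[j] ** 2 + prior_prec
            mean = (sums[j] / sigma[j] ** 2
                    + s.mu_prior_mean[j] * prior_prec) / prec
            sd = 1.0 / np.sqrt(prec)
            if j == 1:
                mu[1] = _trunc_normal(rng, mean, sd, hi=mu[0])
            elif j == 2:
                mu[2] = _trunc_normal(rng, mean, sd, lo=mu[0])
            else:
                mu[0] = _trunc_normal(rng, mean, sd, lo=mu[1], hi=mu[2])

        # variances; with sigma_ordering the precisions satisfy
        # tau0 >= max(tau1, tau2), sampled from truncated Gamma conditionals
        resid_ss = np.bincount(comp, weights=(z - mu[comp]) ** 2, minlength=3)
        shapes = a0 + counts / 2.0
        rates = b0 + resid_ss / 2.0
        if s.sigma_ordering:
            tau = 1.0 / sigma ** 2
            tau[0] = _trunc_gamma(rng, shapes[0], rates[0],
                                  lo=max(tau[1], tau[2]))
            for j in (1, 2):
                tau[j] = _trunc_gamma(rng, shapes[j], rates[j], hi=tau[0])
            sigma = 1.0 / np.sqrt(tau)
        else:
            for j in range(3):
                sigma[j] = np.sqrt(rates[j] / rng.gamma(shapes[j]))

        # weights
        pi = rng.dirichlet(np.asarray(s.dirichlet) + counts)

        if it >= s.burn_in:
            t = it - s.burn_in
            chain_mu0[t] = mu[0]
            chain_sig0[t] = sigma[0]
            chain_pi[t] = pi
            chain_mu[t] = mu
            chain_sig[t] = sigma

    rb = _split_rhat(chain_mu0)
    ri = _split_rhat(chain_sig0)
    chain = pd.DataFrame({"mu0": chain_mu[:, 0], "mu1": chain_mu[:, 1],
                          "mu2": chain_mu[:, 2], "sigma0": chain_sig[:, 0],
                          "sigma1": chain_sig[:, 1], "sigma2": chain_sig[:, 2]})
    return BaconFit(
        pi=np.median(chain_pi, axis=0),
        mu=np.median(chain_mu, axis=0),
        sigma=np.median(chain_sig, axis=0),
        bias=float(np.median(chain_mu0)),
        inflation=float(np.median(chain_sig0)),
        settings=s,
        rhat_bias=rb,
        rhat_inflation=ri,
        converged=bool(np.nan_to_num(max(rb, ri), nan=np.inf)
                       <= s.rhat_threshold),
        n_stats=n,
        chain=chain,
    )


def correct(results: pd.DataFrame, fit: BaconFit) -> pd.DataFrame:
    """Bias/inflation-corrected copy of an EWAS result table.

    Requires columns effect, se, z; rewrites z, se, effect and p.
    """
    if fit.inflation <= 0:
        raise ValueError("inflation must be > 0")
    out = results.copy()
    z = (out["z"] - fit.bias) / fit.inflation
    out["effect"] = out["effect"] - fit.bias * out["se"]
    out["se"] = out["se"] * fit.inflation
    out["z"] = z
    out["p"] = np.maximum(2 * norm.sf(np.abs(z)), np.finfo(float).tiny)
    return out


def qq_summary(z) -> tuple[float, pd.DataFrame]:
    """Genomic-control lambda (median z^2 over the chi-square(1) median) and a
    decile table of |z| for reporting."""
    z = np.asarray(z, dtype=float).ravel()
    if z.size == 0:
        raise ValueError("empty statistics vector")
    lam = float(np.median(z ** 2) / CHI2_MEDIAN)
    qs = np.arange(0.1, 1.0, 0.1)
    table = pd.DataFrame({"quantile": qs, "abs_z": np.quantile(np.abs(z), qs)})
    return lam, table
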