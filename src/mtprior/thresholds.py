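"""Data-driven cutoffs: disease score threshold and variability cutoff.

Over a population of disease scores the empirical distribution is bimodal:
a low-score component of benign substitutions and a high-score component
enriched for damaging ones.  A two-component univariate normal mixture is
fitted by expectation-maximization; the Disease Score Threshold (DST) is
the lowest score at which the posterior odds of the high-mean component
over the low-mean one reach a chosen ratio (10:1 by default).  The
Nucleotide Variability Cutoff (NVC) is the third quartile of the
nucleotide variability values of the variants scoring above the DST.

The canonical values shipped in :class:`mtprior.core.Thresholds`
(DST = 0.4311, NVC = 0.0026) were derived on a large population database of
healthy mitochondrial genomes; this module recomputes thresholds for any
score population supplied by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .core import MtPriorError

__all__ = [
    "GaussianMixtureFit",
    "fit_mixture",
    "derive_dst",
    "derive_nvc",
    "equal_variance_dst",
    "DegenerateFitError",
    "NoThresholdError",
]

SIGMA_FLOOR = 1e-6


class DegenerateFitError(MtPriorError):
    pass


class NoThresholdError(MtPriorError):
    pass


@dataclass
class GaussianMixtureFit:
    """Parameters of a fitted two-component normal mixture.

    Components are sorted by mean: index 0 is the low-mean (benign-like)
    component, index 1 the high-mean one.  ``data_range`` records the
    observed value range, used as the default search grid for the DST.
    """

    pi: tuple[float, float]
    mu: tuple[float, float]
    sigma: tuple[float, float]
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    seed: int = 0
    data_range: tuple[float, float] = (0.0, 1.0)

    def posterior_odds(self, x: np.ndarray | float) -> np.ndarray | float:
        """Odds of the high-mean component against the low-mean one at x."""
        num = self.pi[1] * norm.pdf(x, self.mu[1], self.sigma[1])
        den = self.pi[0] * norm.pdf(x, self.mu[0], self.sigma[0])
        with np.errstate(divide="ignore", invalid="ignore"):
            return num / den


def _em_once(x, pi, mu, sigma, tol, max_iter):
    loglik_trace = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step in log space for numerical safety
        logp = np.stack([
            np.log(pi[k]) + norm.logpdf(x, mu[k], sigma[k]) for k in range(2)
        ])
        lognorm = logsumexp(logp, axis=0)
        resp = np.exp(logp - lognorm)
        loglik = float(lognorm.sum())
        loglik_trace.append(loglik)
        # M step
        nk = resp.sum(axis=1)
        if np.any(nk <= 0):
            raise DegenerateFitError("a component lost all responsibility")
        pi = nk / nk.sum()
        mu = (resp * x).sum(axis=1) / nk
        var = (resp * (x - mu[:, None]) ** 2).sum(axis=1) / nk
        sigma = np.sqrt(var)
        if np.any(sigma < SIGMA_FLOOR):
            raise DegenerateFitError("component standard deviation collapsed")
        if abs(loglik - prev) < tol:
            converged = True
            break
        prev = loglik
    return pi, mu, sigma, loglik_trace, converged, it


def _median_split_init(x):
    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    if len(lo) == 0 or len(hi) == 0:  # all values equal to the median
        raise DegenerateFitError("cannot median-split: no spread")
    mu = np.array([lo.mean(), hi.mean()])
    sigma = np.array([max(lo.std(), SIGMA_FLOOR * 10), max(hi.std(), SIGMA_FLOOR * 10)])
    pi = np.array([len(lo), len(hi)], dtype=float) / len(x)
    return pi, mu, sigma


def fit_mixture(
    values,
    init: tuple | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int = 0,
    max_restarts: int = 10,
) -> GaussianMixtureFit:
    """EM fit of a two-component univariate normal mixture.

    Deterministic by default: initialization splits the sample at its
    median and takes each half's moments.  ``init`` may override it as
    (pi, mu, sigma) arrays of length 2.  On degenerate collapse the fit is
    retried from seeded random initializations up to ``max_restarts`` times.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise MtPriorError(f"need at least 10 finite values, got {x.size}")
    if np.ptp(x) == 0:
        raise MtPriorError("values have zero spread")

    rng = np.random.default_rng(seed)
    attempts = []
    if init is not None:
        pi0, mu0, sigma0 = (np.asarray(a, dtype=float) for a in init)
        attempts.append((pi0, mu0, sigma0))
    else:
        attempts.append(_median_split_init(x))
    for _ in range(max_restarts):
        mu0 = rng.choice(x, size=2, replace=False)
        s0 = max(x.std() / 2, SIGMA_FLOOR * 10)
        attempts.append((np.array([0.5, 0.5]), np.sort(mu0), np.array([s0, s0])))

    last_error: Exception | None = None
    for pi0, mu0, sigma0 in attempts:
        try:
            pi, mu, sigma, trace, converged, n_iter = _em_once(
                x, pi0, mu0, sigma0, tol, max_iter
            )
        except DegenerateFitError as exc:
            last_error = exc
            continue
        order = np.argsort(mu)
        return GaussianMixtureFit(
            pi=tuple(pi[order]),
            mu=tuple(mu[order]),
            sigma=tuple(sigma[order]),
            loglik_trace=trace,
            converged=converged,
            n_iter=n_iter,
            seed=seed,
            data_range=(float(x.min()), float(x.max())),
        )
    raise DegenerateFitError(f"all EM attempts collapsed: {last_error}")


def derive_dst(
    fit: GaussianMixtureFit,
    ratio: float = 10.0,
    grid_points: int = 10001,
    value_range: tuple[float, float] | None = None,
) -> float:
    """Smallest grid value whose posterior odds for the high-mean component
    reach ``ratio`` ("this many times more probable"), i.e. odds >= ratio.

    The grid spans the observed value range of the fit (overridable); with
    equal component variances the crossing is unique and the grid estimate
    converges to the closed form within one grid step.
    """
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    lo, hi = value_range if value_range is not None else fit.data_range
    grid = np.linspace(lo, hi, grid_points)
    odds = np.asarray(fit.posterior_odds(grid))
    qualifying = np.nonzero(odds >= ratio)[0]
    if qualifying.size == 0:
        raise NoThresholdError(
            f"posterior odds never reach {ratio} on [{lo}, {hi}]"
        )
    return float(grid[qualifying[0]])


def equal_variance_dst(
    mu1: float, mu2: float, sigma: float, pi1: float, pi2: float, ratio: float = 10.0
) -> float:
    """Closed-form odds crossing for equal component variances:

    s* = (mu1+mu2)/2 + sigma^2 ln(ratio)/(mu2-mu1) + sigma^2 ln(pi1/pi2)/(mu2-mu1)
    """
    if mu2 <= mu1:
        raise ValueError("requires mu2 > mu1")
    return (
        (mu1 + mu2) / 2
        + sigma**2 * np.log(ratio) / (mu2 - mu1)
        + sigma**2 * np.log(pi1 / pi2) / (mu2 - mu1)
    )


def derive_nvc(nv_values_above_dst, quantile_rule: str = "linear") -> float:
    """Third quartile of the variability values of above-threshold variants.

    The default quantile method ("linear") matches the common statistical-
    environment default (R type 7).
    """
    x = np.asarray(list(nv_values_above_dst), dtype=float)
    if x.size == 0:
        raise MtPriorError("need at least one variability value")
    return float(np.quantile(x, 0.75, method=quantile_rule))
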