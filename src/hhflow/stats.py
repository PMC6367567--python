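"""Statistical layer: binomial compliance CIs, latent-scale ICC, kappa,
design-effect sample size.

The intracluster correlation coefficient (ICC) for a binary behavior is
computed on the log-odds scale from a univariate random-intercept logistic
model: outcome y_ij for attendant i, opportunity j follows

    logit Pr(y_ij = 1) = beta0 + u_i,    u_i ~ N(0, sigma_u^2).

Under the latent-threshold formulation the within-attendant residual variance
is pi^2/3, so

    ICC = sigma_u^2 / (sigma_u^2 + pi^2/3),

the share of latent-scale variation between attendants; 1 - ICC is the share
within attendants across opportunities. The marginal likelihood integrates
the random intercept out by adaptive Gauss-Hermite quadrature (nodes centered
and scaled at each cluster's posterior mode), which is exact in the limit of
many nodes and deterministic for a fixed order (default 21).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

LATENT_LOGISTIC_VARIANCE = math.pi**2 / 3.0
LOGIT_CAP = 10.0  # intercept cap when all outcomes are identical
DEFAULT_QUADRATURE_ORDER = 21


# ---------------------------------------------------------------------------
# Proportions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProportionEstimate:
    """A compliance proportion with a binomial confidence interval.

    ``p_hat`` is the exact fraction k/n; ``ci_low``/``ci_high`` are on the
    percent scale, matching the "% (95% CI, lo-hi; k/n)" reporting style.
    """

    k: int
    n: int
    p_hat: float
    ci_low: float
    ci_high: float
    method: str
    alpha: float

    @property
    def percent(self) -> float:
        return 100.0 * self.p_hat

    def __str__(self) -> str:
        return (
            f"{self.percent:.1f}% (95% CI, {self.ci_low:.1f}-{self.ci_high:.1f}; "
            f"{self.k}/{self.n})"
        )


def proportion_ci(
    k: int, n: int, method: str = "clopper_pearson", alpha: float = 0.05
) -> ProportionEstimate:
    """Binomial proportion with Clopper-Pearson (exact) or Wilson interval."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    sm_method = {"clopper_pearson": "beta", "wilson": "wilson"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown CI method {method!r}")
    lo, hi = proportion_confint(k, n, alpha=alpha, method=sm_method)
    return ProportionEstimate(
        k=k,
        n=n,
        p_hat=k / n,
        ci_low=100.0 * float(lo),
        ci_high=100.0 * float(hi),
        method=method,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Sample size
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleSizeSpec:
    p: float
    d: float
    alpha: float
    deff: float
    n_required: int


def sample_size_proportion(
    p: float, d: float, alpha: float = 0.05, deff: float = 1.0
) -> SampleSizeSpec:
    """Sample size to estimate a proportion from a cross-sectional survey.

    n = floor( deff * z_{1-alpha/2}^2 * p(1-p) / d^2 ), with z the exact
    normal quantile. Floor rounding reproduces conventional printed values
    (e.g. p=0.10, d=0.03, deff=2 -> 768 from 768.29).
    """
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    if d <= 0:
        raise ValueError("d must be > 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if deff < 1:
        raise ValueError("deff must be >= 1")
    z = norm.ppf(1 - alpha / 2)
    n = math.floor(deff * z**2 * p * (1 - p) / d**2)
    return SampleSizeSpec(p=p, d=d, alpha=alpha, deff=deff, n_required=n)


# ---------------------------------------------------------------------------
# Random-intercept logistic model and ICC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RandomInterceptFit:
    beta0: float
    sigma_u2: float
    loglik: float
    n_attendants: int
    n_obs: int
    converged: bool
    boundary: bool = False  # all outcomes identical; estimates at caps


@dataclass(frozen=True)
class IccResult:
    beta0: float
    sigma_u2: float
    icc: float
    ci_low: float | None
    ci_high: float | None
    n_attendants: int
    n_obs: int
    min_opportunities: int


def _cluster_stats(groups: Mapping[str, Sequence[int]]) -> np.ndarray:
    """Unique (k, n) sufficient statistics with multiplicities, as an array
    of rows (k, n, count)."""
    tally: dict[tuple[int, int], int] = {}
    for outcomes in groups.values():
        arr = [int(y) for y in outcomes]
        if any(y not in (0, 1) for y in arr):
            raise ValueError("outcomes must be binary 0/1")
        key = (sum(arr), len(arr))
        tally[key] = tally.get(key, 0) + 1
    return np.array([(k, n, c) for (k, n), c in sorted(tally.items())], dtype=float)


def _agq_loglik(
    beta0: float,
    sigma: float,
    stats: np.ndarray,
    nodes: np.ndarray,
    weights: np.ndarray,
) -> float:
    """Marginal log-likelihood via adaptive Gauss-Hermite quadrature.

    For each unique (k, n) cluster pattern the integrand
    exp(k*eta - n*log(1+e^eta)) * N(u; 0, sigma^2) is maximized by Newton
    iteration, and the quadrature grid is centered at the mode with scale from
    the curvature there.
    """
    k = stats[:, 0]
    n = stats[:, 1]
    count = stats[:, 2]
    sigma2 = sigma * sigma
    # Newton iterations for the per-pattern posterior mode of u.
    u = np.zeros_like(k)
    for _ in range(50):
        p = expit(beta0 + u)
        grad = k - n * p - u / sigma2
        hess = -n * p * (1 - p) - 1.0 / sigma2
        step = grad / hess
        u -= step
        if np.max(np.abs(step)) < 1e-10:
            break
    p = expit(beta0 + u)
    scale = 1.0 / np.sqrt(n * p * (1 - p) + 1.0 / sigma2)
    # Quadrature points u_q = mode + sqrt(2)*scale*x_q per pattern.
    uq = u[:, None] + math.sqrt(2.0) * scale[:, None] * nodes[None, :]
    eta = beta0 + uq
    log_f = k[:, None] * eta - n[:, None] * np.logaddexp(0.0, eta)
    log_phi = -0.5 * (uq**2) / sigma2 - 0.5 * math.log(2 * math.pi * sigma2)
    log_terms = np.log(weights)[None, :] + nodes[None, :] ** 2 + log_f + log_phi
    log_li = (
        math.log(math.sqrt(2.0))
        + np.log(scale)
        + logsumexp(log_terms, axis=1)
    )
    return float(np.dot(count, log_li))


def fit_random_intercept_logistic(
    groups: Mapping[str, Sequence[int]],
    quadrature_order: int = DEFAULT_QUADRATURE_ORDER,
) -> RandomInterceptFit:
    """Maximum-likelihood fit of the random-intercept logistic model.

    ``groups`` maps attendant id to that attendant's binary outcomes. The
    marginal likelihood is maximized over (beta0, log sigma) with the random
    intercept integrated out by adaptive quadrature; the result is
    deterministic for fixed data and order.
    """
    if len(groups) < 2:
        raise ValueError("need outcomes for at least 2 attendants")
    stats = _cluster_stats(groups)
    n_obs = int(stats[:, 1] @ stats[:, 2])
    n_att = int(stats[:, 2].sum())
    k_tot = int(stats[:, 0] @ stats[:, 2])
    if k_tot == 0 or k_tot == n_obs:
        warnings.warn(
            "all outcomes identical: between-attendant variance is 0 and the "
            "intercept is reported at its cap",
            stacklevel=2,
        )
        beta0 = -LOGIT_CAP if k_tot == 0 else LOGIT_CAP
        return RandomInterceptFit(
            beta0=beta0,
            sigma_u2=0.0,
            loglik=0.0,
            n_attendants=n_att,
            n_obs=n_obs,
            converged=True,
            boundary=True,
        )
    nodes, weights = hermgauss(quadrature_order)

    def nll(theta: np.ndarray) -> float:
        beta0, log_sigma = theta
        sigma = math.exp(min(max(log_sigma, -12.0), 5.0))
        return -_agq_loglik(beta0, sigma, stats, nodes, weights)

    p_bar = k_tot / n_obs
    x0 = np.array([math.log(p_bar / (1 - p_bar)), math.log(0.5)])
    res = minimize(
        nll,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    if not res.success:
        raise RuntimeError(
            f"random-intercept fit did not converge: {res.message} "
            f"(nit={res.nit}, x={res.x})"
        )
    beta0, log_sigma = res.x
    sigma = math.exp(min(max(log_sigma, -12.0), 5.0))
    sigma_u2 = sigma * sigma
    if sigma_u2 < 1e-8:  # boundary: no detectable between-attendant variance
        sigma_u2 = 0.0
    return RandomInterceptFit(
        beta0=float(beta0),
        sigma_u2=float(sigma_u2),
        loglik=-float(res.fun),
        n_attendants=n_att,
        n_obs=n_obs,
        converged=True,
    )


def icc_from_fit(sigma_u2: float) -> float:
    """Latent-scale ICC: sigma_u^2 / (sigma_u^2 + pi^2/3)."""
    if sigma_u2 < 0:
        raise ValueError("sigma_u2 must be >= 0")
    return sigma_u2 / (sigma_u2 + LATENT_LOGISTIC_VARIANCE)


def bootstrap_ci(
    groups: Mapping[str, Sequence[int]],
    B: int = 500,
    seed: int | None = None,
    alpha: float = 0.05,
    quadrature_order: int = DEFAULT_QUADRATURE_ORDER,
) -> tuple[float, float]:
    """Percentile parametric-bootstrap CI for the ICC.

    Resimulates outcomes from the fitted model (same cluster sizes), refits,
    and takes percentile bounds of the ICC replicates. Seeded and
    reproducible.
    """
    if B < 100:
        raise ValueError("bootstrap requires B >= 100 replicates")
    if seed is None:
        raise ValueError("bootstrap requires an explicit seed")
    fit = fit_random_intercept_logistic(groups, quadrature_order)
    sizes = [len(v) for v in groups.values()]
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(fit.sigma_u2)
    reps = []
    for _ in range(B):
        sim = {}
        for i, n_i in enumerate(sizes):
            u = rng.normal(0.0, sigma)
            y = rng.random(n_i) < expit(fit.beta0 + u)
            sim[f"a{i}"] = y.astype(int).tolist()
        k_tot = sum(sum(v) for v in sim.values())
        n_tot = sum(len(v) for v in sim.values())
        if k_tot == 0 or k_tot == n_tot:
            reps.append(0.0)
            continue
        try:
            refit = fit_random_intercept_logistic(sim, quadrature_order)
        except RuntimeError:
            continue
        reps.append(icc_from_fit(refit.sigma_u2))
    lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def filter_min_opportunities(
    groups: Mapping[str, Sequence[int]], k: int = 5
) -> dict[str, list[int]]:
    """Retain attendants contributing at least k opportunities."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return {a: list(v) for a, v in groups.items() if len(v) >= k}


def icc_analysis(
    groups: Mapping[str, Sequence[int]],
    min_opportunities: int = 5,
    bootstrap_B: int = 0,
    seed: int | None = None,
    quadrature_order: int = DEFAULT_QUADRATURE_ORDER,
) -> IccResult:
    """Filter, fit, and summarize the ICC for one behavior."""
    kept = filter_min_opportunities(groups, min_opportunities)
    fit = fit_random_intercept_logistic(kept, quadrature_order)
    icc = icc_from_fit(fit.sigma_u2)
    lo = hi = None
    if bootstrap_B:
        lo, hi = bootstrap_ci(
            kept, B=bootstrap_B, seed=seed, quadrature_order=quadrature_order
        )
    return IccResult(
        beta0=fit.beta0,
        sigma_u2=fit.sigma_u2,
        icc=icc,
        ci_low=lo,
        ci_high=hi,
        n_attendants=fit.n_attendants,
        n_obs=fit.n_obs,
        min_opportunities=min_opportunities,
    )


# ---------------------------------------------------------------------------
# Cohen's kappa
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KappaResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    po: float
    pe: float
    kappa: float | None
    n_items: int


def cohen_kappa(table: Sequence[Sequence[int]]) -> KappaResult:
    """Chance-corrected agreement between two raters from a 2x2 table.

    kappa = (po - pe) / (1 - pe) with po the observed agreement (diagonal
    share) and pe the chance agreement from the marginal products. Degenerate
    marginals (pe = 1) leave kappa undefined, reported as None.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must be a 2x2 array of non-negative integers")
    total = t.sum()
    if total < 1:
        raise ValueError("table total must be >= 1")
    po = np.trace(t) / total
    row = t.sum(axis=1) / total
    col = t.sum(axis=0) / total
    pe = float(row @ col)
    kappa = None if math.isclose(pe, 1.0) else (po - pe) / (1 - pe)
    it = tuple(tuple(int(x) for x in r) for r in np.round(t).astype(int))
    return KappaResult(table=it, po=float(po), pe=pe, kappa=kappa, n_items=int(total))
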