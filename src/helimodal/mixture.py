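"""One- and two-component Gaussian fits, BIC model selection and Bayes-factor evidence.

Model selection between the uninormal model M1 (k = 2 free parameters:
μ, σ) and the binormal model M2 (k = 5: μ1, σ1, μ2, σ2, p_r) uses the
Bayesian Information Criterion

    BIC = −2 ln L + k ln n        (lower is better),

and the BIC difference is converted to an approximate Bayes factor
F = exp((BIC1 − BIC2)/2), hence a posterior probability of the
two-component model p(M2|data) = F/(1+F) under equal prior odds. Strong
evidence for M2 requires p(M2|data) > 0.95, strong evidence for M1
requires p(M2|data) < 0.05; anything in between is reported as IE
(insufficient evidence). Mixtures with three or more components are never
fitted: with sparse distributions they over-fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logsumexp

from .io import HelicalEnsemble
from .synthetic import BinormalSpec

_LOG_2PI = math.log(2.0 * math.pi)


class DegenerateFitError(ValueError):
    """Sample variance is zero; a Gaussian MLE does not exist."""


@dataclass(frozen=True)
class GaussianFit:
    """Maximum-likelihood single-Gaussian fit (k = 2 free parameters)."""

    mu: float
    sigma: float
    loglik: float
    n: int
    k: int = 2


@dataclass(frozen=True)
class BinormalFit:
    """Best-of-restarts EM fit of the two-component mixture (k = 5)."""

    model: BinormalSpec
    loglik: float
    n: int
    converged: bool
    n_restarts_used: int
    k: int = 5


@dataclass(frozen=True)
class EvidenceResult:
    """BIC pair, Bayes-factor posterior and the M1/IE/M2 evidence label."""

    bic1: float
    bic2: float
    p_m2: float
    label: str
    fit1: GaussianFit | None = None
    fit2: BinormalFit | None = None


def _as_values(data: HelicalEnsemble | np.ndarray) -> np.ndarray:
    if isinstance(data, HelicalEnsemble):
        return data.values
    return np.asarray(data, dtype=float)


def fit_gaussian(data: HelicalEnsemble | np.ndarray) -> GaussianFit:
    """Closed-form Gaussian MLE (variance divisor n) with exact log-likelihood."""
    x = _as_values(data)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    mu = float(np.mean(x))
    var = float(np.mean((x - mu) ** 2))
    if var <= 0.0:
        raise DegenerateFitError("zero sample variance")
    sigma = math.sqrt(var)
    # At the MLE, Σ (x−μ)²/σ² = n, so the quadratic term collapses to n/2.
    loglik = -0.5 * n * (_LOG_2PI + math.log(var) + 1.0)
    return GaussianFit(mu=mu, sigma=sigma, loglik=loglik, n=n)


def _mixture_loglik(x: np.ndarray, mu1, s1, mu2, s2, p) -> float:
    la = (math.log(p) - math.log(s1) - 0.5 * _LOG_2PI
          - 0.5 * ((x - mu1) / s1) ** 2)
    lb = (math.log(1.0 - p) - math.log(s2) - 0.5 * _LOG_2PI
          - 0.5 * ((x - mu2) / s2) ** 2)
    return float(np.sum(logsumexp(np.stack([la, lb]), axis=0)))


def _em_once(
    x: np.ndarray,
    mu1: float, s1: float, mu2: float, s2: float, p: float,
    sigma_floor: float,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[float, float, float, float, float, float, bool]:
    """Run EM to convergence from one starting point; returns params + loglik."""
    n = x.size
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        # E step: responsibilities of component 1 in a numerically safe form
        la = math.log(p) - math.log(s1) - 0.5 * ((x - mu1) / s1) ** 2
        lb = math.log(1.0 - p) - math.log(s2) - 0.5 * ((x - mu2) / s2) ** 2
        r = expit(la - lb)
        w1 = float(np.sum(r))
        w2 = n - w1
        # M step with collapse guards
        p = min(max(w1 / n, 1e-3), 1.0 - 1e-3)
        if w1 > 0:
            mu1 = float(np.sum(r * x) / w1)
            s1 = math.sqrt(max(float(np.sum(r * (x - mu1) ** 2) / w1),
                               sigma_floor ** 2))
        if w2 > 0:
            mu2 = float(np.sum((1.0 - r) * x) / w2)
            s2 = math.sqrt(max(float(np.sum((1.0 - r) * (x - mu2) ** 2) / w2),
                               sigma_floor ** 2))
        ll = _mixture_loglik(x, mu1, s1, mu2, s2, p)
        if ll - prev < tol and np.isfinite(prev):
            converged = True
            prev = ll
            break
        prev = ll
    return mu1, s1, mu2, s2, p, prev, converged


def fit_binormal(
    data: HelicalEnsemble | np.ndarray,
    n_restarts: int = 4,
    seed: int = 0,
    fit_range: tuple[float, float] | None = None,
) -> BinormalFit:
    """Fit the two-component mixture by EM with deterministic seeded restarts.

    Restart 0 splits the sample at its median and uses half-sample moments;
    restarts 1..n_restarts perturb the two starting means with seeded
    Gaussian noise. The best log-likelihood over all restarts is kept and
    components are reported in ascending-mean order. A σ floor of
    1e−3 × sample SD and a p_r clamp to [1e−3, 1−1e−3] prevent the
    unbounded likelihood spikes of component collapse.

    ``fit_range`` restricts the fit to samples inside the closed interval
    (the analysis window used when a parameter's tail mixes in unrelated
    structure).
    """
    x = _as_values(data)
    if fit_range is not None:
        lo, hi = fit_range
        x = x[(x >= lo) & (x <= hi)]
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 observations inside the fit range")
    sd = float(np.std(x))
    if sd <= 0.0:
        raise DegenerateFitError("zero sample variance")
    sigma_floor = 1e-3 * sd
    med = float(np.median(x))
    lowp = x[x <= med]
    highp = x[x > med]
    if highp.size == 0:  # ties at the median can empty the upper half
        lowp, highp = x[x < med], x[x >= med]
    m1 = float(np.mean(lowp)) if lowp.size else med - sd
    m2 = float(np.mean(highp)) if highp.size else med + sd
    s1 = max(float(np.std(lowp)) if lowp.size > 1 else sd, sigma_floor)
    s2 = max(float(np.std(highp)) if highp.size > 1 else sd, sigma_floor)

    rng = np.random.default_rng(seed)
    mean = float(np.mean(x))
    # the coincident start is the nested single-Gaussian solution: keeping it
    # guarantees loglik(binormal) >= loglik(gaussian)
    starts = [(m1, s1, m2, s2, 0.5), (mean, sd, mean, sd, 0.5)]
    for _ in range(max(n_restarts, 0)):
        d1, d2 = rng.normal(scale=sd, size=2)
        starts.append((m1 + d1, sd, m2 + d2, sd, 0.5))

    best = None
    any_converged = False
    for st in starts:
        res = _em_once(x, *st, sigma_floor=sigma_floor)
        any_converged = any_converged or res[6]
        if best is None or res[5] > best[5]:
            best = res
    assert best is not None
    mu1, sig1, mu2, sig2, p, ll, _ = best
    if mu1 > mu2:  # ascending-mean convention removes label switching
        mu1, sig1, mu2, sig2, p = mu2, sig2, mu1, sig1, 1.0 - p
    model = BinormalSpec(mu1=mu1, sigma1=sig1, mu2=mu2, sigma2=sig2, p_r=p)
    return BinormalFit(model=model, loglik=ll, n=n, converged=any_converged,
                       n_restarts_used=len(starts))


def bic(loglik: float, k: int, n: int) -> float:
    """Bayesian Information Criterion, −2 ln L + k ln n (lower is better)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return -2.0 * loglik + k * math.log(n)


def bayes_posterior(bic1: float, bic2: float) -> float:
    """Posterior probability of the two-component model under equal priors.

    With Bayes factor F ≈ exp((BIC1 − BIC2)/2), returns p(M2|data) =
    F/(1+F), evaluated as a logistic in log space so large BIC gaps cannot
    overflow.
    """
    if not (np.isfinite(bic1) and np.isfinite(bic2)):
        raise ValueError("BIC values must be finite")
    return float(expit((bic1 - bic2) / 2.0))


def classify_evidence(p_m2: float, hi: float = 0.95, lo: float = 0.05) -> str:
    """Evidence label: M2 if p_m2 > hi, M1 if p_m2 < lo, IE otherwise.

    The thresholds are strict inequalities, so the boundary values
    themselves fall in IE.
    """
    if not (0.0 <= p_m2 <= 1.0):
        raise ValueError("p_m2 must lie in [0, 1]")
    if p_m2 > hi:
        return "M2"
    if p_m2 < lo:
        return "M1"
    return "IE"


def evidence(
    data: HelicalEnsemble | np.ndarray,
    n_restarts: int = 4,
    seed: int = 0,
    fit_range: tuple[float, float] | None = None,
    hi: float = 0.95,
    lo: float = 0.05,
) -> EvidenceResult:
    """Full evidence analysis: both fits, BIC pair, posterior and label."""
    x = _as_values(data)
    if fit_range is not None:
        lo_r, hi_r = fit_range
        x = x[(x >= lo_r) & (x <= hi_r)]
    f1 = fit_gaussian(x)
    f2 = fit_binormal(x, n_restarts=n_restarts, seed=seed)
    b1 = bic(f1.loglik, f1.k, f1.n)
    b2 = bic(f2.loglik, f2.k, f2.n)
    p = bayes_posterior(b1, b2)
    return EvidenceResult(bic1=b1, bic2=b2, p_m2=p,
                          label=classify_evidence(p, hi=hi, lo=lo),
                          fit1=f1, fit2=f2)
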