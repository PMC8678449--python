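"""Shared negative-binomial helpers: parameterizations, draws, regression.

Two overdispersion parameterizations are used, both common in count
modelling:

* ``linear``   : var = mu * (1 + phi); dispersion is phi (NB1 shape).
* ``quadratic``: var = mu * (1 + mu / k); dispersion is the size k (NB2).

Both map onto numpy's ``negative_binomial(n, p)`` with n the size parameter
and p = n / (n + mu); for the linear form the size is mu / phi (so p is
constant across means), for the quadratic form the size is k itself.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats
from statsmodels.discrete.discrete_model import NegativeBinomial as _SMNegBin
import statsmodels.api as sm

LINEAR = "linear"
QUADRATIC = "quadratic"

_DISPERSION_CAP = 1e8  # effectively Poisson


def nb_size(mean: float, dispersion: float, parameterization: str) -> float:
    """Size (number-of-failures) parameter for the given mean/dispersion."""
    if parameterization == LINEAR:
        if dispersion <= 0:
            return np.inf
        return mean / dispersion
    if parameterization == QUADRATIC:
        return dispersion
    raise ValueError(f"unknown parameterization {parameterization!r}")


def nb_draw(rng: np.random.Generator, mean, dispersion: float, parameterization: str):
    """Vectorized NB draws at per-element means; mean 0 yields count 0."""
    mu = np.asarray(mean, dtype=float)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if not pos.any():
        return out
    if parameterization == LINEAR:
        if dispersion <= 0:
            out[pos] = rng.poisson(mu[pos])
            return out
        size = mu[pos] / dispersion
        p = 1.0 / (1.0 + dispersion)
        out[pos] = rng.negative_binomial(size, p)
        return out
    if parameterization == QUADRATIC:
        k = dispersion
        if not np.isfinite(k) or k >= _DISPERSION_CAP:
            out[pos] = rng.poisson(mu[pos])
            return out
        out[pos] = rng.negative_binomial(k, k / (k + mu[pos]))
        return out
    raise ValueError(f"unknown parameterization {parameterization!r}")


def _nb_negloglik(y: np.ndarray, mu: float, size: float) -> float:
    return -float(stats.nbinom.logpmf(y, size, size / (size + mu)).sum())


def nb_mle(counts: np.ndarray, parameterization: str) -> tuple[float, float, bool]:
    """Maximum-likelihood (mean, dispersion, overdispersed?) for iid counts.

    For the quadratic (NB2) form the MLE of the mean is the sample mean and
    the size k is profiled in one dimension.  For the linear (NB1) form mean
    and phi are maximized jointly.  Samples with variance <= mean are pinned
    at the Poisson boundary (phi = 0, or k at a large cap) and flagged.
    """
    y = np.asarray(counts)
    mean = float(y.mean())
    var = float(y.var(ddof=1))
    if mean <= 0:
        raise ValueError("all-zero counts: NB mean undefined at 0")
    if var <= mean:
        pinned = 0.0 if parameterization == LINEAR else _DISPERSION_CAP
        return mean, pinned, False

    if parameterization == QUADRATIC:
        # moment start: var = mu (1 + mu/k)
        k0 = mean**2 / (var - mean)

        def nll(log_k: float) -> float:
            return _nb_negloglik(y, mean, math_exp(log_k))

        lk0 = float(np.log(k0))
        res = optimize.minimize_scalar(
            nll, bounds=(lk0 - 8.0, lk0 + 8.0), method="bounded",
            options={"xatol": 1e-8},
        )
        k = float(np.exp(np.clip(res.x, -20, np.log(_DISPERSION_CAP))))
        return mean, k, True

    if parameterization == LINEAR:
        phi0 = var / mean - 1.0

        def nll2(params: np.ndarray) -> float:
            mu, phi = np.exp(params)
            return _nb_negloglik(y, mu, mu / phi)

        res = optimize.minimize(
            nll2, x0=np.log([mean, phi0]), method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
        mu, phi = np.exp(res.x)
        return float(mu), float(phi), True

    raise ValueError(f"unknown parameterization {parameterization!r}")


def math_exp(x: float) -> float:
    return float(np.exp(np.clip(x, -30, 30)))


def _nb_logpmf(y, mu, k):
    from scipy import special

    return (
        special.gammaln(y + k)
        - special.gammaln(k)
        - special.gammaln(y + 1)
        + k * np.log(k / (k + mu))
        + y * np.log(mu / (k + mu))
    )


# box constraints for the pair-GLMM nuisance parameters (log k, log sigma);
# estimates on a bound are treated as boundary cases when forming the SE
_LK_LO, _LK_HI = -4.0, 8.0
_LS_LO, _LS_HI = -4.0, 2.0


def _pair_laplace_nll(theta, y2, t2):
    """Negative Laplace log-likelihood of the paired NB random-intercept model.

    ``y2``/``t2`` are (n_blocks, 2) count and treatment-indicator arrays.
    theta = (intercept, treatment coef, log k, log sigma); each block carries
    a N(0, sigma^2) intercept integrated out by Laplace around its mode,
    which is found by a vectorized Newton iteration (gradient and curvature
    of the NB log-likelihood in the block effect are closed-form).
    """
    b0, bt, lk, ls = theta
    k = float(np.exp(np.clip(lk, -10, 10)))
    s2 = float(np.exp(np.clip(2 * ls, -20, 10)))
    eta = b0 + bt * t2
    b = np.zeros(y2.shape[0])
    for _ in range(40):
        mu = np.exp(np.clip(eta + b[:, None], -30, 30))
        grad = (y2 - (y2 + k) * mu / (mu + k)).sum(1) - b / s2
        curv = ((y2 + k) * k * mu / (mu + k) ** 2).sum(1) + 1 / s2
        step = np.clip(grad / curv, -2.0, 2.0)
        b = b + step
        if np.max(np.abs(step)) < 1e-9:
            break
    mu = np.exp(np.clip(eta + b[:, None], -30, 30))
    curv = ((y2 + k) * k * mu / (mu + k) ** 2).sum(1) + 1 / s2
    ll = _nb_logpmf(y2, mu, k).sum(1) - 0.5 * b * b / s2 - 0.5 * np.log(s2) - 0.5 * np.log(curv)
    return -float(ll.sum())


def nb_glmm_pair(y, treated, blocks):
    """NB2 regression with a per-block random intercept, for blocks of two.

    Returns ``(treatment_coef, se, converged)``.  The marginal likelihood is
    maximized by Nelder-Mead over (intercept, treatment, log k, log sigma)
    with the Laplace approximation above; the Wald SE comes from a
    finite-difference observed information restricted to parameters that did
    not land on a box bound (a variance component estimated at zero carries
    no curvature and would make the full information singular).
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(treated, dtype=bool)
    b = np.asarray(blocks)
    order = np.argsort(b, kind="stable")
    if y.size % 2:
        raise ValueError("paired model needs blocks of two")
    y2 = y[order].reshape(-1, 2)
    t2 = t[order].reshape(-1, 2).astype(float)
    if not np.all(t2.sum(1) == 1):
        raise ValueError("each block must contain one treated and one control plot")

    mean_c = max(float(y[~t].mean()), 0.1)
    mean_t = max(float(y[t].mean()), 0.5)
    x0 = np.array([np.log(mean_c), np.log(mean_t / mean_c), np.log(5.0), np.log(0.5)])
    res = optimize.minimize(
        _pair_laplace_nll,
        x0,
        args=(y2, t2),
        method="Nelder-Mead",
        bounds=[(None, None), (None, None), (_LK_LO, _LK_HI), (_LS_LO, _LS_HI)],
        options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 2000},
    )
    theta = res.x
    free = [0, 1]
    if _LK_LO + 1e-3 < theta[2] < _LK_HI - 1e-3:
        free.append(2)
    if _LS_LO + 1e-3 < theta[3] < _LS_HI - 1e-3:
        free.append(3)
    m = len(free)
    hess = np.zeros((m, m))
    eps = 1e-4
    for a, i in enumerate(free):
        for c, j in enumerate(free):
            if c < a:
                continue
            ei = np.zeros(4)
            ej = np.zeros(4)
            ei[i] = eps
            ej[j] = eps
            hess[a, c] = hess[c, a] = (
                _pair_laplace_nll(theta + ei + ej, y2, t2)
                - _pair_laplace_nll(theta + ei - ej, y2, t2)
                - _pair_laplace_nll(theta - ei + ej, y2, t2)
                + _pair_laplace_nll(theta - ei - ej, y2, t2)
            ) / (4 * eps * eps)
    try:
        cov = np.linalg.inv(hess)
        se = float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        return float(theta[1]), np.nan, False
    if not np.isfinite(se) or se <= 0:
        return float(theta[1]), np.nan, False
    return float(theta[1]), se, True


class NBRegressionResult:
    """Minimal NB2 regression result: coefficients, SEs, convergence flag."""

    __slots__ = ("params", "bse", "converged", "alpha")

    def __init__(self, params, bse, converged, alpha):
        self.params = np.asarray(params, dtype=float)
        self.bse = np.asarray(bse, dtype=float)
        self.converged = bool(converged)
        self.alpha = float(alpha)


def nb2_regression(y: np.ndarray, X: np.ndarray) -> NBRegressionResult:
    """Log-link NB2 regression of counts on a design matrix (MLE).

    Thin wrapper over statsmodels' NegativeBinomial MLE, warm-started from a
    Poisson GLM.  Non-convergence or unusable standard errors are reported
    via ``converged`` rather than raised, so simulation loops can tally them.
    """
    import warnings

    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    try:
        with warnings.catch_warnings(), np.errstate(all="ignore"):
            warnings.simplefilter("ignore")
            poisson = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            start = np.append(poisson.params, 0.1)
            res = _SMNegBin(y, X).fit(
                start_params=start, method="bfgs", maxiter=200, disp=0, warn_convergence=False
            )
        params = res.params[:-1]
        bse = res.bse[:-1]
        ok = bool(res.mle_retvals.get("converged", True))
        if not np.isfinite(bse).all() or (np.asarray(bse) <= 0).any():
            ok = False
        return NBRegressionResult(params, bse, ok, res.params[-1])
    except Exception:  # pragma: no cover - statsmodels failure paths vary
        k = X.shape[1]
        return NBRegressionResult(np.full(k, np.nan), np.full(k, np.nan), False, np.nan)
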