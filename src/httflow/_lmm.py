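"""Linear mixed model with two crossed random intercepts.

The driver analysis needs thousands of small (n ~ 20) fits for all-subsets
AIC ranking and the Monte-Carlo calibrations, so the model

    y = X b + Z_a u_a + Z_t u_t + e,
    u_a ~ N(0, s_a^2 I), u_t ~ N(0, s_t^2 I), e ~ N(0, s^2 I)

is fitted directly: for fixed variance ratios g_a = s_a^2/s^2 and
g_t = s_t^2/s^2 the GLS estimate of b and the profiled s^2 are closed-form,
leaving a 2-parameter optimization over (log g_a, log g_t). Both ML (for AIC
comparison) and REML (for reported coefficients) criteria are supported.
The fitter is cross-checked against statsmodels MixedLM in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.linalg import solve_triangular

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class LMMResult:
    params: np.ndarray  # fixed effects
    bse: np.ndarray
    pvalues: np.ndarray
    sigma2: float  # residual variance
    var_acting: float
    var_target: float
    llf: float
    aic: float
    n_params: int
    converged: bool
    reml: bool


def _profile(
    log_gammas: np.ndarray,
    y: np.ndarray,
    x: np.ndarray,
    za: np.ndarray,
    zt: np.ndarray,
    reml: bool,
) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Negative criterion plus (beta, cov_beta_unit, sigma2) at given ratios."""
    n, p = x.shape
    ga, gt = np.exp(log_gammas)
    v0 = np.eye(n) + ga * (za @ za.T) + gt * (zt @ zt.T)
    try:
        c = np.linalg.cholesky(v0)
    except np.linalg.LinAlgError:
        return np.inf, np.full(p, np.nan), np.full((p, p), np.nan), np.nan
    xw = solve_triangular(c, x, lower=True)
    yw = solve_triangular(c, y, lower=True)
    xtx = xw.T @ xw
    beta = np.linalg.solve(xtx, xw.T @ yw)
    resid = yw - xw @ beta
    rss = float(resid @ resid)
    logdet_v0 = 2.0 * float(np.log(np.diag(c)).sum())
    if reml:
        dof = n - p
        sigma2 = rss / dof
        sign, logdet_xtx = np.linalg.slogdet(xtx)
        ll = -0.5 * (
            dof * _LOG_2PI + dof + dof * math.log(sigma2)
            + logdet_v0 + logdet_xtx
        )
    else:
        sigma2 = rss / n
        ll = -0.5 * (n * _LOG_2PI + n + n * math.log(sigma2) + logdet_v0)
    cov_unit = np.linalg.inv(xtx)
    return -ll, beta, cov_unit, sigma2


def fit_lmm_crossed(
    y: np.ndarray,
    x: np.ndarray,
    acting: np.ndarray,
    target: np.ndarray,
    reml: bool = False,
) -> LMMResult:
    """Fit the crossed random-intercept model.

    Parameters
    ----------
    y, x:
        Response vector and fixed-effect design (include the intercept
        column explicitly).
    acting, target:
        Integer group codes of the two crossed random factors.
    reml:
        Maximize the REML criterion instead of the ML likelihood. AIC is
        only reported for ML fits (NaN under REML).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    za = _indicator(acting)
    zt = _indicator(target)

    def objective(lg: np.ndarray) -> float:
        return _profile(lg, y, x, za, zt, reml)[0]

    best = None
    for start in ([-2.0, -2.0], [1.0, 1.0]):
        res = optimize.minimize(
            objective, np.array(start), method="L-BFGS-B",
            bounds=[(-12.0, 6.0)] * 2,
            options={"maxiter": 100, "ftol": 1e-11},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    neg_ll, beta, cov_unit, sigma2 = _profile(best.x, y, x, za, zt, reml)
    if not math.isfinite(neg_ll):
        raise RuntimeError("mixed-model fit failed (singular covariance)")
    ga, gt = np.exp(best.x)
    bse = np.sqrt(np.diag(cov_unit) * sigma2)
    dof = max(n - p, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / bse
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=dof)
    k = p + 3  # fixed effects + residual variance + two variance ratios
    llf = -neg_ll
    return LMMResult(
        params=beta,
        bse=bse,
        pvalues=pvals,
        sigma2=sigma2,
        var_acting=ga * sigma2,
        var_target=gt * sigma2,
        llf=llf,
        aic=(-2.0 * llf + 2.0 * k) if not reml else float("nan"),
        n_params=k,
        converged=bool(best.success),
        reml=reml,
    )


def _indicator(codes: np.ndarray) -> np.ndarray:
    codes = np.asarray(codes)
    levels, inv = np.unique(codes, return_inverse=True)
    z = np.zeros((codes.size, levels.size))
    z[np.arange(codes.size), inv] = 1.0
    return z
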