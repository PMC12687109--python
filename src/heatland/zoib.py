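"""Zero-one inflated beta (ZOIB) regression for exposure fractions.

End-of-century exposure fractions live on [0, 1] with genuine point masses
at 0 (species untouched) and 1 (species losing their whole suitable area,
including those hitting the absorbing extinction rule before 2100). The
ZOIB model is the standard conditional mixture:

    P(y = 0)              = p0
    P(y = 1)              = (1 − p0) · q1
    f(y), y ∈ (0, 1)      = (1 − p0)(1 − q1) · Beta(y; μφ, (1 − μ)φ)

with logit links for p0, q1 and μ on a shared design matrix X and a single
log-precision log φ. The likelihood factorises into two logistic parts and
a beta part, so the joint MLE equals the three separate MLEs — used as an
independent cross-check in the test-suite (statsmodels Logit / BetaModel).

Fitting is numerical maximum likelihood (quasi-Newton BFGS) from a
deterministic start: intercepts at the logits of the empirical masses and
the interior mean, zero slopes, φ = 1. Non-convergence is flagged in the
returned report, never raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

_EPS = 1e-10


@dataclass
class ZOIBParams:
    """Coefficient blocks of the ZOIB model (one entry per design column)."""

    beta_zero: np.ndarray   # logit P(y=0)
    beta_one: np.ndarray    # logit P(y=1 | y>0)
    beta_mu: np.ndarray     # logit beta mean
    log_phi: float          # log precision

    def __post_init__(self) -> None:
        self.beta_zero = np.atleast_1d(np.asarray(self.beta_zero, float))
        self.beta_one = np.atleast_1d(np.asarray(self.beta_one, float))
        self.beta_mu = np.atleast_1d(np.asarray(self.beta_mu, float))
        if not (len(self.beta_zero) == len(self.beta_one) == len(self.beta_mu)):
            raise ValueError("coefficient blocks must have equal length")

    @property
    def n_covariates(self) -> int:
        return len(self.beta_zero)

    def pack(self) -> np.ndarray:
        return np.concatenate([self.beta_zero, self.beta_one, self.beta_mu,
                               [self.log_phi]])

    @classmethod
    def unpack(cls, theta: np.ndarray, p: int) -> "ZOIBParams":
        theta = np.asarray(theta, float)
        return cls(beta_zero=theta[:p], beta_one=theta[p:2 * p],
                   beta_mu=theta[2 * p:3 * p], log_phi=float(theta[-1]))


@dataclass
class ZOIBData:
    """Response vector in [0, 1] and matching design matrix."""

    y: np.ndarray
    X: np.ndarray
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, float)
        self.X = np.atleast_2d(np.asarray(self.X, float))
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("rows of X must match y")
        if np.any(self.y < 0) or np.any(self.y > 1):
            raise ValueError("y must lie in [0, 1]")
        if not self.names:
            self.names = tuple(f"x{j}" for j in range(self.X.shape[1]))


@dataclass
class ZOIBFit:
    params: ZOIBParams
    se: np.ndarray
    loglik: float
    converged: bool
    grad_norm: float
    boundary: bool
    n_obs: int
    names: tuple[str, ...]

    def summary(self) -> dict:
        blocks = {"zero": self.params.beta_zero,
                  "one": self.params.beta_one,
                  "mu": self.params.beta_mu}
        p = self.params.n_covariates
        se = {"zero": self.se[:p], "one": self.se[p:2 * p],
              "mu": self.se[2 * p:3 * p], "log_phi": self.se[-1]}
        return {
            "coefficients": {b: dict(zip(self.names, map(float, v)))
                             for b, v in blocks.items()},
            "log_phi": self.params.log_phi,
            "se": {b: (dict(zip(self.names, map(float, v)))
                       if b != "log_phi" else float(v))
                   for b, v in se.items()},
            "loglik": self.loglik,
            "converged": self.converged,
            "grad_norm": self.grad_norm,
            "boundary": self.boundary,
            "n_obs": self.n_obs,
        }


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -x)


def zoib_loglik(params: ZOIBParams, data: ZOIBData) -> float:
    """Log-likelihood of the ZOIB mixture."""
    X, y = data.X, data.y
    if X.shape[1] != params.n_covariates:
        raise ValueError("design matrix width does not match coefficients")
    eta0 = X @ params.beta_zero
    eta1 = X @ params.beta_one
    etam = X @ params.beta_mu
    phi = np.exp(params.log_phi)
    mu = np.clip(special.expit(etam), _EPS, 1 - _EPS)

    log_p0 = _log_sigmoid(eta0)
    log_1mp0 = _log_sigmoid(-eta0)
    log_q1 = _log_sigmoid(eta1)
    log_1mq1 = _log_sigmoid(-eta1)

    is0 = y == 0
    is1 = y == 1
    mid = ~(is0 | is1)

    ll = np.empty_like(y)
    ll[is0] = log_p0[is0]
    ll[is1] = log_1mp0[is1] + log_q1[is1]
    if mid.any():
        a = mu[mid] * phi
        b = (1 - mu[mid]) * phi
        ll[mid] = (log_1mp0[mid] + log_1mq1[mid]
                   + stats.beta.logpdf(y[mid], a, b))
    return float(ll.sum())


def zoib_score(params: ZOIBParams, data: ZOIBData) -> np.ndarray:
    """Analytic gradient of the log-likelihood wrt the packed parameters."""
    X, y = data.X, data.y
    p = params.n_covariates
    eta0 = X @ params.beta_zero
    eta1 = X @ params.beta_one
    etam = X @ params.beta_mu
    phi = np.exp(params.log_phi)
    p0 = special.expit(eta0)
    q1 = special.expit(eta1)
    mu = np.clip(special.expit(etam), _EPS, 1 - _EPS)

    is0 = y == 0
    is1 = y == 1
    mid = ~(is0 | is1)

    # d ll / d eta0: (1-p0) for zeros, -p0 otherwise
    d0 = np.where(is0, 1.0 - p0, -p0)
    # d ll / d eta1: (1-q1) for ones, -q1 for interior, 0 for zeros
    d1 = np.where(is1, 1.0 - q1, np.where(mid, -q1, 0.0))
    # beta part
    dm = np.zeros_like(y)
    dphi = 0.0
    if mid.any():
        ym, mum = y[mid], mu[mid]
        a = mum * phi
        b = (1 - mum) * phi
        star = np.log(ym) - np.log1p(-ym) - special.digamma(a) \
            + special.digamma(b)
        dm[mid] = phi * star * mum * (1 - mum)
        dphi = phi * np.sum(
            special.digamma(phi) - mum * special.digamma(a)
            - (1 - mum) * special.digamma(b)
            + mum * np.log(ym) + (1 - mum) * np.log1p(-ym))
    return np.concatenate([X.T @ d0, X.T @ d1, X.T @ dm, [dphi]])


def simulate_zoib(params: ZOIBParams, X: np.ndarray,
                  seed: int | np.random.Generator) -> np.ndarray:
    """Draw a response vector from the ZOIB mixture (reproducible)."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    X = np.atleast_2d(np.asarray(X, float))
    p0 = special.expit(X @ params.beta_zero)
    q1 = special.expit(X @ params.beta_one)
    mu = np.clip(special.expit(X @ params.beta_mu), _EPS, 1 - _EPS)
    phi = np.exp(params.log_phi)
    n = X.shape[0]
    u = rng.uniform(size=n)
    y = rng.beta(mu * phi, (1 - mu) * phi, size=n)
    # interior draws can round to exactly 0/1 in floating point; nudge them
    y = np.clip(y, _EPS, 1 - _EPS)
    y = np.where(u < p0, 0.0, np.where(u < p0 + (1 - p0) * q1, 1.0, y))
    return y


def _start_values(data: ZOIBData) -> ZOIBParams:
    p = data.X.shape[1]
    y = data.y
    frac0 = np.clip(np.mean(y == 0), 0.01, 0.99)
    nonzero = y[y > 0]
    frac1 = np.clip(np.mean(nonzero == 1) if nonzero.size else 0.5, 0.01, 0.99)
    mid = y[(y > 0) & (y < 1)]
    mu0 = np.clip(mid.mean() if mid.size else 0.5, 0.01, 0.99)
    b0 = np.zeros(p); b0[0] = special.logit(frac0)
    b1 = np.zeros(p); b1[0] = special.logit(frac1)
    bm = np.zeros(p); bm[0] = special.logit(mu0)
    return ZOIBParams(b0, b1, bm, 0.0)


def _numeric_hessian(grad, theta: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central-difference Jacobian of a gradient function at theta."""
    k = theta.size
    H = np.zeros((k, k))
    for i in range(k):
        ei = np.zeros(k); ei[i] = h
        H[i] = (grad(theta + ei) - grad(theta - ei)) / (2 * h)
    return (H + H.T) / 2


def fit_zoib(data: ZOIBData, compute_se: bool = True) -> ZOIBFit:
    """Maximum-likelihood ZOIB fit via BFGS; failures flagged, not raised."""
    p = data.X.shape[1]
    n_params = 3 * p + 1
    if len(data.y) < 5 * n_params:
        raise ValueError(
            f"need n >= {5 * n_params} observations for {n_params} parameters")
    start = _start_values(data)

    def nll(theta: np.ndarray) -> float:
        val = zoib_loglik(ZOIBParams.unpack(theta, p), data)
        return np.inf if not np.isfinite(val) else -val

    def ngrad(theta: np.ndarray) -> np.ndarray:
        return -zoib_score(ZOIBParams.unpack(theta, p), data)

    res = optimize.minimize(nll, start.pack(), jac=ngrad, method="BFGS",
                            options={"gtol": 1e-6, "maxiter": 500})
    params = ZOIBParams.unpack(res.x, p)
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
    # BFGS can report precision loss with the optimum in hand; judge
    # convergence by the scaled gradient instead of the status flag alone
    converged_opt = bool(res.success) or grad_norm < 1e-3 * max(
        1.0, abs(res.fun))

    # boundary diagnosis: fitted point masses collapsing to 0 or 1
    p0_hat = special.expit(data.X @ params.beta_zero)
    q1_hat = special.expit(data.X @ params.beta_one)
    boundary = bool(np.mean(p0_hat) > 0.999 or np.mean(p0_hat) < 0.001
                    or np.mean(q1_hat) > 0.999 or np.mean(q1_hat) < 0.001)

    se = np.full(n_params, np.nan)
    if compute_se and not boundary:
        H = _numeric_hessian(ngrad, res.x)
        try:
            cov = np.linalg.pinv(H)
            diag = np.diag(cov)
            se = np.where(diag > 0, np.sqrt(np.abs(diag)), np.nan)
        except np.linalg.LinAlgError:
            pass

    return ZOIBFit(params=params, se=se, loglik=-res.fun,
                   converged=converged_opt and not boundary,
                   grad_norm=grad_norm, boundary=boundary,
                   n_obs=len(data.y), names=data.names)


def build_design(
    log_range: np.ndarray,
    redlist: Sequence[str],
    reference: str = "LC",
    ordinal: bool = False,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Design matrix: intercept, log10 initial range area, Red List terms.

    By default Red List categories enter as unordered indicators with LC as
    the reference (categories absent from the data are dropped). With
    ``ordinal=True`` a single ordinal score column (LC=0 … CR=4, DD treated
    as missing → score of LC) is used instead.
    """
    log_range = np.asarray(log_range, float)
    n = len(log_range)
    cols = [np.ones(n), log_range]
    names = ["intercept", "log_range"]
    rl = np.asarray(redlist, dtype=object)
    if ordinal:
        scores = {"LC": 0, "NT": 1, "VU": 2, "EN": 3, "CR": 4, "DD": 0}
        cols.append(np.array([scores[c] for c in rl], float))
        names.append("redlist_score")
    else:
        for cat in ("NT", "VU", "EN", "CR", "DD"):
            if cat == reference:
                continue
            ind = (rl == cat).astype(float)
            if ind.any():
                cols.append(ind)
                names.append(f"redlist_{cat}")
    return np.column_stack(cols), tuple(names)
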