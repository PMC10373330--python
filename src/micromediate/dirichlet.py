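"""Dirichlet regression of microbial compositions on exposure and covariates.

The composition of sample ``i`` is modelled as
``M_i | (R_i, X_i) ~ Dirichlet(gamma_1(R_i, X_i), ..., gamma_J(R_i, X_i))``
with a log link on each concentration parameter::

    log gamma_j(R, X) = b0_j + bR_j R + bX_j' X

Under this law ``E[M_j] = gamma_j / sum(gamma)`` and
``E[log M_j] = psi(gamma_j) - psi(sum(gamma))`` with ``psi`` the digamma
function; the latter closed form is what the disparity decomposition
consumes.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy import linalg, optimize, special
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "DirichletParams",
    "DirichletRegression",
    "gamma_values",
    "dirichlet_loglik",
    "expected_log_abundance",
    "fit_dirichlet",
]

_MAX_LINPRED = 500.0  # exp() overflow guard on the log-concentration scale


@dataclasses.dataclass
class DirichletParams:
    """Per-taxon coefficients of the mediator model."""

    beta0: np.ndarray  # (J,)
    beta_r: np.ndarray  # (J,)
    beta_x: np.ndarray  # (J, K)
    converged: bool = True
    se: Optional[dict] = None

    def __post_init__(self):
        self.beta0 = np.asarray(self.beta0, dtype=float)
        self.beta_r = np.asarray(self.beta_r, dtype=float)
        self.beta_x = np.asarray(self.beta_x, dtype=float)
        if self.beta_x.ndim == 1:
            self.beta_x = self.beta_x[:, None] if self.beta_x.size else self.beta_x.reshape(len(self.beta0), 0)
        j = len(self.beta0)
        if self.beta_r.shape != (j,) or self.beta_x.shape[0] != j:
            raise ValueError("inconsistent coefficient dimensions")

    @property
    def n_taxa(self) -> int:
        return len(self.beta0)

    @property
    def n_covariates(self) -> int:
        return self.beta_x.shape[1]


def gamma_values(params: DirichletParams, r, x=None) -> np.ndarray:
    """Concentrations ``gamma_j = exp(b0_j + bR_j r + bX_j' x)``; all positive."""
    x = np.zeros(params.n_covariates) if x is None else np.asarray(x, dtype=float)
    lin = params.beta0 + params.beta_r * float(r) + params.beta_x @ x
    if np.any(lin > _MAX_LINPRED):
        j = int(np.argmax(lin))
        raise OverflowError(
            f"linear predictor {lin[j]:.3g} for taxon index {j} overflows exp()"
        )
    return np.exp(lin)


def expected_log_abundance(params: DirichletParams, r, x=None) -> np.ndarray:
    """``E[log M_j | R=r, X=x] = psi(gamma_j) - psi(sum_m gamma_m)``.

    Entries are strictly negative: each component of a Dirichlet vector
    is below 1 almost surely.
    """
    g = gamma_values(params, r, x)
    return special.digamma(g) - special.digamma(g.sum())


def _design(r, x):
    r = np.asarray(r, dtype=float)
    n = len(r)
    x = np.zeros((n, 0)) if x is None else np.asarray(x, dtype=float).reshape(n, -1)
    return np.hstack([np.ones((n, 1)), r[:, None], x])


def _coef_matrix(params: DirichletParams) -> np.ndarray:
    # rows: intercept, exposure, covariates; columns: taxa
    return np.vstack([params.beta0, params.beta_r, params.beta_x.T])


def _trigamma(x):
    """Vectorized psi'(x) via recurrence + asymptotic series (x > 0).

    Much faster than the generic Hurwitz-zeta route for the dense
    arrays the Newton iterations evaluate.
    """
    x = np.asarray(x, dtype=float)
    # unconditional 8-step recurrence shift into the asymptotic regime
    out = 1.0 / (x * x)
    z = x + 1.0
    for _ in range(7):
        out += 1.0 / (z * z)
        z += 1.0
    inv = 1.0 / z
    inv2 = inv * inv
    # psi'(z) ~ 1/z + 1/(2 z^2) + sum B_2k / z^(2k+1)
    out += inv * (
        1.0
        + inv * (0.5 + inv * (1.0 / 6.0 + inv2 * (-1.0 / 30.0 + inv2 * (1.0 / 42.0 + inv2 * (-1.0 / 30.0)))))
    )
    return out


def _loglik_hessian(b, d, logm):
    """Hessian of the log-likelihood in (taxon, predictor) flattening."""
    n, p = d.shape
    j = b.shape[1]
    lin = np.clip(d @ b, -_MAX_LINPRED, _MAX_LINPRED)
    gam = np.exp(lin)
    s = gam.sum(axis=1)
    g = special.digamma(s)[:, None] - special.digamma(gam) + logm
    psi1_s = _trigamma(s)
    psi1_g = _trigamma(gam)
    # off-diagonal-in-taxa part factorizes: H = F'F with F_i,(j,k) = sqrt(psi1(S_i)) gam_ij d_ik
    f = (np.sqrt(psi1_s)[:, None] * gam)[:, :, None] * d[:, None, :]
    f = f.reshape(n, j * p)
    h = f.T @ f
    diag = gam * g - gam**2 * psi1_g
    for jj in range(j):
        h[jj * p : (jj + 1) * p, jj * p : (jj + 1) * p] += d.T @ (diag[:, jj][:, None] * d)
    return h


def _loglik_terms(b, d, logm):
    lin = d @ b
    lin = np.clip(lin, -_MAX_LINPRED, _MAX_LINPRED)
    gam = np.exp(lin)
    s = gam.sum(axis=1)
    ll = (
        special.gammaln(s)
        - special.gammaln(gam).sum(axis=1)
        + ((gam - 1.0) * logm).sum(axis=1)
    )
    return ll, gam, s


def dirichlet_loglik(params: DirichletParams, data) -> float:
    """Total log-likelihood of the compositions in ``data`` under ``params``."""
    m = data.m
    if np.any(m <= 0):
        raise ValueError("compositions must be strictly positive")
    ll, _, _ = _loglik_terms(_coef_matrix(params), _design(data.r, data.x), np.log(m))
    return float(ll.sum())


class DirichletRegression(BaseEstimator):
    """Maximum-likelihood Dirichlet regression with a log link.

    ``fit(X, Y)`` takes ``X`` with columns ``[R, X_1..X_K]`` (exposure
    first) and ``Y`` the strictly positive compositions (rows on the
    simplex). Optimization is quasi-Newton (L-BFGS) with the analytic
    digamma gradient, started from a method-of-moments fit of a
    common-concentration model.

    Attributes
    ----------
    beta0_, beta_r_ : arrays (J,)
    beta_x_ : array (J, K)
    loglik_ : float
        Maximized log-likelihood.
    converged_ : bool
    """

    def __init__(
        self,
        max_iter: int = 300,
        gtol: float = 1e-6,
        compute_se: bool = False,
        method: str = "newton",
    ):
        self.max_iter = max_iter
        self.gtol = gtol
        self.compute_se = compute_se
        self.method = method

    def fit(self, X, Y, init: Optional[DirichletParams] = None):
        X = np.asarray(X, dtype=float)
        m = np.asarray(Y, dtype=float)
        if np.any(m <= 0) or np.any(np.abs(m.sum(axis=1) - 1) > 1e-6):
            raise ValueError("Y must be strictly positive compositions summing to 1")
        n, j = m.shape
        r = X[:, 0]
        xc = X[:, 1:]
        k = xc.shape[1]
        if n <= k + 2:
            raise ValueError(f"need n > K + 2 = {k + 2} samples")
        d = _design(r, xc)
        p = d.shape[1]
        logm = np.log(m)

        if init is not None:
            b0 = _coef_matrix(init)
        else:
            b0 = np.zeros((p, j))
            b0[0] = np.log(self._moment_gamma(m))

        def nll_grad(bflat):
            b = bflat.reshape(p, j)
            ll, gam, s = _loglik_terms(b, d, logm)
            g = special.digamma(s)[:, None] - special.digamma(gam) + logm
            grad = d.T @ (gam * g)
            return -ll.sum(), -grad.ravel()

        b = None
        if self.method == "newton":
            b, nll, nit, ok = self._newton(b0, d, logm)
            if not ok and nit >= self.max_iter:
                b = None  # fall through to quasi-Newton
            else:
                self.loglik_ = -nll
                self.converged_ = ok
                self.n_iter_ = nit
        if b is None:
            res = optimize.minimize(
                nll_grad,
                b0.ravel(),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": self.max_iter, "gtol": self.gtol, "ftol": 1e-12},
            )
            b = res.x.reshape(p, j)
            self.loglik_ = -float(res.fun)
            self.converged_ = bool(res.success)
            self.n_iter_ = int(res.nit)
        self.beta0_ = b[0].copy()
        self.beta_r_ = b[1].copy()
        self.beta_x_ = b[2:].T.copy()
        self.n_taxa_ = j
        self.n_features_in_ = X.shape[1]
        self.se_ = self._standard_errors(b, d, logm) if self.compute_se else None
        return self

    def _newton(self, b0, d, logm):
        """Damped Newton with the analytic Hessian; returns (b, nll, nit, ok).

        Convergence when the gradient max-norm drops below ``gtol`` or
        the relative log-likelihood change falls below 1e-9.
        """
        n, p = d.shape
        j = b0.shape[1]
        b = b0.copy()
        ll, gam, s = _loglik_terms(b, d, logm)
        nll = -float(ll.sum())
        damp = 1e-8
        it = 0
        for it in range(1, self.max_iter + 1):
            g = special.digamma(s)[:, None] - special.digamma(gam) + logm
            grad = -(d.T @ (gam * g))  # (p, j) gradient of the negative loglik
            if np.abs(grad).max() < self.gtol:
                return b, nll, it, True
            info = -_loglik_hessian(b, d, logm)
            gflat = grad.T.ravel()  # (taxon, predictor) flattening
            step = None
            for _ in range(8):
                try:
                    cf = linalg.cho_factor(info + damp * np.eye(j * p))
                    step = linalg.cho_solve(cf, gflat)
                    break
                except np.linalg.LinAlgError:
                    damp *= 100.0
            if step is None:
                return b, nll, it, False
            direction = -step.reshape(j, p).T  # back to (p, j)
            t = 1.0
            for _ in range(30):
                b_try = b + t * direction
                ll_try, gam_try, s_try = _loglik_terms(b_try, d, logm)
                nll_try = -float(ll_try.sum())
                if np.isfinite(nll_try) and nll_try <= nll:
                    break
                t *= 0.5
            else:
                return b, nll, it, False
            rel = (nll - nll_try) / max(1.0, abs(nll))
            b, nll, gam, s = b_try, nll_try, gam_try, s_try
            damp = max(damp / 10.0, 1e-10)
            if rel < 1e-9:
                return b, nll, it, True
        return b, nll, it, False

    @staticmethod
    def _moment_gamma(m: np.ndarray) -> np.ndarray:
        """Method-of-moments common-concentration estimate from pooled moments."""
        mean = m.mean(axis=0)
        var = m.var(axis=0)
        ok = (var > 1e-12) & (mean > 1e-12) & (mean < 1 - 1e-12)
        if ok.any():
            s = np.median(mean[ok] * (1 - mean[ok]) / var[ok] - 1.0)
            s = float(np.clip(s, 1e-2, 1e4))
        else:
            s = 1.0
        return np.clip(s * mean, 1e-6, None)

    def _standard_errors(self, b, d, logm):
        """SEs from the observed information (analytic Hessian)."""
        p = d.shape[1]
        j = b.shape[1]
        info = -_loglik_hessian(b, d, logm)
        try:
            cov = np.linalg.inv(info + 1e-10 * np.eye(j * p))
        except np.linalg.LinAlgError:
            return None
        se = np.sqrt(np.clip(np.diag(cov), 0, None)).reshape(j, p)
        return {"beta0": se[:, 0], "beta_r": se[:, 1], "beta_x": se[:, 2:]}

    def params_(self) -> DirichletParams:
        check_is_fitted(self, "beta0_")
        return DirichletParams(
            beta0=self.beta0_,
            beta_r=self.beta_r_,
            beta_x=self.beta_x_,
            converged=self.converged_,
            se=self.se_,
        )

    def expected_log_abundance(self, r, x=None) -> np.ndarray:
        return expected_log_abundance(self.params_(), r, x)


def fit_dirichlet(data, compute_se: bool = False, init=None, max_iter: int = 300) -> DirichletParams:
    """Fit the mediator model on a :class:`~micromediate.io.StudyData`."""
    est = DirichletRegression(compute_se=compute_se, max_iter=max_iter)
    est.fit(np.hstack([data.r[:, None], data.x]), data.m, init=init)
    return est.params_()
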