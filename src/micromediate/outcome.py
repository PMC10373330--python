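"""Linear log-contrast regression of a continuous outcome on microbiome
composition, exposure, and exposure x composition interactions.

Model::

    Y = a0 + aX' X + aR R + aM' log(M) + aC' log(M) R + eps,
    sum_j aM_j = 0,  sum_j aC_j = 0,  eps ~ N(0, sigma^2)

The sum-to-zero constraints make the fit invariant to the compositional
scale of ``M``. Unpenalized fits work in an orthonormal basis of the
(J-1)-dimensional sum-to-zero subspace; the sparse-group penalized fit
used for taxon selection runs a monotone proximal-gradient scheme whose
proximal step (L1 + sum-to-zero) is solved exactly, so selected
coefficients are exactly zero and exactly centered.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._solver import fista_sparse_group

__all__ = [
    "OutcomeParams",
    "PenaltyConfig",
    "LogContrastRegression",
    "sum_zero_basis",
    "design_matrix",
    "fit_ols",
    "fit_penalized",
    "refit_unpenalized",
]

_ZERO_TOL = 1e-10


@dataclasses.dataclass
class OutcomeParams:
    """Fitted coefficients of the outcome model (back-transformed to J-vectors)."""

    alpha0: float
    alpha_x: np.ndarray  # (K,)
    alpha_r: float
    alpha_m: np.ndarray  # (J,), sums to zero
    alpha_c: np.ndarray  # (J,), sums to zero
    sigma: float
    converged: bool = True
    se: Optional[dict] = None  # standard errors for unpenalized fits

    def __post_init__(self):
        self.alpha_x = np.atleast_1d(np.asarray(self.alpha_x, dtype=float))
        self.alpha_m = np.asarray(self.alpha_m, dtype=float)
        self.alpha_c = np.asarray(self.alpha_c, dtype=float)


@dataclasses.dataclass
class PenaltyConfig:
    """Sparse-group penalty configuration for taxon selection.

    ``lambda1`` weights the L1 norms of the composition and interaction
    coefficients; ``lambda2`` weights per-taxon group norms
    ``||(aM_j, aC_j, bR_j)||_2`` in which the mediator-model exposure
    coefficient ``bR_j`` enters as a fixed weight, so a taxon whose
    whole mediation pathway is weak is shrunk jointly.
    """

    lambda1: Optional[float] = None  # None -> data-driven grid
    lambda2: float = 0.0
    grid: Optional[Sequence] = None  # candidate (lambda1, lambda2) pairs
    criterion: str = "ebic"
    max_iter: int = 2000
    tol: float = 1e-9


def sum_zero_basis(j: int) -> np.ndarray:
    """Orthonormal basis U (j x j-1) of the sum-to-zero subspace: U'1 = 0, U'U = I."""
    if j < 2:
        raise ValueError("need at least 2 taxa")
    u = linalg.null_space(np.ones((1, j)))
    return u


def _soft(v: np.ndarray, t: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def _prox_l1_sumzero(v: np.ndarray, t: float) -> np.ndarray:
    """Exact prox of ``t * ||a||_1 + indicator(sum(a) = 0)`` at ``v``.

    Solved through the scalar dual: find mu with
    ``sum(soft(v - mu, t)) = 0``; the sum is piecewise linear in mu with
    kinks at ``v_i +- t``, so the root is located exactly by sorting.
    """
    if t == 0.0:
        return v - v.mean()
    bp = np.sort(np.concatenate([v - t, v + t]))
    z = np.abs(v - bp[:, None])
    np.subtract(z, t, out=z)
    np.maximum(z, 0.0, out=z)
    gv = np.einsum("ij,ij->i", z, np.sign(v - bp[:, None]))
    # gv is non-increasing; root bracketed by construction
    k = int(np.searchsorted(-gv, 0.0, side="right")) - 1
    k = min(max(k, 0), len(bp) - 2)
    if gv[k] <= 0.0:
        mu = bp[k]
    elif gv[k + 1] >= 0.0:
        mu = bp[k + 1]
    elif gv[k] > gv[k + 1]:
        mu = bp[k] + gv[k] * (bp[k + 1] - bp[k]) / (gv[k] - gv[k + 1])
    else:
        mu = 0.5 * (bp[k] + bp[k + 1])
    out = _soft(v - mu, t)
    # remove the O(eps) constraint residual without disturbing exact zeros
    nz = out != 0.0
    if nz.any():
        out[nz] -= out[nz].sum() / nz.sum()
    return out


class LogContrastRegression(BaseEstimator, RegressorMixin):
    """Constrained log-contrast regression with optional sparse-group penalty.

    Parameters
    ----------
    n_covariates : int
        Number of covariate columns in ``X`` (see layout below).
    lambda1, lambda2 : float
        Sparse-group penalty weights (0 gives the ordinary constrained
        least-squares fit).
    beta_r : array-like of shape (J,), optional
        Fixed exposure coefficients from the mediator model, used as
        per-taxon group weights when ``lambda2 > 0``.
    restrict : array-like of int, optional
        Indices of taxa allowed nonzero coefficients; all others are
        fixed at zero (used for post-selection refits).

    The feature matrix ``X`` has columns ``[R, X_1..X_K, M_1..M_J]``:
    exposure first, then ``n_covariates`` covariates, then the strictly
    positive composition (logged internally).

    Attributes
    ----------
    alpha0_, alpha_x_, alpha_r_, alpha_m_, alpha_c_, sigma_ :
        Fitted coefficients; ``alpha_m_`` and ``alpha_c_`` are J-vectors
        summing to zero exactly.
    selected_ : boolean array (J,)
        Taxa with a nonzero composition or interaction coefficient.
    """

    def __init__(
        self,
        n_covariates: int = 0,
        lambda1: float = 0.0,
        lambda2: float = 0.0,
        beta_r=None,
        restrict=None,
        max_iter: int = 2000,
        tol: float = 1e-9,
    ):
        self.n_covariates = n_covariates
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.beta_r = beta_r
        self.restrict = restrict
        self.max_iter = max_iter
        self.tol = tol

    # ----- layout helpers -------------------------------------------------
    def _split_x(self, X):
        X = np.asarray(X, dtype=float)
        k = self.n_covariates
        if X.shape[1] < k + 3:
            raise ValueError("X needs exposure, covariates and >= 2 taxa columns")
        r = X[:, 0]
        xc = X[:, 1 : 1 + k]
        m = X[:, 1 + k :]
        if np.any(m <= 0):
            raise ValueError("compositions must be strictly positive (replace zeros first)")
        return r, xc, m

    def fit(self, X, y):
        r, xc, m = self._split_x(X)
        y = np.asarray(y, dtype=float)
        n, j = m.shape
        logm = np.log(m)
        if self.restrict is not None:
            active = np.zeros(j, dtype=bool)
            active[np.asarray(self.restrict, dtype=int)] = True
        else:
            active = np.ones(j, dtype=bool)
        self.n_features_in_ = X.shape[1]
        self.n_taxa_ = j

        if self.lambda1 == 0.0 and self.lambda2 == 0.0:
            self._fit_ols(r, xc, logm, y, active)
        else:
            self._fit_prox(r, xc, logm, y, active)

        zt = _ZERO_TOL
        self.selected_ = (np.abs(self.alpha_m_) > zt) | (np.abs(self.alpha_c_) > zt)
        return self

    # ----- unpenalized constrained least squares --------------------------
    def _fit_ols(self, r, xc, logm, y, active):
        n, j = logm.shape
        ja = int(active.sum())
        cols = [np.ones((n, 1)), xc, r[:, None]]
        if ja >= 2:
            u = sum_zero_basis(ja)
            lm = logm[:, active]
            cols += [lm @ u, (lm * r[:, None]) @ u]
        else:
            u = np.zeros((ja, 0))
        z = np.hstack(cols)
        p = z.shape[1]
        if n <= p:
            raise ValueError(
                f"need more samples than the {p} free parameters (got n={n})"
            )
        gram = z.T @ z
        # tiny ridge jitter guards against exact collinearity
        theta = linalg.solve(gram + 1e-10 * np.eye(p), z.T @ y, assume_a="pos")
        resid = y - z @ theta
        dof = max(n - p, 1)
        sigma2 = float(resid @ resid) / dof
        k = xc.shape[1]
        self.alpha0_ = float(theta[0])
        self.alpha_x_ = theta[1 : 1 + k].copy()
        self.alpha_r_ = float(theta[1 + k])
        am = np.zeros(j)
        ac = np.zeros(j)
        if ja >= 2:
            q = u.shape[1]
            am[active] = u @ theta[2 + k : 2 + k + q]
            ac[active] = u @ theta[2 + k + q : 2 + k + 2 * q]
        self.alpha_m_ = am
        self.alpha_c_ = ac
        self.sigma_ = float(np.sqrt(sigma2))
        self.converged_ = True
        self.n_iter_ = 0
        # standard errors via the reduced-basis covariance
        cov_theta = sigma2 * linalg.inv(gram + 1e-10 * np.eye(p))
        se = {
            "alpha0": float(np.sqrt(cov_theta[0, 0])),
            "alpha_x": np.sqrt(np.diag(cov_theta)[1 : 1 + k]),
            "alpha_r": float(np.sqrt(cov_theta[1 + k, 1 + k])),
        }
        se_m = np.zeros(j)
        se_c = np.zeros(j)
        if ja >= 2:
            q = u.shape[1]
            cm = cov_theta[2 + k : 2 + k + q, 2 + k : 2 + k + q]
            cc = cov_theta[2 + k + q : 2 + k + 2 * q, 2 + k + q : 2 + k + 2 * q]
            se_m[active] = np.sqrt(np.clip(np.diag(u @ cm @ u.T), 0, None))
            se_c[active] = np.sqrt(np.clip(np.diag(u @ cc @ u.T), 0, None))
        se["alpha_m"] = se_m
        se["alpha_c"] = se_c
        self.se_ = se

    # ----- penalized fit --------------------------------------------------
    def _fit_prox(self, r, xc, logm, y, active):
        if not active.all():
            raise NotImplementedError(
                "taxa restriction is only supported for unpenalized refits"
            )
        n, j = logm.shape
        k = xc.shape[1]
        z = np.hstack([np.ones((n, 1)), xc, r[:, None], logm, logm * r[:, None]])
        gram = z.T @ z / n
        zy = z.T @ y / n
        yy = float(y @ y) / n
        lip = float(np.linalg.norm(gram, 2))
        lam1, lam2 = float(self.lambda1), float(self.lambda2)
        if lam2 > 0:
            if self.beta_r is None:
                raise ValueError("lambda2 > 0 requires beta_r group weights")
            br = np.abs(np.asarray(self.beta_r, dtype=float))
            if br.shape != (j,):
                raise ValueError("beta_r must have one entry per taxon")
            br = np.maximum(br, 1e-8)
        else:
            br = np.zeros(j)
        w0 = getattr(self, "warm_start_coef_", None)
        p = z.shape[1]
        if w0 is None or w0.shape != (p,):
            w0 = np.zeros(p)
        w, obj, nit, converged = fista_sparse_group(
            gram, zy, yy, br**2, 2 + k, j, lam1, lam2,
            np.ascontiguousarray(w0, dtype=float), self.max_iter, self.tol, lip,
        )
        self.warm_start_coef_ = w.copy()
        self._unpack_penalized(w, y, z, k, j, obj, nit, converged)

    def _unpack_penalized(self, w, y, z, k, j, obj, nit, converged):
        n = len(y)
        am = w[2 + k : 2 + k + j].copy()
        ac = w[2 + k + j : 2 + k + 2 * j].copy()
        am[np.abs(am) < _ZERO_TOL] = 0.0
        ac[np.abs(ac) < _ZERO_TOL] = 0.0
        self.alpha0_ = float(w[0])
        self.alpha_x_ = w[1 : 1 + k].copy()
        self.alpha_r_ = float(w[1 + k])
        self.alpha_m_ = am
        self.alpha_c_ = ac
        resid = y - z @ w
        nz = 2 + k + int((am != 0).sum()) + int((ac != 0).sum())
        self.sigma_ = float(np.sqrt(resid @ resid / max(n - nz, 1)))
        self.converged_ = converged
        self.n_iter_ = nit
        self.objective_ = obj
        self.se_ = None

    def predict(self, X):
        check_is_fitted(self, "alpha_m_")
        r, xc, m = self._split_x(X)
        logm = np.log(m)
        return (
            self.alpha0_
            + xc @ self.alpha_x_
            + self.alpha_r_ * r
            + logm @ self.alpha_m_
            + (logm * r[:, None]) @ self.alpha_c_
        )

    def params_(self) -> OutcomeParams:
        check_is_fitted(self, "alpha_m_")
        return OutcomeParams(
            alpha0=self.alpha0_,
            alpha_x=self.alpha_x_,
            alpha_r=self.alpha_r_,
            alpha_m=self.alpha_m_,
            alpha_c=self.alpha_c_,
            sigma=self.sigma_,
            converged=self.converged_,
            se=getattr(self, "se_", None),
        )


# ---------------------------------------------------------------------------
# StudyData-level wrappers


def _study_design(data):
    return np.hstack([data.r[:, None], data.x, data.m])


def design_matrix(data):
    """Reduced design matrix [1, X, R, logM U, R logM U] and column map."""
    n, j = data.m.shape
    k = data.x.shape[1]
    u = sum_zero_basis(j)
    logm = np.log(data.m)
    z = np.hstack(
        [np.ones((n, 1)), data.x, data.r[:, None], logm @ u, (logm * data.r[:, None]) @ u]
    )
    colmap = {
        "intercept": [0],
        "covariates": list(range(1, 1 + k)),
        "exposure": [1 + k],
        "log_composition": list(range(2 + k, 1 + k + j)),
        "interaction": list(range(1 + k + j, k + 2 * j)),
    }
    return z, colmap, u


def fit_ols(data) -> OutcomeParams:
    """Unpenalized constrained least-squares fit of the outcome model."""
    est = LogContrastRegression(n_covariates=data.x.shape[1])
    est.fit(_study_design(data), data.y)
    return est.params_()


def fit_ols_arrays(r, xc, logm, y, restrict=None) -> OutcomeParams:
    """Array-level constrained OLS (log-compositions passed directly)."""
    j = logm.shape[1]
    est = LogContrastRegression(n_covariates=xc.shape[1])
    active = np.ones(j, dtype=bool)
    if restrict is not None:
        active[:] = False
        active[np.asarray(restrict, dtype=int)] = True
    est._fit_ols(r, xc, logm, y, active)
    est.selected_ = (np.abs(est.alpha_m_) > _ZERO_TOL) | (np.abs(est.alpha_c_) > _ZERO_TOL)
    return est.params_()


def default_lambda_grid(data, beta_r=None, n_lambda1: int = 6, ratio: float = 0.5):
    """Data-driven (lambda1, lambda2) candidates.

    lambda1 values are fractions of the smallest L1 weight that zeroes
    every composition coefficient at the null (taxa-free) fit; the
    group weight is tied to it as ``lambda2 = ratio * lambda1`` (the
    usual sparse-group parametrization), so the path is 1-dimensional.
    """
    return lambda_grid_arrays(
        data.r, data.x, np.log(data.m), data.y, n_lambda1=n_lambda1, ratio=ratio
    )


def lambda_grid_arrays(r, xc, logm, y, n_lambda1: int = 6, ratio: float = 0.5):
    n = len(y)
    # residual from the taxa-free model
    xz = np.hstack([np.ones((n, 1)), xc, r[:, None]])
    coef, *_ = np.linalg.lstsq(xz, y, rcond=None)
    resid = y - xz @ coef
    g_m = logm.T @ resid / n
    g_c = (logm * r[:, None]).T @ resid / n
    lam_max = max(
        np.abs(g_m - g_m.mean()).max(), np.abs(g_c - g_c.mean()).max(), 1e-8
    )
    grid = []
    for frac in np.geomspace(0.6, 0.08, n_lambda1):
        l1 = frac * lam_max
        grid.append((l1, ratio * l1))
    return grid


def fit_penalized(data, cfg: PenaltyConfig, beta_r=None):
    """Sparse-group penalized fit; returns (OutcomeParams, selected index array).

    When ``cfg.grid`` is given (or ``cfg.lambda1`` is None) the penalty
    pair is chosen by the configured criterion (BIC by default) over the
    candidate grid, warm-starting along the path.
    """
    grid = cfg.grid
    if grid is None and cfg.lambda1 is not None:
        grid = [(cfg.lambda1, cfg.lambda2)]
    if grid is None:
        grid = default_lambda_grid(data, beta_r)
    return penalized_path_arrays(
        data.r, data.x, np.log(data.m), data.y, grid, beta_r,
        criterion=cfg.criterion, max_iter=cfg.max_iter, tol=cfg.tol,
    )


def penalized_path_arrays(
    r, xc, logm, y, grid, beta_r=None, criterion="ebic", max_iter=2000, tol=1e-9,
    warm_cache=None,
):
    """Array-level penalty path with shared design; see :func:`fit_penalized`."""
    n, j = logm.shape
    k = xc.shape[1]
    z = np.hstack([np.ones((n, 1)), xc, r[:, None], logm, logm * r[:, None]])
    gram = z.T @ z / n
    zy = z.T @ y / n
    yy = float(y @ y) / n
    lip = float(np.linalg.norm(gram, 2))
    p = z.shape[1]
    need_group = any(l2 > 0 for _, l2 in grid)
    if need_group:
        if beta_r is None:
            raise ValueError("group penalty requires beta_r weights")
        br2 = np.maximum(np.abs(np.asarray(beta_r, dtype=float)), 1e-8) ** 2
    else:
        br2 = np.zeros(j)
    zeros_br2 = np.zeros(j)
    warm = None
    if warm_cache is not None:
        warm = warm_cache.get("w")
    if warm is None or warm.shape != (p,):
        warm = np.zeros(p)
    first_w = None
    best = None
    for lam1, lam2 in grid:
        w, obj, nit, conv = fista_sparse_group(
            gram, zy, yy, br2 if lam2 > 0 else zeros_br2, 2 + k, j,
            float(lam1), float(lam2), warm, max_iter, tol, lip,
        )
        warm = w
        if first_w is None:
            first_w = w
        am = w[2 + k : 2 + k + j].copy()
        ac = w[2 + k + j :].copy()
        am[np.abs(am) < _ZERO_TOL] = 0.0
        ac[np.abs(ac) < _ZERO_TOL] = 0.0
        rss = n * max(float(w @ (gram @ w) - 2.0 * (zy @ w) + yy), 1e-300)
        df = 2 + k + max(int((am != 0).sum()) - 1, 0) + max(int((ac != 0).sum()) - 1, 0)
        if criterion == "ebic":
            # extended BIC: extra df * 2 * log(2J) guards against the
            # over-selection plain BIC shows on correlated log-contrasts
            score = n * np.log(rss / n) + df * (np.log(n) + 2.0 * np.log(2 * j))
        elif criterion == "bic":
            score = n * np.log(rss / n) + df * np.log(n)
        elif criterion == "aic":
            score = n * np.log(rss / n) + 2 * df
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        if best is None or score < best[0]:
            sigma = float(np.sqrt(rss / max(n - df, 1)))
            best = (score, w.copy(), am, ac, sigma, conv)
    if warm_cache is not None:
        warm_cache["w"] = first_w
    _, w, am, ac, sigma, conv = best
    params = OutcomeParams(
        alpha0=float(w[0]),
        alpha_x=w[1 : 1 + k].copy(),
        alpha_r=float(w[1 + k]),
        alpha_m=am,
        alpha_c=ac,
        sigma=sigma,
        converged=conv,
    )
    selected = np.flatnonzero((np.abs(am) > _ZERO_TOL) | (np.abs(ac) > _ZERO_TOL))
    return params, selected


def refit_unpenalized(data, selected) -> OutcomeParams:
    """OLS refit with composition coefficients outside ``selected`` fixed at 0.

    With fewer than two selected taxa the sum-to-zero constraint forces
    all composition coefficients to zero and the model reduces to
    ``Y ~ 1 + X + R``.
    """
    selected = np.asarray(selected, dtype=int)
    est = LogContrastRegression(
        n_covariates=data.x.shape[1],
        restrict=selected if selected.size >= 2 else np.array([], dtype=int),
    )
    est.fit(_study_design(data), data.y)
    return est.params_()
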