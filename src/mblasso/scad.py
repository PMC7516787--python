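"""SCAD-penalized least squares via cyclic coordinate descent.

The objective minimized is the penalized mean-squared loss

    xi(beta) = (1/2n) sum_i (y_i - sum_j X_ij beta_j)^2
               + sum_j rho_{lambda,gamma}(|beta_j|)

(the ncvreg convention: the 1/2n factor puts lambda on the scale of the
standardized coefficients, so the penalty's bias-free outer branch is
actually reachable along the path) with the smoothly clipped absolute
deviation (SCAD) penalty

    rho(b) = lambda*b                                  if b < lambda
           = -(b^2 - 2*gamma*lambda*b + lambda^2)
             / (2*(gamma - 1))                         if lambda <= b < gamma*lambda
           = (gamma + 1)*lambda^2 / 2                  if b >= gamma*lambda

for b = |beta_j| >= 0 and gamma > 2. The folded-concave shape penalizes small
coefficients like the Lasso but leaves large ones nearly unbiased, which is
what makes it suitable for refining marginally screened SNP sets.

Columns are standardized to unit variance internally (intercept handled by
centering, unpenalized); coefficients are reported back on the original
scale. Each coordinate update is the exact minimizer of the piecewise
quadratic one-dimensional restriction of xi, so the objective is
non-increasing across sweeps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold


def scad_penalty(beta, lam: float, gamma: float = 3.7):
    """SCAD penalty rho_{lambda,gamma}(|beta|), elementwise."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if gamma <= 2:
        raise ValueError("gamma must exceed 2")
    b = np.abs(np.asarray(beta, dtype=float))
    out = np.where(
        b < lam,
        lam * b,
        np.where(
            b < gamma * lam,
            -(b**2 - 2 * gamma * lam * b + lam**2) / (2 * (gamma - 1)),
            (gamma + 1) * lam**2 / 2,
        ),
    )
    return out if out.ndim else float(out)


def scad_prox(u: float, c: float, lam: float, gamma: float = 3.7) -> float:
    """Exact minimizer over beta of  c*(beta - u)^2 + rho_{lambda,gamma}(|beta|).

    ``c`` is the curvature of the quadratic part (for a standardized column
    in the RSS objective, c = sum_i x_ij^2). Piecewise-analytic: the three
    penalty branches each give a candidate stationary point which is clamped
    into its branch; the best of those and beta = 0 wins. The minimizer
    shares the sign of ``u``.
    """
    if c <= 0:
        raise ValueError("quadratic curvature c must be positive")
    a = abs(u)
    sign = 1.0 if u >= 0 else -1.0

    def f(b):  # objective restricted to beta = sign*b, b >= 0
        return c * (b - a) ** 2 + scad_penalty(b, lam, gamma)

    candidates = [0.0]
    # branch 1: b in [0, lam)
    b1 = a - lam / (2 * c)
    candidates.append(min(max(b1, 0.0), np.nextafter(lam, 0.0)))
    # branch 2: b in [lam, gamma*lam); stationary point of
    # c*(b-a)^2 - (b^2 - 2*gamma*lam*b + lam^2)/(2*(gamma-1))
    denom = 2 * c - 1.0 / (gamma - 1)
    if denom > 0:
        b2 = (2 * c * a - gamma * lam / (gamma - 1)) / denom
        candidates.append(min(max(b2, lam), np.nextafter(gamma * lam, lam)))
    else:  # concave branch: optimum at an endpoint
        candidates.extend([lam, np.nextafter(gamma * lam, lam)])
    # branch 3: b >= gamma*lam, penalty constant
    candidates.append(max(a, gamma * lam))

    best = min(candidates, key=f)
    return sign * best


@njit(cache=True)
def _prox_nb(u, c, lam, gamma):  # pragma: no cover - numba kernel
    """Numba twin of :func:`scad_prox` (same piecewise minimization)."""
    a = abs(u)
    sign = 1.0 if u >= 0 else -1.0
    glam = gamma * lam
    best_b = 0.0
    best_f = c * a * a  # objective at beta = 0
    # branch 1: [0, lam)
    b = a - lam / (2.0 * c)
    if b < 0.0:
        b = 0.0
    elif b > lam:
        b = lam * (1.0 - 1e-16)
    f = c * (b - a) ** 2 + lam * b
    if f < best_f:
        best_f = f
        best_b = b
    # branch 2: [lam, gamma*lam)
    denom = 2.0 * c - 1.0 / (gamma - 1.0)
    if denom > 0.0:
        b = (2.0 * c * a - glam / (gamma - 1.0)) / denom
        if b < lam:
            b = lam
        elif b > glam:
            b = glam * (1.0 - 1e-16)
        pen = -(b * b - 2.0 * glam * b + lam * lam) / (2.0 * (gamma - 1.0))
        f = c * (b - a) ** 2 + pen
        if f < best_f:
            best_f = f
            best_b = b
    else:
        for b in (lam, glam * (1.0 - 1e-16)):
            pen = -(b * b - 2.0 * glam * b + lam * lam) / (2.0 * (gamma - 1.0))
            f = c * (b - a) ** 2 + pen
            if f < best_f:
                best_f = f
                best_b = b
    # branch 3: [gamma*lam, inf), constant penalty
    b = a if a > glam else glam
    f = c * (b - a) ** 2 + (gamma + 1.0) * lam * lam / 2.0
    if f < best_f:
        best_f = f
        best_b = b
    return sign * best_b


@njit(cache=True)
def _pen_nb(b, lam, gamma):  # pragma: no cover - numba kernel
    """SCAD penalty at |b| (numba twin of :func:`scad_penalty`)."""
    b = abs(b)
    if b < lam:
        return lam * b
    if b < gamma * lam:
        return -(b * b - 2.0 * gamma * lam * b + lam * lam) / (2.0 * (gamma - 1.0))
    return (gamma + 1.0) * lam * lam / 2.0


@njit(cache=True)
def _cd_path_nb(G, Xty, diag, curv, lambdas, gamma, tol, tol_obj,
                max_sweeps, df_stop):  # pragma: no cover - numba kernel
    """Warm-started coordinate descent along a decreasing lambda path.

    Gram-matrix updates with an active-set strategy: one full sweep, then
    cycle the nonzero set to convergence, then verify with a full sweep.
    Each coordinate update minimizes the exact 1-D restriction, so the
    objective never increases; a sweep improving it by less than
    ``tol_obj`` also counts as converged (the nonconvex prox can 2-cycle
    between equal-objective solutions without meeting the coefficient
    tolerance). The path stops once a solution carries more than
    ``df_stop`` nonzero coefficients (near-saturated fits; see caller).
    Returns (betas, sweeps_used, converged, n_done).
    """
    m = G.shape[0]
    n_lam = lambdas.shape[0]
    beta = np.zeros(m)
    resid_corr = Xty.copy()  # X^T (y - X beta)
    betas = np.zeros((n_lam, m))
    sweeps_used = np.zeros(n_lam, dtype=np.int64)
    conv = np.ones(n_lam, dtype=np.bool_)
    for li in range(n_lam):
        lam = lambdas[li]
        sweeps = 0
        done = False
        while not done:
            # full sweep over all coordinates
            sweeps += 1
            max_delta = 0.0
            obj_drop = 0.0
            for j in range(m):
                bj = beta[j]
                u = resid_corr[j] / diag[j] + bj
                new = _prox_nb(u, curv[j], lam, gamma)
                if new != bj:
                    d = new - bj
                    for t in range(m):
                        resid_corr[t] -= G[j, t] * d
                    beta[j] = new
                    if abs(d) > max_delta:
                        max_delta = abs(d)
                    obj_drop += (curv[j] * ((bj - u) ** 2 - (new - u) ** 2)
                                 + _pen_nb(bj, lam, gamma)
                                 - _pen_nb(new, lam, gamma))
            if max_delta < tol or obj_drop < tol_obj:
                done = True
                break
            if sweeps >= max_sweeps:
                conv[li] = False
                done = True
                break
            # inner cycles on the active set only
            active = np.flatnonzero(beta)
            while active.shape[0] > 0 and sweeps < max_sweeps:
                sweeps += 1
                max_delta = 0.0
                obj_drop = 0.0
                for idx in range(active.shape[0]):
                    j = active[idx]
                    bj = beta[j]
                    u = resid_corr[j] / diag[j] + bj
                    new = _prox_nb(u, curv[j], lam, gamma)
                    if new != bj:
                        d = new - bj
                        for t in range(m):
                            resid_corr[t] -= G[j, t] * d
                        beta[j] = new
                        if abs(d) > max_delta:
                            max_delta = abs(d)
                        obj_drop += (curv[j] * ((bj - u) ** 2 - (new - u) ** 2)
                                     + _pen_nb(bj, lam, gamma)
                                     - _pen_nb(new, lam, gamma))
                if max_delta < tol or obj_drop < tol_obj:
                    break
        betas[li] = beta
        sweeps_used[li] = sweeps
        if np.count_nonzero(beta) > df_stop:
            return betas, sweeps_used, conv, li + 1
    return betas, sweeps_used, conv, n_lam


@dataclass
class ScadFit:
    """Result of a SCAD path fit at the selected lambda.

    ``beta_hat`` is on the original covariate scale; ``beta_std`` and
    ``objective`` refer to the internally standardized problem, so that
    ``objective`` can be re-derived from ``beta_std`` alone.
    """

    beta_hat: np.ndarray
    intercept: float
    lam: float
    gamma: float
    nonzero: np.ndarray
    objective: float
    beta_std: np.ndarray
    n_sweeps: int
    converged: bool


class ScadRegressor(RegressorMixin, BaseEstimator):
    """Linear regression with the SCAD folded-concave penalty.

    Parameters
    ----------
    gamma : float, default 3.7
        Shrinkage parameter of the penalty (must exceed 2); 3.7 is the
        value recommended in the original SCAD work.
    lambda_strategy : {"bic", "cv", "fixed"}, default "bic"
        How to pick lambda on the path. "bic": extended BIC (EBIC,
        gamma = 0.5) evaluated on the least-squares refit of each path
        support — deterministic, and robust on marginally screened panels
        where m approaches n. "cv": k-fold cross-validated prediction
        error. "fixed": solve down to ``lambda_value`` and keep that fit.
    lambda_value : float or None
        The penalty level used when lambda_strategy="fixed".
    n_lambda : int, default 100
        Number of path points, log-spaced from lambda_max (smallest lambda
        with an all-zero solution) down to lambda_min_ratio * lambda_max.
    lambda_min_ratio : float, default 1e-3
    cv : int, default 5
        Fold count when lambda_strategy="cv".
    tol : float, default 1e-7
        Convergence: max absolute coefficient change per sweep (on the
        internally doubly standardized problem).
    tol_obj : float, default 1e-10
        Secondary convergence rule on the per-sweep objective decrease;
        breaks equal-objective cycles of the nonconvex updates.
    max_sweeps : int, default 10_000
        Sweep cap per lambda; non-convergence warns and keeps the best
        iterate.
    random_state : int or None
        Seeds the CV fold shuffle only.

    Internally both the columns of X and y are standardized; reported
    coefficients are on the original scales and the intercept is
    unpenalized (handled by centering). ``lambda_`` and ``objective_``
    refer to the standardized problem.
    """

    def __init__(self, gamma=3.7, lambda_strategy="bic", lambda_value=None,
                 n_lambda=100, lambda_min_ratio=1e-3, cv=5, tol=1e-7,
                 tol_obj=1e-10, max_sweeps=10_000, random_state=None):
        self.gamma = gamma
        self.lambda_strategy = lambda_strategy
        self.lambda_value = lambda_value
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.tol = tol
        self.tol_obj = tol_obj
        self.max_sweeps = max_sweeps
        self.random_state = random_state

    # -- core path solver on a standardized design ------------------------
    def _cd_path(self, Xs, ys, lambdas, gamma, tol, max_sweeps):
        """Coordinate descent with warm starts along a decreasing path.

        Uses Gram-matrix (covariance) updates inside a compiled kernel.
        Returns (betas: n_done x m, sweeps, converged flags); the path may
        stop early once fits become near-saturated (df > 90% of min(n, m)),
        a region no selection rule here can pick but where the nonconvex
        descent converges very slowly.
        """
        n, m = Xs.shape
        G = np.ascontiguousarray(Xs.T @ Xs)
        Xty = Xs.T @ ys
        diag = np.diag(G).copy()
        diag[diag <= 0] = 1.0  # zero-variance columns stay at 0 anyway
        curv = diag / (2.0 * n)  # curvature of the (1/2n) RSS term
        # saturation only threatens when the panel size approaches n
        df_stop = m if m <= 0.9 * n else max(1, int(0.9 * n))
        lambdas = np.asarray(lambdas, dtype=float)
        betas, sweeps_used, conv, n_done = _cd_path_nb(
            G, Xty, diag, curv, lambdas, gamma, tol, self.tol_obj,
            max_sweeps, df_stop)
        betas = betas[:n_done]
        sweeps_used = sweeps_used[:n_done]
        conv = conv[:n_done]
        if not conv.all():
            bad = lambdas[:n_done][~conv]
            warnings.warn(
                "SCAD coordinate descent did not converge at "
                f"{bad.size} lambda value(s) (smallest {bad.min():.4g}); "
                "keeping best iterates"
            )
        return betas, sweeps_used, conv

    def _select_ebic(self, Xs, ys, betas, n, m):
        """Refitted extended BIC along the path.

        Each path support is refit by OLS (removing the penalization bias
        that would otherwise make sparse fits near lambda_max look poor),
        then scored by n log(RSS/n) + df (log n + log m) — the EBIC with
        gamma = 0.5. Supports denser than 3n/4 are excluded. Ties (the
        same support over a lambda stretch) resolve to the smallest
        lambda, where the surviving coefficients are least biased.
        """
        crit = np.full(len(betas), np.inf)
        cache: dict = {}
        df_cap = max(1, int(0.75 * n))
        for i, b in enumerate(betas):
            sup = np.flatnonzero(b)
            key = sup.tobytes()
            if key in cache:
                crit[i] = cache[key]
                continue
            df = sup.size
            if df == 0:
                rss = float(ys @ ys)
            elif df > df_cap:
                cache[key] = np.inf
                continue
            else:
                coef, _, _, _ = np.linalg.lstsq(Xs[:, sup], ys, rcond=None)
                r = ys - Xs[:, sup] @ coef
                rss = float(r @ r)
            val = (n * np.log(max(rss, 1e-300) / n)
                   + df * (np.log(n) + np.log(m)))
            cache[key] = val
            crit[i] = val
        ties = np.flatnonzero(crit <= crit.min() + 1e-9)
        return int(ties[-1])

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be n x m with n matching len(y)")
        n, m = X.shape
        if n < 2:
            raise ValueError("need at least 2 observations")
        if m < 1:
            raise ValueError("need at least 1 feature")
        if self.gamma <= 2:
            raise ValueError("gamma must exceed 2")

        x_mean = X.mean(axis=0)
        x_scale = X.std(axis=0)
        const = x_scale == 0
        x_scale = np.where(const, 1.0, x_scale)
        Xs = (X - x_mean) / x_scale
        y_mean = y.mean()
        y_scale = y.std()
        if y_scale == 0:
            y_scale = 1.0
        ys = (y - y_mean) / y_scale

        corr0 = np.abs(Xs.T @ ys)
        lam_max = corr0.max() / n  # all-zero solution first stable here
        if lam_max <= 0:  # y constant: all-zero fit at any lambda
            lam_max = 1.0
        if self.lambda_strategy == "fixed":
            if self.lambda_value is None or self.lambda_value <= 0:
                raise ValueError("lambda_strategy='fixed' needs a positive "
                                 "lambda_value")
            lam_lo = float(self.lambda_value)
            if lam_lo >= lam_max:
                lambdas = np.array([lam_lo])
            else:
                lambdas = np.geomspace(lam_max, lam_lo, self.n_lambda)
        else:
            lambdas = np.geomspace(lam_max, self.lambda_min_ratio * lam_max,
                                   self.n_lambda)

        betas, sweeps, conv = self._cd_path(Xs, ys, lambdas, self.gamma,
                                            self.tol, self.max_sweeps)
        lambdas = lambdas[:len(betas)]  # path may stop before saturation

        if self.lambda_strategy == "bic":
            best = self._select_ebic(Xs, ys, betas, n, m)
        elif self.lambda_strategy == "fixed":
            best = len(betas) - 1
        elif self.lambda_strategy == "cv":
            rng = np.random.default_rng(self.random_state)
            kf = KFold(n_splits=self.cv, shuffle=True,
                       random_state=int(rng.integers(2**31 - 1)))
            cv_err = np.zeros(len(lambdas))
            n_eval = len(lambdas)
            for tr, te in kf.split(Xs):
                b_fold, _, _ = self._cd_path(Xs[tr], ys[tr], lambdas,
                                             self.gamma, self.tol,
                                             self.max_sweeps)
                n_eval = min(n_eval, len(b_fold))
                pred = b_fold @ Xs[te].T
                cv_err[:len(b_fold)] += (
                    (ys[te][None, :] - pred) ** 2).sum(axis=1)
            best = int(np.argmin(cv_err[:n_eval]))
        else:
            raise ValueError(
                "lambda_strategy must be 'bic', 'cv' or 'fixed'")

        beta_std = betas[best]
        coef = np.where(const, 0.0, beta_std * y_scale / x_scale)
        self.coef_ = coef
        self.intercept_ = y_mean - float(x_mean @ coef)
        self.lambda_ = float(lambdas[best])
        self.lambda_path_ = lambdas
        self.coef_std_ = beta_std
        self.y_scale_ = float(y_scale)
        self.nonzero_ = np.flatnonzero(beta_std != 0)
        rss_best = float(((ys - Xs @ beta_std) ** 2).sum())
        self.objective_ = rss_best / (2.0 * n) + float(
            np.sum(scad_penalty(beta_std, self.lambda_, self.gamma))
        )
        self.n_sweeps_ = int(sweeps[best])
        self.converged_ = bool(conv[best])
        self.n_features_in_ = m
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_


def scad_fit(y, X_sub, gamma: float = 3.7, lambda_strategy: str = "bic",
             **kwargs) -> ScadFit:
    """Functional wrapper: fit SCAD on a candidate design, return a ScadFit."""
    est = ScadRegressor(gamma=gamma, lambda_strategy=lambda_strategy, **kwargs)
    est.fit(X_sub, y)
    return ScadFit(
        beta_hat=est.coef_,
        intercept=est.intercept_,
        lam=est.lambda_,
        gamma=gamma,
        nonzero=est.nonzero_,
        objective=est.objective_,
        beta_std=est.coef_std_,
        n_sweeps=est.n_sweeps_,
        converged=est.converged_,
    )
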